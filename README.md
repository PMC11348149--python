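# aopmoa

Network-toxicology toolkit that converts exposure transcriptomics into
adverse-outcome-pathway (AOP) based mechanism-of-action (MOA) networks.

Stages:

1. **Framework input** — exposed-vs-control contrasts with top/bottom
   deregulated seed-gene selection (`expression_io`), or benchmark-dose
   (BMD) gene selection for dose series (`dose_response`).
2. **Co-expression network inference** — a Hotelling T² test on the
   bivariate replicate means of every seed-gene pair, FDR-adjusted, keeping
   edges below the 5th percentile of the tested p distribution
   (`coexpression`).
3. **Topological KE enrichment** — key events scored by the average
   shortest-path length of their annotated genes on the input network
   against size-matched random node sets, plus the classic Fisher gene-set
   enrichment baseline (`ke_enrichment`).
4. **MOA reconstruction** — sequential filtering of enriched KEs,
   prioritisation of plausible MIEs/AOs by gene-level p-values and AOP
   distance, and assembly of the induced AOP subgraph (`moa_builder`).
5. **Scores & comparison** — completeness/connectivity information scores
   and a biological-system similarity score (`moa_scores`); edge-based
   consensus distances, consensus clustering, Ward clustering of MOAs,
   hypergeometric overrepresented-edge extraction and weighted-KS edge-set
   (pathway) enrichment (`cohort_comparison`).

The AOP knowledge layer (`aop_knowledge`) loads the event network and
KE→gene annotation from tab-separated files, merges redundant events by
gene-set Jaccard similarity, and answers event-distance queries.
`synthetic_fixtures` generates seeded toy AOP networks and expression
studies with planted co-deregulated MIE→KE→AO chains so the whole pipeline
runs without any external download.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (statistical
oracles, null calibrations, planted-mechanism recovery, determinism).

## CLI

All stages are exposed as `aopmoa` subcommands; every tabular output
carries a provenance header (version, config hash, seed) and seeded reruns
are byte-identical.

```sh
aopmoa simulate --seed 0 --out-dir fx                       # synthetic fixture
aopmoa infer-network --matrix fx/matrix.tsv --meta fx/meta.tsv --out-dir run
aopmoa enrich --network-edges run/network_edges.tsv \
    --aop-edges fx/aop_edges.tsv --aop-annotation fx/aop_annotation.tsv \
    --out run/enrichment.tsv --seed 0
aopmoa reconstruct-moa --enrichment run/enrichment.tsv \
    --contrast run/contrast.tsv --aop-edges fx/aop_edges.tsv \
    --aop-annotation fx/aop_annotation.tsv --out-dir run
aopmoa score --moa run/moa.graphml --out run/scores.json
aopmoa compare --network-edges run/network_edges.tsv ... --out dist.tsv
aopmoa cluster --distances dist.tsv --k 2 --out labels.tsv
aopmoa bmd-filter --matrix dose_matrix.tsv --meta dose_meta.tsv --out bmd.tsv
```

Input formats: expression matrix (TSV, first column gene id), sample
metadata (TSV: sample_id, condition ∈ {control, exposed}, exposure, dose,
time), AOP edge table (TSV: upstream_event_id, downstream_event_id,
upstream_type, downstream_type), annotation (TSV: event_id, gene), pathway
sets (GMT). Networks are exported as GraphML plus flat TSV edge lists;
dendrograms as Newick.

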