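"""Seeded synthetic fixtures: toy AOP networks with planted MIE->KE->AO
chains and matched control/exposed expression studies in which each planted
event's gene module is co-deregulated through a shared latent factor.

These generators are the test bed for every downstream stage and are also
exposed through the CLI so full pipelines can run without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aop_knowledge import AOPEvent, AOPNetwork
from .errors import ParameterError
from .expression_io import ExpressionStudy, write_expression_study


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 500
    n_chains: int = 1
    module_size: int = 12
    n_decoy_chains: int = 8
    decoy_set_size: int = 8
    effect_size: float = 2.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.n_replicates < 2:
            raise ParameterError("n_replicates must be >= 2")
        needed = 3 * self.n_chains * self.module_size
        if needed > self.n_genes:
            raise ParameterError("planted chains exceed the gene universe")


def gene_universe(spec: FixtureSpec) -> list[str]:
    return [f"g{i:04d}" for i in range(spec.n_genes)]


def planted_chain_ids(spec: FixtureSpec) -> list[tuple[str, str, str]]:
    return [(f"MIE_P{c}", f"KE_P{c}", f"AO_P{c}") for c in range(spec.n_chains)]


def planted_modules(spec: FixtureSpec) -> dict[str, list[str]]:
    """Deterministic block assignment of module genes to planted events.

    Per chain: MIE and KE modules are up-shifted, the AO module down-shifted
    (sign handled in :func:`simulate_study`).
    """
    genes = gene_universe(spec)
    modules: dict[str, list[str]] = {}
    cursor = 0
    for mie, ke, ao in planted_chain_ids(spec):
        for eid in (mie, ke, ao):
            modules[eid] = genes[cursor : cursor + spec.module_size]
            cursor += spec.module_size
    return modules


def make_toy_aop(spec: FixtureSpec) -> AOPNetwork:
    """Typed event DAG: the planted chains plus decoy chains with random,
    planted-disjoint gene annotations."""
    rng = np.random.default_rng(spec.seed)
    modules = planted_modules(spec)
    planted_genes = {g for gs in modules.values() for g in gs}
    free_genes = sorted(set(gene_universe(spec)) - planted_genes)
    if spec.n_decoy_chains and len(free_genes) < spec.decoy_set_size:
        raise ParameterError("not enough free genes for decoy annotations")

    events, links = [], []
    for mie, ke, ao in planted_chain_ids(spec):
        for eid, etype in ((mie, "MIE"), (ke, "KE"), (ao, "AO")):
            events.append(
                AOPEvent(event_id=eid, event_type=etype, gene_set=frozenset(modules[eid]))
            )
        links += [(mie, ke), (ke, ao)]
    for c in range(spec.n_decoy_chains):
        ids = (f"MIE_D{c}", f"KE_D{c}", f"AO_D{c}")
        for eid, etype in zip(ids, ("MIE", "KE", "AO")):
            gs = rng.choice(free_genes, size=spec.decoy_set_size, replace=False)
            events.append(AOPEvent(event_id=eid, event_type=etype, gene_set=frozenset(gs)))
        links += [(ids[0], ids[1]), (ids[1], ids[2])]
    return AOPNetwork(events, links, annotation_source=f"toy:{spec.seed}")


def simulate_study(spec: FixtureSpec, aop: AOPNetwork | None = None) -> ExpressionStudy:
    """Control/exposed log-expression with planted co-deregulated modules.

    Controls are Normal(baseline_g, noise_sd).  Each planted event module is
    co-expressed at baseline through a signed shared latent factor (one draw
    per replicate and condition, loading +1/-1 alternately across the
    module's genes, standing in for most of the per-gene noise); exposure
    adds a common shift of mean ``effect_size`` to every module gene
    (MIE/KE modules up, AO modules down).  Opposite-loading module pairs
    therefore shift along their low-variance joint direction, which is what
    makes within-module pairs the strongest co-deregulation signal for the
    pairwise test.  Everything derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = gene_universe(spec)
    n = spec.n_replicates
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    ctrl = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    expo = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

    gene_index = {g: i for i, g in enumerate(genes)}
    modules = planted_modules(spec)
    resid_sd = spec.noise_sd / 5.0
    for mie, ke, ao in planted_chain_ids(spec):
        for eid, sign in ((mie, 1.0), (ke, 1.0), (ao, -1.0)):
            idx = [gene_index[g] for g in modules[eid]]
            loadings = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(idx))])
            for arr, shift in ((ctrl, 0.0), (expo, sign * spec.effect_size)):
                latent = rng.normal(0.0, spec.noise_sd, size=n)
                arr[idx, :] = (
                    baseline[idx][:, None]
                    + shift
                    + loadings[:, None] * latent[None, :]
                    + rng.normal(0.0, resid_sd, size=(len(idx), n))
                )

    cols = [f"ctrl_{r}" for r in range(n)] + [f"exp_{r}" for r in range(n)]
    matrix = pd.DataFrame(np.hstack([ctrl, expo]), index=pd.Index(genes, name="gene"), columns=cols)
    meta = pd.DataFrame(
        {
            "condition": ["control"] * n + ["exposed"] * n,
            "exposure": ["toy_exposure"] * 2 * n,
            "dose": [0.0] * n + [1.0] * n,
            "time": [24.0] * 2 * n,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionStudy(matrix=matrix, sample_meta=meta, study_id=f"toy_seed{spec.seed}")


def make_pathway_sets(spec: FixtureSpec, n_sets: int = 10, set_size: int = 12) -> dict:
    """Random gene sets over the fixture universe, for edge-set enrichment."""
    rng = np.random.default_rng(spec.seed + 2)
    genes = gene_universe(spec)
    return {
        f"PATH{i:03d}": set(rng.choice(genes, size=set_size, replace=False))
        for i in range(n_sets)
    }


def write_fixture_dir(spec: FixtureSpec, outdir) -> dict:
    """Write all standard framework inputs for one fixture to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aop = make_toy_aop(spec)
    study = simulate_study(spec, aop)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "meta": outdir / "meta.tsv",
        "aop_edges": outdir / "aop_edges.tsv",
        "aop_annotation": outdir / "aop_annotation.tsv",
        "pathways": outdir / "pathways.gmt",
    }
    write_expression_study(study, paths["matrix"], paths["meta"])
    edge_rows = []
    for u, v in sorted(aop.links):
        edge_rows.append(
            {
                "upstream_event_id": u,
                "downstream_event_id": v,
                "upstream_type": aop.events[u].event_type,
                "downstream_type": aop.events[v].event_type,
            }
        )
    pd.DataFrame(edge_rows).to_csv(paths["aop_edges"], sep="\t", index=False)
    ann_rows = [
        {"event_id": eid, "gene": g}
        for eid in sorted(aop.events)
        for g in sorted(aop.gene_set(eid))
    ]
    pd.DataFrame(ann_rows).to_csv(paths["aop_annotation"], sep="\t", index=False)
    with open(paths["pathways"], "w") as fh:
        for name, genes in sorted(make_pathway_sets(spec).items()):
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")
    return paths
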