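"""Key-event enrichment.

Two modes: the topological (shortest-path) enrichment of KE gene sets on an
input co-expression network against size-matched random node sets, and the
classic Fisher gene-list enrichment used as comparison baseline.  The
sequential filter applied before MOA reconstruction lives here too.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.stats import fisher_exact

from ._stats import bh_adjust, percentile_cutoff, welch_t_p
from .aop_knowledge import AOPNetwork
from .coexpression import CoexpressionNetwork
from .errors import ParameterError
from .expression_io import DEGSelection

RECORD_COLUMNS = [
    "event_id",
    "n_genes_annotated",
    "n_genes_in_network",
    "mean_sp_ke",
    "mean_sp_rand",
    "ratio",
    "p_avg",
    "p_adj",
    "enriched",
    "skip_reason",
]


def _distance_matrix(graph: nx.Graph) -> tuple[np.ndarray, dict]:
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr")
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return dist, index


def _pair_lengths(dist: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Finite pairwise shortest-path lengths among the given node indices."""
    ia, ib = np.triu_indices(len(idx), k=1)
    vals = dist[idx[ia], idx[ib]]
    return vals[np.isfinite(vals)]


def topological_enrichment(
    net: CoexpressionNetwork | nx.Graph,
    aop: AOPNetwork,
    n_draws: int = 1000,
    seed: int = 0,
    event_types: tuple = ("KE",),
) -> pd.DataFrame:
    """Score every annotated KE by its average pairwise shortest-path length
    on ``net`` against ``n_draws`` random node sets of the same size.

    For each draw, a Welch t-test compares the KE's finite path-length
    multiset with the draw's; ``p_avg`` averages the draw p-values and
    ``ratio`` = mean_sp_ke / mean(random averages).  ``enriched`` is the raw
    ratio < 1 call; ``p_adj`` is Benjamini-Hochberg over scored KEs.
    Disconnected pairs are excluded from all multisets; KEs (or draws) with
    fewer than 2 finite pairs are skipped.
    """
    if n_draws < 2:
        raise ParameterError("n_draws must be >= 2")
    graph = net.graph if isinstance(net, CoexpressionNetwork) else net
    if graph.number_of_nodes() == 0:
        raise ParameterError("input network is empty")
    rng = np.random.default_rng(seed)
    dist, index = _distance_matrix(graph)
    node_ids = np.arange(len(index))
    net_genes = set(index)

    records = []
    candidate_events = sorted(
        e for t in event_types for e in aop.event_ids_by_type(t) if aop.gene_set(e)
    )
    for eid in candidate_events:
        genes = aop.gene_set(eid)
        present = sorted(g for g in genes if g in net_genes)
        rec = {
            "event_id": eid,
            "n_genes_annotated": len(genes),
            "n_genes_in_network": len(present),
            "mean_sp_ke": np.nan,
            "mean_sp_rand": np.nan,
            "ratio": np.nan,
            "p_avg": np.nan,
            "p_adj": np.nan,
            "enriched": False,
            "skip_reason": "",
        }
        if len(present) < 2:
            rec["skip_reason"] = "fewer_than_2_genes_in_network"
            records.append(rec)
            continue
        idx = np.array([index[g] for g in present])
        ke_lengths = _pair_lengths(dist, idx)
        if ke_lengths.size < 2:
            rec["skip_reason"] = "fewer_than_2_connected_pairs"
            records.append(rec)
            continue
        size = len(present)
        # draws as one (n_draws, size) index matrix; per-draw finite-pair stats
        draws = np.empty((n_draws, size), dtype=int)
        for d in range(n_draws):
            draws[d] = rng.choice(node_ids, size=size, replace=False)
        ia, ib = np.triu_indices(size, k=1)
        lengths = dist[draws[:, ia], draws[:, ib]]  # (n_draws, n_pairs)
        finite = np.isfinite(lengths)
        counts = finite.sum(axis=1)
        valid = counts >= 2
        if not valid.any():
            rec["skip_reason"] = "no_valid_random_draws"
            records.append(rec)
            continue
        masked = np.ma.MaskedArray(lengths, mask=~finite)
        rmeans = masked.mean(axis=1).filled(np.nan)
        rvars = masked.var(axis=1, ddof=1).filled(np.nan)
        ps = welch_t_p(
            ke_lengths.mean(),
            ke_lengths.var(ddof=1),
            ke_lengths.size,
            rmeans[valid],
            rvars[valid],
            counts[valid],
        )
        rec["mean_sp_ke"] = float(ke_lengths.mean())
        rec["mean_sp_rand"] = float(np.mean(rmeans[valid]))
        rec["ratio"] = rec["mean_sp_ke"] / rec["mean_sp_rand"] if rec["mean_sp_rand"] > 0 else np.nan
        rec["p_avg"] = float(np.mean(ps))
        rec["enriched"] = bool(rec["ratio"] < 1)
        records.append(rec)

    out = pd.DataFrame(records, columns=RECORD_COLUMNS)
    scored = out["skip_reason"] == ""
    if scored.any():
        out.loc[scored, "p_adj"] = bh_adjust(out.loc[scored, "p_avg"].to_numpy())
    return out


def fisher_enrichment(
    degs: DEGSelection, aop: AOPNetwork, background: set
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment of ``degs`` against each
    annotated KE gene set, over the caller-supplied ``background``."""
    if not background:
        raise ParameterError("background must be nonempty")
    deg_set = set(degs.genes)
    if not deg_set <= set(background):
        raise ParameterError("DEG selection must be a subset of the background")
    bg = set(background)
    rows = []
    for eid in sorted(aop.annotated_events(min_genes=1)):
        ke = aop.gene_set(eid) & bg
        if not ke:
            continue
        a = len(deg_set & ke)
        b = len(deg_set - ke)
        c = len(ke - deg_set)
        d = len(bg) - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"event_id": eid, "overlap": a, "p": float(p)})
    out = pd.DataFrame(rows, columns=["event_id", "overlap", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def filter_enriched(
    records: pd.DataFrame,
    contrast: pd.DataFrame,
    aop: AOPNetwork,
    max_genes: int = 1000,
    alpha: float = 0.05,
    percentile: float = 5.0,
    lfc: float = 0.58,
    lfc_aggregate: str = "max",
) -> pd.DataFrame:
    """Sequential filter of scored enrichment records.

    1. drop KEs with more than ``max_genes`` annotated genes or adjusted
       p above ``alpha`` (also drops skipped/unenriched records);
    2. keep survivors whose ``p_avg`` is at or below the ``percentile``-th
       percentile of the survivors' ``p_avg`` distribution;
    3. drop KEs whose annotated genes never reach \\|logFC\\| >= ``lfc`` in
       the contrast (aggregate: max, or mean when configured).

    The stage at which the set became empty is recorded in
    ``result.attrs['empty_stage']``.
    """
    if lfc_aggregate not in ("max", "mean"):
        raise ParameterError("lfc_aggregate must be 'max' or 'mean'")
    out = records[records["skip_reason"] == ""].copy()
    out = out[
        (out["n_genes_annotated"] <= max_genes)
        & (out["p_adj"] <= alpha)
        & out["enriched"]
    ]
    result_attrs = {"empty_stage": ""}
    if out.empty:
        result_attrs["empty_stage"] = "stage1_size_and_fdr"
        out.attrs.update(result_attrs)
        return out
    cutoff = percentile_cutoff(out["p_avg"].to_numpy(), percentile)
    out = out[out["p_avg"] <= cutoff]
    if out.empty:
        result_attrs["empty_stage"] = "stage2_percentile"
        out.attrs.update(result_attrs)
        return out
    lfc_by_gene = dict(zip(contrast["gene"], contrast["logFC"].abs()))
    agg = max if lfc_aggregate == "max" else (lambda v: sum(v) / len(v))
    keep = []
    for eid in out["event_id"]:
        vals = [lfc_by_gene[g] for g in aop.gene_set(eid) if g in lfc_by_gene]
        keep.append(bool(vals) and agg(vals) >= lfc)
    out = out[np.array(keep, dtype=bool)]
    if out.empty:
        result_attrs["empty_stage"] = "stage3_logfc"
    out.attrs.update(result_attrs)
    return out.reset_index(drop=True)
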