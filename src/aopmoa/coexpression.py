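"""Per-exposure co-expression network inference.

Every unordered pair of seed genes is tested with a two-sample Hotelling T2
test on the bivariate (gene_a, gene_b) replicate means of the exposed vs
control groups.  Edges are the pairs whose raw p-value falls strictly below
the requested percentile of the tested-pair p distribution; FDR-adjusted
p-values are stored alongside for auditability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import TINY_P, bh_adjust, percentile_cutoff
from .errors import DegeneratePairError, ParameterError
from .expression_io import DEGSelection, ExpressionStudy, differential_expression

# relative tolerance for declaring a pooled 2x2 covariance singular
_SINGULAR_RTOL = 1e-12


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p: float


class CoexpressionNetwork:
    """Undirected gene graph: nodes carry ``logfc``, edges carry ``p``,
    ``p_adj`` and ``neglog_p`` = -log10(p)."""

    def __init__(self, graph: nx.Graph, exposure_id: str = "", tested_p: np.ndarray | None = None):
        for u, v in graph.edges():
            if u == v:
                raise ParameterError("self-edges are not allowed")
        self.graph = graph
        self.exposure_id = exposure_id
        #: raw p-values of every nondegenerate tested pair (audit trail for
        #: the percentile edge-selection rule); None when not inferred here
        self.tested_p = tested_p

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes())

    @property
    def edge_set(self) -> frozenset:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges())

    def to_edgelist_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": min(u, v),
                "gene_b": max(u, v),
                "p": d.get("p", np.nan),
                "p_adj": d.get("p_adj", np.nan),
                "neglog_p": d.get("neglog_p", np.nan),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "p", "p_adj", "neglog_p"])
        return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_edgelist_frame(
        cls, df: pd.DataFrame, logfc: dict | None = None, exposure_id: str = ""
    ) -> "CoexpressionNetwork":
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(
                row["gene_a"],
                row["gene_b"],
                p=float(row["p"]),
                p_adj=float(row.get("p_adj", np.nan)),
                neglog_p=float(row.get("neglog_p", -math.log10(max(row["p"], TINY_P)))),
            )
        for n in g.nodes():
            g.nodes[n]["logfc"] = float((logfc or {}).get(n, 0.0))
        return cls(g, exposure_id=exposure_id)

    @classmethod
    def from_graph(cls, graph: nx.Graph, exposure_id: str = "") -> "CoexpressionNetwork":
        return cls(graph.copy(), exposure_id=exposure_id)


def hotelling_pair_test(x_ctrl, y_ctrl, x_exp, y_exp) -> HotellingResult:
    """Two-sample Hotelling T2 test for one gene pair.

    ``x_*``/``y_*`` are the replicate vectors of the two genes in the control
    and exposed groups.  T2 uses the pooled 2x2 covariance; the p-value comes
    from the exact F(2, n1+n2-3) transform.
    """
    c = np.vstack([np.asarray(x_ctrl, float), np.asarray(y_ctrl, float)])
    e = np.vstack([np.asarray(x_exp, float), np.asarray(y_exp, float)])
    n1, n2 = c.shape[1], e.shape[1]
    if n1 < 3 or n2 < 3:
        raise ParameterError("need >= 3 replicates per group")
    d = e.mean(axis=1) - c.mean(axis=1)
    s1 = np.cov(c, ddof=1)
    s2 = np.cov(e, ddof=1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    det = sp[0, 0] * sp[1, 1] - sp[0, 1] ** 2
    scale = max(sp[0, 0] * sp[1, 1], 1.0)
    if det <= _SINGULAR_RTOL * scale:
        raise DegeneratePairError("singular pooled covariance")
    inv = np.array([[sp[1, 1], -sp[0, 1]], [-sp[0, 1], sp[0, 0]]]) / det
    t2 = float(n1 * n2 / (n1 + n2) * d @ inv @ d)
    df1, df2 = 2, n1 + n2 - 3
    f = (n1 + n2 - df1 - 1) / (df1 * (n1 + n2 - 2)) * t2
    p = float(stats.f.sf(f, df1, df2))
    return HotellingResult(t2=t2, f_stat=f, df1=df1, df2=df2, p=max(p, TINY_P))


def _hotelling_all_pairs(xc: np.ndarray, xe: np.ndarray):
    """Vectorised Hotelling T2 over all unordered row pairs.

    ``xc``/``xe``: genes x replicates arrays for control and exposed.
    Returns (idx_a, idx_b, p) for the nondegenerate pairs.
    """
    n1, n2 = xc.shape[1], xe.shape[1]
    m = xc.shape[0]
    d = xe.mean(axis=1) - xc.mean(axis=1)
    s1 = np.cov(xc, ddof=1)
    s2 = np.cov(xe, ddof=1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    ia, ib = np.triu_indices(m, k=1)
    a = sp[ia, ia]
    b = sp[ia, ib]
    c = sp[ib, ib]
    det = a * c - b * b
    ok = det > _SINGULAR_RTOL * np.maximum(a * c, 1.0)
    da, db = d[ia], d[ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (c * da * da - 2.0 * b * da * db + a * db * db) / det
    t2 = n1 * n2 / (n1 + n2) * quad
    f = (n1 + n2 - 3) / (2.0 * (n1 + n2 - 2)) * t2
    p = stats.f.sf(f, 2, n1 + n2 - 3)
    return ia[ok], ib[ok], np.clip(p[ok], TINY_P, 1.0)


def infer_network(
    study: ExpressionStudy,
    seed_genes: DEGSelection,
    edge_percentile: float = 5.0,
    contrast: pd.DataFrame | None = None,
    exposure_id: str | None = None,
) -> CoexpressionNetwork:
    """Infer the binary co-expression network over ``seed_genes``.

    All C(m, 2) seed-gene pairs are Hotelling-tested; degenerate pairs
    (singular pooled covariance) are excluded from both the test list and
    the percentile distribution.  Retained edges have raw p strictly below
    the ``edge_percentile``-th percentile of tested-pair p-values.
    """
    genes = [g for g in seed_genes.genes if g in set(study.genes)]
    if len(genes) != len(seed_genes.genes):
        raise ParameterError("seed genes must be a subset of the study genes")
    if len(genes) < 2:
        raise ParameterError("need >= 2 seed genes to infer a network")
    if not 0 < edge_percentile <= 100:
        raise ParameterError("edge_percentile must be in (0, 100]")

    ctrl = study.samples("control")
    expo = study.samples("exposed")
    xc = study.matrix.loc[genes, ctrl].to_numpy(float)
    xe = study.matrix.loc[genes, expo].to_numpy(float)
    ia, ib, p = _hotelling_all_pairs(xc, xe)
    if p.size == 0:
        warnings.warn("all gene pairs degenerate; returning an empty network")
        return CoexpressionNetwork(nx.Graph(), exposure_id=exposure_id or study.study_id)
    p_adj = bh_adjust(p)
    cutoff = percentile_cutoff(p, edge_percentile)
    keep = p < cutoff

    if contrast is None:
        contrast = differential_expression(study)
    logfc = dict(zip(contrast["gene"], contrast["logFC"]))

    g = nx.Graph()
    tested_genes = sorted({genes[i] for i in ia} | {genes[i] for i in ib})
    for gene in tested_genes:
        g.add_node(gene, logfc=float(logfc.get(gene, 0.0)))
    for i, j, pv, pa in zip(ia[keep], ib[keep], p[keep], p_adj[keep]):
        g.add_edge(
            genes[i],
            genes[j],
            p=float(pv),
            p_adj=float(pa),
            neglog_p=float(-math.log10(max(pv, TINY_P))),
        )
    return CoexpressionNetwork(
        g, exposure_id=exposure_id or study.study_id, tested_p=p.copy()
    )
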