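"""Comparison of network collections.

Edge-based consensus distances and consensus clustering of co-expression
networks, Ward clustering of MOA networks, hypergeometric extraction of
cluster-overrepresented edges, and the weighted Kolmogorov-Smirnov
edge-set (pathway) enrichment with permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation

from ._stats import TINY_P, bh_adjust
from .coexpression import CoexpressionNetwork
from .errors import ParameterError
from .moa_builder import MOANetwork

COMPONENT_NAMES = ("jaccard_sim", "jaccard_dist", "kendall", "hamming", "smc")


@dataclass
class NetworkDistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # consensus distance
    components: dict = field(default_factory=dict)  # name -> matrix (nan = missing)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ParameterError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def _edge_sets(nets: list[CoexpressionNetwork]) -> list[frozenset]:
    return [net.edge_set for net in nets]


def edge_distance_matrix(nets: list[CoexpressionNetwork]) -> NetworkDistanceMatrix:
    """Per-pair edge-based distances and their consensus (mean of the
    available components, each oriented as a distance in [0, 1]).

    Components: 1 - Jaccard similarity, Jaccard distance, (1 - tau)/2 for
    the Kendall correlation of common edges ranked by edge betweenness,
    normalised Hamming and 1 - SMC over the union edge universe.  Pairs with
    fewer than 3 common edges drop the Kendall component.
    """
    if len(nets) < 2:
        raise ParameterError("need >= 2 networks")
    n = len(nets)
    ids = [net.exposure_id or f"net{i}" for i, net in enumerate(nets)]
    edge_sets = _edge_sets(nets)
    universe = sorted(frozenset().union(*edge_sets), key=lambda e: tuple(sorted(e)))
    uni_index = {e: i for i, e in enumerate(universe)}
    indicators = np.zeros((n, len(universe)), dtype=bool)
    for i, es in enumerate(edge_sets):
        for e in es:
            indicators[i, uni_index[e]] = True
    betweenness = [nx.edge_betweenness_centrality(net.graph) for net in nets]
    bmaps = [
        {frozenset((u, v)): val for (u, v), val in b.items()} for b in betweenness
    ]

    comps = {name: np.zeros((n, n)) for name in COMPONENT_NAMES}
    comps["kendall"][:] = np.nan
    np.fill_diagonal(comps["kendall"], 0.0)
    consensus = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = edge_sets[i], edge_sets[j]
            union = len(ei | ej)
            jac_sim = len(ei & ej) / union if union else 1.0
            d_jac = 1.0 - jac_sim
            u = len(universe)
            mism = int(np.sum(indicators[i] != indicators[j]))
            hamming = mism / u if u else 0.0
            smc_dist = 1.0 - (u - mism) / u if u else 0.0
            common = sorted(ei & ej, key=lambda e: tuple(sorted(e)))
            kd = np.nan
            if len(common) >= 3:
                bi = [bmaps[i][e] for e in common]
                bj = [bmaps[j][e] for e in common]
                tau = stats.kendalltau(bi, bj).statistic
                if np.isfinite(tau):
                    kd = (1.0 - tau) / 2.0
            vals = {
                "jaccard_sim": d_jac,
                "jaccard_dist": d_jac,
                "kendall": kd,
                "hamming": hamming,
                "smc": smc_dist,
            }
            for name, v in vals.items():
                comps[name][i, j] = comps[name][j, i] = v
            present = [v for v in vals.values() if np.isfinite(v)]
            consensus[i, j] = consensus[j, i] = float(np.mean(present))
    return NetworkDistanceMatrix(ids=ids, matrix=consensus, components=comps)


# -- clustering ------------------------------------------------------------


def _kmedoids(dist: np.ndarray, k: int, seed: int, n_iter: int = 100) -> np.ndarray:
    """Seeded PAM-style k-medoids on a precomputed distance matrix."""
    rng = np.random.default_rng(seed)
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(n_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                continue
            costs = dist[np.ix_(members, members)].sum(axis=0)
            new[c] = members[np.argmin(costs)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(dist[:, medoids], axis=1)


def consensus_cluster(dist: NetworkDistanceMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Consensus of hierarchical, affinity-propagation and k-medoids
    clusterings via a co-association matrix, cut hierarchically into ``k``
    clusters.  Returns integer labels aligned with ``dist.ids``."""
    d = dist.matrix
    n = d.shape[0]
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of networks ({n})")

    labelings = []
    z = linkage(squareform(d, checks=False), method="average")
    labelings.append(fcluster(z, t=k, criterion="maxclust"))

    sim = 1.0 - d
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = AffinityPropagation(
            affinity="precomputed",
            preference=float(np.median(sim)),
            random_state=seed,
            damping=0.9,
            max_iter=500,
        ).fit(sim)
    ap_labels = ap.labels_
    if np.any(ap_labels < 0):  # did not converge; fall back to hierarchical
        ap_labels = labelings[0]
    labelings.append(np.asarray(ap_labels))

    labelings.append(_kmedoids(d, k, seed=seed))

    coassoc = np.zeros((n, n))
    for lab in labelings:
        lab = np.asarray(lab)
        coassoc += (lab[:, None] == lab[None, :]).astype(float)
    coassoc /= len(labelings)
    co_dist = 1.0 - coassoc
    np.fill_diagonal(co_dist, 0.0)
    zf = linkage(squareform(co_dist, checks=False), method="average")
    return fcluster(zf, t=k, criterion="maxclust")


def moa_distance_matrix(moas: list[MOANetwork]) -> NetworkDistanceMatrix:
    """1 - mean(node Jaccard, edge Jaccard) between MOA networks."""
    if len(moas) < 2:
        raise ParameterError("need >= 2 MOA networks")
    n = len(moas)
    ids = [m.exposure_id or f"moa{i}" for i, m in enumerate(moas)]
    d = np.zeros((n, n))

    def jac(x, y):
        union = x | y
        return len(x & y) / len(union) if union else 1.0

    for i in range(n):
        for j in range(i + 1, n):
            sim = 0.5 * (
                jac(moas[i].event_ids, moas[j].event_ids)
                + jac(moas[i].link_set, moas[j].link_set)
            )
            d[i, j] = d[j, i] = 1.0 - sim
    return NetworkDistanceMatrix(ids=ids, matrix=d)


def cluster_moa_networks(moas: list[MOANetwork], k: int | None = None):
    """Ward-squared agglomeration of MOA similarity distances.

    Returns ``(linkage_matrix, labels, ids)``; ``labels`` is None unless a
    flat cut level ``k`` is requested.
    """
    dist = moa_distance_matrix(moas)
    z = linkage(squareform(dist.matrix, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust") if k is not None else None
    return z, labels, dist.ids


def linkage_to_newick(z: np.ndarray, ids: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string."""
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    trees = {i: ids[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        node = n + step
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        trees[node] = f"({trees[a]}:{la:g},{trees[b]}:{lb:g})"
        heights[node] = h
    return trees[n + len(z) - 1] + ";"


# -- overrepresented edges -------------------------------------------------


def overrepresented_edges(
    nets: list[CoexpressionNetwork], cluster_ids: set, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric upper-tail test of each edge's occurrence inside the
    cluster versus the whole collection; BH across tested edges, keeping
    ``p_adj`` <= ``alpha``."""
    all_ids = [net.exposure_id for net in nets]
    if len(set(all_ids)) != len(all_ids):
        raise ParameterError("networks must have unique exposure ids")
    cluster_ids = set(cluster_ids)
    if not cluster_ids or not cluster_ids <= set(all_ids):
        raise ParameterError("cluster_ids must be a nonempty subset of network ids")
    if cluster_ids == set(all_ids):
        raise ParameterError("cluster must be a proper subset of the networks")
    total = len(nets)
    cluster_size = len(cluster_ids)
    counts_total: dict[frozenset, int] = {}
    counts_cluster: dict[frozenset, int] = {}
    for net in nets:
        inside = net.exposure_id in cluster_ids
        for e in net.edge_set:
            counts_total[e] = counts_total.get(e, 0) + 1
            if inside:
                counts_cluster[e] = counts_cluster.get(e, 0) + 1
    rows = []
    for e in sorted(counts_cluster, key=lambda e: tuple(sorted(e))):
        in_cluster = counts_cluster[e]
        in_total = counts_total[e]
        p = float(stats.hypergeom.sf(in_cluster - 1, total, in_total, cluster_size))
        a, b = sorted(e)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "in_cluster": in_cluster,
                "cluster_size": cluster_size,
                "in_total": in_total,
                "total": total,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "in_cluster", "cluster_size", "in_total", "total", "p"],
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out[out["p_adj"] <= alpha].reset_index(drop=True)
    else:
        out["p_adj"] = []
    return out


# -- edge-set (pathway) enrichment ----------------------------------------


def _weighted_ks(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the weighted running sum over the ranking."""
    n_hit = int(hit_mask.sum())
    n_miss = hit_mask.size - n_hit
    if n_hit == 0:
        return 0.0
    w = np.where(hit_mask, weights, 0.0)
    w_total = w.sum()
    step_hit = w / w_total if w_total > 0 else hit_mask / n_hit
    step_miss = np.where(~hit_mask, 1.0 / n_miss, 0.0) if n_miss else 0.0
    running = np.cumsum(step_hit - step_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def edge_set_enrichment(
    edges: pd.DataFrame,
    pathway_sets: dict,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted Kolmogorov-Smirnov enrichment of pathway edge sets on top of
    the p-ranked edge list.

    A pathway's background edge set is every unordered gene pair co-annotated
    to it; hits are weighted by -log10(p).  ``p_perm`` is one-sided (greater)
    over ``n_perm`` seeded random reassignments of the set membership, with
    resolution 1/(n_perm + 1); BH adjustment across scored pathways.
    """
    if not pathway_sets:
        raise ParameterError("pathway_sets must be nonempty")
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives coarse permutation p resolution")
    df = edges.sort_values("p", kind="mergesort").reset_index(drop=True)
    weights = -np.log10(np.clip(df["p"].to_numpy(float), TINY_P, 1.0))
    pair_genes = list(zip(df["gene_a"], df["gene_b"]))
    rng = np.random.default_rng(seed)
    n_edges = len(df)

    rows = []
    for name in sorted(pathway_sets):
        genes = set(pathway_sets[name])
        if len(genes) < 2:
            continue
        hit_mask = np.array([a in genes and b in genes for a, b in pair_genes])
        n_hit = int(hit_mask.sum())
        if n_hit == 0:
            rows.append({"set_name": name, "es": 0.0, "n_hits": 0, "p_perm": 1.0})
            continue
        es = _weighted_ks(hit_mask, weights)
        exceed = 0
        for _ in range(n_perm):
            perm_idx = rng.choice(n_edges, size=n_hit, replace=False)
            perm_mask = np.zeros(n_edges, dtype=bool)
            perm_mask[perm_idx] = True
            if _weighted_ks(perm_mask, weights) >= es:
                exceed += 1
        p_perm = (1 + exceed) / (n_perm + 1)
        rows.append({"set_name": name, "es": es, "n_hits": n_hit, "p_perm": p_perm})
    out = pd.DataFrame(rows, columns=["set_name", "es", "n_hits", "p_perm"])
    out["p_adj"] = bh_adjust(out["p_perm"].to_numpy()) if len(out) else []
    return out


def combine_edge_pvalues(p_list) -> float:
    """Fisher's (sumlog) combination: -2 sum(ln p) against chi2(2k)."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ParameterError("p_list must be nonempty")
    if np.any(p <= 0):
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.clip(p, TINY_P, 1.0)
    if np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    res = stats.combine_pvalues(p, method="fisher")
    return float(res.pvalue)


def read_gmt(path) -> dict:
    """Read a GMT file into {set_name: set(genes)} (description column ignored)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
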