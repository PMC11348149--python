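"""Information-content and cross-system similarity scores for MOA networks.

All graph metrics are computed on the undirected view.  Degenerate graphs
(empty or edgeless) score zero on every completeness metric so that the
scores are total functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .aop_knowledge import AOPNetwork
from .errors import ComparabilityError
from .moa_builder import MOANetwork


@dataclass(frozen=True)
class CompletenessMetrics:
    transitivity: float
    mean_betweenness: float
    mean_shortest_path: float
    diameter: int


@dataclass(frozen=True)
class SimilarityBreakdown:
    coverage_sim: float
    node_jaccard: float
    edge_jaccard: float
    diameter_ratio: float

    @property
    def score(self) -> float:
        return (self.coverage_sim + self.node_jaccard + self.edge_jaccard + self.diameter_ratio) / 4.0


def _undirected(moa: MOANetwork) -> nx.Graph:
    return moa.graph.to_undirected(as_view=False)


def completeness_metrics(moa: MOANetwork) -> CompletenessMetrics:
    g = _undirected(moa)
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        return CompletenessMetrics(0.0, 0.0, 0.0, 0)
    betweenness = nx.betweenness_centrality(g)
    sp_lengths = [
        l
        for _, lengths in nx.all_pairs_shortest_path_length(g)
        for l in lengths.values()
        if l > 0
    ]
    diameter = max(
        nx.diameter(g.subgraph(c)) for c in nx.connected_components(g) if len(c) > 1
    )
    return CompletenessMetrics(
        transitivity=float(nx.transitivity(g)),
        mean_betweenness=float(np.mean(list(betweenness.values()))),
        mean_shortest_path=float(np.mean(sp_lengths)) if sp_lengths else 0.0,
        diameter=int(diameter),
    )


def compare_completeness(a: CompletenessMetrics, b: CompletenessMetrics) -> str:
    """'A' if ``a`` is strictly higher on >= 3 of the 4 metrics, 'B'
    symmetrically, else 'tie'."""
    fields = ("transitivity", "mean_betweenness", "mean_shortest_path", "diameter")
    a_wins = sum(getattr(a, f) > getattr(b, f) for f in fields)
    b_wins = sum(getattr(b, f) > getattr(a, f) for f in fields)
    if a_wins >= 3:
        return "A"
    if b_wins >= 3:
        return "B"
    return "tie"


def connectivity_score(moa: MOANetwork) -> float:
    """Ratio of degree>=1 events to isolated ones (denominator floored at 1)."""
    g = _undirected(moa)
    if g.number_of_nodes() == 0:
        return 0.0
    degrees = dict(g.degree())
    n_connected = sum(1 for d in degrees.values() if d >= 1)
    n_isolated = len(degrees) - n_connected
    return n_connected / max(n_isolated, 1)


def _largest_component_diameter(g: nx.Graph) -> int:
    comps = [c for c in nx.connected_components(g) if len(c) > 1]
    if not comps:
        return 0
    biggest = max(comps, key=len)
    return int(nx.diameter(g.subgraph(biggest)))


def biosystem_similarity(
    moa_a: MOANetwork, moa_b: MOANetwork, aop: AOPNetwork
) -> SimilarityBreakdown:
    """Mean of four [0, 1] components: AOP-coverage similarity, node Jaccard,
    edge Jaccard and largest-component diameter ratio."""
    if moa_a.aop_source != moa_b.aop_source:
        raise ComparabilityError("MOA networks built against different AOP networks")
    n_total_ke = max(len(aop.event_ids_by_type("KE")), 1)
    cov_a = len(moa_a.enriched_kes) / n_total_ke
    cov_b = len(moa_b.enriched_kes) / n_total_ke
    coverage_sim = 1.0 - abs(cov_a - cov_b)

    def jac(x: frozenset, y: frozenset) -> float:
        union = x | y
        return len(x & y) / len(union) if union else 1.0

    node_j = jac(moa_a.event_ids, moa_b.event_ids)
    edge_j = jac(moa_a.link_set, moa_b.link_set)
    da = _largest_component_diameter(_undirected(moa_a))
    db = _largest_component_diameter(_undirected(moa_b))
    if da == 0 and db == 0:
        dr = 1.0
    else:
        dr = min(da, db) / max(da, db)
    return SimilarityBreakdown(
        coverage_sim=coverage_sim, node_jaccard=node_j, edge_jaccard=edge_j, diameter_ratio=dr
    )
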