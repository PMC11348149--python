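"""MOA reconstruction: prioritise plausible MIEs/AOs around the filtered
enriched KEs and assemble the induced AOP subgraph."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from .aop_knowledge import AOPNetwork, event_distance
from .errors import ValidationError


@dataclass(frozen=True)
class PrioritizedEvent:
    event_id: str
    event_type: str
    best_gene_p: float
    dist_to_enriched: int
    gene_set_size: int
    rank: int


@dataclass
class MOANetwork:
    """Reconstructed mechanism: enriched KEs + prioritised terminals with the
    AOP links among them."""

    graph: nx.DiGraph
    exposure_id: str = ""
    enriched_kes: frozenset = field(default_factory=frozenset)
    terminals: tuple = ()
    aop_source: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def event_ids(self) -> frozenset:
        return frozenset(self.graph.nodes())

    @property
    def link_set(self) -> frozenset:
        return frozenset(self.graph.edges())

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for n, d in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "event_id": n,
                    "type": d.get("event_type", ""),
                    "role": d.get("role", ""),
                    "ratio": d.get("ratio", float("nan")),
                    "p_adj": d.get("p_adj", float("nan")),
                    "rank": d.get("rank", -1),
                }
            )
        return pd.DataFrame(rows, columns=["event_id", "type", "role", "ratio", "p_adj", "rank"])


def prioritize_terminals(
    enriched: pd.DataFrame,
    aop: AOPNetwork,
    contrast: pd.DataFrame,
    max_events: int = 20,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.58,
) -> list[PrioritizedEvent]:
    """Rank candidate MIEs and AOs around the enriched KEs.

    A candidate must have at least one annotated gene passing the DEG filter
    (p < ``p_thresh`` and \\|logFC\\| > ``lfc_thresh``) and a finite undirected
    AOP distance to some enriched KE.  The composite rank is the mean of
    rank(best gene p, ascending) and rank(distance, ascending); ties prefer
    smaller gene sets then lexicographic event id.  At most ``max_events``
    per type are returned.
    """
    enriched_ids = set(enriched["event_id"])
    if not enriched_ids:
        warnings.warn("no enriched KEs; no terminals to prioritize")
        return []
    deg = contrast[(contrast["p"] < p_thresh) & (contrast["logFC"].abs() > lfc_thresh)]
    p_by_gene = dict(zip(deg["gene"], deg["p"]))

    out: list[PrioritizedEvent] = []
    for etype in ("MIE", "AO"):
        cands = []
        for eid in aop.event_ids_by_type(etype):
            genes = aop.gene_set(eid)
            pvals = [p_by_gene[g] for g in genes if g in p_by_gene]
            if not pvals:
                continue
            dist = event_distance(aop, eid, enriched_ids)
            if math.isinf(dist):
                continue
            cands.append((eid, min(pvals), int(dist), len(genes)))
        if not cands:
            continue
        rank_p = stats.rankdata([c[1] for c in cands])
        rank_d = stats.rankdata([c[2] for c in cands])
        composite = (rank_p + rank_d) / 2.0
        order = sorted(
            range(len(cands)), key=lambda i: (composite[i], cands[i][3], cands[i][0])
        )
        for rank, i in enumerate(order[:max_events], start=1):
            eid, best_p, dist, size = cands[i]
            out.append(
                PrioritizedEvent(
                    event_id=eid,
                    event_type=etype,
                    best_gene_p=best_p,
                    dist_to_enriched=dist,
                    gene_set_size=size,
                    rank=rank,
                )
            )
    return out


def assemble_moa(
    enriched: pd.DataFrame,
    terminals: list[PrioritizedEvent],
    aop: AOPNetwork,
    exposure_id: str = "",
) -> MOANetwork:
    """Induced AOP subgraph on the enriched KEs plus the prioritised
    terminals; isolated included events are retained."""
    included = set(enriched["event_id"]) | {t.event_id for t in terminals}
    unknown = included - set(aop.events)
    if unknown:
        raise ValidationError(f"events not in the AOP network: {sorted(unknown)}")
    g = nx.DiGraph()
    stats_by_event = enriched.set_index("event_id") if len(enriched) else None
    for eid in sorted(included):
        attrs = {"event_type": aop.events[eid].event_type}
        if stats_by_event is not None and eid in stats_by_event.index:
            row = stats_by_event.loc[eid]
            attrs.update(role="enriched_ke", ratio=float(row["ratio"]), p_adj=float(row["p_adj"]))
        g.add_node(eid, **attrs)
    for t in terminals:
        g.nodes[t.event_id].update(
            role="terminal", rank=int(t.rank), best_gene_p=float(t.best_gene_p)
        )
    for u, v in aop.links:
        if u in included and v in included:
            g.add_edge(u, v)
    # every MOA link must exist in the source AOP network
    assert set(g.edges()) <= aop.links
    return MOANetwork(
        graph=g,
        exposure_id=exposure_id,
        enriched_kes=frozenset(enriched["event_id"]),
        terminals=tuple(terminals),
        aop_source=aop.annotation_source,
        provenance={"n_enriched": int(len(enriched)), "n_terminals": len(terminals)},
    )
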