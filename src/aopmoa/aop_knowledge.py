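"""Adverse-outcome-pathway knowledge layer.

Loads and validates the event network (MIE/KE/AO nodes with directed
upstream -> downstream links) together with the event -> gene annotation,
merges redundant events by gene-set similarity, and answers distance
queries used during terminal prioritisation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, LookupError_, ParameterError, ValidationError

EVENT_TYPES = ("MIE", "KE", "AO")

EDGE_COLUMNS = (
    "upstream_event_id",
    "downstream_event_id",
    "upstream_type",
    "downstream_type",
)
ANNOTATION_COLUMNS = ("event_id", "gene")


@dataclass(frozen=True)
class AOPEvent:
    """A typed event node with its (possibly empty) annotated gene set."""

    event_id: str
    event_type: str
    label: str = ""
    gene_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(
                f"event {self.event_id!r}: unknown event_type {self.event_type!r}"
            )


@dataclass(frozen=True)
class ClusteredKE:
    """Result of merging redundant events into a single node."""

    merged_event_id: str
    member_event_ids: frozenset
    gene_set: frozenset

    def __post_init__(self):
        if len(self.member_event_ids) < 2:
            raise ValidationError("a clustered event needs >= 2 members")


class AOPNetwork:
    """Directed graph of typed events plus the event -> gene annotation."""

    def __init__(
        self,
        events: Iterable[AOPEvent],
        links: Iterable[tuple],
        annotation_source: str = "",
    ):
        self.events: dict[str, AOPEvent] = {}
        for ev in events:
            if ev.event_id in self.events:
                raise ValidationError(f"duplicate event id {ev.event_id!r}")
            self.events[ev.event_id] = ev
        self.links: set[tuple] = set()
        for u, v in links:
            if u == v:
                raise ValidationError(f"self-link on {u!r}")
            missing = [e for e in (u, v) if e not in self.events]
            if missing:
                raise ValidationError(f"link ({u!r}, {v!r}) references unknown events {missing}")
            self.links.add((u, v))
        self.annotation_source = annotation_source
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.events)
        self._graph.add_edges_from(self.links)
        self._undirected = self._graph.to_undirected(as_view=False)

    # -- basic queries -----------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def undirected(self) -> nx.Graph:
        return self._undirected

    def gene_set(self, event_id: str) -> frozenset:
        try:
            return self.events[event_id].gene_set
        except KeyError:
            raise LookupError_(event_id) from None

    def event_ids_by_type(self, event_type: str) -> list[str]:
        return sorted(e for e, ev in self.events.items() if ev.event_type == event_type)

    def annotated_events(self, min_genes: int = 1) -> list[str]:
        return sorted(e for e, ev in self.events.items() if len(ev.gene_set) >= min_genes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AOPNetwork):
            return NotImplemented
        return self.events == other.events and self.links == other.links

    def __repr__(self) -> str:
        return f"AOPNetwork({len(self.events)} events, {len(self.links)} links)"

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for ev in self.events.values():
            g.add_node(
                ev.event_id,
                event_type=ev.event_type,
                label=ev.label,
                genes=";".join(sorted(ev.gene_set)),
            )
        g.add_edges_from(self.links)
        nx.write_graphml(g, path)


def load_aop_network(edge_table, annotation_table, annotation_source: str = "") -> AOPNetwork:
    """Read the event edge table and gene annotation into an :class:`AOPNetwork`.

    Events present only in the annotation are retained as isolated nodes
    (typed ``KE`` by convention); duplicated links are collapsed.
    """
    edges = pd.read_csv(edge_table, sep="\t", dtype=str)
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise FormatError(f"edge table missing required columns: {missing}")
    ann = pd.read_csv(annotation_table, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation table missing required columns: {missing}")

    types: dict[str, str] = {}
    offenders = []
    for _, row in edges.iterrows():
        for id_col, ty_col in (
            ("upstream_event_id", "upstream_type"),
            ("downstream_event_id", "downstream_type"),
        ):
            eid, ety = row[id_col], row[ty_col]
            if pd.isna(eid):
                raise FormatError("edge table contains an empty event id")
            if pd.isna(ety) or ety not in EVENT_TYPES:
                offenders.append(eid)
                continue
            if types.setdefault(eid, ety) != ety:
                raise ValidationError(f"conflicting types for event {eid!r}")
    if offenders:
        raise ValidationError(f"links reference untyped events: {sorted(set(offenders))}")

    gene_sets: dict[str, set] = {}
    for _, row in ann.iterrows():
        gene_sets.setdefault(row["event_id"], set()).add(row["gene"])

    events = []
    for eid in sorted(set(types) | set(gene_sets)):
        events.append(
            AOPEvent(
                event_id=eid,
                event_type=types.get(eid, "KE"),
                gene_set=frozenset(gene_sets.get(eid, ())),
            )
        )
    links = {
        (row["upstream_event_id"], row["downstream_event_id"]) for _, row in edges.iterrows()
    }
    return AOPNetwork(events, links, annotation_source=annotation_source)


def jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def merge_redundant_kes(
    net: AOPNetwork, jaccard_threshold: float = 0.8
) -> tuple[AOPNetwork, list[ClusteredKE]]:
    """Merge events whose gene sets overlap at or above ``jaccard_threshold``.

    Single linkage over the threshold graph, applied to a fixed point so the
    operation is idempotent; only events of the same type with nonempty gene
    sets are candidates.  The merged node carries the union of member gene
    sets and of incident links.
    """
    if not 0.0 <= jaccard_threshold <= 1.0:
        raise ParameterError(f"jaccard_threshold must be in [0, 1], got {jaccard_threshold}")

    # members: current node id -> frozenset of original ids it represents
    members: dict[str, frozenset] = {e: frozenset([e]) for e in net.events}
    gene_sets: dict[str, frozenset] = {e: ev.gene_set for e, ev in net.events.items()}
    types: dict[str, str] = {e: ev.event_type for e, ev in net.events.items()}
    links: set[tuple] = set(net.links)

    def merged_id(member_ids: frozenset) -> str:
        return "CL:" + "|".join(sorted(member_ids))

    changed = True
    while changed:
        changed = False
        sim = nx.Graph()
        candidates = sorted(e for e in members if gene_sets[e])
        sim.add_nodes_from(candidates)
        for a, b in itertools.combinations(candidates, 2):
            if types[a] != types[b]:
                continue
            if jaccard(gene_sets[a], gene_sets[b]) >= jaccard_threshold:
                sim.add_edge(a, b)
        for comp in nx.connected_components(sim):
            if len(comp) < 2:
                continue
            changed = True
            all_members = frozenset().union(*(members[c] for c in comp))
            new_id = merged_id(all_members)
            gene_sets[new_id] = frozenset().union(*(gene_sets[c] for c in comp))
            types[new_id] = types[next(iter(comp))]
            members[new_id] = all_members
            remap = {c: new_id for c in comp}
            links = {
                (remap.get(u, u), remap.get(v, v))
                for u, v in links
                if remap.get(u, u) != remap.get(v, v)
            }
            for c in comp:
                del members[c], gene_sets[c], types[c]

    clusters = [
        ClusteredKE(merged_event_id=e, member_event_ids=members[e], gene_set=gene_sets[e])
        for e in sorted(members)
        if len(members[e]) > 1
    ]
    merged_events = [
        AOPEvent(
            event_id=e,
            event_type=types[e],
            label=net.events[e].label if e in net.events else "",
            gene_set=gene_sets[e],
        )
        for e in sorted(members)
    ]
    return AOPNetwork(merged_events, links, annotation_source=net.annotation_source), clusters


def event_distance(net: AOPNetwork, from_id: str, to_ids: Iterable[str]) -> float:
    """Undirected shortest-path length (in links) from ``from_id`` to the
    nearest member of ``to_ids``; ``math.inf`` when unreachable."""
    to_ids = set(to_ids)
    unknown = ({from_id} | to_ids) - set(net.events)
    if unknown:
        raise LookupError_(f"unknown event ids: {sorted(unknown)}")
    if from_id in to_ids:
        return 0
    lengths = nx.single_source_shortest_path_length(net.undirected, from_id)
    best = min((lengths[t] for t in to_ids if t in lengths), default=math.inf)
    return best
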