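"""Sequence similarity network of precursor peptides.

Nodes are unique precursor sequences (exact-string deduplication, with a
multiplicity recording how many mined records carried that sequence);
edges join pairs whose local alignment reaches both the percent-identity
threshold (default 50%) and a raw-score floor. Connected components of
size >= 2 become numbered groups, ranked by size; size-1 components are
singletons. The score floor replaces the E-value pre-filter a database
search would apply — a local all-by-all has no database context, so an
explicit score is the deterministic analogue.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .align import AlignmentParams, align_local
from .models import ProteinRecord


@dataclass(frozen=True)
class SSNNode:
    id: str                      # first-seen record id
    sequence: str
    multiplicity: int            # number of source records with this sequence
    source_ids: tuple[str, ...]  # producer record/genome ids


@dataclass
class SSNGraph:
    nodes: list[SSNNode]
    edges: list[tuple[str, str, float, float]]  # (a, b, identity_pct, raw_score)
    identity_threshold_pct: float = 50.0
    min_score: float = 60.0
    node_attrs: dict = field(default_factory=dict)  # id -> {group_id, subgroup, gravy, pI}

    def validate(self) -> None:
        ids = {n.id for n in self.nodes}
        seen = set()
        for a, b, ident, _score in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in ids or b not in ids:
                raise ValueError(f"edge references unknown node: {a!r}-{b!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            seen.add(key)
            if ident < self.identity_threshold_pct:
                raise ValueError(f"edge {a!r}-{b!r} below identity threshold")


def dedupe_sequences(records: list[ProteinRecord]) -> list[SSNNode]:
    """Collapse exact duplicate sequences into nodes with multiplicity."""
    by_seq: dict[str, list[ProteinRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.sequence not in by_seq:
            by_seq[r.sequence] = []
            order.append(r.sequence)
        by_seq[r.sequence].append(r)
    return [
        SSNNode(
            id=by_seq[seq][0].id,
            sequence=seq,
            multiplicity=len(by_seq[seq]),
            source_ids=tuple(r.id for r in by_seq[seq]),
        )
        for seq in order
    ]


def build_ssn(
    nodes: list[SSNNode],
    params: AlignmentParams = AlignmentParams(),
    identity_threshold_pct: float = 50.0,
    min_score: float = 60.0,
) -> SSNGraph:
    """All-by-all local alignment; edge iff identity and score pass."""
    if not nodes:
        raise ValueError("SSN requires at least one node")
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            res = align_local(nodes[i].sequence, nodes[j].sequence, params,
                              query_id=nodes[i].id, subject_id=nodes[j].id)
            if res.identity_pct >= identity_threshold_pct and res.raw_score >= min_score:
                edges.append((nodes[i].id, nodes[j].id, res.identity_pct, res.raw_score))
    return SSNGraph(nodes=nodes, edges=edges,
                    identity_threshold_pct=identity_threshold_pct, min_score=min_score)


@dataclass(frozen=True)
class GroupAssignment:
    group_id: int
    members: tuple[str, ...]
    is_singleton: bool


def assign_groups(graph: SSNGraph) -> list[GroupAssignment]:
    """Connected components, size-ranked.

    Components of size >= 2 get ids 1..n by descending unique-member
    count (ties broken by the lexicographically smallest member id);
    singletons follow, numbered after the groups in the same order.
    """
    g = nx.Graph()
    g.add_nodes_from(n.id for n in graph.nodes)
    g.add_edges_from((a, b) for a, b, _i, _s in graph.edges)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    out = []
    for rank, comp in enumerate(comps, start=1):
        out.append(GroupAssignment(group_id=rank, members=comp, is_singleton=len(comp) == 1))
    return out
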