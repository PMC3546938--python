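"""Contin assembly and neuron-skeleton derivation.

Assembly partitions the annotated objects into contins — the connected
components of the relationship graph — and derives, for each neurite
contin, a rooted skeleton with branch points and endpoints.  Isolated
objects form singleton contins.  Contin identifiers are assigned
deterministically as the minimum member object id, which is stable when
later annotation rounds append new objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .core import AnnotationObject, Contin, ObjType, Relationship

__all__ = [
    "NameConflict",
    "NeuriteSkeleton",
    "build_contins",
    "resolve_names",
    "build_skeleton",
]


@dataclass(frozen=True)
class NameConflict:
    """Distinct cell names found inside one neurite contin."""

    contin_id: int
    name_counts: tuple[tuple[str, int], ...]


@dataclass
class NeuriteSkeleton:
    """Rooted tree view of one neurite contin.

    ``removed_edges`` lists relationship edges dropped to break cycles
    (deterministically: within each cycle the edge whose endpoints have
    the maximal combined object id is removed).
    """

    contin_id: int
    nodes: dict[int, AnnotationObject]
    edges: list[tuple[int, int]]
    root: int
    branch_points: list[int]
    endpoints: list[int]
    removed_edges: list[tuple[int, int]] = field(default_factory=list)
    cell_name: Optional[str] = None

    @property
    def is_tree(self) -> bool:
        return len(self.edges) == len(self.nodes) - 1

    def degree(self, object_id: int) -> int:
        return sum(1 for a, b in self.edges if object_id in (a, b))

    def children(self) -> dict[int, list[int]]:
        """Parent -> children map from a deterministic DFS at the root."""
        adj: dict[int, list[int]] = {i: [] for i in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        out: dict[int, list[int]] = {i: [] for i in self.nodes}
        seen = {self.root}
        stack = [self.root]
        while stack:
            cur = stack.pop()
            for nb in sorted(adj[cur]):
                if nb not in seen:
                    seen.add(nb)
                    out[cur].append(nb)
                    stack.append(nb)
        return out


def build_contins(
    objects: Sequence[AnnotationObject],
    relationships: Sequence[Relationship],
    assign: bool = True,
) -> list[Contin]:
    """Partition objects into contins (connected components).

    Every object belongs to exactly one contin; isolated objects form
    singletons.  When ``assign`` is true the objects' ``contin_id``
    fields are filled in.  Returns contins sorted by contin id.
    """
    by_id = {o.object_id: o for o in objects}
    g = nx.Graph()
    g.add_nodes_from(by_id)
    g.add_edges_from(r.pair for r in relationships)

    contins: list[Contin] = []
    for comp in nx.connected_components(g):
        cid = min(comp)
        kind = by_id[cid].obj_type
        contins.append(Contin(cid, kind, frozenset(comp)))
        if assign:
            for i in comp:
                by_id[i].contin_id = cid
    contins.sort(key=lambda c: c.contin_id)
    return contins


def resolve_names(
    contins: Sequence[Contin], objects: Sequence[AnnotationObject]
) -> list[NameConflict]:
    """Fill ``resolved_name`` on neurite contins; report conflicts.

    A contin resolves to the unique non-empty cell name among its
    members.  Multiple distinct names leave it unresolved and emit a
    conflict entry listing all names with their member counts; a contin
    whose members are all unnamed stays unresolved without conflict.
    """
    by_id = {o.object_id: o for o in objects}
    conflicts: list[NameConflict] = []
    for contin in contins:
        if contin.kind is not ObjType.NEURITE:
            continue
        counts: dict[str, int] = {}
        for i in contin.object_ids:
            name = by_id[i].cell_name
            if name:
                counts[name] = counts.get(name, 0) + 1
        if len(counts) == 1:
            contin.resolved_name = next(iter(counts))
        elif len(counts) > 1:
            contin.resolved_name = None
            conflicts.append(
                NameConflict(
                    contin.contin_id, tuple(sorted(counts.items()))
                )
            )
    return conflicts


def _break_cycles(
    node_ids: set[int], edges: list[tuple[int, int]]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Kruskal spanning forest keeping low-id edges.

    Edges are admitted in ascending (a+b, a, b) order, so within each
    cycle the edge with maximal combined object id is the one dropped.
    """
    parent = {i: i for i in node_ids}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    kept, removed = [], []
    for a, b in sorted(edges, key=lambda e: (e[0] + e[1], e)):
        ra, rb = find(a), find(b)
        if ra == rb:
            removed.append((a, b))
        else:
            parent[ra] = rb
            kept.append((a, b))
    return kept, removed


def build_skeleton(
    contin: Contin,
    objects: Sequence[AnnotationObject],
    relationships: Sequence[Relationship],
) -> NeuriteSkeleton:
    """Derive the rooted skeleton of a neurite contin.

    Root selection: the member flagged as cell body if any (ties by
    minimal object id), else the endpoint with minimal section number,
    ties broken by minimal object id.  Cycles are broken deterministically
    before rooting so the result is always a tree.
    """
    if contin.kind is not ObjType.NEURITE:
        raise ValueError(
            f"contin {contin.contin_id} is {contin.kind.value}, "
            "not NEURITE"
        )
    members = contin.object_ids
    nodes = {
        o.object_id: o for o in objects if o.object_id in members
    }
    edges = [
        r.pair
        for r in relationships
        if r.object_id_a in members and r.object_id_b in members
    ]
    edges, removed = _break_cycles(set(nodes), edges)

    deg = {i: 0 for i in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    endpoints = sorted(i for i, d in deg.items() if d <= 1)
    branch_points = sorted(i for i, d in deg.items() if d >= 3)

    bodies = sorted(i for i, o in nodes.items() if o.is_cell_body)
    if bodies:
        root = bodies[0]
    else:
        root = min(endpoints, key=lambda i: (nodes[i].z, i))

    return NeuriteSkeleton(
        contin_id=contin.contin_id,
        nodes=nodes,
        edges=edges,
        root=root,
        branch_points=branch_points,
        endpoints=endpoints,
        removed_edges=removed,
        cell_name=contin.resolved_name,
    )
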