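"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: the
connected-component oracle is a plain breadth-first search over a dict
adjacency, used to cross-check contin assembly which is built on
networkx.
"""

from __future__ import annotations

import numpy as np
import pytest

from continet import AnnotationObject, ObjType, Relationship


def neurite(oid, z, name=None, x=0.0, y=0.0, body=False, **kw):
    return AnnotationObject(
        oid, x, y, z, ObjType.NEURITE, cell_name=name,
        is_cell_body=body, **kw,
    )


def chem(oid, z, pre, posts, x=0.0, y=0.0, **kw):
    return AnnotationObject(
        oid, x, y, z, ObjType.CHEMICAL, pre_cell=pre,
        post_cells=tuple(posts), **kw,
    )


def gap(oid, z, partners, x=0.0, y=0.0, **kw):
    return AnnotationObject(
        oid, x, y, z, ObjType.GAP, partner_cells=tuple(partners), **kw,
    )


def chain(objs, annotator=""):
    """Link a list of objects into a linear chain."""
    return [
        Relationship(a.object_id, b.object_id, annotator)
        for a, b in zip(objs, objs[1:])
    ]


def bfs_components(node_ids, edges):
    """Brute-force connected components: frozenset partition."""
    from collections import deque

    adj = {i: set() for i in node_ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), set()
    for start in node_ids:
        if start in seen:
            continue
        comp, queue = {start}, deque([start])
        seen.add(start)
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.add(frozenset(comp))
    return comps


def random_project(rng, n_max=500, p_edge_per_node=0.8):
    """Random neurite project: objects plus valid same-type links."""
    n = int(rng.integers(2, n_max + 1))
    ids = rng.permutation(np.arange(1, 10 * n))[:n]
    zs = rng.integers(0, 100, size=n)
    xy = rng.uniform(0, 1000, size=(n, 2))
    objects = [
        neurite(int(i), z=int(z), x=float(x), y=float(y))
        for i, z, (x, y) in zip(ids, zs, xy)
    ]
    n_edges = int(n * p_edge_per_node)
    draws = rng.integers(0, n, size=(2 * n_edges, 2))
    rels, seen = [], set()
    for ia, ib in draws:
        if len(rels) == n_edges:
            break
        if ia == ib:
            continue
        a, b = int(ids[ia]), int(ids[ib])
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        rels.append(Relationship(*key))
    return objects, rels


@pytest.fixture
def rng():
    return np.random.default_rng(20130116)
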