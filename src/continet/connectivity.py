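"""Weighted adjacency matrices and connectivity similarity.

Edge weight between a pair of cells is the total synaptic interaction
strength: the sum, over all their synapses, of the number of serial
sections each synapse traverses.  Chemical matrices are directed (rows
presynaptic, columns postsynaptic); gap-junction matrices are symmetric
with self-junctions counted once on the diagonal.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import AdjacencyMatrix, ObjType, Synapse
from .synaptics import expand_polyad

__all__ = [
    "chemical_adjacency",
    "gap_adjacency",
    "connectivity_vector",
    "similarity",
    "permutation_test",
]


def _usable(synapses: Iterable[Synapse], include_inconsistent: bool):
    return [
        s for s in synapses if include_inconsistent or not s.inconsistent
    ]


def _cell_index(
    needed: set[str], cell_order: Optional[Sequence[str]]
) -> list[str]:
    if cell_order is None:
        return sorted(needed)
    missing = needed - set(cell_order)
    if missing:
        raise ValueError(
            "cell_order is missing cells present in synapses: "
            + ", ".join(sorted(missing))
        )
    return list(cell_order)


def chemical_adjacency(
    synapses: Sequence[Synapse],
    cell_order: Optional[Sequence[str]] = None,
    include_inconsistent: bool = False,
    polyad_split: bool = False,
) -> AdjacencyMatrix:
    """Directed chemical connectivity matrix in units of sections.

    Each postsynaptic partner of a polyad contributes the synapse's full
    section count unless ``polyad_split`` divides it evenly among the
    partners.  Synapses flagged inconsistent are excluded by default.
    """
    syns = [
        s
        for s in _usable(synapses, include_inconsistent)
        if s.syn_type is ObjType.CHEMICAL
    ]
    needed: set[str] = set()
    for s in syns:
        needed.add(s.pre_cell)
        needed.update(s.post_cells)
    cells = _cell_index(needed, cell_order)
    idx = {c: i for i, c in enumerate(cells)}
    dtype = float if polyad_split else int
    w = np.zeros((len(cells), len(cells)), dtype=dtype)
    for s in syns:
        share = 1.0 / len(s.post_cells) if polyad_split else 1
        for pre, post, size in expand_polyad(s):
            w[idx[pre], idx[post]] += size * share
    return AdjacencyMatrix(cells, w, ObjType.CHEMICAL)


def gap_adjacency(
    synapses: Sequence[Synapse],
    cell_order: Optional[Sequence[str]] = None,
    include_inconsistent: bool = False,
) -> AdjacencyMatrix:
    """Symmetric gap-junction matrix; self-junctions counted once."""
    syns = [
        s
        for s in _usable(synapses, include_inconsistent)
        if s.syn_type is ObjType.GAP
    ]
    needed: set[str] = set()
    for s in syns:
        needed.update(s.partner_cells)
    cells = _cell_index(needed, cell_order)
    idx = {c: i for i, c in enumerate(cells)}
    w = np.zeros((len(cells), len(cells)), dtype=int)
    for s in syns:
        a, b = s.partner_cells
        ia, ib = idx[a], idx[b]
        w[ia, ib] += s.size_sections
        if ia != ib:
            w[ib, ia] += s.size_sections
    return AdjacencyMatrix(cells, w, ObjType.GAP)


def connectivity_vector(
    matrix: AdjacencyMatrix, cell: str, direction: str = "BOTH"
) -> dict[str, float]:
    """Nonzero connection weights of one cell.

    OUT reads the cell's matrix row, IN its column, BOTH their
    element-wise sum.  Zero entries are omitted.
    """
    i = matrix.index(cell)
    direction = direction.upper()
    if direction == "OUT":
        vec = matrix.weights[i, :]
    elif direction == "IN":
        vec = matrix.weights[:, i]
    elif direction == "BOTH":
        vec = matrix.weights[i, :] + matrix.weights[:, i]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return {
        c: float(v)
        for c, v in zip(matrix.cells, vec)
        if v != 0
    }


def _aligned(vec_a: dict, vec_b: dict) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set(vec_a) | set(vec_b))
    a = np.array([vec_a.get(k, 0.0) for k in keys], dtype=float)
    b = np.array([vec_b.get(k, 0.0) for k in keys], dtype=float)
    return a, b


def similarity(
    vec_a: dict[str, float],
    vec_b: dict[str, float],
    method: str = "cosine",
) -> float:
    """Similarity of two connectivity vectors over their partner union.

    Methods: ``cosine``, ``pearson``, ``jaccard_binary`` (overlap of the
    nonzero supports).  Absent partners count as weight 0.  Degenerate
    inputs (both vectors empty, or zero variance for pearson) return 0.0
    with a warning.
    """
    a, b = _aligned(vec_a, vec_b)
    if a.size == 0 or (not a.any() and not b.any()):
        warnings.warn("similarity of two empty vectors is undefined; 0.0")
        return 0.0
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b / (na * nb))
    if method == "pearson":
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            warnings.warn(
                "pearson undefined for constant vectors; returning 0.0"
            )
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])
    if method == "jaccard_binary":
        sa, sb = a != 0, b != 0
        union = (sa | sb).sum()
        return float((sa & sb).sum() / union) if union else 0.0
    raise ValueError(f"unknown similarity method {method!r}")


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Label-shuffling test for a difference in mean similarity scores.

    Used to ask whether duplicate annotations of one neuron are more
    similar to each other than presumptively equivalent neuron pairs
    are.  Returns the observed mean difference (a - b) and the
    two-sided permutation p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = a.size
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        diff = pooled[:n_a].mean() - pooled[n_a:].mean()
        if abs(diff) >= abs(observed) - 1e-12:
            hits += 1
    return {
        "observed_diff": float(observed),
        "p_value": (hits + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }
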