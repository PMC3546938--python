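"""Duplicate-annotation comparison.

Different people annotating the same electron micrographs do not produce
identical synapse lists: presynaptic densities can be faint, polyad
partners doubtful and gap-junction structures uncertain.  This module
quantifies that disagreement two ways: per-synapse agreement categories
(identical / size differs / partner differs / scored by only one
annotator) and per-edge weight uncertainty across two or more duplicate
adjacency matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AdjacencyMatrix, ObjType, Synapse

__all__ = [
    "Category",
    "MatchResult",
    "ConcordanceReport",
    "match_synapses",
    "classify_matches",
    "edge_weight_uncertainty",
    "DEFAULT_TOL_XY",
    "DEFAULT_BIN_EDGES",
]

#: default centroid x/y matching tolerance, in pixels
DEFAULT_TOL_XY = 500.0
#: default reference-weight bin edges for the uncertainty summary:
#: [1, 10], (10, 40], (40, inf)
DEFAULT_BIN_EDGES = (10.0, 40.0)

IDENTICAL = "IDENTICAL"
SIZE_DIFFER = "SIZE_DIFFER"
PARTNER_DIFFER = "PARTNER_DIFFER"
SINGLETON = "SINGLETON"
CATEGORIES = (IDENTICAL, SIZE_DIFFER, PARTNER_DIFFER, SINGLETON)

Category = str


@dataclass
class MatchResult:
    pairs: list[tuple[Synapse, Synapse]]
    unmatched_a: list[Synapse]
    unmatched_b: list[Synapse]


@dataclass
class ConcordanceReport:
    """Synapse-level agreement between two duplicate annotations.

    Fractions are over the total number of distinct synapse sites seen
    by either annotator: matched pairs plus singletons from both sides.
    """

    n_reference_synapses: int
    counts: dict[Category, int]
    matched_pairs: list[tuple[Synapse, Synapse, Category]]
    singletons: list[tuple[str, Synapse]] = field(default_factory=list)
    overlap_both: int = 0  # pairs differing in BOTH partners and size

    @property
    def fractions(self) -> dict[Category, float]:
        total = self.n_reference_synapses
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: self.counts[c] / total for c in CATEGORIES}


def _z_compatible(a: Synapse, b: Synapse, max_gap: int) -> bool:
    (alo, ahi), (blo, bhi) = a.z_span, b.z_span
    return blo - ahi <= max_gap and alo - bhi <= max_gap


def _xy_dist(a: Synapse, b: Synapse) -> float:
    return math.hypot(
        a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1]
    )


def match_synapses(
    set_a: Sequence[Synapse],
    set_b: Sequence[Synapse],
    tol_xy: float = DEFAULT_TOL_XY,
    require_same_pre: bool = False,
    max_z_gap: int = 1,
) -> MatchResult:
    """Greedy one-to-one matching of two duplicate synapse sets.

    Candidate pairs must share synapse type, have overlapping or
    adjacent section spans (gap at most ``max_z_gap``), lie within
    ``tol_xy`` pixels in centroid x/y and, if ``require_same_pre``,
    agree on the presynaptic cell.  Candidates are matched closest
    centroid first; whatever remains on either side is a singleton.
    """
    candidates = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.syn_type is not b.syn_type:
                continue
            if not _z_compatible(a, b, max_z_gap):
                continue
            if require_same_pre and a.pre_cell != b.pre_cell:
                continue
            d = _xy_dist(a, b)
            if d <= tol_xy:
                candidates.append((d, i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Synapse, Synapse]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((set_a[i], set_b[j]))
    unmatched_a = [a for i, a in enumerate(set_a) if i not in used_a]
    unmatched_b = [b for j, b in enumerate(set_b) if j not in used_b]
    return MatchResult(pairs, unmatched_a, unmatched_b)


def classify_matches(match: MatchResult) -> ConcordanceReport:
    """Assign each synapse site an agreement category.

    A matched pair is IDENTICAL when sizes and partner sets agree;
    PARTNER_DIFFER when the postsynaptic (or gap partner) sets differ —
    this takes precedence over a simultaneous size difference, the
    overlap being tallied separately in ``overlap_both`` — and
    SIZE_DIFFER otherwise.  Unmatched synapses are SINGLETONs.  The
    denominator is the number of distinct sites: pairs + singletons.
    """
    counts = {c: 0 for c in CATEGORIES}
    labelled: list[tuple[Synapse, Synapse, Category]] = []
    overlap = 0
    for a, b in match.pairs:
        partners_differ = a.partners() != b.partners()
        sizes_differ = a.size_sections != b.size_sections
        if not partners_differ and not sizes_differ:
            cat = IDENTICAL
        elif partners_differ:
            cat = PARTNER_DIFFER
            if sizes_differ:
                overlap += 1
        else:
            cat = SIZE_DIFFER
        counts[cat] += 1
        labelled.append((a, b, cat))

    singles = [("a", s) for s in match.unmatched_a] + [
        ("b", s) for s in match.unmatched_b
    ]
    counts[SINGLETON] = len(singles)
    total = len(match.pairs) + len(singles)
    return ConcordanceReport(
        n_reference_synapses=total,
        counts=counts,
        matched_pairs=labelled,
        singletons=singles,
        overlap_both=overlap,
    )


def edge_weight_uncertainty(
    matrices: Sequence[AdjacencyMatrix],
    focal_cell: Optional[str] = None,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-edge weight disagreement across duplicate annotations.

    Considers the union of nonzero edges across all matrices
    (optionally restricted to edges touching ``focal_cell``).  For each
    edge the mean absolute pairwise difference between annotators is
    computed, and relative uncertainty = that difference divided by the
    reference weight, the weight assigned by the first-listed annotator.
    The binned summary groups edges by reference weight.

    Returns (per-edge table, binned summary).
    """
    if len(matrices) < 2:
        raise ValueError("need at least two duplicate matrices")
    cells = matrices[0].cells
    mtype = matrices[0].matrix_type
    for m in matrices[1:]:
        if m.cells != cells:
            raise ValueError("matrices must share an identical cell set")
        if m.matrix_type is not mtype:
            raise ValueError("matrices must share a matrix type")

    stack = np.stack([np.asarray(m.weights, dtype=float) for m in matrices])
    nonzero = stack.any(axis=0)
    if mtype is ObjType.GAP:
        nonzero &= np.triu(np.ones_like(nonzero, dtype=bool))
    rows = []
    n = len(cells)
    k = stack.shape[0]
    pair_idx = list(itertools.combinations(range(k), 2))
    for i in range(n):
        for j in range(n):
            if not nonzero[i, j]:
                continue
            if focal_cell is not None and focal_cell not in (
                cells[i],
                cells[j],
            ):
                continue
            weights = stack[:, i, j]
            mad = float(
                np.mean([abs(weights[p] - weights[q]) for p, q in pair_idx])
            )
            ref = float(weights[0])
            rows.append(
                {
                    "pre": cells[i],
                    "post": cells[j],
                    **{
                        f"weight_{a}": float(weights[a]) for a in range(k)
                    },
                    "mean_abs_diff": mad,
                    "reference_weight": ref,
                    "relative_uncertainty": (
                        mad / ref if ref > 0 else float("nan")
                    ),
                }
            )
    per_edge = pd.DataFrame(rows)

    edges = [0.0, *bin_edges, float("inf")]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(
            f"({lo:g}, {hi:g}]" if math.isfinite(hi) else f"> {lo:g}"
        )
    if per_edge.empty:
        binned = pd.DataFrame(
            columns=[
                "bin",
                "n_edges",
                "mean_abs_diff",
                "mean_relative_uncertainty",
            ]
        )
        return per_edge, binned
    usable = per_edge[per_edge["reference_weight"] > 0].copy()
    usable["bin"] = pd.cut(
        usable["reference_weight"], bins=edges, labels=labels
    )
    binned = (
        usable.groupby("bin", observed=False)
        .agg(
            n_edges=("relative_uncertainty", "size"),
            mean_abs_diff=("mean_abs_diff", "mean"),
            mean_relative_uncertainty=("relative_uncertainty", "mean"),
        )
        .reset_index()
    )
    return per_edge, binned
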