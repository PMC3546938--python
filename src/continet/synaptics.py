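"""Synapse consolidation and polyad expansion.

A synapse annotated across several sections is a contin of linked
CHEMICAL or GAP objects; consolidation collapses each such contin into
one Synapse record.  Synapse size is the number of distinct sections the
presynaptic density or gap junction traverses, which makes repeated
objects within one section size-neutral.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

from .core import AnnotationObject, Contin, ObjType, Synapse

__all__ = ["consolidate_synapses", "expand_polyad", "synapse_table_rows"]


def _consensus(payloads: Sequence[tuple]) -> tuple[tuple, bool, tuple]:
    """Majority payload over member objects.

    Returns (winner, inconsistent, variants).  Ties for the majority are
    flagged inconsistent; the winner is then the lexicographically
    smallest of the tied payloads so consolidation stays deterministic.
    """
    counts = Counter(payloads)
    variants = tuple(sorted(counts.items(), key=lambda kv: kv[0]))
    if len(counts) == 1:
        return payloads[0], False, variants
    best = max(counts.values())
    winners = sorted(k for k, v in counts.items() if v == best)
    tied = len(winners) > 1
    return winners[0], True if tied else False, variants


def consolidate_synapses(
    contins: Sequence[Contin],
    objects: Sequence[AnnotationObject],
) -> list[Synapse]:
    """One Synapse record per CHEMICAL/GAP contin.

    Payload (pre/post or partner pair) is the majority vote over member
    objects; any disagreement that leaves a tie flags the synapse
    INCONSISTENT, and in all disagreement cases every variant is
    retained in ``payload_variants`` for reporting.  size_sections is
    the count of distinct member section numbers; the centroid is the
    arithmetic mean of member coordinates.
    """
    by_id = {o.object_id: o for o in objects}
    out: list[Synapse] = []
    for contin in contins:
        if contin.kind is ObjType.NEURITE:
            continue
        members = sorted(
            (by_id[i] for i in contin.object_ids),
            key=lambda o: o.object_id,
        )
        zs = [m.z for m in members]
        payload, _tied, variants = _consensus(
            [m.payload_key() for m in members]
        )
        # any payload disagreement flags the synapse; majority (ties by
        # lexicographic order) still provides a deterministic payload
        inconsistent = len(variants) > 1
        if contin.kind is ObjType.CHEMICAL:
            pre, posts = payload
            partner_pair: tuple[str, ...] = ()
        else:
            pre, posts = None, ()
            (partner_pair,) = payload
        n = len(members)
        centroid = (
            sum(m.x for m in members) / n,
            sum(m.y for m in members) / n,
            sum(zs) / n,
        )
        out.append(
            Synapse(
                synapse_id=contin.contin_id,
                syn_type=contin.kind,
                pre_cell=pre,
                post_cells=tuple(posts),
                partner_cells=tuple(partner_pair),
                size_sections=len(set(zs)),
                centroid=centroid,
                z_span=(min(zs), max(zs)),
                inconsistent=bool(inconsistent),
                payload_variants=variants,
                member_ids=tuple(m.object_id for m in members),
            )
        )
    out.sort(key=lambda s: s.synapse_id)
    return out


def expand_polyad(synapse: Synapse) -> list[tuple[str, str, int]]:
    """Expand a chemical synapse into per-partner (pre, post, size) triples.

    Each postsynaptic partner of a polyad receives the full section
    count, matching the convention that adjacency weights count the
    sections of the presynaptic density per edge.  Gap junctions expand
    to their single unordered pair.
    """
    if synapse.syn_type is ObjType.GAP:
        raise ValueError(
            "expand_polyad applies to chemical synapses; use the "
            "partner pair of a gap junction directly"
        )
    return [
        (synapse.pre_cell, post, synapse.size_sections)
        for post in synapse.post_cells
    ]


def synapse_table_rows(synapses: Sequence[Synapse]) -> list[dict]:
    """Rows for the synapse-list TSV output."""
    rows = []
    for s in synapses:
        rows.append(
            {
                "synapse_id": s.synapse_id,
                "type": s.syn_type.value,
                "pre": s.pre_cell or "",
                "posts": ",".join(
                    s.post_cells
                    if s.syn_type is ObjType.CHEMICAL
                    else s.partner_cells
                ),
                "size_sections": s.size_sections,
                "z_min": s.z_span[0],
                "z_max": s.z_span[1],
                "centroid_x": f"{s.centroid[0]:.2f}",
                "centroid_y": f"{s.centroid[1]:.2f}",
                "centroid_z": f"{s.centroid[2]:.2f}",
                "inconsistent": int(s.inconsistent),
            }
        )
    return rows
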