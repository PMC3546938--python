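"""Synthetic nervous systems and simulated annotators.

Real duplicate-annotation data is not publishable at desk scale, so this
module generates ground-truth projects with the statistical structure of
serial-section EM annotation — multi-section neurons traced as one point
per section, polyadic chemical synapses, multi-section synapse sizes,
gap junctions — and then simulates independent annotators whose output
departs from the truth through three planted error channels: missed
synapses (faint presynaptic densities), swapped polyad partners
(doubtful postsynaptic cells) and +/-1-section size jitter.  Neurite
tracing itself is copied faithfully: architecture determination from a
good series is reliable, and tracing noise is deliberately out of the
default model.

All randomness flows from a single seeded generator, consumed in a
documented order (neurons, then synapses, then noise), so a fixed seed
gives byte-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .connectivity import chemical_adjacency, gap_adjacency
from .core import (
    AdjacencyMatrix,
    AnnotationObject,
    ObjType,
    Relationship,
    Synapse,
)
from .io import ProjectBundle, SectionMeta

__all__ = [
    "NoiseModel",
    "SynthConfig",
    "GroundTruth",
    "generate_truth",
    "simulate_annotator",
    "expected_category_fractions",
    "CrossMatchStats",
    "cross_match_statistics",
    "recover_noise_rates",
]

#: field of view in pixels (large montaged TEM mosaics)
FOV = 16_000.0


@dataclass(frozen=True)
class NoiseModel:
    """Planted annotator error rates.

    miss_probability
        Chance a true synapse is not scored at all.
    partner_swap_probability
        Chance one partner of a scored synapse is replaced by a random
        other neuron.
    size_jitter_probability
        Chance the scored size differs by one section (+/-1; a
        size-1 synapse can only grow).
    xy_jitter_sd
        Gaussian jitter, in pixels, on each synapse object's placement.
    """

    miss_probability: float = 0.0
    partner_swap_probability: float = 0.0
    size_jitter_probability: float = 0.0
    jitter_magnitude: int = 1
    xy_jitter_sd: float = 30.0

    def validate(self) -> None:
        for name in (
            "miss_probability",
            "partner_swap_probability",
            "size_jitter_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.xy_jitter_sd < 0:
            raise ValueError("xy_jitter_sd must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic nervous system.

    Defaults describe a small but realistic posterior-ganglion-sized
    series: 30 neurons over 80 sections, mostly unbranched neurites,
    polyads common (roughly two thirds of chemical synapses have more
    than one postsynaptic partner would be too many; here ~65% are
    monads or dyads), synapse sizes concentrated on 1-3 sections, and
    about one synapse in seven a gap junction.
    """

    n_neurons: int = 30
    n_sections: int = 80
    mean_profiles_per_section: float = 15.0
    branch_probability: float = 0.03
    synapse_density: float = 12.0  # expected synapses per neuron
    polyad_size_distribution: tuple[float, ...] = (0.35, 0.45, 0.20)
    synapse_size_distribution: tuple[float, ...] = (
        0.35,
        0.30,
        0.20,
        0.10,
        0.05,
    )
    gap_fraction: float = 0.15
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be positive")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.synapse_density < 0:
            raise ValueError("synapse_density must be non-negative")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability outside [0, 1]")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction outside [0, 1]")
        for name in (
            "polyad_size_distribution",
            "synapse_size_distribution",
        ):
            dist = getattr(self, name)
            if not dist or any(p < 0 for p in dist):
                raise ValueError(f"{name} must be non-negative")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if (
            self.synapse_density > 0
            and self.n_neurons < 2
        ):
            raise ValueError(
                "synapses need at least two neurons (pre and post)"
            )
        self.noise.validate()


@dataclass
class _Neuron:
    name: str
    z0: int
    trunk: dict[int, tuple[int, float, float]]  # z -> (object_id, x, y)

    def covers(self, z: int) -> bool:
        return z in self.trunk


@dataclass
class GroundTruth:
    """A generated project plus its known answers."""

    config: SynthConfig
    bundle: ProjectBundle
    synapses: list[Synapse]
    chemical_matrix: AdjacencyMatrix
    gap_matrix: AdjacencyMatrix
    neuron_names: list[str]


def _draw(rng: np.random.Generator, dist: Sequence[float]) -> int:
    """Index 1..len(dist) drawn from a probability vector."""
    return int(rng.choice(len(dist), p=np.asarray(dist) / sum(dist))) + 1


def generate_truth(config: SynthConfig) -> GroundTruth:
    """Generate a ground-truth project from the configuration.

    Each neuron is a lattice random walk through its section range (one
    NEURITE object per occupied section, cell body at the lowest
    section), with side branches spawned at per-node probability
    ``branch_probability``.  Synapses sit at neuron-adjacent positions
    with sizes and polyad widths drawn from the configured
    distributions.  The returned matrices are computed from the true
    synapse list, so by construction they equal what the assembly
    pipeline should recover from the tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    objects: list[AnnotationObject] = []
    relationships: list[Relationship] = []
    next_id = 1

    def new_id() -> int:
        nonlocal next_id
        i = next_id
        next_id += 1
        return i

    # --- neurons -------------------------------------------------------
    target_span = max(
        2.0,
        config.mean_profiles_per_section
        * config.n_sections
        / config.n_neurons,
    )
    neurons: list[_Neuron] = []
    width = len(str(config.n_neurons))
    for n_idx in range(config.n_neurons):
        name = f"N{n_idx + 1:0{width}d}"
        span = int(
            np.clip(
                round(rng.normal(target_span, target_span / 4)),
                2,
                config.n_sections,
            )
        )
        z0 = int(rng.integers(1, config.n_sections - span + 2))
        x = float(rng.uniform(0.05 * FOV, 0.95 * FOV))
        y = float(rng.uniform(0.05 * FOV, 0.95 * FOV))
        trunk: dict[int, tuple[int, float, float]] = {}
        prev_id: Optional[int] = None
        for z in range(z0, z0 + span):
            oid = new_id()
            objects.append(
                AnnotationObject(
                    oid,
                    round(x, 1),
                    round(y, 1),
                    z,
                    ObjType.NEURITE,
                    cell_name=name,
                    annotator_id="truth",
                    is_cell_body=(z == z0),
                )
            )
            trunk[z] = (oid, x, y)
            if prev_id is not None:
                relationships.append(Relationship(prev_id, oid, "truth"))
            prev_id = oid
            x += float(rng.normal(0, 40))
            y += float(rng.normal(0, 40))
        # side branches off the trunk
        for z in range(z0, z0 + span - 1):
            if rng.random() >= config.branch_probability:
                continue
            length = min(
                1 + int(rng.geometric(0.3)), z0 + span - 1 - z
            )
            if length < 1:
                continue
            parent_id, bx, by = trunk[z]
            bx += float(rng.normal(0, 120))
            by += float(rng.normal(0, 120))
            prev = parent_id
            for bz in range(z + 1, z + 1 + length):
                oid = new_id()
                objects.append(
                    AnnotationObject(
                        oid,
                        round(bx, 1),
                        round(by, 1),
                        bz,
                        ObjType.NEURITE,
                        cell_name=name,
                        annotator_id="truth",
                    )
                )
                relationships.append(Relationship(prev, oid, "truth"))
                prev = oid
                bx += float(rng.normal(0, 40))
                by += float(rng.normal(0, 40))
        neurons.append(_Neuron(name, z0, trunk))

    # --- synapses ------------------------------------------------------
    synapses: list[Synapse] = []
    n_syn = int(round(config.n_neurons * config.synapse_density))
    names = [n.name for n in neurons]
    for _ in range(n_syn):
        is_gap = bool(rng.random() < config.gap_fraction)
        size = _draw(rng, config.synapse_size_distribution)
        pre = neurons[int(rng.integers(config.n_neurons))]
        span = len(pre.trunk)
        size = min(size, span)
        z_lo = min(pre.trunk)
        z_start = int(rng.integers(z_lo, z_lo + span - size + 1))
        # partners: prefer neurons passing through the same section
        candidates = [
            n.name
            for n in neurons
            if n.name != pre.name and n.covers(z_start)
        ]
        if not candidates:
            candidates = [n for n in names if n != pre.name]
        if is_gap:
            partner = str(rng.choice(candidates))
            pre_cell, posts = None, ()
            partner_cells = (pre.name, partner)
        else:
            k = min(_draw(rng, config.polyad_size_distribution),
                    len(candidates))
            posts = tuple(
                str(c)
                for c in rng.choice(candidates, size=k, replace=False)
            )
            pre_cell, partner_cells = pre.name, ()
        member_ids: list[int] = []
        xs, ys, zs = [], [], []
        prev = None
        for z in range(z_start, z_start + size):
            _, tx, ty = pre.trunk[min(pre.trunk, key=lambda t: abs(t - z))]
            ox = round(tx + float(rng.normal(0, 20)), 1)
            oy = round(ty + float(rng.normal(0, 20)), 1)
            oid = new_id()
            objects.append(
                AnnotationObject(
                    oid,
                    ox,
                    oy,
                    z,
                    ObjType.GAP if is_gap else ObjType.CHEMICAL,
                    pre_cell=pre_cell,
                    post_cells=posts,
                    partner_cells=partner_cells,
                    annotator_id="truth",
                )
            )
            if prev is not None:
                relationships.append(Relationship(prev, oid, "truth"))
            prev = oid
            member_ids.append(oid)
            xs.append(ox)
            ys.append(oy)
            zs.append(z)
        synapses.append(
            Synapse(
                synapse_id=min(member_ids),
                syn_type=ObjType.GAP if is_gap else ObjType.CHEMICAL,
                pre_cell=pre_cell,
                post_cells=posts,
                partner_cells=partner_cells,
                size_sections=len(set(zs)),
                centroid=(
                    sum(xs) / len(xs),
                    sum(ys) / len(ys),
                    sum(zs) / len(zs),
                ),
                z_span=(min(zs), max(zs)),
                member_ids=tuple(member_ids),
            )
        )

    bundle = ProjectBundle(
        objects=objects,
        relationships=relationships,
        series_meta={
            z: SectionMeta(80.0, True)
            for z in range(1, config.n_sections + 1)
        },
    )
    return GroundTruth(
        config=config,
        bundle=bundle,
        synapses=synapses,
        chemical_matrix=chemical_adjacency(synapses, cell_order=names),
        gap_matrix=gap_adjacency(synapses, cell_order=names),
        neuron_names=names,
    )


def simulate_annotator(
    truth: GroundTruth,
    noise: NoiseModel,
    seed: int,
    annotator_id: str = "sim",
) -> ProjectBundle:
    """One simulated annotator's tables for a ground-truth project.

    Neurite annotations are copied faithfully.  Each true synapse is
    independently dropped with the miss probability; survivors have one
    partner swapped to a random other neuron with the swap probability,
    their size perturbed by one section with the jitter probability
    (size 1 can only grow), and every synapse object's x/y jittered.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    names = truth.neuron_names
    n_sections = truth.config.n_sections

    objects: list[AnnotationObject] = []
    relationships: list[Relationship] = []
    for o in truth.bundle.objects:
        if o.obj_type is ObjType.NEURITE:
            objects.append(o.copy(annotator_id=annotator_id,
                                  contin_id=None))
    neurite_ids = {o.object_id for o in objects}
    for r in truth.bundle.relationships:
        if r.object_id_a in neurite_ids and r.object_id_b in neurite_ids:
            relationships.append(
                Relationship(r.object_id_a, r.object_id_b, annotator_id)
            )

    next_id = max(o.object_id for o in truth.bundle.objects) + 1
    for syn in truth.synapses:
        if rng.random() < noise.miss_probability:
            continue
        pre_cell = syn.pre_cell
        posts = list(syn.post_cells)
        partner_cells = list(syn.partner_cells)
        if rng.random() < noise.partner_swap_probability:
            if syn.syn_type is ObjType.CHEMICAL:
                idx = int(rng.integers(len(posts)))
                pool = [
                    n
                    for n in names
                    if n != pre_cell and n not in posts
                ]
                if pool:
                    posts[idx] = str(rng.choice(pool))
            else:
                idx = int(rng.integers(2))
                pool = [n for n in names if n not in partner_cells]
                if pool:
                    partner_cells[idx] = str(rng.choice(pool))
        size = syn.size_sections
        if rng.random() < noise.size_jitter_probability:
            if size <= 1:
                delta = noise.jitter_magnitude
            else:
                delta = int(rng.choice([-1, 1])) * noise.jitter_magnitude
            size = max(1, size + delta)
        z_start = syn.z_span[0]
        if z_start + size - 1 > n_sections:
            z_start = max(1, n_sections - size + 1)
        cx, cy = syn.centroid[0], syn.centroid[1]
        prev = None
        for z in range(z_start, z_start + size):
            ox = round(cx + float(rng.normal(0, noise.xy_jitter_sd)), 1)
            oy = round(cy + float(rng.normal(0, noise.xy_jitter_sd)), 1)
            oid = next_id
            next_id += 1
            objects.append(
                AnnotationObject(
                    oid,
                    ox,
                    oy,
                    z,
                    syn.syn_type,
                    pre_cell=pre_cell,
                    post_cells=tuple(posts),
                    partner_cells=tuple(partner_cells),
                    annotator_id=annotator_id,
                )
            )
            if prev is not None:
                relationships.append(Relationship(prev, oid, annotator_id))
            prev = oid

    return ProjectBundle(
        objects=objects,
        relationships=relationships,
        series_meta=dict(truth.bundle.series_meta),
    )


@dataclass
class CrossMatchStats:
    """Confusable-synapse statistics feeding the concordance model.

    ``n_pairs`` counts unordered pairs of distinct true synapses a
    position-based matcher could conflate (same type, overlapping or
    adjacent section spans, within the x/y tolerance) — synapses on the
    same neurite at nearby sections.  ``sum_p_cross_both`` and
    ``sum_p_cross_three`` accumulate, over those pairs, the
    probabilities that greedy closest-first matching crosses them when
    all four copies survive, respectively when one copy is missing.
    """

    n_pairs: int = 0
    sum_p_cross_both: float = 0.0
    sum_p_cross_three: float = 0.0

    def __add__(self, other: "CrossMatchStats") -> "CrossMatchStats":
        return CrossMatchStats(
            self.n_pairs + other.n_pairs,
            self.sum_p_cross_both + other.sum_p_cross_both,
            self.sum_p_cross_three + other.sum_p_cross_three,
        )


def cross_match_statistics(
    truth: GroundTruth,
    noise: NoiseModel,
    tol_xy: float = 500.0,
    max_z_gap: int = 1,
    n_mc: int = 2000,
    mc_seed: int = 12345,
) -> CrossMatchStats:
    """Cross-pairing probabilities for every confusable synapse pair.

    For a confusable pair at centroid separation d, each annotator's
    copy of each synapse lands at the true centroid plus Gaussian
    centroid jitter (xy_jitter_sd / sqrt(size), the mean of per-object
    jitters).  Greedy closest-first matching crosses the pair when the
    smallest of the four candidate distances is a cross distance; the
    probabilities have no closed form in d, so they are evaluated by a
    fixed-seed Monte Carlo per pair.
    """
    rng = np.random.default_rng(mc_seed)
    stats = CrossMatchStats()
    syns = truth.synapses
    for i, a in enumerate(syns):
        for b in syns[i + 1:]:
            if a.syn_type is not b.syn_type:
                continue
            (alo, ahi), (blo, bhi) = a.z_span, b.z_span
            if blo - ahi > max_z_gap or alo - bhi > max_z_gap:
                continue
            dx = a.centroid[0] - b.centroid[0]
            dy = a.centroid[1] - b.centroid[1]
            d2 = dx * dx + dy * dy
            if d2 > tol_xy * tol_xy:
                continue
            d = math.sqrt(d2)
            sa = noise.xy_jitter_sd / math.sqrt(a.size_sections)
            sb = noise.xy_jitter_sd / math.sqrt(b.size_sections)
            # a_i, b_i at origin (jitter sa); a_j, b_j at (d, 0) (sb)
            ai = rng.normal(0.0, sa, size=(n_mc, 2))
            bi = rng.normal(0.0, sa, size=(n_mc, 2))
            aj = rng.normal(0.0, sb, size=(n_mc, 2)) + (d, 0.0)
            bj = rng.normal(0.0, sb, size=(n_mc, 2)) + (d, 0.0)
            t1 = np.linalg.norm(ai - bi, axis=1)
            t2 = np.linalg.norm(aj - bj, axis=1)
            c1 = np.linalg.norm(ai - bj, axis=1)
            c2 = np.linalg.norm(aj - bi, axis=1)
            p_both = float(
                (np.minimum(c1, c2) < np.minimum(t1, t2)).mean()
            )
            p_three = float(0.5 * ((c1 < t2).mean() + (c2 < t1).mean()))
            stats = stats + CrossMatchStats(1, p_both, p_three)
    return stats


def expected_category_fractions(
    noise: NoiseModel,
    size_distribution: Sequence[float],
    n_synapses: Optional[int] = None,
    cross_stats: Optional[CrossMatchStats] = None,
) -> dict[str, float]:
    """Analytic concordance-category expectations for two annotators.

    With independent annotators each missing a synapse at rate m, the
    expected fraction of sites seen by only one of them is
    2m(1-m) / (1 - m^2) = 2m / (1 + m); matched pairs make up the
    remaining (1-m)/(1+m).  A pair differs in partners unless neither
    annotator swapped: probability 1 - (1-q)^2 (coincidentally equal
    swaps are neglected).  Given equal partners, sizes differ when
    exactly one annotator jittered, or both jittered with opposite
    signs — the latter is impossible for size-1 synapses, whose jitter
    is always +1, so with pi1 the probability of a size-1 synapse the
    size-difference probability is 2s(1-s) + s^2 (1 - pi1)/2.

    When ``n_synapses`` and ``cross_stats`` (from
    :func:`cross_match_statistics`) are given, the expectations also
    model matcher confusion between co-located synapse pairs {i, j}:

    - one annotator missed i and the other missed j (probability
      2 m^2 (1-m)^2 per pair): the two would-be singletons form one
      false pair, counted as PARTNER_DIFFER;
    - all four copies survive ((1-m)^4) and greedy matching crosses
      them (probability p_cross_both): two pairs that would be
      classified normally both become PARTNER_DIFFER;
    - exactly one of the four copies is missing (4 m (1-m)^3) and the
      surviving odd copy steals the match (p_cross_three): one pair
      becomes PARTNER_DIFFER, the singleton count is unchanged.
    """
    m = noise.miss_probability
    q = noise.partner_swap_probability
    s = noise.size_jitter_probability
    dist = np.asarray(size_distribution, dtype=float)
    dist = dist / dist.sum()
    pi1 = float(dist[0])

    f_single = 2 * m / (1 + m) if m < 1 else 1.0
    pair_frac = 1.0 - f_single
    p_partner = 1 - (1 - q) ** 2
    p_size = 2 * s * (1 - s) + s**2 * (1 - pi1) / 2
    f_partner = pair_frac * p_partner
    f_size = pair_frac * (1 - p_partner) * p_size
    f_identical = pair_frac * (1 - p_partner) * (1 - p_size)
    fractions = {
        "SINGLETON": f_single,
        "PARTNER_DIFFER": f_partner,
        "SIZE_DIFFER": f_size,
        "IDENTICAL": f_identical,
    }
    if n_synapses is None or cross_stats is None:
        return fractions
    sites = n_synapses * (1 - m**2)
    counts = {k: v * sites for k, v in fractions.items()}
    false_matches = 2 * cross_stats.n_pairs * m**2 * (1 - m) ** 2
    counts["SINGLETON"] -= 2 * false_matches
    counts["PARTNER_DIFFER"] += false_matches
    sites -= false_matches
    pairs_crossed = (
        2 * (1 - m) ** 4 * cross_stats.sum_p_cross_both
        + 4 * m * (1 - m) ** 3 * cross_stats.sum_p_cross_three
    )
    shifted = pairs_crossed * (1 - p_partner)
    counts["PARTNER_DIFFER"] += shifted
    counts["IDENTICAL"] -= shifted * (1 - p_size)
    counts["SIZE_DIFFER"] -= shifted * p_size
    return {k: v / sites for k, v in counts.items()}


def recover_noise_rates(
    fractions: dict[str, float], size_distribution: Sequence[float]
) -> tuple[float, float, float]:
    """Invert the analytic mapping: category fractions -> (m, q, s)."""
    f_single = fractions["SINGLETON"]
    m = f_single / (2 - f_single)
    pair_frac = 1.0 - f_single
    if pair_frac <= 0:
        return m, float("nan"), float("nan")
    p_partner = min(1.0, fractions["PARTNER_DIFFER"] / pair_frac)
    q = 1.0 - math.sqrt(max(0.0, 1.0 - p_partner))
    dist = np.asarray(size_distribution, dtype=float)
    pi1 = float(dist[0] / dist.sum())
    denom = pair_frac * (1 - p_partner)
    if denom <= 0:
        return m, q, float("nan")
    p_size = min(1.0, fractions["SIZE_DIFFER"] / denom)
    # solve 2s(1-s) + s^2 (1-pi1)/2 = p_size for s in [0, 1]
    a = (1 - pi1) / 2 - 2
    if a == 0:
        return m, q, p_size / 2
    disc = 4 + 4 * a * p_size
    s = (-2 + math.sqrt(max(0.0, disc))) / (2 * a)
    return m, q, s
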