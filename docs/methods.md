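# Methods

This note documents the procedures, conventions and numerical choices
behind `continet`, in the spirit of a methods appendix: what each stage
computes, which decisions were genuinely open and how they were made,
and what the synthetic-data experiments do and do not establish.

## Data model

An annotation project is two flat UTF-8 TSV tables (plus an optional
per-section metadata table), each opened by a one-line schema tag that
readers verify.

- **Object table** — one row per annotated point. `x`/`y` are 0-based
  pixel coordinates in the source image; `z` is the 1-based section
  number as printed on micrographs (sections are 70–90 nm slices; we
  default to 80 nm where a physical thickness is needed). `obj_type`
  is NEURITE, CHEMICAL or GAP and determines the payload: a neurite
  profile may carry a cell name and a cell-body flag; a chemical
  synapse object carries the presynaptic cell and an ordered list of
  postsynaptic partners (more than one makes it a *polyad*); a gap
  junction carries its unordered pair of partners. Cell names are free
  text, case-sensitive, whitespace-stripped on ingest.
- **Relationship table** — one row per undirected continuity link
  between two objects, stored canonically with the smaller id first.
  Links must join objects of the same type.

Writers sort rows (objects by id, relationships by pair) and format
numbers minimally, so identical content yields byte-identical files and
write∘read∘write is a fixed point. Multi-valued fields join on `,`,
safe because fields are tab-delimited.

`validate_project` checks every invariant — dangling references,
type-mixing links, duplicate ids and links, malformed synaptic
payloads, section gaps inside a neurite chain beyond a tolerance
(default 3 sections: small gaps are real missing sections, not errors),
cycles in neurite chains, conflicting cell names within one chain — and
returns a sorted issue list rather than raising, so imperfect data can
be loaded and repaired. Cycles and name conflicts are warnings (real
neurites are trees, but an annotation error should not block loading);
structural problems are errors. Validation is order-independent.

## Assembly

Contins are the connected components of the relationship graph, with
isolated objects as singletons (networkx provides the components; an
independent hand-written BFS serves as the test oracle). The contin id
is the minimum member object id — stable when later annotation rounds
append objects, unlike sequential numbering. Object membership is
exclusive; a neurite contin's name resolves to the unique non-empty
member cell name, with conflicts reported rather than guessed.

A neurite contin becomes a rooted skeleton. Root choice: the member
flagged as cell body (ties by minimal id), else the endpoint with the
lowest section number, ties again by id — the soma, when marked, is the
biologically meaningful origin; otherwise the series start is the most
reproducible anchor. If the chain contains cycles they are broken
deterministically before rooting: edges are admitted in ascending order
of the sum of their endpoint ids (Kruskal), so within each cycle the
edge whose endpoints have the maximal combined id is dropped and
recorded. Branch points are nodes of degree ≥ 3, endpoints degree ≤ 1.

## Synapses

Each CHEMICAL/GAP contin consolidates to one synapse record.

- **Size** = number of *distinct* member section numbers. Two objects
  in the same section are size-neutral, which also future-proofs the
  format for more than one synapse object per synapse per image (the
  in-plane extension used for mammalian neuropil is out of scope).
- **Payload consensus** = majority vote over member objects' payloads;
  ties resolve to the lexicographically smallest payload so output is
  deterministic. Any disagreement flags the synapse INCONSISTENT and
  all variants are kept for reporting. Inconsistent synapses are
  excluded from adjacency matrices unless explicitly included.
- **Centroid** = arithmetic mean of member (x, y, z).
- **Polyad expansion**: a chemical synapse of size *w* with partners
  {p₁…p_k} expands to k triples (pre, p_i, w). Each partner receives
  the full section count because the matrix convention is "connection
  strength in number of serial sections" per edge; an even split
  (w/k per partner) is available as an option but off by default.

## Adjacency matrices

Chemical: `W[pre][post] += size` per expanded triple; directed; total
therefore equals Σ size × #partners exactly (asserted on every run).
Gap: symmetric, both `W[i][j]` and `W[j][i]` incremented per junction;
a self-junction lands once on the diagonal (the convention is ours —
the data model does not forbid autapses). Cells sort lexicographically
unless a caller supplies an order; CSV output puts presynaptic cells on
rows. Connectivity vectors (row, column, or their sum, zeros omitted)
feed three similarity measures over the union of partner namespaces —
cosine, Pearson, binary Jaccard — and a seeded label-shuffling
permutation test (default 10,000 permutations) for comparing groups of
similarity scores, e.g. duplicate-annotation similarities against
left/right-homolog similarities. The similarity measure used in the
original analyses of this kind is not documented anywhere we could
follow; these are standard, explicitly named defaults, not a
reconstruction.

## Skeleton maps

The 2D map plots section number on the horizontal axis (scale bar
included) and assigns branches to horizontal lanes: depth-first from
the root, children ordered by subtree z-extent (largest first), the
largest child continuing its parent's lane and each other branch taking
the lowest lane whose reserved z-intervals it does not overlap. The
no-two-branches-share-a-lane-over-overlapping-z property is asserted by
a pairwise scan in tests. Gaps of more than one section inside a
branch are drawn dashed, to scale (we draw missing sections at their
true width rather than collapsing them). Synapses attach to the
skeleton node nearest their centroid (Euclidean, with z scaled by
section thickness) and render as perpendicular ticks: red = chemical
input (cell is postsynaptic), magenta = chemical output, green = gap
junction; tick stroke width = base width × synapse size; the cell body
is a solid blue box. SVG is emitted via deterministic element-tree
serialisation: identical inputs give byte-identical files. SWC export
(sample ids from 1, root parent −1, parents before children, type code
0, radius = half a section thickness since the reconstruction is
non-volumetric) covers 3D interchange.

## Concordance

Two duplicate annotations are compared in three steps.

1. **Matching.** Candidate pairs must share synapse type, have
   overlapping or adjacent z-spans (gap ≤ 1 section), centroid x/y
   distance ≤ 500 px (configurable; generous relative to the ~30 px
   placement scatter we model, to be robust to real offsets), and
   optionally the same presynaptic cell. Greedy, closest centroid
   first, one-to-one. Everything unmatched is a singleton.
2. **Categories.** A pair is IDENTICAL (equal sizes and equal partner
   sets), PARTNER_DIFFER (partner sets differ — this takes precedence
   when size also differs, being the graver error; the overlap is
   tallied separately), else SIZE_DIFFER. Fractions are over all
   distinct sites: matched pairs + singletons from both annotators.
3. **Edge-weight uncertainty.** Over ≥ 2 duplicate matrices sharing a
   cell set, each nonzero-anywhere edge (optionally restricted to a
   focal cell) gets the mean absolute pairwise difference across
   annotators and a relative uncertainty = that difference divided by
   the first-listed annotator's weight (an explicit, arbitrary
   reference). Binned summary by reference weight, default bins
   [1, 10], (10, 40], (40, ∞).

## Synthetic data

`generate_truth` emulates the statistical structure of a small
serial-section reconstruction. Each neuron occupies a contiguous
section range (span drawn around mean_profiles_per_section ×
n_sections / n_neurons) and walks laterally with ~40 px/section steps
across a 16,000 px field of view; one NEURITE object per occupied
section, cell body at the lowest section, side branches spawned with a
per-node probability. Synapses pick a presynaptic neuron, a size from
the configured distribution, a section window inside that neuron's
span, and partners preferentially among neurons passing through the
same section; objects are laid one per section alongside the
presynaptic trunk and chained. Defaults (30 neurons, 80 sections,
~12 synapses/neuron, polyad widths 1–3 with probabilities
0.35/0.45/0.20, sizes 1–5 with probabilities 0.35/0.30/0.20/0.10/0.05,
15% gap junctions) describe a small ganglion-scale series with polyads
common and most synapses 1–3 sections, as in nematode neuropil. One
seeded generator is consumed in documented order (neurons, then
synapses, then noise), so a fixed seed gives byte-identical tables.

`simulate_annotator` copies neurite tracing faithfully — architecture
determination from a good series is reliable, and tracing noise is
deliberately excluded from the default model — and corrupts only the
synapse channel, mirroring the real ambiguity classes: each true
synapse is dropped with probability *m* (faint densities), one partner
is swapped to a random other neuron with probability *q* (doubtful
polyad partners), size changes by ±1 section with probability *s*
(size-1 synapses can only grow), and object positions get Gaussian
x/y jitter (default sd 30 px).

What the generator does **not** emulate: neurite tracing errors
(split/merge), image registration drift, section loss, correlated
errors between annotators, or realistic neurite geometry beyond
section-by-section continuity. Passing tests therefore demonstrate the
bookkeeping — assembly, sizing, weighting, comparison — is correct, not
that real annotators behave like the noise model.

## Analytic concordance expectations

For two independent annotators with rates (m, q, s), per true synapse:
both miss with m², one misses with 2m(1−m) (a singleton), both keep
with (1−m)² (a pair). Hence the expected SINGLETON fraction of sites is
2m/(1+m). A pair's partner sets differ unless neither swapped:
1 − (1−q)² (coincidentally equal swaps are neglected; with ~30 neurons
the probability is < 10⁻³). Given equal partners, sizes differ if
exactly one annotator jittered, or both jittered with opposite signs —
impossible for size-1 synapses, whose jitter is always +1 — giving
2s(1−s) + s²(1−π₁)/2 with π₁ the probability of a size-1 synapse.

Position-based matching adds a geometric confusion term: two true
synapses on the same neurite at overlapping sections are *confusable*
(same type, z-compatible, within tolerance). For each such pair,
(a) if one annotator missed one and the other missed the other
(2m²(1−m)²), the leftovers falsely pair — two singletons become one
PARTNER_DIFFER pair; (b) if all four copies survive ((1−m)⁴) greedy
matching crosses them whenever the smallest of the four candidate
distances is a cross distance, converting two normally-classified pairs
into PARTNER_DIFFER; (c) if exactly one copy is missing (4m(1−m)³) the
odd survivor can steal the match, converting one pair. The crossing
probabilities depend on the pair's centroid separation relative to the
centroid jitter (xy_jitter_sd/√size) and have no closed form, so they
are evaluated per confusable pair by a fixed-seed Monte Carlo
(`cross_match_statistics`, 2,000 draws/pair). On three independent
batches of 150 simulated duplicate pairs (~5,850 sites each) all four
category fractions agree with these expectations within one binomial
standard error. `recover_noise_rates` inverts the uncorrected mapping
to estimate (m, q, s) from observed fractions.

## Problem sizes and tolerances in the tests

The acceptance-style checks use sizes chosen to finish in seconds on
one CPU while keeping Monte-Carlo error well below the assertion bands:
100 random projects up to 5,000 objects for the assembly oracle;
50 simulated duplicate-annotation projects of 40 synapses each
(≈ 2,000 sites) for noise-rate recovery at (m, q, s) =
(0.15, 0.2, 0.25), asserted within 3 binomial standard errors; the
uncertainty trend aggregates edges from six simulations (two
configurations × three sub-seeds, ~1,000 edges) so all three weight
bins are well populated, and asserts strict monotone decrease of mean
relative uncertainty. Exactness claims (weight conservation, gap
symmetry, round trips, noise-free end-to-end agreement, byte-level
determinism) are asserted with zero tolerance.

## Known limitations

- Matching is greedy, not optimal assignment; in dense neuropil with
  co-located synapses it conflates neighbours at the rate modelled
  above. The analytic correction assumes confusable pairs are isolated
  (clusters of ≥ 3 co-located synapses are rare at the densities used).
- Polyad partner differences are counted per synapse, not per partner.
- Gap junctions are undirected with no per-partner convention beyond
  the pair; relative weight uncertainty is undefined (NaN) for edges
  the reference annotator scored zero, and such edges are excluded from
  the binned summary.
- The SWC radius is a nominal constant (half a section thickness): the
  reconstruction carries no volumetric information.
- Skeleton lane layout is a readability heuristic; it asserts
  non-collision, not minimal height.
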