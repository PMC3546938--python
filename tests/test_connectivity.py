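"""Adjacency matrices, connectivity vectors and similarity measures."""

import numpy as np
import pytest
import scipy.stats

from continet import (
    ObjType,
    Synapse,
    chemical_adjacency,
    connectivity_vector,
    gap_adjacency,
    permutation_test,
    similarity,
)


def make_chem(sid, pre, posts, size, inconsistent=False):
    return Synapse(
        sid, ObjType.CHEMICAL, pre, tuple(posts), (), size,
        (0.0, 0.0, 0.0), (1, size), inconsistent=inconsistent,
    )


def make_gap(sid, partners, size):
    return Synapse(
        sid, ObjType.GAP, None, (), tuple(partners), size,
        (0.0, 0.0, 0.0), (1, size),
    )


def random_chems(rng, n, n_cells=12):
    cells = [f"C{i:02d}" for i in range(n_cells)]
    syns = []
    for sid in range(1, n + 1):
        pre = str(rng.choice(cells))
        k = int(rng.integers(1, 4))
        posts = rng.choice(
            [c for c in cells if c != pre], size=k, replace=False
        )
        syns.append(make_chem(sid, pre, [str(p) for p in posts],
                              int(rng.integers(1, 6))))
    return cells, syns


class TestChemicalAdjacency:
    def test_sizes_sum_per_edge(self):
        syns = [make_chem(1, "A", ["B"], 2), make_chem(2, "A", ["B"], 3)]
        m = chemical_adjacency(syns)
        assert m["A", "B"] == 5

    def test_empty_synapse_list_zero_matrix(self):
        m = chemical_adjacency([], cell_order=["A", "B"])
        assert m.cells == ["A", "B"]
        assert m.total() == 0

    def test_inconsistent_excluded_by_default(self):
        syns = [make_chem(1, "A", ["B"], 2, inconsistent=True)]
        assert chemical_adjacency(syns, cell_order=["A", "B"]).total() == 0
        assert (
            chemical_adjacency(syns, include_inconsistent=True).total() == 2
        )

    def test_cell_order_missing_cell_named(self):
        with pytest.raises(ValueError, match="B"):
            chemical_adjacency([make_chem(1, "A", ["B"], 1)],
                               cell_order=["A"])

    def test_polyad_split_divides_weight(self):
        syns = [make_chem(1, "A", ["B", "C"], 3)]
        m = chemical_adjacency(syns, polyad_split=True)
        assert m["A", "B"] == pytest.approx(1.5)
        assert m.total() == pytest.approx(3.0)

    def test_weight_conservation_and_entry_oracle(self, rng):
        cells, syns = random_chems(rng, 300)
        m = chemical_adjacency(syns, cell_order=cells)
        assert m.total() == sum(
            s.size_sections * len(s.post_cells) for s in syns
        )
        # brute-force accumulation oracle, independent of expand_polyad
        acc = {}
        for s in syns:
            for post in s.post_cells:
                acc[(s.pre_cell, post)] = (
                    acc.get((s.pre_cell, post), 0) + s.size_sections
                )
        for (pre, post), w in acc.items():
            assert m[pre, post] == w
        assert m.total() == sum(acc.values())


class TestGapAdjacency:
    def test_single_junction_both_entries(self):
        m = gap_adjacency([make_gap(1, ["C", "D"], 4)])
        assert m["C", "D"] == 4 and m["D", "C"] == 4

    def test_self_junction_counted_once_on_diagonal(self):
        syn = Synapse(1, ObjType.GAP, None, (), ("C", "C"), 4,
                      (0.0, 0.0, 0.0), (1, 4))
        m = gap_adjacency([syn])
        assert m["C", "C"] == 4
        assert m.total() == 4

    def test_symmetry_exact_on_random_sets(self, rng):
        cells = [f"G{i}" for i in range(8)]
        syns = []
        for sid in range(1, 150):
            a, b = rng.choice(cells, size=2, replace=False)
            syns.append(make_gap(sid, [str(a), str(b)],
                                 int(rng.integers(1, 5))))
        m = gap_adjacency(syns, cell_order=cells)
        assert (m.weights == m.weights.T).all()


class TestConnectivityVector:
    def test_out_in_directions(self):
        m = chemical_adjacency([make_chem(1, "A", ["B"], 5)])
        assert connectivity_vector(m, "A", "OUT") == {"B": 5}
        assert connectivity_vector(m, "B", "IN") == {"A": 5}
        assert connectivity_vector(m, "A", "IN") == {}

    def test_both_equals_in_plus_out(self, rng):
        cells, syns = random_chems(rng, 100)
        m = chemical_adjacency(syns, cell_order=cells)
        for cell in cells:
            vin = connectivity_vector(m, cell, "IN")
            vout = connectivity_vector(m, cell, "OUT")
            both = connectivity_vector(m, cell, "BOTH")
            want = {
                k: vin.get(k, 0) + vout.get(k, 0)
                for k in set(vin) | set(vout)
            }
            assert both == want

    def test_unknown_cell_rejected(self):
        m = chemical_adjacency([make_chem(1, "A", ["B"], 1)])
        with pytest.raises(KeyError):
            connectivity_vector(m, "ZZZ", "OUT")


class TestSimilarity:
    def test_identical_vectors_score_one(self):
        v = {"A": 3.0, "B": 1.0}
        for method in ("cosine", "pearson", "jaccard_binary"):
            assert similarity(v, dict(v), method) == pytest.approx(1.0)

    def test_disjoint_support_cosine_zero(self):
        assert similarity({"A": 2.0}, {"B": 5.0}, "cosine") == 0.0

    def test_empty_vectors_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert similarity({}, {}, "cosine") == 0.0

    def test_pearson_matches_scipy_on_random_vectors(self, rng):
        keys = [f"K{i}" for i in range(15)]
        for _ in range(20):
            va = {k: float(rng.integers(0, 9)) for k in keys}
            vb = {k: float(rng.integers(0, 9)) for k in keys}
            a = np.array([va[k] for k in sorted(keys)])
            b = np.array([vb[k] for k in sorted(keys)])
            if a.std() == 0 or b.std() == 0:
                continue
            want = scipy.stats.pearsonr(a, b).statistic
            assert similarity(va, vb, "pearson") == pytest.approx(want)

    def test_union_of_partners_with_implicit_zeros(self):
        # absent partner counts as 0 in the union namespace
        got = similarity({"A": 1.0, "B": 1.0}, {"A": 1.0}, "cosine")
        assert got == pytest.approx(1.0 / np.sqrt(2.0))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            similarity({"A": 1.0}, {"A": 1.0}, "spearman")


class TestPermutationTest:
    def test_separated_groups_significant(self):
        res = permutation_test(
            [0.95, 0.97, 0.96, 0.98], [0.60, 0.55, 0.65, 0.58],
            n_permutations=2000, seed=1,
        )
        assert res["observed_diff"] > 0.3
        assert res["p_value"] < 0.05

    def test_identical_groups_not_significant(self):
        res = permutation_test(
            [0.5, 0.6, 0.7, 0.4], [0.6, 0.5, 0.4, 0.7],
            n_permutations=2000, seed=1,
        )
        assert res["p_value"] > 0.2

    def test_seed_reproducible(self):
        a, b = [0.9, 0.8, 0.85], [0.7, 0.75, 0.6]
        r1 = permutation_test(a, b, n_permutations=500, seed=42)
        r2 = permutation_test(a, b, n_permutations=500, seed=42)
        assert r1 == r2
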