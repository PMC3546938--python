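"""Duplicate-annotation matching, categories and weight uncertainty."""

import numpy as np
import pytest

from continet import (
    AdjacencyMatrix,
    ObjType,
    Synapse,
    classify_matches,
    edge_weight_uncertainty,
    match_synapses,
)
from continet.concordance import (
    IDENTICAL,
    PARTNER_DIFFER,
    SINGLETON,
    SIZE_DIFFER,
)


def syn(sid, pre="A", posts=("B",), size=2, x=0.0, y=0.0, z0=10,
        syn_type=ObjType.CHEMICAL, partners=()):
    z1 = z0 + size - 1
    return Synapse(sid, syn_type, pre if not partners else None,
                   tuple(posts) if not partners else (),
                   tuple(partners), size,
                   (x, y, (z0 + z1) / 2), (z0, z1))


class TestMatchSynapses:
    def test_identical_sets_perfect_matching(self):
        a = [syn(1, x=100), syn(2, x=900, z0=30)]
        b = [syn(11, x=100), syn(12, x=900, z0=30)]
        res = match_synapses(a, b)
        assert len(res.pairs) == 2
        assert res.unmatched_a == [] and res.unmatched_b == []

    def test_empty_b_all_singletons(self):
        a = [syn(1), syn(2, z0=40)]
        res = match_synapses(a, [])
        assert res.pairs == [] and len(res.unmatched_a) == 2

    def test_type_z_and_distance_gates(self):
        a = [syn(1, x=0.0, z0=10)]
        far = [syn(2, x=1e5, z0=10)]  # beyond tol_xy
        wrong_z = [syn(3, x=0.0, z0=50)]  # z spans not adjacent
        gapjunc = [syn(4, partners=("A", "B"), syn_type=ObjType.GAP)]
        for other in (far, wrong_z, gapjunc):
            assert match_synapses(a, other).pairs == []
        adjacent = [syn(5, x=0.0, z0=12)]  # spans (10,11) and (12,13)
        assert len(match_synapses(a, adjacent).pairs) == 1

    def test_require_same_pre(self):
        a = [syn(1, pre="A")]
        b = [syn(2, pre="X")]
        assert match_synapses(a, b).pairs  # position alone matches
        assert not match_synapses(a, b, require_same_pre=True).pairs

    def test_closest_first_greedy(self):
        a = [syn(1, x=0.0)]
        b = [syn(2, x=300.0), syn(3, x=50.0)]
        res = match_synapses(a, b)
        assert res.pairs == [(a[0], b[1])]

    def test_planted_pairing_recovered_under_jitter(self, rng):
        # jittered copy of a scattered set matches its own counterpart
        a, b = [], []
        for sid in range(60):
            x = float(rng.uniform(0, 15000))
            y = float(rng.uniform(0, 15000))
            z0 = int(rng.integers(1, 200))
            a.append(syn(sid, x=x, y=y, z0=z0))
            b.append(syn(1000 + sid,
                         x=x + float(rng.normal(0, 30)),
                         y=y + float(rng.normal(0, 30)), z0=z0))
        res = match_synapses(a, b)
        got = {(p.synapse_id, q.synapse_id) for p, q in res.pairs}
        assert got == {(sid, 1000 + sid) for sid in range(60)}


class TestClassify:
    def classify(self, pairs, singles_a=(), singles_b=()):
        from continet.concordance import MatchResult

        return classify_matches(
            MatchResult(list(pairs), list(singles_a), list(singles_b))
        )

    def test_identical_pair(self):
        rep = self.classify([(syn(1, posts=("B", "C"), size=3),
                              syn(2, posts=("C", "B"), size=3))])
        assert rep.counts[IDENTICAL] == 1

    def test_partner_difference(self):
        rep = self.classify([(syn(1, posts=("B", "C"), size=3),
                              syn(2, posts=("B", "D"), size=3))])
        assert rep.counts[PARTNER_DIFFER] == 1

    def test_size_difference(self):
        rep = self.classify([(syn(1, posts=("B", "C"), size=2),
                              syn(2, posts=("B", "C"), size=4))])
        assert rep.counts[SIZE_DIFFER] == 1

    def test_partner_takes_precedence_and_overlap_tallied(self):
        rep = self.classify([(syn(1, posts=("B",), size=2),
                              syn(2, posts=("D",), size=4))])
        assert rep.counts[PARTNER_DIFFER] == 1
        assert rep.counts[SIZE_DIFFER] == 0
        assert rep.overlap_both == 1

    def test_fractions_sum_to_one_over_all_sites(self):
        rep = self.classify(
            [(syn(1), syn(2)), (syn(3, size=1), syn(4, size=2))],
            singles_a=[syn(5)], singles_b=[syn(6), syn(7)],
        )
        assert rep.n_reference_synapses == 5
        assert rep.counts[SINGLETON] == 3
        assert sum(rep.fractions.values()) == pytest.approx(1.0)

    def test_gap_partner_sets_compared(self):
        rep = self.classify([
            (syn(1, partners=("A", "B"), syn_type=ObjType.GAP),
             syn(2, partners=("B", "C"), syn_type=ObjType.GAP)),
        ])
        assert rep.counts[PARTNER_DIFFER] == 1


def mat(weights, cells=("A", "B", "C"), mtype=ObjType.CHEMICAL):
    return AdjacencyMatrix(list(cells), np.array(weights), mtype)


class TestEdgeWeightUncertainty:
    def test_identical_matrices_zero_everywhere(self):
        w = [[0, 10, 0], [0, 0, 3], [1, 0, 0]]
        for k in (2, 3, 4):
            per_edge, binned = edge_weight_uncertainty([mat(w)] * k)
            assert (per_edge["mean_abs_diff"] == 0).all()
            assert (per_edge["relative_uncertainty"] == 0).all()

    def test_hand_enumerated_three_scorers(self):
        # weights 10, 11, 9: (|10-11| + |10-9| + |11-9|) / 3 = 4/3
        ws = [[[0, w], [0, 0]] for w in (10, 11, 9)]
        per_edge, _ = edge_weight_uncertainty(
            [mat(w, cells=("A", "B")) for w in ws]
        )
        assert per_edge.loc[0, "mean_abs_diff"] == pytest.approx(4 / 3)
        assert per_edge.loc[0, "reference_weight"] == 10

    def test_relative_uncertainty_arithmetic(self):
        ws = [[[0, 40], [0, 0]], [[0, 41], [0, 0]]]
        per_edge, _ = edge_weight_uncertainty(
            [mat(w, cells=("A", "B")) for w in ws]
        )
        assert per_edge.loc[0, "relative_uncertainty"] == pytest.approx(
            1 / 40
        )

    def test_union_of_nonzero_edges_considered(self):
        a = mat([[0, 5, 0], [0, 0, 0], [0, 0, 0]])
        b = mat([[0, 0, 0], [0, 0, 7], [0, 0, 0]])
        per_edge, _ = edge_weight_uncertainty([a, b])
        edges = set(zip(per_edge["pre"], per_edge["post"]))
        assert edges == {("A", "B"), ("B", "C")}

    def test_focal_cell_restriction(self):
        a = mat([[0, 5, 0], [0, 0, 7], [2, 0, 0]])
        per_edge, _ = edge_weight_uncertainty([a, a], focal_cell="A")
        edges = set(zip(per_edge["pre"], per_edge["post"]))
        assert edges == {("A", "B"), ("C", "A")}

    def test_gap_matrix_edges_counted_once(self):
        g = mat([[0, 4, 0], [4, 0, 0], [0, 0, 0]], mtype=ObjType.GAP)
        per_edge, _ = edge_weight_uncertainty([g, g])
        assert len(per_edge) == 1

    def test_binned_summary_by_reference_weight(self):
        ws = []
        for delta in (0, 1):
            w = np.zeros((3, 3), dtype=float)
            w[0, 1] = 5 + delta     # low bin
            w[0, 2] = 20 + delta    # mid bin
            w[1, 2] = 50 + delta    # high bin
            ws.append(mat(w))
        _, binned = edge_weight_uncertainty(ws)
        assert binned["n_edges"].tolist() == [1, 1, 1]
        got = binned["mean_relative_uncertainty"].tolist()
        assert got == pytest.approx([1 / 5, 1 / 20, 1 / 50])

    def test_mismatched_cells_rejected(self):
        a = mat([[0, 1], [0, 0]], cells=("A", "B"))
        b = mat([[0, 1], [0, 0]], cells=("A", "C"))
        with pytest.raises(ValueError, match="cell set"):
            edge_weight_uncertainty([a, b])
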