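"""Synthetic ground truth and simulated-annotator noise."""

import numpy as np
import pytest

from continet import (
    NoiseModel,
    ObjType,
    SynthConfig,
    build_contins,
    consolidate_synapses,
    expected_category_fractions,
    generate_truth,
    recover_noise_rates,
    simulate_annotator,
    write_project,
)

SMALL = dict(n_neurons=8, n_sections=30, mean_profiles_per_section=4.0,
             synapse_density=5.0)


class TestGenerateTruth:
    def test_single_unbranched_neuron(self):
        cfg = SynthConfig(
            n_neurons=1, n_sections=10, mean_profiles_per_section=1.0,
            branch_probability=0.0, synapse_density=0.0,
        )
        truth = generate_truth(cfg)
        assert len(truth.bundle.objects) == 10
        contins = build_contins(
            truth.bundle.objects, truth.bundle.relationships
        )
        assert len(contins) == 1 and len(contins[0]) == 10

    def test_zero_density_no_synapses(self):
        truth = generate_truth(SynthConfig(synapse_density=0.0, **{
            k: v for k, v in SMALL.items() if k != "synapse_density"
        }))
        assert truth.synapses == []
        assert truth.chemical_matrix.total() == 0

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_sections=0),
            dict(branch_probability=1.5),
            dict(polyad_size_distribution=(0.5, 0.4)),
            dict(n_neurons=1),  # synapses need a partner
            dict(gap_fraction=-0.1),
        ],
    )
    def test_infeasible_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_truth(SynthConfig(**bad))

    def test_generated_project_is_valid(self):
        from continet import validate_project
        from continet.core import has_errors

        truth = generate_truth(SynthConfig(seed=3, **SMALL))
        assert not has_errors(
            validate_project(truth.bundle.objects,
                             truth.bundle.relationships)
        )

    def test_truth_matrix_matches_pipeline_reassembly(self):
        truth = generate_truth(SynthConfig(seed=5, **SMALL))
        contins = build_contins(
            truth.bundle.objects, truth.bundle.relationships
        )
        syns = consolidate_synapses(contins, truth.bundle.objects)
        from continet import chemical_adjacency, gap_adjacency

        chem = chemical_adjacency(syns, cell_order=truth.neuron_names)
        gapm = gap_adjacency(syns, cell_order=truth.neuron_names)
        assert (chem.weights == truth.chemical_matrix.weights).all()
        assert (gapm.weights == truth.gap_matrix.weights).all()

    def test_same_seed_byte_identical_tables(self, tmp_path):
        for sub in ("x", "y"):
            truth = generate_truth(SynthConfig(seed=11, **SMALL))
            write_project(truth.bundle, tmp_path / sub)
        for name in ("objects.tsv", "relationships.tsv", "sections.tsv"):
            assert (tmp_path / "x" / name).read_bytes() == (
                tmp_path / "y" / name
            ).read_bytes()


class TestSimulateAnnotator:
    def test_zero_noise_semantically_identical(self):
        truth = generate_truth(SynthConfig(seed=2, **SMALL))
        annot = simulate_annotator(truth, NoiseModel(xy_jitter_sd=0.0),
                                   seed=9)
        contins = build_contins(annot.objects, annot.relationships)
        syns = consolidate_synapses(contins, annot.objects)
        assert len(syns) == len(truth.synapses)
        got = sorted(
            (s.syn_type.value, s.pre_cell, s.partners(),
             s.size_sections, s.z_span)
            for s in syns
        )
        want = sorted(
            (s.syn_type.value, s.pre_cell, s.partners(),
             s.size_sections, s.z_span)
            for s in truth.synapses
        )
        assert got == want

    def test_full_miss_drops_every_synapse(self):
        truth = generate_truth(SynthConfig(seed=2, **SMALL))
        annot = simulate_annotator(
            truth, NoiseModel(miss_probability=1.0), seed=9
        )
        assert all(
            o.obj_type is ObjType.NEURITE for o in annot.objects
        )

    def test_neurites_copied_faithfully(self):
        truth = generate_truth(SynthConfig(seed=4, **SMALL))
        annot = simulate_annotator(truth, NoiseModel(), seed=1,
                                   annotator_id="a1")
        t_neur = [o for o in truth.bundle.objects
                  if o.obj_type is ObjType.NEURITE]
        a_neur = [o for o in annot.objects
                  if o.obj_type is ObjType.NEURITE]
        assert [(o.object_id, o.x, o.y, o.z, o.cell_name)
                for o in t_neur] == [
            (o.object_id, o.x, o.y, o.z, o.cell_name) for o in a_neur
        ]
        assert all(o.annotator_id == "a1" for o in a_neur)

    def test_miss_rate_within_binomial_error(self):
        # aggregate over seeds: observed drop fraction near m = 0.1
        m = 0.1
        truth = generate_truth(SynthConfig(seed=6, **SMALL))
        n_true = len(truth.synapses)
        dropped, total = 0, 0
        for seed in range(25):
            annot = simulate_annotator(
                truth, NoiseModel(miss_probability=m), seed=seed
            )
            contins = build_contins(annot.objects, annot.relationships)
            n_kept = len(consolidate_synapses(contins, annot.objects))
            dropped += n_true - n_kept
            total += n_true
        se = np.sqrt(m * (1 - m) / total)
        assert abs(dropped / total - m) < 3 * se

    def test_invalid_noise_rejected(self):
        truth = generate_truth(SynthConfig(seed=2, **SMALL))
        with pytest.raises(ValueError):
            simulate_annotator(
                truth, NoiseModel(miss_probability=1.2), seed=0
            )


class TestAnalyticMapping:
    def test_expectations_sum_to_one(self):
        noise = NoiseModel(miss_probability=0.15,
                           partner_swap_probability=0.2,
                           size_jitter_probability=0.25)
        exp = expected_category_fractions(
            noise, SynthConfig().synapse_size_distribution
        )
        assert sum(exp.values()) == pytest.approx(1.0)

    def test_zero_noise_all_identical(self):
        exp = expected_category_fractions(
            NoiseModel(), SynthConfig().synapse_size_distribution
        )
        assert exp["IDENTICAL"] == pytest.approx(1.0)
        assert exp["SINGLETON"] == 0.0

    @pytest.mark.parametrize("m,q,s", [(0.1, 0.2, 0.3), (0.15, 0.2, 0.25),
                                       (0.0, 0.5, 0.1)])
    def test_recovery_inverts_forward_mapping(self, m, q, s):
        dist = SynthConfig().synapse_size_distribution
        noise = NoiseModel(miss_probability=m,
                           partner_swap_probability=q,
                           size_jitter_probability=s)
        exp = expected_category_fractions(noise, dist)
        got = recover_noise_rates(exp, dist)
        assert got == pytest.approx((m, q, s), abs=1e-9)
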