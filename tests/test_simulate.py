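"""Generator contracts: determinism, clean-limit shapes, calibration."""

import numpy as np
import pytest

from gradscope.candidates import flag_hmw
from gradscope.errors import ParameterError
from gradscope.profiles import normalize_matrix, normalize_profile
from gradscope.simulate import (
    GradientClass,
    SimConfig,
    TimecourseClass,
    default_gradient_config,
    default_timecourse_config,
    simulate_gradient,
    simulate_timecourse,
    _gaussian_bump,
)
from gradscope.timecourse import genome_read_fraction


def _single_complex_config(seed=0, **overrides):
    defaults = dict(
        noise_cv=0.0,
        dropout_threshold=0.0,
        fraction_scale_factor_sd=0.0,
        free_fraction_per_protein=0.0,
    )
    defaults.update(overrides)
    return SimConfig(
        classes=[
            GradientClass(
                "mono", "host", 10, center=14.0, width=1.0,
                reference="50S", annotated=True,
            )
        ],
        seed=seed,
        **defaults,
    )


class TestGradientSimulation:
    def test_noise_free_members_peak_at_center(self):
        matrix, truth = simulate_gradient(_single_complex_config())
        for p in normalize_matrix(matrix):
            if p.organism == "spike_in":
                continue
            assert p.peak_fraction == 14

    def test_clean_limit_recovers_gaussian_shape(self):
        """Without noise and dropout, normalized profiles equal the
        renormalized discrete Gaussian of their class."""
        matrix, truth = simulate_gradient(_single_complex_config())
        bump = _gaussian_bump(14.0, 1.0)
        expected = bump / bump.max()
        for p in normalize_matrix(matrix):
            if p.organism == "spike_in":
                continue
            np.testing.assert_allclose(p.fractions, expected, atol=1e-9)

    def test_same_seed_byte_identical(self, tmp_path):
        from gradscope.io import write_intensity_table

        cfg = default_gradient_config(seed=7)
        m1, _ = simulate_gradient(cfg)
        m2, _ = simulate_gradient(default_gradient_config(seed=7))
        assert np.array_equal(m1.values, m2.values)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_intensity_table(m1, p1)
        write_intensity_table(m2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        m1, _ = simulate_gradient(default_gradient_config(seed=1))
        m2, _ = simulate_gradient(default_gradient_config(seed=2))
        assert not np.array_equal(m1.values, m2.values)

    def test_spike_in_identity_oracle(self):
        """Dividing the distorted matrix by the spike-in row column-wise
        reproduces the undistorted matrix exactly: the technical scale
        factors cancel because the spike-in shares them."""
        distorted, _ = simulate_gradient(default_gradient_config(seed=42))
        undistorted, _ = simulate_gradient(
            default_gradient_config(seed=42, fraction_scale_factor_sd=0.0)
        )
        spike = distorted.values[distorted.spike_index]
        level = undistorted.values[undistorted.spike_index][0]
        recovered = distorted.values / (spike / level)[np.newaxis, :]
        col_got = recovered.sum(axis=0)
        col_want = undistorted.values.sum(axis=0)
        np.testing.assert_allclose(col_got, col_want, rtol=1e-10)

    def test_every_row_has_truth(self):
        matrix, truth = simulate_gradient(default_gradient_config(seed=3))
        for pid, org in zip(matrix.protein_ids, matrix.organism):
            if org != "spike_in":
                assert pid in truth.proteins

    def test_free_proteins_never_hmw(self, gradient_sim):
        """Free-class members stay in the LMW fractions at the default
        noise level."""
        matrix, truth = gradient_sim
        from gradscope.profiles import spike_in_normalize

        for p in normalize_matrix(spike_in_normalize(matrix)):
            t = truth.proteins.get(p.protein_id)
            if t is not None and t.class_label == "free":
                assert not flag_hmw(p, hmw_min_fraction=4)

    def test_pellet_share_reflects_pellet_mass(self, normalized_study):
        truth = normalized_study["truth"]
        for p in normalized_study["retained"]:
            t = truth.proteins[p.protein_id]
            if t.class_label == "virion":
                assert p.pellet_share > 0.2
            elif t.class_label in ("rib30", "rib50"):
                assert p.pellet_share < 0.1

    @pytest.mark.parametrize(
        "field,value",
        [
            ("noise_cv", -0.1),
            ("dropout_threshold", -1e-3),
            ("fraction_scale_factor_sd", -0.5),
            ("spike_in_level", 0.0),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = default_gradient_config()
        setattr(cfg, field, value)
        with pytest.raises(ParameterError):
            simulate_gradient(cfg)

    def test_subfraction_width_rejected(self):
        with pytest.raises(ParameterError, match="width"):
            GradientClass("x", "host", 3, center=5.0, width=0.2).validate()


class TestTimecourseSimulation:
    def test_zero_phage_amplitude_means_zero_share(self):
        cfg = default_timecourse_config(seed=5)
        for c in cfg.classes:
            if c.genome == "phage":
                c.amplitude = 0.0
        tc, _ = simulate_timecourse(cfg)
        np.testing.assert_array_equal(genome_read_fraction(tc), 0.0)

    def test_no_phage_reads_before_infection(self, timecourse_sim):
        tc, _ = timecourse_sim
        assert genome_read_fraction(tc)[0] == 0.0

    def test_determinism(self):
        tc1, _ = simulate_timecourse(default_timecourse_config(seed=9))
        tc2, _ = simulate_timecourse(default_timecourse_config(seed=9))
        assert np.array_equal(tc1.counts, tc2.counts)

    def test_endpoint_share_calibration(self):
        """Phage CDS share at t=10 lands in [0.35, 0.45] across seeds."""
        for seed in range(20):
            tc, _ = simulate_timecourse(default_timecourse_config(seed=seed))
            share = genome_read_fraction(tc)[-1]
            assert 0.35 <= share <= 0.45, f"seed {seed}: share {share:.3f}"

    def test_early_classes_outrank_mid(self):
        """Early transcripts accumulate more reads over the window than
        the mid (phage-polymerase) class in >= 95% of replicates."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            tc, truth = simulate_timecourse(
                default_timecourse_config(seed=seed)
            )
            sums = tc.counts.sum(axis=1)
            by_class: dict[str, list[int]] = {}
            for i, tid in enumerate(tc.transcript_ids):
                by_class.setdefault(
                    truth.transcripts[tid].class_label, []
                ).append(sums[i])
            early = np.mean(
                by_class["early_ribosome"] + by_class["early_other"]
            )
            mid = np.mean(by_class["mid_nvRNAP"])
            wins += early > mid
        assert wins >= 95

    def test_nonincreasing_onsets_rejected(self):
        cfg = default_timecourse_config()
        cfg.classes[2].tau = 2.0  # mid now earlier than early
        with pytest.raises(ParameterError, match="increasing"):
            simulate_timecourse(cfg)

    def test_late_class_targets(self):
        tc, truth = simulate_timecourse(default_timecourse_config(seed=11))
        assert all(
            t.genome in ("host", "phage") for t in truth.transcripts.values()
        )
        assert len(tc.transcript_ids) == len(truth.transcripts)


def test_timecourse_class_id_length_mismatch_rejected():
    with pytest.raises(ParameterError, match="transcript_ids"):
        TimecourseClass(
            "x", "phage", 3, tau=1.0, transcript_ids=["a", "b"]
        ).validate()
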