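"""The cohort generator: determinism, effects, marker/GRF synthesis."""

import numpy as np
import pytest

from msfgait.core import EULER_PAIRS, N_CYCLE_POINTS
from msfgait.errors import ConfigurationError, DegenerateGeometryError, NoContactError
from msfgait.gait_cycle import detect_events
from msfgait.kinematics import REFERENCE_GEOMETRY, SEGMENT_MARKERS
from msfgait.synthetic import (
    CohortConfig,
    generate_angle_templates,
    simulate_cohort,
    synthesize_grf,
    synthesize_markers,
)


def _quiet_config(**kw):
    """Cohort with all participant-level variation switched off."""
    defaults = dict(
        coef_jitter_rel=0.0, offset_jitter_sd=0.0, phase_jitter_max=0.0,
        angle_noise_sd=0.0, f2g_calibration=False,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_autism=1, n_control=1)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.4])
    def test_stance_fraction_bounds(self, frac):
        with pytest.raises(ConfigurationError):
            CohortConfig(stance_fraction=frac)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(marker_noise_sd=-1.0)

    def test_unknown_effect_channel_named_in_error(self):
        cfg = CohortConfig(effect_map={"Hip_Knee_AngleX": 3.0})
        with pytest.raises(ConfigurationError, match="Hip_Knee_AngleX"):
            simulate_cohort(cfg, mode="angles")

    def test_derived_cal_met_channel_rejected_in_marker_mode(self):
        cfg = CohortConfig(effect_map={"Cal_Met_AngleY": 3.0})
        with pytest.raises(ConfigurationError, match="Cal_Met_AngleY"):
            simulate_cohort(cfg, mode="markers")


class TestDeterminism:
    def test_identical_seed_gives_identical_cohort(self):
        a = simulate_cohort(CohortConfig(n_autism=3, n_control=3, seed=9), "angles")
        b = simulate_cohort(CohortConfig(n_autism=3, n_control=3, seed=9), "angles")
        for ta, tb in zip(a, b):
            for ch in ta.observed_angle_curves.channel_names():
                np.testing.assert_array_equal(
                    ta.observed_angle_curves.get_channel(ch),
                    tb.observed_angle_curves.get_channel(ch),
                )

    def test_marker_mode_deterministic(self):
        cfg = dict(n_autism=2, n_control=2, seed=4)
        a = simulate_cohort(CohortConfig(**cfg), "markers")
        b = simulate_cohort(CohortConfig(**cfg), "markers")
        np.testing.assert_array_equal(
            a[0].marker_set.positions["M1H"], b[0].marker_set.positions["M1H"]
        )
        np.testing.assert_array_equal(a[0].grf_z, b[0].grf_z)


class TestGroupEffects:
    def test_zero_effect_zero_variation_means_identical(self):
        cfg = _quiet_config(n_autism=3, n_control=3, effect_map={})
        rng = np.random.default_rng(0)
        templates = generate_angle_templates(cfg, rng)
        autism = [t for _, lab, t in templates if lab == "autism"]
        control = [t for _, lab, t in templates if lab == "control"]
        for ch in autism[0].channel_names():
            a = np.mean([t.get_channel(ch) for t in autism], axis=0)
            c = np.mean([t.get_channel(ch) for t in control], axis=0)
            np.testing.assert_allclose(a, c, atol=1e-12)

    def test_configured_offset_recovered_in_group_means(self):
        cfg = CohortConfig(
            n_autism=200, n_control=200, angle_noise_sd=0.0,
            effect_map={"Mid_Met_AngleY": -5.0}, f2g_calibration=False, seed=21,
        )
        templates = generate_angle_templates(cfg, np.random.default_rng(21))
        diff = np.mean(
            [t.euler["Mid_Met"][:, 1] for _, lab, t in templates if lab == "autism"],
            axis=0,
        ) - np.mean(
            [t.euler["Mid_Met"][:, 1] for _, lab, t in templates if lab == "control"],
            axis=0,
        )
        # Monte-Carlo error of a mean difference at n=200/group, offset sd 1.5
        assert abs(np.mean(diff) + 5.0) < 0.5
        # the effect stays on its channel
        other = np.mean(
            [t.euler["Cal_Mid"][:, 1] for _, lab, t in templates if lab == "autism"],
            axis=0,
        ) - np.mean(
            [t.euler["Cal_Mid"][:, 1] for _, lab, t in templates if lab == "control"],
            axis=0,
        )
        assert abs(np.mean(other)) < 0.5

    def test_scale_effect_shrinks_dynamic_range(self):
        cfg = _quiet_config(
            n_autism=2, n_control=2, effect_map={"Mid_Met_AngleX": {"scale": 0.5}}
        )
        templates = generate_angle_templates(cfg, np.random.default_rng(0))
        a = next(t for _, lab, t in templates if lab == "autism")
        c = next(t for _, lab, t in templates if lab == "control")
        rom_a = np.ptp(a.euler["Mid_Met"][:, 0])
        rom_c = np.ptp(c.euler["Mid_Met"][:, 0])
        np.testing.assert_allclose(rom_a, 0.5 * rom_c, rtol=1e-9)


class TestF2GCalibration:
    def test_group_means_approach_reported_targets(self):
        cfg = CohortConfig(n_autism=150, n_control=150, angle_noise_sd=0.0, seed=3)
        trials = simulate_cohort(cfg, mode="angles")
        maxima = {"autism": [], "control": []}
        for tr in trials:
            c = tr.true_angle_curves
            n_st = int(np.floor(c.stance_end)) + 1
            maxima[tr.label].append(np.max(c.planar["F2G"][:n_st]))
        # sampling error of the mean at n=150: sd/sqrt(150) ~ 1.2 deg
        assert abs(np.mean(maxima["autism"]) - 84.15) < 3.0
        assert abs(np.mean(maxima["control"]) - 91.38) < 2.5


class TestMarkerSynthesis:
    def test_identity_pose_zero_noise_reproduces_reference(self, rng):
        T = 5
        poses = {s: np.tile(np.eye(3), (T, 1, 1)) for s in SEGMENT_MARKERS}
        ms = synthesize_markers(poses, np.arange(T) * 0.01, 100.0, 0.0, rng)
        for name, ref in REFERENCE_GEOMETRY.items():
            np.testing.assert_allclose(ms.positions[name], np.tile(ref, (T, 1)))

    def test_collinear_reference_markers_rejected(self, rng):
        geo = dict(REFERENCE_GEOMETRY)
        geo["SHA1"], geo["SHA2"], geo["SHA3"] = [0, 0, 0], [1, 0, 0], [2, 0, 0]
        poses = {s: np.tile(np.eye(3), (2, 1, 1)) for s in SEGMENT_MARKERS}
        with pytest.raises(DegenerateGeometryError):
            synthesize_markers(poses, np.arange(2) * 0.01, 100.0, 0.0, rng,
                               geometry=geo)

    def test_noise_perturbs_markers_with_requested_scale(self, rng):
        T = 200
        poses = {s: np.tile(np.eye(3), (T, 1, 1)) for s in SEGMENT_MARKERS}
        ms = synthesize_markers(poses, np.arange(T) * 0.01, 100.0, 1.0, rng)
        resid = ms.positions["M1H"] - np.asarray(REFERENCE_GEOMETRY["M1H"])
        assert 0.8 < np.std(resid) < 1.2


class TestGrfSynthesis:
    def test_support_duration_matches_stance(self):
        t, fz = synthesize_grf([(0.2, 0.8)], 1000.0, 500.0, 1.2)
        active = t[fz > 0]
        assert active[0] > 0.2 and active[-1] < 0.8
        assert (active[-1] - active[0]) > 0.58
        assert np.all(fz >= 0)

    def test_double_bump_shape(self):
        t, fz = synthesize_grf([(0.0, 0.6)], 1000.0, 400.0, 0.7)
        s = t / 0.6
        early_peak = fz[(s > 0.2) & (s < 0.36)].max()
        valley = fz[(s > 0.45) & (s < 0.55)].max()
        late_peak = fz[(s > 0.64) & (s < 0.8)].max()
        assert early_peak > valley and late_peak > valley

    def test_zero_body_weight_trace_rejected_downstream(self):
        t, fz = synthesize_grf([(0.2, 0.8)], 1000.0, 0.0, 1.2)
        assert np.all(fz == 0)
        with pytest.raises(NoContactError):
            detect_events(fz, 1000.0, time=t)


class TestTrialStructure:
    def test_normalized_truth_has_cycle_grid(self, marker_trials):
        tr = marker_trials[0]
        assert tr.true_angle_curves.n_samples == N_CYCLE_POINTS
        assert set(tr.true_angle_curves.euler) == set(EULER_PAIRS)
        assert 0 < tr.true_angle_curves.stance_end < 100

    def test_event_times_strictly_increasing(self, marker_trials):
        for tr in marker_trials:
            hs, to, hs2 = tr.event_times
            assert hs < to < hs2

    def test_both_sides_mode_doubles_samples(self):
        cfg = CohortConfig(n_autism=2, n_control=2, sides="both", seed=1)
        trials = simulate_cohort(cfg, mode="angles")
        assert len(trials) == 8
        assert {t.side for t in trials} == {"left", "right"}
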