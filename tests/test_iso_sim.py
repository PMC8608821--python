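"""Tests of the synthetic endurance-trial generator."""

import numpy as np
import pytest

from isofatigue import (
    SimConfig,
    apply_termination_rule,
    simulate_cohort,
    simulate_kinematics,
    simulate_power_decay,
    simulate_semg,
    simulate_trial,
)
from isofatigue.features import spectral_features
from isofatigue.preprocess import bandpass_emg


class TestSimConfig:
    def test_group_defaults_resolve(self):
        cfg = SimConfig(muscle_group="knee_extensors")
        assert cfg.rom_deg == (80.0, 170.0)
        assert cfg.n_max == 31
        assert 0 < cfg.decay_frac < 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"muscle_group": "biceps"},
            {"rom_deg": (70.0, 130.0)},  # outside plantar-flexor range
            {"pace_cpm": 0.0},
            {"decay_frac": 1.0},
            {"emg_mnf_start_Hz": 60.0, "emg_mnf_end_Hz": 90.0},  # inverted drift
            {"fs_Hz": 400.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestKinematics:
    def test_angle_bell_endpoints(self):
        cfg = SimConfig(rom_deg=(80.0, 130.0), pace_cpm=60.0, noise_cv=0.0)
        cyc = simulate_kinematics(cfg, 1)
        assert cyc.time_s[-1] == pytest.approx(1.0 - 1 / cfg.fs_Hz)
        assert cyc.angle_deg[0] == pytest.approx(80.0)
        mid = len(cyc.angle_deg) // 2
        assert cyc.angle_deg[mid] == pytest.approx(130.0, abs=1e-6)
        # returns to the start angle at the end of the cycle
        assert cyc.angle_deg[-1] == pytest.approx(80.0, abs=0.01)

    def test_velocity_integral_equals_rom_span(self):
        cfg = SimConfig(noise_cv=0.0)
        cyc = simulate_kinematics(cfg, 1)
        half = len(cyc.velocity_deg_s) // 2
        travelled = np.trapezoid(cyc.velocity_deg_s[:half], cyc.time_s[:half])
        assert travelled == pytest.approx(cfg.rom_span_deg, rel=1e-3)

    def test_velocity_has_one_positive_and_one_negative_lobe(self):
        cyc = simulate_kinematics(SimConfig(noise_cv=0.0), 1)
        v = cyc.velocity_deg_s
        signs = np.sign(v[np.abs(v) > 1e-9])
        flips = np.sum(np.diff(signs) != 0)
        assert flips == 1

    def test_instantaneous_power_torque_times_velocity(self):
        # 100 N·m at 90 °/s must give 157.08 W
        from isofatigue.preprocess import compute_power

        assert compute_power(np.array([100.0]), np.array([90.0]))[0] == pytest.approx(
            157.0796, abs=1e-3
        )

    def test_rep_index_validated(self):
        with pytest.raises(ValueError):
            simulate_kinematics(SimConfig(), 0)


class TestPowerDecay:
    def test_default_retention_ratio_matches_protocol(self):
        """mean(last 5)/mean(first 5) of the noise-free default schedule
        sits at the ~0.617 retention observed for plantar flexors."""
        p = simulate_power_decay(SimConfig(noise_cv=0.0))
        assert p[-5:].mean() / p[:5].mean() == pytest.approx(0.617, abs=0.01)

    def test_zero_decay_zero_noise_is_constant(self):
        cfg = SimConfig(decay_frac=0.0, noise_cv=0.0)
        p = simulate_power_decay(cfg)
        assert np.allclose(p, cfg.baseline_peak_power_W)

    def test_linear_decay_endpoint_arithmetic(self):
        cfg = SimConfig(
            baseline_peak_power_W=600.0, decay_frac=0.4, noise_cv=0.0, n_max=50
        )
        p = simulate_power_decay(cfg)
        assert p[0] == pytest.approx(600.0)
        assert p[-1] == pytest.approx(360.0)

    def test_expected_value_monotone_decreasing(self):
        for shape in ("linear", "exponential"):
            p = simulate_power_decay(SimConfig(decay_shape=shape, noise_cv=0.0))
            assert np.all(np.diff(p) < 0)


class TestTerminationRule:
    # cycle end times chosen so only the first cycle completes within 5 s,
    # making the baseline equal to the first value
    def _times(self, n):
        return 5.0 * np.arange(1, n + 1)

    def test_two_consecutive_subthreshold_cycles_trigger(self):
        p = np.array([100.0, 100, 80, 74, 74, 74])
        assert apply_termination_rule(p, self._times(6)) == 5

    def test_never_triggering_returns_length(self):
        p = np.array([100.0, 90, 95, 88, 92])
        assert apply_termination_rule(p, self._times(5)) == 5

    def test_alternating_dips_do_not_trigger(self):
        p = np.array([100.0, 70, 100, 70, 100])
        assert apply_termination_rule(p, self._times(5)) == 5

    def test_baseline_uses_cycles_within_window(self):
        # 1 s cycles: first five form the baseline (mean 100)
        p = np.array([110.0, 100, 90, 100, 100, 74, 74])
        t = np.arange(1.0, 8.0)
        assert apply_termination_rule(p, t) == 7

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            apply_termination_rule(np.array([]), np.array([]))

    def test_order_exact_after_trigger(self, rng):
        """Permuting cycles after the trigger point never changes the index."""
        p = np.array([100.0, 96, 92, 70, 70, 88, 60, 95, 50, 40])
        t = self._times(10)
        k = apply_termination_rule(p, t)
        assert k == 5
        for _ in range(20):
            q = p.copy()
            q[k:] = rng.permutation(q[k:])
            assert apply_termination_rule(q, t) == k


class TestSemg:
    def test_deterministic_under_fixed_seed(self, short_cfg):
        _, emg1, _, _ = simulate_trial(short_cfg)
        _, emg2, _, _ = simulate_trial(short_cfg)
        assert np.array_equal(emg1.samples, emg2.samples)

    def test_imposed_centroid_realized_within_5pct(self, clean_trial, clean_cfg):
        """Measured per-segment MNF tracks the imposed shaping-filter
        centroid (artifact-free fidelity check)."""
        _, emg, segments, truth = clean_trial
        filtered = bandpass_emg(emg)
        for seg, target in zip(segments[:3], truth.mnf_Hz[:3]):
            mnf, _ = spectral_features(filtered.samples[seg.slice()], clean_cfg.fs_Hz)
            assert mnf == pytest.approx(target, rel=0.05)

    def test_centroid_regression_slope_near_unity(self):
        """Over an ensemble of artifact-free trials the measured MNF
        regresses on the imposed centroid with slope 1 ± 0.1."""
        meas, imposed = [], []
        for seed in range(50):
            cfg = SimConfig(
                n_max=6, seed=1000 + seed, noise_cv=0.05,
                emg_amp_cv=0.0, artifact_rate=0.0,
            )
            _, emg, segments, truth = simulate_trial(cfg)
            filtered = bandpass_emg(emg)
            for seg, c in zip(segments, truth.mnf_Hz):
                meas.append(spectral_features(filtered.samples[seg.slice()], cfg.fs_Hz)[0])
                imposed.append(c)
        slope = np.polyfit(imposed, meas, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_rms_growth_realized(self):
        """Imposed 20 % amplitude growth is recovered as a final/first RMS
        ratio near 1.2 (Monte-Carlo over 50 seeds)."""
        ratios = []
        for seed in range(50):
            cfg = SimConfig(
                n_max=6, seed=2000 + seed, emg_amp_growth_frac=0.2,
                emg_amp_cv=0.0, artifact_rate=0.0,
            )
            _, emg, segments, truth = simulate_trial(cfg)
            first = np.sqrt(np.mean(emg.samples[segments[0].slice()] ** 2))
            last = np.sqrt(np.mean(emg.samples[segments[-1].slice()] ** 2))
            ratios.append(last / first)
        assert np.mean(ratios) == pytest.approx(1.2, abs=0.05)

    def test_rest_intervals_carry_low_baseline(self, short_trial):
        _, emg, segments, _ = short_trial
        seg_rms = np.sqrt(np.mean(emg.samples[segments[0].slice()] ** 2))
        gap = emg.samples[segments[0].end_idx : segments[1].start_idx]
        gap_rms = np.sqrt(np.mean(gap**2))
        assert 0 < gap_rms < 0.15 * seg_rms

    def test_centroid_beyond_nyquist_rejected(self, short_cfg, short_trial):
        import copy

        _, _, segments, truth = short_trial
        bad = copy.deepcopy(truth)
        bad.mnf_Hz = truth.mnf_Hz + 1000.0
        with pytest.raises(ValueError):
            simulate_semg(short_cfg, segments, bad)


class TestCohort:
    def test_three_files_per_subject_and_rerun_identical(self, tmp_path):
        cfgs = [SimConfig(n_max=4, seed=s) for s in (1, 2, 3)]
        paths = simulate_cohort(cfgs, tmp_path / "a")
        assert len(paths) == 3
        files = sorted(p.name for d in paths for p in d.values())
        assert len(files) == 9
        paths2 = simulate_cohort(cfgs, tmp_path / "b")
        for d1, d2 in zip(paths, paths2):
            for key in d1:
                assert d1[key].read_bytes() == d2[key].read_bytes()

    def test_duplicate_seeds_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            simulate_cohort([SimConfig(seed=1), SimConfig(seed=1)], tmp_path)

    def test_repetition_counts_plausible(self):
        """Default cohort configs produce trials of tens of repetitions,
        with the 75 %-indicator repetition inside the trial."""
        for group in ("plantar_flexors", "knee_extensors", "hip_extensors"):
            cfg = SimConfig(muscle_group=group, seed=5)
            truth = simulate_trial(cfg.replace(n_max=cfg.n_max))[3]
            assert 20 <= truth.n_reps <= 60
            assert 1 < truth.termination_index <= truth.n_reps
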