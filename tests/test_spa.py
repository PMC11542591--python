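"""Single-particle metrics: FSC, resolution criterion, SSNR/ppSSNR, Guinier
B-factor, Q-score calibration, and dose arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dqekit import (
    DataError,
    ExposureSpec,
    FrequencyCurve,
    GuinierModel,
    HalfMapPair,
    QCalibration,
    SubsetReconstruction,
    SubsetSSNR,
    compute_fsc,
    cumulative_dose,
    dose_weight_input_100kv,
    guinier_bfactor,
    noise_substituted_fsc,
    ppssnr_from_subsets,
    qscore_to_resolution,
    resolution_at_threshold,
    simulate_half_maps,
    simulate_subset_fscs,
    soft_spherical_mask,
    ssnr_from_fsc,
    to_fraction_of_nyquist,
    two_point_q_calibration,
)


class TestComputeFsc:
    def test_identical_maps_give_unit_fsc(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((32, 32, 32))
        pair = HalfMapPair(vol, vol.copy(), 1.0)
        fsc = compute_fsc(pair)
        assert np.allclose(fsc.values, 1.0, atol=1e-10)

    def test_independent_noise_is_null(self):
        rng = np.random.default_rng(1)
        pair = HalfMapPair(
            rng.standard_normal((48, 48, 48)), rng.standard_normal((48, 48, 48)), 1.0
        )
        fsc = compute_fsc(pair)
        counts = 4 * np.pi * np.arange(1, 25) ** 2
        assert np.all(np.abs(fsc.values) < 3 / np.sqrt(counts))

    def test_swapping_halves_changes_nothing(self):
        pair = simulate_half_maps(32, 1.1, 2.0, seed=3)
        a = compute_fsc(pair)
        b = compute_fsc(pair.swapped())
        assert np.allclose(a.values, b.values, atol=1e-12)
        ra = resolution_at_threshold(a)
        rb = resolution_at_threshold(b)
        assert ra == rb

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            HalfMapPair(np.zeros((8, 8, 8)), np.zeros((9, 9, 9)), 1.0)

    def test_non_cubic_rejected_with_message(self):
        a = np.zeros((8, 8, 12))
        with pytest.raises(DataError, match="cubic"):
            compute_fsc(HalfMapPair(a, a.copy(), 1.0))

    def test_frequency_axis_in_inverse_angstrom(self):
        pair = simulate_half_maps(32, 2.0, 1.0, seed=4)
        fsc = compute_fsc(pair)
        assert fsc.frequency[-1] == pytest.approx(0.25, abs=1e-9)  # Nyquist of 2 A voxels


class TestNoiseSubstitutedFsc:
    def test_trivial_mask_changes_little(self):
        pair = simulate_half_maps(48, 1.0, 3.0, seed=5)
        plain = compute_fsc(pair)
        corrected = noise_substituted_fsc(pair, np.ones_like(pair.map_a), 6.0, seed=1)
        sel = plain.frequency < 0.9 / (2 * 1.0)
        assert np.max(np.abs(plain.values[sel] - corrected.values[sel])) < 0.1

    def test_soft_mask_correction_tracks_ground_truth(self):
        pair = simulate_half_maps(48, 1.0, 4.0, seed=6)
        truth = compute_fsc(pair)
        mask = soft_spherical_mask(48, radius=16, soft_width=6)
        corrected = noise_substituted_fsc(pair, mask, randomization_resolution=8.0, seed=2)
        sel = (truth.frequency > 1 / 8.0) & (truth.frequency < 0.45)
        assert np.mean(np.abs(corrected.values[sel] - truth.values[sel])) < 0.05

    def test_randomization_beyond_nyquist_rejected(self):
        pair = simulate_half_maps(32, 1.0, 1.0, seed=7)
        with pytest.raises(DataError):
            noise_substituted_fsc(pair, None, randomization_resolution=1.5, seed=0)


class TestResolutionAtThreshold:
    @staticmethod
    def step_curve(f_step=0.25, df=0.005):
        freq = np.arange(df, 0.5, df)
        vals = np.where(freq <= f_step, 1.0, 0.0)
        return FrequencyCurve(freq, vals, "FSC", frequency_unit="1/A")

    def test_step_curve_crossing(self):
        res = resolution_at_threshold(self.step_curve(), threshold=0.143)
        assert res.crossed
        # crossing interpolated within one shell of the step at 0.25 1/A (4 A)
        assert abs(1 / res.resolution_A - 0.25) < 0.005

    def test_analytic_crossing_interpolated(self):
        freq = np.linspace(0.01, 0.5, 50)
        vals = np.exp(-freq / 0.1)  # crosses 0.143 at f = -0.1*ln(0.143)
        curve = FrequencyCurve(freq, vals, "FSC", frequency_unit="1/A")
        res = resolution_at_threshold(curve, 0.143)
        f_true = -0.1 * np.log(0.143)
        assert abs(1 / res.resolution_A - f_true) < (freq[1] - freq[0])

    def test_stricter_threshold_is_coarser(self):
        freq = np.linspace(0.01, 0.5, 50)
        curve = FrequencyCurve(freq, np.exp(-freq / 0.1), "FSC", frequency_unit="1/A")
        r143 = resolution_at_threshold(curve, 0.143).resolution_A
        r500 = resolution_at_threshold(curve, 0.5).resolution_A
        assert r500 > r143

    def test_never_below_returns_nyquist_flagged(self):
        freq = np.linspace(0.01, 0.5, 20)
        curve = FrequencyCurve(freq, np.full(20, 0.9), "FSC", frequency_unit="1/A")
        res = resolution_at_threshold(curve)
        assert not res.crossed
        assert res.resolution_A == pytest.approx(2.0)

    def test_never_above_rejected(self):
        freq = np.linspace(0.01, 0.5, 20)
        curve = FrequencyCurve(freq, np.full(20, 0.05), "FSC", frequency_unit="1/A")
        with pytest.raises(DataError):
            resolution_at_threshold(curve)

    def test_ordered_ssnr_gives_ordered_resolution(self):
        """Better half-SSNR profile yields a finer 0.143 resolution."""
        def res_for(scale, seed):
            pair = simulate_half_maps(
                48, 1.0, lambda f: scale * np.exp(-(f / 0.15) ** 2), seed=seed
            )
            return resolution_at_threshold(compute_fsc(pair)).resolution_A

        good = np.mean([res_for(50.0, s) for s in range(3)])
        poor = np.mean([res_for(5.0, s) for s in range(3)])
        assert good < poor


class TestSsnr:
    def test_known_values(self):
        curve = FrequencyCurve(
            np.array([0.1, 0.2]), np.array([0.5, 0.143]), "FSC", frequency_unit="1/A"
        )
        ssnr = ssnr_from_fsc(curve)
        assert ssnr.values[0] == pytest.approx(1.0)
        assert ssnr.values[1] == pytest.approx(0.143 / 0.857, rel=1e-6)

    def test_negative_fsc_maps_to_zero_with_flag(self):
        curve = FrequencyCurve(np.array([0.1]), np.array([-0.2]), "FSC", frequency_unit="1/A")
        ssnr = ssnr_from_fsc(curve)
        assert ssnr.values[0] == 0.0
        assert ssnr.metadata["n_clamped_negative"] == 1

    def test_unit_fsc_clamped(self):
        curve = FrequencyCurve(np.array([0.1]), np.array([1.0]), "FSC", frequency_unit="1/A")
        ssnr = ssnr_from_fsc(curve)
        assert np.isfinite(ssnr.values[0])
        assert ssnr.metadata["n_clamped_high"] == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 0.999), min_size=1, max_size=30))
    def test_roundtrip_identity(self, fsc_vals):
        freq = np.arange(1, len(fsc_vals) + 1) * 0.01
        curve = FrequencyCurve(freq, np.array(fsc_vals), "FSC", frequency_unit="1/A")
        s = ssnr_from_fsc(curve).values
        back = s / (s + 1.0)
        assert np.max(np.abs(back - np.array(fsc_vals))) < 1e-9


class TestPpssnr:
    @staticmethod
    def subsets_from_profile(sizes, seed=0, n_samples=20000):
        profile = np.geomspace(2e-4, 2e-6, 30)
        freq = np.linspace(0.02, 0.45, 30)
        curve = FrequencyCurve(freq, profile, "PPSSNR", frequency_unit="1/A")
        return curve, simulate_subset_fscs(curve, sizes, n_samples, seed=seed)

    def test_identical_subsets_have_zero_spread(self):
        _, subs = self.subsets_from_profile([80_000], seed=1)
        twin = [subs[0], SubsetReconstruction(subs[0].fsc, subs[0].n_particles)]
        curve = ppssnr_from_subsets(twin)
        assert np.allclose(curve.spread, 0.0)

    def test_recovered_mean_independent_of_subset_size(self):
        profile, subs = self.subsets_from_profile([60_000, 90_000, 120_000], seed=2)
        curve = ppssnr_from_subsets(subs)
        truth = profile.interp(curve.frequency)
        rel = np.abs(curve.values - truth) / truth
        assert np.median(rel) < 0.05
        assert rel.max() < 0.25

    def test_doubling_n_halves_ppssnr(self):
        fsc = FrequencyCurve(
            np.array([0.1, 0.2]), np.array([0.5, 0.3]), "FSC", frequency_unit="1/A"
        )
        a = SubsetReconstruction(fsc, 50_000)
        b = SubsetReconstruction(fsc, 100_000)
        curve = ppssnr_from_subsets([a, b], truncate_threshold=0.1)
        pa = ssnr_from_fsc(fsc).values / 50_000
        pb = ssnr_from_fsc(fsc).values / 100_000
        assert np.allclose(pb, pa / 2)
        assert np.allclose(curve.values, (pa + pb) / 2)

    def test_truncated_at_smallest_subset_crossing(self):
        _, subs = self.subsets_from_profile([60_000, 120_000], seed=3)
        curve = ppssnr_from_subsets(subs)
        smallest = min(subs, key=lambda s: s.n_particles)
        res = resolution_at_threshold(smallest.fsc, 0.143)
        assert curve.frequency[-1] <= 1 / res.resolution_A + 1e-9
        assert "ln_mean" in curve.metadata

    def test_mismatched_grids_rejected(self):
        f1 = FrequencyCurve(np.array([0.1, 0.2]), np.array([0.5, 0.4]), "FSC")
        f2 = FrequencyCurve(np.array([0.1, 0.25]), np.array([0.5, 0.4]), "FSC")
        with pytest.raises(DataError):
            ppssnr_from_subsets(
                [SubsetReconstruction(f1, 100), SubsetReconstruction(f2, 100)]
            )

    def test_estimator_summary(self):
        _, subs = self.subsets_from_profile([60_000, 90_000], seed=4)
        res = SubsetSSNR(subs).fit()
        assert "Per-particle SSNR" in res.summary()


class TestFractionOfNyquist:
    def test_map_curve_rescaled_by_pixel_size(self):
        curve = FrequencyCurve(np.array([0.25]), np.array([1.0]), "FSC", frequency_unit="1/A")
        frac = to_fraction_of_nyquist(curve, pixel_size=2.0)
        assert frac.frequency[0] == pytest.approx(1.0)  # 0.25 1/A is Nyquist at 2 A/px

    def test_detector_curve_rescaled_by_half(self):
        curve = FrequencyCurve(np.array([0.25, 0.5]), np.array([1.0, 0.5]), "MTF")
        frac = to_fraction_of_nyquist(curve)
        assert np.allclose(frac.frequency, [0.5, 1.0])
        assert np.allclose(frac.values, curve.values)


class TestGuinier:
    @staticmethod
    def amplitude_curve(b_factor, noise=0.0, n=60, seed=0):
        freq = np.linspace(1 / 20.0, 1 / 2.2, n)
        amps = 100.0 * np.exp(-(b_factor / 4.0) * freq**2)
        if noise:
            rng = np.random.default_rng(seed)
            amps = amps * np.exp(rng.normal(0, noise, n))
        return FrequencyCurve(freq, amps, "SSNR", frequency_unit="1/A")

    def test_exact_recovery_from_noiseless_decay(self):
        fit = guinier_bfactor(self.amplitude_curve(100.0), d_max=7.0, d_min=2.7)
        assert fit.b_factor == pytest.approx(100.0, abs=1e-9)

    def test_flat_spectrum_gives_zero(self):
        fit = guinier_bfactor(self.amplitude_curve(0.0), d_max=7.0, d_min=2.7)
        assert fit.b_factor == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        fit = guinier_bfactor(
            self.amplitude_curve(90.9, noise=0.05, n=30, seed=1), d_max=7.0, d_min=2.7
        )
        assert fit.b_factor == pytest.approx(90.9, rel=0.05)

    def test_too_few_shells_rejected(self):
        curve = self.amplitude_curve(50.0, n=60)
        with pytest.raises(DataError):
            guinier_bfactor(curve, d_max=2.4, d_min=2.3)

    def test_estimator_summary(self):
        fit = GuinierModel(self.amplitude_curve(90.9)).fit()
        assert "B-factor" in fit.summary()
        assert fit.slope == pytest.approx(-90.9 / 4)


class TestQCalibration:
    def test_monotone_decreasing_in_q(self):
        qs = np.linspace(0.3, 1.0, 15)
        ds = [qscore_to_resolution(q) for q in qs]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            qscore_to_resolution(1.2)
        with pytest.raises(DataError):
            qscore_to_resolution(0.0)

    def test_positive_slope_rejected(self):
        with pytest.raises(DataError):
            QCalibration(slope=0.1)

    def test_two_point_calibration_hits_anchors(self):
        cal = two_point_q_calibration(0.85, 1.51, 0.88, 1.35)
        assert qscore_to_resolution(0.85, cal) == pytest.approx(1.51, abs=1e-9)
        assert qscore_to_resolution(0.88, cal) == pytest.approx(1.35, abs=1e-9)


class TestDose:
    def test_unit_case(self):
        rep = cumulative_dose(ExposureSpec(1.0, 1.0, 1.0, 1.0))
        assert rep.total == 1.0
        assert rep.n_frames == 1

    def test_frames_from_exposure_and_frame_time(self):
        rep = cumulative_dose(ExposureSpec(5.2, 7.0, 0.1, 0.852))
        assert rep.n_frames == 70

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    def test_dose_weight_linearity(self, a, b):
        assert dose_weight_input_100kv(a + b) == pytest.approx(
            dose_weight_input_100kv(a) + dose_weight_input_100kv(b), rel=1e-12, abs=1e-9
        )

    def test_dose_weight_values(self):
        assert dose_weight_input_100kv(0.0) == 0.0
        assert dose_weight_input_100kv(143.0) == pytest.approx(224.51)
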