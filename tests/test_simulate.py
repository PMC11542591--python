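"""Event-level simulator: counting semantics, coincidence loss, edge geometry,
and the analytic transfer-function oracles."""

import dataclasses
import math

import numpy as np
import pytest

from dqekit import (
    DataError,
    DetectorModel,
    ExposureSpec,
    analytic_dqe,
    analytic_mtf,
    coincidence_loss_fraction,
    gaussian_kernel,
    simulate_edge_image,
    simulate_flat_stack,
)


def total_incident(rate, time_s, model):
    return rate * time_s * model.sensor_rows * model.sensor_cols


class TestFlatStack:
    def test_counting_conservation_low_dose(self, ideal_detector, short_exposure):
        """With unit efficiency and negligible coincidence loss, counted ~= incident."""
        stack = simulate_flat_stack(ideal_detector, short_exposure, 16, seed=1)
        counted = stack.data.sum()
        expected = total_incident(7.5, 16 / 75, ideal_detector) * (
            1 - coincidence_loss_fraction(7.5, 1500)
        )
        # 3 sigma of the Poisson-dominated count
        assert abs(counted - expected) < 3 * math.sqrt(expected)

    def test_efficiency_thins_counts(self, short_exposure):
        m = DetectorModel(counting_efficiency=0.5)
        stack = simulate_flat_stack(m, short_exposure, 16, seed=2)
        expected = 0.5 * total_incident(7.5, 16 / 75, m)
        assert abs(stack.data.sum() - expected) < 4 * math.sqrt(expected)

    @pytest.mark.parametrize("lam", [0.005, 0.0267, 0.1])
    def test_coincidence_loss_matches_closed_form(self, lam):
        """Counted/incident deficit matches 1 - (1 - e^-lam)/lam at several rates."""
        rate = lam * 1500.0
        m = DetectorModel(sensor_rows=128, sensor_cols=128)
        exposure = ExposureSpec(rate, 15 / 75, 1 / 75, 1.0)
        stack = simulate_flat_stack(m, exposure, 15, seed=3)
        incident = total_incident(rate, 15 / 75, m)
        observed = stack.data.sum() / incident
        expected = 1.0 - coincidence_loss_fraction(rate, 1500.0)
        se = math.sqrt(expected / incident) * 2.0  # count + beam fluctuation
        assert abs(observed - expected) < 3 * se

    def test_counted_rate_concave_increasing_in_dose(self):
        m = DetectorModel(sensor_rows=64, sensor_cols=64)
        rates = [5.0, 20.0, 80.0, 320.0]
        counted = []
        for i, r in enumerate(rates):
            stack = simulate_flat_stack(m, ExposureSpec(r, 30 / 75, 1 / 75, 1.0), 30, seed=10 + i)
            counted.append(stack.data.sum() / (r * 30 / 75 * 64 * 64))
        # counted fraction decreases with dose rate (concavity of the counted rate)
        assert all(a > b for a, b in zip(counted, counted[1:]))

    def test_seeded_determinism(self, ideal_detector, short_exposure):
        a = simulate_flat_stack(ideal_detector, short_exposure, 4, seed=42)
        b = simulate_flat_stack(ideal_detector, short_exposure, 4, seed=42)
        assert np.array_equal(a.data, b.data)
        c = simulate_flat_stack(ideal_detector, short_exposure, 4, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_dose_rate_too_high_rejected(self):
        m = DetectorModel(internal_frame_rate=75, output_frame_rate=75)
        with pytest.raises(DataError, match="counting model"):
            simulate_flat_stack(m, ExposureSpec(1000.0, 1 / 75, 1 / 75, 1.0), 1, seed=0)

    def test_super_resolution_doubles_grid(self, short_exposure):
        m = DetectorModel(sensor_rows=64, sensor_cols=64, super_resolution_factor=2)
        stack = simulate_flat_stack(m, short_exposure, 2, seed=5)
        assert stack.data.shape == (2, 128, 128)
        assert stack.is_super_resolution

    def test_counts_binary_per_internal_frame(self):
        """One internal frame per output frame: counting gives at most 1 per pixel."""
        m = DetectorModel(internal_frame_rate=75, output_frame_rate=75)
        stack = simulate_flat_stack(m, ExposureSpec(300.0, 1 / 75, 1 / 75, 1.0), 1, seed=6)
        assert stack.data.max() <= 1


class TestEdgeImage:
    def test_crossings_follow_true_angle(self, ideal_detector):
        exposure = ExposureSpec(30.0, 10.0, 1 / 75, 1.0)
        img = simulate_edge_image(ideal_detector, exposure, 3.0, 0.0, "vertical", seed=7)
        # row-wise 50%-crossing positions regress to a line with slope tan(3 deg)
        data = img.data.astype(float)
        bright = data[:, -40:].mean(axis=1)
        crossings = []
        for i in range(data.shape[0]):
            col = np.searchsorted(np.cumsum(data[i] > bright[i] / 2), 1)
            crossings.append(col)
        slope = np.polyfit(np.arange(len(crossings)), crossings, 1)[0]
        assert abs(math.degrees(math.atan(slope)) - 3.0) < 0.3

    def test_zero_offset_centers_edge(self, ideal_detector):
        exposure = ExposureSpec(30.0, 5.0, 1 / 75, 1.0)
        img = simulate_edge_image(ideal_detector, exposure, 2.0, 0.0, "vertical", seed=8)
        center_row = img.data[img.data.shape[0] // 2]
        crossing = np.argmax(np.cumsum(center_row > 70) > 0)
        assert abs(crossing - img.data.shape[1] / 2) < 3

    def test_efficiency_halves_bright_plateau(self):
        exposure = ExposureSpec(30.0, 5.0, 1 / 75, 1.0)
        full = simulate_edge_image(DetectorModel(), exposure, 3.0, 0.0, "vertical", seed=9)
        half = simulate_edge_image(
            DetectorModel(counting_efficiency=0.5), exposure, 3.0, 0.0, "vertical", seed=9
        )
        bright_full = full.data[:, -40:].mean()
        bright_half = half.data[:, -40:].mean()
        assert abs(bright_half / bright_full - 0.5) < 0.02

    def test_horizontal_orientation_transposes_geometry(self, ideal_detector):
        exposure = ExposureSpec(30.0, 2.0, 1 / 75, 1.0)
        img = simulate_edge_image(ideal_detector, exposure, 3.0, 0.0, "horizontal", seed=10)
        # bright side is the bottom half
        assert img.data[-30:].mean() > 10 * max(img.data[:30].mean(), 0.1)

    @pytest.mark.parametrize("angle", [0.0, 0.2, 20.0])
    def test_angle_window_enforced(self, ideal_detector, angle):
        exposure = ExposureSpec(30.0, 1.0, 1 / 75, 1.0)
        with pytest.raises(DataError):
            simulate_edge_image(ideal_detector, exposure, angle, 0.0, "vertical", seed=0)


class TestAnalyticOracles:
    def test_ideal_mtf_is_pixel_aperture_sinc(self, ideal_detector):
        f = np.linspace(0, 0.5, 11)
        curve = analytic_mtf(ideal_detector, f)
        assert np.allclose(curve.values, np.abs(np.sinc(f)), atol=1e-12)
        assert abs(curve.values[-1] - 2 / np.pi) < 1e-12

    def test_gaussian_psf_adds_exponential_factor(self):
        # on the super-resolution grid the kernel is well sampled and the
        # discrete transform matches the continuous Gaussian closely
        sf = 2
        sigma_phys = 0.5
        m = DetectorModel(
            event_psf=gaussian_kernel(sigma_phys * sf), super_resolution_factor=sf
        )
        f = np.linspace(0.0, 0.5, 6)
        curve = analytic_mtf(m, f)
        expected = np.exp(-2 * np.pi**2 * sigma_phys**2 * f**2) * np.abs(np.sinc(f / sf))
        assert np.allclose(curve.values, expected, atol=0.01)

    def test_mtf_normalized_at_zero(self):
        m = DetectorModel(
            event_psf=gaussian_kernel(1.2),
            backscatter_fraction=0.2,
            backscatter_psf=gaussian_kernel(4.0),
        )
        curve = analytic_mtf(m, np.array([0.0, 0.1]))
        assert curve.values[0] == 1.0

    def test_ideal_dqe_closed_form(self, ideal_detector):
        curve = analytic_dqe(ideal_detector, np.array([0.0, 0.5]))
        assert abs(curve.values[0] - 1.0) < 1e-12
        assert abs(curve.values[1] - (2 / np.pi) ** 2) < 1e-12

    def test_dqe_zero_equals_efficiency(self):
        m = DetectorModel(counting_efficiency=0.8)
        curve = analytic_dqe(m, np.array([0.0]))
        assert abs(curve.values[0] - 0.8) < 1e-12

    def test_backscatter_degrades_mtf(self):
        clean = DetectorModel(event_psf=gaussian_kernel(0.3))
        dirty = dataclasses.replace(
            clean, backscatter_fraction=0.3, backscatter_psf=gaussian_kernel(4.0)
        )
        f = np.array([0.1, 0.25, 0.5])
        assert np.all(analytic_mtf(dirty, f).values < analytic_mtf(clean, f).values)
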