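import numpy as np
import pytest

from fetaltdi.core import ROISpec
from fetaltdi.synthetic import (
    HeartGeometry,
    HeartModelParams,
    build_waveform,
    generate_dataset,
    generate_field,
    generate_trace,
    sample_roi,
)

from conftest import TINY_ROI


def cycle_quadrature(params, n_points=100_000):
    """Trapezoid integral over one cycle on a phase-aligned grid."""
    f, onsets = build_waveform(params)
    T = params.cycle_length
    edges = np.concatenate([onsets, [T]])
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        n = max(2, int(round(n_points * (b - a) / T)))
        t = np.linspace(a, b - 1e-12 * T, n)
        total += np.trapezoid(f(t), t)
    return total


class TestWaveform:
    def test_cycle_length_arithmetic(self):
        assert HeartModelParams(heart_rate=140).cycle_length == pytest.approx(60 / 140)

    def test_peak_s_attained_exactly(self, default_params):
        f, onsets = build_waveform(default_params)
        T = default_params.cycle_length
        ej = np.linspace(onsets[2], onsets[3], 40_001)
        assert np.max(f(ej)) == pytest.approx(default_params.peak_s, abs=1e-9)

    def test_diastolic_peaks_attained(self, default_params):
        f, onsets = build_waveform(default_params)
        T = default_params.cycle_length
        # grid evaluation: the exact peak sits between samples, so allow the
        # quadratic interpolation error of the grid spacing
        atrial = np.linspace(0, onsets[1], 40_001)
        rapid = np.linspace(onsets[4], onsets[5], 40_001)
        assert np.min(f(atrial)) == pytest.approx(default_params.peak_a, abs=1e-6)
        assert np.min(f(rapid)) == pytest.approx(default_params.peak_e, abs=1e-6)
        assert np.min(f(atrial)) >= default_params.peak_a - 1e-12
        assert np.min(f(rapid)) >= default_params.peak_e - 1e-12

    def test_zero_net_displacement(self, default_params):
        assert abs(cycle_quadrature(default_params)) < 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_zero_net_displacement_random_params(self, seed):
        rng = np.random.default_rng(seed)
        params = HeartModelParams(
            heart_rate=float(rng.uniform(100, 180)),
            peak_s=float(rng.uniform(3, 8)),
            peak_e=-float(rng.uniform(4, 9)),
            peak_a=-float(rng.uniform(3, 7)),
            transient_amp=float(rng.uniform(0.5, 2.5)),
        )
        assert abs(cycle_quadrature(params)) < 1e-9

    def test_biphasic_variant_balances_too(self):
        assert abs(cycle_quadrature(HeartModelParams(biphasic_transients=True))) < 1e-9

    def test_onsets_match_fractions(self, default_params):
        _, onsets = build_waveform(default_params)
        T = default_params.cycle_length
        expected = np.cumsum((0,) + default_params.phase_fractions[:-1]) * T
        np.testing.assert_allclose(onsets, expected, atol=1e-12)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            HeartModelParams(phase_fractions=(0.2, 0.2, 0.2, 0.2, 0.2, 0.2))
        with pytest.raises(ValueError):
            HeartModelParams(phase_fractions=(0.5, 0.5, 0.0, 0.0, 0.0, 0.0))

    def test_heart_rate_bounds(self):
        with pytest.raises(ValueError):
            HeartModelParams(heart_rate=60)
        with pytest.raises(ValueError):
            HeartModelParams(heart_rate=250)


class TestField:
    def test_seed_determinism(self, geometry_ga3):
        p = HeartModelParams(noise_sd=1.0, n_cycles=3)
        f1 = generate_field(p, geometry_ga3, seed=9)
        f2 = generate_field(p, geometry_ga3, seed=9)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_apex_row_zero(self, default_params, geometry_ga3):
        fld = generate_field(default_params, geometry_ga3, seed=0)
        assert np.allclose(fld.values[-1], 0.0)
        assert fld.positions[-1] == pytest.approx(geometry_ga3.ventricular_length_mm)

    def test_linear_decay_half_depth(self, default_params, geometry_ga3):
        # dz chosen so that L/2 = 16.25 mm falls exactly on the depth grid
        fld = generate_field(default_params, geometry_ga3, seed=0, dz_mm=0.125)
        L = geometry_ga3.ventricular_length_mm
        mid = int(np.argmin(np.abs(fld.positions - L / 2)))
        assert fld.positions[mid] == pytest.approx(L / 2, abs=1e-12)
        np.testing.assert_allclose(fld.values[mid], 0.5 * fld.values[0], atol=1e-9)

    def test_spatial_monotonicity(self, default_params, geometry_ga3):
        fld = generate_field(default_params, geometry_ga3, seed=0)
        mags = np.abs(fld.values)
        assert np.all(mags[:-1] + 1e-12 >= mags[1:])

    def test_noise_moments(self, geometry_ga3):
        sd = 0.8
        p = HeartModelParams(noise_sd=sd, n_cycles=2)
        noisy = generate_field(p, geometry_ga3, seed=12)
        clean = generate_field(HeartModelParams(n_cycles=2), geometry_ga3, seed=12)
        resid = (noisy.values - clean.values).ravel()
        n = resid.size
        assert n >= 10_000
        assert abs(resid.mean()) < 3 * sd / np.sqrt(n)
        assert abs(resid.std() - sd) < 3 * sd / np.sqrt(2 * n)

    def test_ground_truth_segments(self, default_params, geometry_ga3):
        fld = generate_field(default_params, geometry_ga3, seed=0)
        assert len(fld.ground_truth) == default_params.n_cycles
        T = default_params.cycle_length
        for seg in fld.ground_truth:
            assert seg.durations_s().sum() == pytest.approx(T, abs=1e-12)


class TestSampleROI:
    def test_tiny_roi_equals_av_row(self, default_params, geometry_ga3):
        fld = generate_field(default_params, geometry_ga3, seed=0)
        tr = sample_roi(fld, TINY_ROI)
        np.testing.assert_allclose(tr.samples, fld.values[0], atol=1e-7)

    def test_peak_attenuation_monotone_in_height(self, default_params, geometry_ga3):
        fld = generate_field(default_params, geometry_ga3, seed=0)
        peaks = []
        for h in (2.0, 4.0, 6.0, 8.0):
            tr = sample_roi(fld, ROISpec.at_av_plane(h, 2.0))
            peaks.append(np.max(tr.samples))
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_roi_beyond_apex_rejected(self, default_params):
        geom = HeartGeometry(5.0, 1.8)
        fld = generate_field(default_params, geom, seed=0)
        with pytest.raises(ValueError):
            sample_roi(fld, ROISpec.at_av_plane(12.0, 2.0))

    def test_roi_above_av_plane_rejected(self):
        with pytest.raises(ValueError):
            ROISpec(2.0, 2.0, 0.0)


class TestDataset:
    def test_determinism(self):
        b1 = generate_dataset(10, [0.0, 0.5], 38.0, seed=7)
        b2 = generate_dataset(10, [0.0, 0.5], 38.0, seed=7)
        for (t1, g1), (t2, g2) in zip(b1, b2):
            np.testing.assert_array_equal(t1.samples, t2.samples)
            assert g1 == g2

    def test_ga3_geometry_length(self):
        assert HeartGeometry.for_ga(38).ventricular_length_mm == pytest.approx(32.5)
        assert HeartGeometry.for_ga(21).ventricular_length_mm == pytest.approx(15.6)
        assert HeartGeometry.for_ga(29).ventricular_length_mm == pytest.approx(23.3)

    def test_cycle_counts_in_range(self):
        for trace, truth in generate_dataset(12, [0.0], 30.0, seed=3):
            assert 5 <= len(truth) <= 10

    def test_empty_noise_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(3, [], 38.0, seed=0)

    def test_bad_n_traces_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(0, [0.0], 38.0, seed=0)

    def test_trace_noise_matches_request(self):
        # residual of one noisy trace against its noise-free twin
        geom = HeartGeometry.for_ga(38)
        roi = ROISpec.at_av_plane(2.0, 2.0)
        p_noisy = HeartModelParams(noise_sd=0.5)
        p_clean = HeartModelParams()
        noisy, _ = generate_trace(p_noisy, geom, roi, seed=4)
        clean, _ = generate_trace(p_clean, geom, roi, seed=4)
        resid = noisy.samples - clean.samples
        assert abs(resid.std() - 0.5) < 3 * 0.5 / np.sqrt(2 * resid.size) + 0.02
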