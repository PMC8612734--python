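"""Medial/junctional partition, normalization, cycles, Fourier polarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from placode import fluorescence as fl
from placode.tissue_io import TissueValidationError


def _square_cell_image(size=20, margin=4):
    labels = np.zeros((size, size), dtype=np.uint16)
    labels[margin:-margin, margin:-margin] = 1
    return labels


class TestPartition:
    def test_constructed_interior_and_edge_band(self):
        labels = _square_cell_image(size=24, margin=4)
        mask = labels == 1
        dist = ndimage.distance_transform_edt(mask)
        intensity = np.zeros_like(labels, dtype=float)
        intensity[mask & (dist <= 3)] = 100.0  # 2-px band + edge pixels
        intensity[mask & (dist > 3)] = 10.0
        out = fl.partition_cell_fluorescence(labels, intensity)
        medial, junctional = out[1]
        assert medial == pytest.approx(10.0)
        assert junctional == pytest.approx(100.0)

    def test_uniform_intensity(self):
        labels = _square_cell_image()
        out = fl.partition_cell_fluorescence(labels, np.full(labels.shape, 42.0))
        medial, junctional = out[1]
        assert medial == pytest.approx(42.0)
        assert junctional == pytest.approx(42.0)

    def test_small_cell_medial_flagged(self):
        labels = np.zeros((12, 12), dtype=np.uint16)
        labels[3:8, 3:8] = 1  # 5x5 cell swallowed by the 2-px band
        out = fl.partition_cell_fluorescence(labels, np.ones(labels.shape))
        medial, junctional = out[1]
        assert np.isnan(medial)
        assert np.isfinite(junctional)

    def test_masks_partition_cell_exactly(self):
        labels = _square_cell_image(size=30, margin=5)
        mask = labels == 1
        dist = ndimage.distance_transform_edt(mask)
        junctional = mask & (dist <= 3)
        medial = mask & ~junctional
        assert not (junctional & medial).any()
        assert (junctional | medial).sum() == mask.sum()

    def test_incongruent_shapes_rejected(self):
        with pytest.raises(TissueValidationError):
            fl.partition_cell_fluorescence(
                np.zeros((4, 4), dtype=int), np.zeros((5, 5))
            )


class TestBackground:
    def test_constant_image_goes_to_zero(self):
        out = fl.subtract_background(np.full((10, 10), 7.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_offset_signal_recovered(self):
        rng = np.random.default_rng(1)
        signal = np.zeros((50, 50))
        signal[10:12, 10:12] = 100.0
        out = fl.subtract_background(signal + 5.0)
        np.testing.assert_allclose(out, signal, atol=1e-12)

    def test_sparse_bright_cells_on_noise_floor(self):
        rng = np.random.default_rng(2)
        floor = 20.0
        img = rng.normal(floor, 2.0, (100, 100))
        img[:10, :10] += 500.0  # 1% bright area
        # recover the estimated background as the clipped-off offset
        corrected = fl.subtract_background(img)
        estimate = np.median((img - corrected)[corrected > 0])
        assert abs(estimate - floor) / floor < 0.05


class TestNormalization:
    def test_equal_values(self):
        out = fl.normalize_p98(np.full(10, 3.3))
        np.testing.assert_allclose(out, 1.0)

    def test_constructed_p98(self):
        vals = np.concatenate([np.linspace(0, 49, 99), [50.0]])
        p98 = np.percentile(vals, 98)
        out = fl.normalize_p98(vals)
        np.testing.assert_allclose(out, vals / p98)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_sorted_interpolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1.0, 100.0, 1000)
        # brute-force linear-interpolation percentile
        s = np.sort(vals)
        pos = 0.98 * (len(s) - 1)
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        oracle = s[lo] + frac * (s[lo + 1] - s[lo])
        np.testing.assert_allclose(fl.normalize_p98(vals), vals / oracle, atol=1e-12)


class TestDetrend:
    def test_linear_ramp_interior_zero(self):
        t = np.arange(30.0)
        out = fl.detrend_boxcar(5.0 + 2.0 * t, dt_min=1.0)
        assert np.all(np.abs(out[3:-3]) < 1e-9)

    def test_constant_trace_all_zero(self):
        out = fl.detrend_boxcar(np.full(20, 9.0), dt_min=1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # analytic boxcar oracle: H = sin(N pi dt/P)/(N sin(pi dt/P))
        P, dt = 4.0, 1.0
        t = np.arange(0, 60, dt)
        x = 3.0 * np.sin(2 * np.pi * t / P) + 0.5 * t
        out = fl.detrend_boxcar(x, dt)
        n_taps = 7
        arg = np.pi * dt / P
        H = np.sin(n_taps * arg) / (n_taps * np.sin(arg))
        expected_amp = 3.0 * abs(1 - H)
        measured = (out[10:-10].max() - out[10:-10].min()) / 2
        assert measured == pytest.approx(expected_amp, rel=0.15)

    def test_short_trace_rejected(self):
        with pytest.raises(TissueValidationError):
            fl.detrend_boxcar(np.arange(4.0), dt_min=1.0)


class TestCycles:
    def test_sinusoid_period_recovered(self):
        t = np.arange(0, 40, 1.0)
        d = fl.detrend_boxcar(100 + 10 * np.sin(2 * np.pi * t / 4), 1.0)
        stats = fl.detect_cycles(d, 1.0)
        assert abs(np.median(stats.cycle_lengths) - 4.0) <= 1.0

    def test_constant_trace_no_cycles(self):
        stats = fl.detect_cycles(np.zeros(30), 1.0)
        assert stats.n_cycles == 0
        assert len(stats.peaks) == 0

    def test_small_ripple_skipped_matches_hand_count(self):
        # 60-min period-5 sinusoid amplitude 10 + amplitude-0.1 ripple:
        # hand count = 11 peaks evenly 5 min apart -> 10/11 cycles retained
        t = np.arange(0, 56, 1.0)
        x = 10 * np.sin(2 * np.pi * t / 5) + 0.1 * np.sin(2 * np.pi * t / 1.7)
        stats = fl.detect_cycles(x, 1.0, min_amp_frac=0.2)
        assert np.median(stats.cycle_lengths) == pytest.approx(5.0, abs=1.0)
        # no ripple-scale cycles survive
        assert stats.cycle_lengths.min() >= 4.0

    def test_peaks_and_troughs_alternate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 80)
        stats = fl.detect_cycles(x, 1.0)
        merged = sorted(
            [(i, "p") for i in stats.peaks] + [(i, "t") for i in stats.troughs]
        )
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestStrength:
    def test_arithmetic(self):
        stats = fl.OscillationStats(
            peaks=np.array([0, 5]),
            troughs=np.array([2]),
            cycle_lengths=np.array([5.0]),
            amplitude=10.0,
            strength=2.0,
        )
        assert fl.oscillation_strength(stats) == pytest.approx(2.0)

    def test_zero_cycles_flagged(self):
        stats = fl.OscillationStats(
            peaks=np.array([], dtype=int),
            troughs=np.array([], dtype=int),
            cycle_lengths=np.array([]),
            amplitude=0.0,
            strength=0.0,
        )
        assert np.isnan(fl.oscillation_strength(stats))

    def test_programmed_strength_recovered_within_15pc(self):
        A, P, dt = 15.0, 4.0, 1.0
        rng = np.random.default_rng(4)
        errs = []
        for phase in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            t = np.arange(0, 60, dt)
            x = 100 + t + A * np.sin(2 * np.pi * t / P + phase)
            x += rng.normal(0, 1.0, len(t))
            stats = fl.detect_cycles(fl.detrend_boxcar(x, dt), dt)
            s = fl.debiased_strength(stats, dt)
            errs.append(abs(s - 2 * A / P) / (2 * A / P))
        assert max(errs) < 0.15


class TestPolarity:
    def test_uniform_profile_no_polarity(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pv = fl.fourier_polarity(th, np.full(64, 5.0))
        assert pv.uni_amp < 1e-12 and pv.bi_amp < 1e-12

    def test_mode1_profile(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pv = fl.fourier_polarity(th, 1 + 0.5 * np.cos(th))
        assert pv.uni_amp == pytest.approx(0.5, abs=1e-9)
        assert pv.uni_phase == pytest.approx(0.0, abs=1e-9)
        assert pv.bi_amp == pytest.approx(0.0, abs=1e-9)

    def test_mode2_profile(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pv = fl.fourier_polarity(th, 1 + 0.4 * np.cos(2 * (th - np.pi / 2)))
        assert pv.bi_amp == pytest.approx(0.4, abs=1e-9)
        assert pv.bi_phase == pytest.approx(np.pi / 2, abs=1e-9)
        assert pv.uni_amp == pytest.approx(0.0, abs=1e-9)

    def test_scaling_covariance(self):
        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        profile = 2 + 0.6 * np.cos(th - 1.0) + 0.3 * np.cos(2 * (th - 0.4))
        a = fl.fourier_polarity(th, profile)
        b = fl.fourier_polarity(th, 7.0 * profile)
        assert b.m0 == pytest.approx(7.0 * a.m0, rel=1e-12)
        assert b.uni_amp == pytest.approx(a.uni_amp, abs=1e-12)
        assert b.bi_amp == pytest.approx(a.bi_amp, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(TissueValidationError):
            fl.fourier_polarity(np.arange(5.0), np.ones(5))


def test_cycle_length_recovery_across_acquisition_range():
    """Sinusoid periods 3-6 min, sampling 0.58-3 min: recovered median cycle
    length within one sampling interval wherever >= 3 samples per cycle."""
    rng = np.random.default_rng(5)
    for P in (3.0, 4.0, 5.0, 6.0):
        for dt in (0.58, 1.0, 1.5, 2.0):
            if dt > P / 3:
                continue
            t = np.arange(0, 70, dt)
            x = 100 + t + 12 * np.sin(2 * np.pi * t / P + rng.uniform(0, 2 * np.pi))
            stats = fl.detect_cycles(fl.detrend_boxcar(x, dt), dt)
            assert abs(np.median(stats.cycle_lengths) - P) <= dt


def test_scaling_leaves_partition_means_proportional():
    labels = _square_cell_image(size=26, margin=5)
    rng = np.random.default_rng(6)
    img = rng.uniform(1, 10, labels.shape)
    a = fl.partition_cell_fluorescence(labels, img)[1]
    b = fl.partition_cell_fluorescence(labels, 3.0 * img)[1]
    assert b[0] == pytest.approx(3.0 * a[0], rel=1e-12)
    assert b[1] == pytest.approx(3.0 * a[1], rel=1e-12)
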