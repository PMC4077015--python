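"""Spectral estimators against brute-force DFT oracles and analytic facts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assrlab.preprocess import Segment
from assrlab.spectral import (
    band_mask,
    band_power,
    mean_psd,
    periodogram_natural,
    phase_locking,
    psd,
    rayleigh_floor,
    scalogram,
    vonmises_plf,
    window_phases,
    PowerSpectrum,
)

FS = 1560.0


def naive_periodogram(x, fs, nfft):
    """O(N^2) DFT periodogram with the same normalization: the oracle."""
    x = np.asarray(x, float)
    n = x.size
    xc = x - x.mean()
    k = np.arange(nfft // 2 + 1)
    power = np.zeros(k.size)
    for i, ki in enumerate(k):
        acc = 0.0 + 0.0j
        for t in range(n):
            acc += xc[t] * np.exp(-2j * np.pi * ki * t / nfft)
        power[i] = abs(acc) ** 2 / (nfft * n)
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    return k * fs / nfft, power


def seg(x, fs=FS):
    return Segment(np.asarray(x, float), fs, 0.0)


class TestPsd:
    def test_matches_naive_dft(self, rng):
        x = rng.standard_normal(64)
        f_ref, p_ref = naive_periodogram(x, FS, 256)
        f_imp, p_imp = periodogram_natural(x, FS, nfft=256)
        np.testing.assert_allclose(f_imp, f_ref, atol=1e-12)
        np.testing.assert_allclose(p_imp, p_ref, atol=1e-10)

    def test_parseval_natural_grid(self, rng):
        x = rng.standard_normal(312) * 2.5
        _, p = periodogram_natural(x, FS)
        assert abs(p.sum() - x.var()) < 1e-8

    def test_sinusoid_peak_location(self):
        t = np.arange(312) / FS
        spectrum = psd(seg(np.sin(2 * np.pi * 40.0 * t)))
        peak = spectrum.freqs_hz[np.argmax(spectrum.power)]
        assert abs(peak - 40.0) <= 100.0 / 255 / 2 + 1e-9

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(312) / FS
        x = np.sin(2 * np.pi * 40.0 * t)
        p1 = psd(seg(x)).power
        p2 = psd(seg(2 * x)).power
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-12)

    def test_hann_taper_suppresses_leakage(self):
        t = np.arange(312) / FS
        x = np.sin(2 * np.pi * 40.3 * t)  # off-bin tone leaks without taper
        plain = psd(seg(x))
        tapered = psd(seg(x), taper="hann")
        far = (plain.freqs_hz > 60) & (plain.freqs_hz < 90)
        assert tapered.power[far].sum() < 0.2 * plain.power[far].sum()

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            psd(seg(np.zeros(312)), fmax=1000.0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            psd(seg(np.zeros(4)))


class TestMeanPsd:
    def test_identical_segments_equal_single(self, rng):
        x = rng.standard_normal(312)
        single = psd(seg(x))
        averaged = mean_psd([seg(x)] * 5)
        np.testing.assert_allclose(averaged.power, single.power)
        assert averaged.n_segments == 5

    def test_two_segments_give_binwise_midpoint(self, rng):
        a, b = rng.standard_normal((2, 312))
        mid = mean_psd([seg(a), seg(b)])
        np.testing.assert_allclose(mid.power, (psd(seg(a)).power + psd(seg(b)).power) / 2)

    def test_averaging_shrinks_variance(self, rng):
        """Bin variance of a 25-segment mean is ~1/25 of a single segment's."""
        bin_idx = 128
        singles = [psd(seg(rng.standard_normal(312))).power[bin_idx] for _ in range(150)]
        means = [
            mean_psd([seg(rng.standard_normal(312)) for _ in range(25)]).power[bin_idx]
            for _ in range(150)
        ]
        ratio = np.var(means) / np.var(singles)
        assert 1 / 60 < ratio < 1 / 10

    def test_mixed_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="mixed segment lengths"):
            mean_psd([seg(np.zeros(312)), seg(np.zeros(311))])


class TestBandPower:
    def test_flat_spectrum_returns_constant(self):
        grid = np.linspace(0, 100, 256)
        spec = PowerSpectrum(grid, np.full(256, 3.7))
        for lo, hi in [(35, 44), (15, 24), (50, 100)]:
            assert band_power(spec, lo, hi) == pytest.approx(3.7)

    def test_35_44_band_covers_23_bins(self):
        grid = np.linspace(0, 100, 256)
        assert band_mask(grid, 35, 44).sum() == 23

    def test_notch_excludes_line_bins(self):
        grid = np.linspace(0, 100, 256)
        power = np.ones(256)
        power[(grid >= 58) & (grid <= 62)] = 100.0  # line-noise bump
        spec = PowerSpectrum(grid, power)
        assert band_power(spec, 50, 100) > 1.0
        assert band_power(spec, 50, 100, notch_hz=60.0) == pytest.approx(1.0)

    def test_empty_band_rejected(self):
        spec = PowerSpectrum(np.linspace(0, 100, 256), np.ones(256))
        with pytest.raises(ValueError, match="no bins"):
            band_power(spec, 200.0, 210.0)


class TestPhaseLocking:
    def test_identical_trials_plf_one(self, rng):
        x = rng.standard_normal(312)
        plf = phase_locking([seg(x)] * 8)
        # every bin has nonzero amplitude almost surely for noise
        assert plf.plf.min() > 0.999

    def test_noise_floor_matches_rayleigh_mean(self, rng):
        # average over bins spaced ~20 Hz apart (wider than the window's
        # spectral correlation length) and over replicates
        probe_bins = [40, 90, 140, 190, 240]
        vals = [
            phase_locking([seg(rng.standard_normal(312)) for _ in range(50)])
            .plf[probe_bins]
            .mean()
            for _ in range(60)
        ]
        assert np.mean(vals) == pytest.approx(rayleigh_floor(50), abs=0.01)

    def test_vonmises_phase_recovers_bessel_ratio(self, rng):
        t = np.arange(312) / FS
        trials = [
            seg(np.sin(2 * np.pi * 40.0 * t + th)) for th in rng.vonmises(0.0, 2.0, 600)
        ]
        plf = phase_locking(trials)
        at40 = plf.plf[np.argmin(np.abs(plf.freqs_hz - 40.0))]
        assert at40 == pytest.approx(vonmises_plf(2.0), abs=0.05)

    def test_amplitude_scaling_invariance(self, rng):
        trials = [rng.standard_normal(312) for _ in range(10)]
        a = phase_locking([seg(x) for x in trials])
        b = phase_locking([seg(5.0 * x) for x in trials])
        np.testing.assert_allclose(a.plf, b.plf, atol=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12))
    def test_plf_bounded(self, seed, n_trials):
        r = np.random.default_rng(seed)
        plf = phase_locking([seg(r.standard_normal(312)) for _ in range(n_trials)])
        assert np.all(plf.plf >= 0.0) and np.all(plf.plf <= 1.0)

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2 trials"):
            phase_locking([seg(rng.standard_normal(312))])

    def test_window_phase_matches_direct_dft(self, rng):
        """Single-window phase extraction against a brute-force DFT."""
        x = rng.standard_normal(128)
        f, phasor = window_phases(x, FS, nfft=128)
        tapered = x * np.hanning(x.size)
        k = np.arange(128 // 2 + 1)
        direct = np.array(
            [sum(tapered[t] * np.exp(-2j * np.pi * ki * t / 128) for t in range(128)) for ki in k]
        )
        np.testing.assert_allclose(
            np.angle(phasor[1:-1]), np.angle(direct[1:-1]), atol=1e-8
        )


class TestScalogram:
    def test_pure_tone_ridge(self):
        t = np.arange(int(FS)) / FS
        sc = scalogram(np.sin(2 * np.pi * 40.0 * t), FS, fmin=10, fmax=100, n_freqs=48)
        mid = sc.magnitude[:, 200:-200]  # avoid edge effects
        ridge = sc.freqs_hz[np.argmax(mid.mean(axis=1))]
        assert ridge == pytest.approx(40.0, rel=0.06)

    def test_zero_signal_zero_magnitude(self):
        sc = scalogram(np.zeros(2000), FS)
        assert np.all(sc.magnitude == 0)

    def test_ridge_tracks_frequency_step(self):
        t = np.arange(int(FS)) / FS
        x = np.concatenate(
            [np.sin(2 * np.pi * 20.0 * t), np.sin(2 * np.pi * 40.0 * t)]
        )
        sc = scalogram(x, FS, fmin=10, fmax=80, n_freqs=48)
        n = len(t)
        ridge_a = sc.freqs_hz[sc.magnitude[:, n // 2].argmax()]
        ridge_b = sc.freqs_hz[sc.magnitude[:, n + n // 2].argmax()]
        assert ridge_a == pytest.approx(20.0, rel=0.08)
        assert ridge_b == pytest.approx(40.0, rel=0.08)

    def test_nonpositive_fmin_rejected(self):
        with pytest.raises(ValueError, match="fmin"):
            scalogram(np.zeros(100), FS, fmin=0.0)
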