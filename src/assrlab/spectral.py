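"""Spectral estimation: FFT power on a 256-bin grid, phase locking, scalograms.

Power estimation is a plain (untapered) periodogram of the mean-removed
segment, zero-padded to ``NFFT = 4096`` samples.  The one-sided spectrum on
the natural FFT grid is normalized so that its sum equals the segment's
population variance (Parseval), then linearly interpolated onto
``bin_count`` evenly spaced frequencies over ``[fmin, fmax]`` — 256 bins
over 0-100 Hz by default, giving a 0.392-Hz bin spacing slightly coarser
than the 0.381-Hz natural resolution at fs = 1560 Hz, so interpolation
never fabricates resolution.

The phase-locking factor (inter-trial coherence) at frequency f is the
magnitude of the across-trial average unit phase vector,
``PLF(f) = |mean_trials exp(i phi_trial(f))|``, estimated in Hanning-tapered
windows slid with 60 % overlap and averaged over window positions.  For n
trials of pure noise the expected PLF is the Rayleigh floor
``sqrt(pi)/(2 sqrt(n))``; for von Mises phase jitter with concentration
kappa it converges to the Bessel ratio ``I1(kappa)/I0(kappa)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .preprocess import Segment

NFFT = 4096


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")


@dataclass
class PLFSpectrum:
    freqs_hz: np.ndarray
    plf: np.ndarray
    n_trials: int
    n_windows: int

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.plf = np.asarray(self.plf, dtype=np.float64)
        if np.any(self.plf < -1e-12) or np.any(self.plf > 1 + 1e-12):
            raise ValueError("PLF values must lie in [0, 1]")


@dataclass
class Scalogram:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValueError("magnitude must be (n_freqs, n_times)")


def periodogram_natural(
    x: np.ndarray, fs: float, nfft: int = NFFT, taper: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram on the natural (zero-padded) FFT grid.

    Mean-removed; normalized so ``sum(power) == x.var()`` exactly
    (population variance).  No taper by default; ``taper="hann"`` applies
    a power-normalized Hanning window for leakage-sensitive uses.
    Returns (freqs_hz, power).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 8:
        raise ValueError("segment too short (need >= 8 samples)")
    if nfft < n:
        raise ValueError("nfft must be >= segment length")
    xc = x - x.mean()
    if taper is not None:
        if taper != "hann":
            raise ValueError(f"unknown taper {taper!r}")
        w = np.hanning(n)
        xc = xc * w * np.sqrt(n / (w ** 2).sum())  # preserve total power
    spec = np.fft.rfft(xc, n=nfft)
    power = np.abs(spec) ** 2 / (nfft * n)
    # fold negative frequencies: double everything except DC (and Nyquist
    # when nfft is even)
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, power


def _bin_grid(fmin: float, fmax: float, bin_count: int) -> np.ndarray:
    return np.linspace(fmin, fmax, bin_count)


def psd(
    segment: Segment,
    fmin: float = 0.0,
    fmax: float = 100.0,
    bin_count: int = 256,
    nfft: int = NFFT,
    taper: str | None = None,
) -> PowerSpectrum:
    """Periodogram of one segment interpolated onto the even analysis grid."""
    if fmax > segment.fs / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    f_nat, p_nat = periodogram_natural(segment.samples, segment.fs, nfft, taper)
    grid = _bin_grid(fmin, fmax, bin_count)
    return PowerSpectrum(grid, np.interp(grid, f_nat, p_nat), n_segments=1)


def mean_psd(
    segments: Sequence[Segment],
    fmin: float = 0.0,
    fmax: float = 100.0,
    bin_count: int = 256,
    nfft: int = NFFT,
    taper: str | None = None,
) -> PowerSpectrum:
    """Arithmetic mean of per-segment spectra (equal windows required)."""
    if not segments:
        raise ValueError("need at least one segment")
    lengths = {seg.samples.size for seg in segments}
    if len(lengths) != 1:
        raise ValueError(f"mixed segment lengths: {sorted(lengths)}")
    spectra = [psd(seg, fmin, fmax, bin_count, nfft, taper) for seg in segments]
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(spectra[0].freqs_hz, power, n_segments=len(segments))


def subtract(a: PowerSpectrum, b: PowerSpectrum) -> PowerSpectrum:
    """Bin-wise ``a - b`` (relative power; may be negative)."""
    if not np.array_equal(a.freqs_hz, b.freqs_hz):
        raise ValueError("spectra are on different grids")
    return PowerSpectrum(a.freqs_hz, a.power - b.power, n_segments=a.n_segments)


def band_mask(
    freqs_hz: np.ndarray,
    lo_hz: float,
    hi_hz: float,
    notch_hz: float | None = None,
    notch_halfwidth_hz: float = 2.0,
) -> np.ndarray:
    mask = (freqs_hz >= lo_hz) & (freqs_hz <= hi_hz)
    if notch_hz is not None:
        mask &= ~(
            (freqs_hz >= notch_hz - notch_halfwidth_hz)
            & (freqs_hz <= notch_hz + notch_halfwidth_hz)
        )
    return mask


def band_power(
    spectrum: PowerSpectrum,
    lo_hz: float,
    hi_hz: float,
    notch_hz: float | None = None,
) -> float:
    """Mean power over bins with lo <= f <= hi (closed interval).

    With ``notch_hz`` set (line-noise frequency), bins within +-2 Hz of it
    are excluded from the average.
    """
    mask = band_mask(spectrum.freqs_hz, lo_hz, hi_hz, notch_hz)
    if not np.any(mask):
        raise ValueError(f"band [{lo_hz}, {hi_hz}] contains no bins")
    return float(spectrum.power[mask].mean())


def window_phases(
    x: np.ndarray, fs: float, nfft: int = NFFT
) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-tapered DFT phase of one window on the natural grid.

    Returns (freqs_hz, unit phasors); bins with zero amplitude get a zero
    phasor so they contribute nothing to phase averages.
    """
    x = np.asarray(x, dtype=np.float64)
    spec = np.fft.rfft(x * np.hanning(x.size), n=nfft)
    mag = np.abs(spec)
    phasor = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0 + 0.0j)
    return np.fft.rfftfreq(nfft, d=1.0 / fs), phasor


def phase_locking(
    trial_segments: Sequence[Segment],
    fmin: float = 0.0,
    fmax: float = 100.0,
    bin_count: int = 256,
    window_s: float = 0.200,
    overlap_frac: float = 0.60,
    nfft: int = NFFT,
) -> PLFSpectrum:
    """Inter-trial phase-locking spectrum.

    A Hanning-tapered window of ``window_s`` slides over each trial with
    step ``(1 - overlap_frac) * window_s``; per window position the PLF is
    the across-trial resultant length of unit phasors, and the final
    spectrum is the mean over positions, interpolated onto the even grid.
    """
    if len(trial_segments) < 2:
        raise ValueError("phase locking needs at least 2 trials")
    fs = trial_segments[0].fs
    if fmax > fs / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    lengths = {seg.samples.size for seg in trial_segments}
    if len(lengths) != 1:
        raise ValueError("trials must have equal lengths")
    trial_len = lengths.pop()
    wlen = int(round(window_s * fs))
    if wlen > trial_len:
        raise ValueError("trials shorter than the phase-locking window")
    step = max(1, int(round((1.0 - overlap_frac) * wlen)))
    starts = list(range(0, trial_len - wlen + 1, step))

    plf_nat = None
    for start in starts:
        phasors = []
        for seg in trial_segments:
            f_nat, ph = window_phases(seg.samples[start : start + wlen], fs, nfft)
            phasors.append(ph)
        resultant = np.abs(np.mean(phasors, axis=0))
        plf_nat = resultant if plf_nat is None else plf_nat + resultant
    plf_nat /= len(starts)

    grid = _bin_grid(fmin, fmax, bin_count)
    plf = np.clip(np.interp(grid, f_nat, plf_nat), 0.0, 1.0)
    return PLFSpectrum(grid, plf, n_trials=len(trial_segments), n_windows=len(starts))


def scalogram(
    signal: np.ndarray,
    fs: float,
    fmin: float = 1.0,
    fmax: float = 100.0,
    n_freqs: int = 64,
    wavelet: str = "cgau8",
) -> Scalogram:
    """Complex-Gaussian continuous wavelet transform magnitude.

    Log-spaced frequency grid; scale = center_frequency * fs / f.  The
    magnitude is amplitude-normalized (divided by scale) so equal-amplitude
    oscillations at different frequencies produce comparable ridge heights
    and the ridge of a pure tone sits at its true frequency rather than
    being tilted toward larger scales.
    """
    if fmin <= 0:
        raise ValueError("fmin must be > 0")
    signal = np.asarray(signal, dtype=np.float64)
    freqs = np.geomspace(fmin, fmax, n_freqs)
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(signal, scales, wavelet, sampling_period=1.0 / fs)
    times = np.arange(signal.size) / fs
    return Scalogram(times, freqs, np.abs(coef) / scales[:, np.newaxis])


def rayleigh_floor(n_trials: int) -> float:
    """Expected PLF of phase-random trials: sqrt(pi) / (2 sqrt(n))."""
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_trials)))


def vonmises_plf(kappa: float) -> float:
    """Asymptotic PLF for von Mises phase jitter: I1(kappa)/I0(kappa)."""
    from scipy.special import i0e, i1e

    return float(i1e(kappa) / i0e(kappa))
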