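"""Synthetic session-structured LFP generator.

Emulates the in-vivo session protocol — a quiescent pre-stimulus span, a
40-Hz click-train session (500-ms trains), a 20-Hz session (1000-ms
trains), trains repeated every 20 s, then a quiescent post-stimulus span —
with a generative model of three ingredients per channel:

* background: 1/f^alpha noise synthesized in the frequency domain (random
  phases, amplitude proportional to f^(-alpha/2)), scaled to a
  state-dependent standard deviation — one gain for awake-quiescent spans
  (pre/post) and one for the stimulated ASSR sessions, blended with a 1-s
  raised-cosine crossfade at epoch boundaries;
* an N1 transient per train: a negative Gaussian-windowed deflection at a
  fixed latency after train onset;
* a steady-state oscillation per train at the drive frequency plus a 2f
  harmonic, whose per-trial phase is drawn von Mises(0, kappa) — kappa is
  the phase-locking dial (kappa -> inf gives perfectly reproducible phase,
  kappa = 0 gives none).

The genotype contrast of the study is reproduced by construction in
:func:`make_genotype_cohort`: NMDAR-hypofunction mutants get halved
steady-state amplitude, a quarter of the phase concentration, and a 1.5x
quiescent background gain, while their *stimulated* background gain equals
the control value — so baseline power normalizes during the ASSR sessions,
the state-dependent signature of the study.  These ratios are modeling
choices for qualitative-pattern recovery, not estimates.

Default physical scales: quiescent background SD 25 uV, so the 0.1-mV N1
inclusion screen sits at ~4 standard deviations of the background and the
default 0.2-mV N1 passes it; steady-state amplitude 50 uV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .lfp_io import Recording, SessionLayout, StimulusEvent


@dataclass
class SimulationConfig:
    """Generator knobs; defaults are the study protocol / realistic scales."""

    fs: float = 1560.0
    n_trials: int = 50
    isi_s: float = 20.0
    pre_s: float = 30.0
    post_s: float = 60.0
    background_exponent: float = 1.0
    background_gain_quiescent: float = 2.5e-5   # volts SD
    background_gain_stimulated: float = 2.5e-5  # volts SD
    n1_amp: float = 2.0e-4                      # volts, negative deflection
    n1_latency_s: float = 0.030
    n1_width_s: float = 0.015
    ss_amp_40: float = 5.0e-5                   # volts, 40-Hz drive
    ss_amp_20: float = 5.0e-5                   # volts, 20-Hz drive
    harmonic_frac: float = 0.3                  # 2f amplitude / f amplitude
    phase_kappa: float = 8.0                    # von Mises concentration
    ss_onset_delay_s: float = 0.100             # steady state starts after N1
    ss_ramp_s: float = 0.050
    crossfade_s: float = 1.0
    train_duration_40_s: float = 0.5
    train_duration_20_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n1_amp, self.ss_amp_40, self.ss_amp_20, self.harmonic_frac) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.phase_kappa < 0:
            raise ValueError("phase_kappa must be >= 0")
        if self.background_gain_quiescent <= 0 or self.background_gain_stimulated <= 0:
            raise ValueError("background gains must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        longest = max(self.train_duration_40_s, self.train_duration_20_s)
        if self.isi_s < longest + self.crossfade_s:
            raise ValueError(
                f"isi_s={self.isi_s} too short to host a {longest}-s train "
                "plus the state crossfade"
            )


def one_over_f_noise(
    n: int, alpha: float, rng: np.random.Generator, fs: float = 1.0
) -> np.ndarray:
    """Unit-SD 1/f^alpha noise via frequency-domain synthesis.

    Independent complex-Gaussian Fourier coefficients with amplitude
    proportional to f^(-alpha/2) for f > 0 and zero DC, inverse-transformed
    and rescaled to population SD 1.
    """
    n_freq = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    coef = amp * (rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq))
    x = np.fft.irfft(coef, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate noise draw")
    return x / sd


def session_layout(cfg: SimulationConfig) -> SessionLayout:
    """Epochs and events implied by the protocol in ``cfg``."""
    t = cfg.pre_s
    assr40_span = cfg.n_trials * cfg.isi_s
    assr20_span = cfg.n_trials * cfg.isi_s
    epochs = [
        ("pre", 0.0, cfg.pre_s),
        ("assr40", t, t + assr40_span),
        ("assr20", t + assr40_span, t + assr40_span + assr20_span),
        ("post", t + assr40_span + assr20_span, t + assr40_span + assr20_span + cfg.post_s),
    ]
    events: list[StimulusEvent] = []
    for k in range(cfg.n_trials):
        events.append(
            StimulusEvent(t + k * cfg.isi_s, 40.0, cfg.train_duration_40_s, "assr40")
        )
    t20 = t + assr40_span
    for k in range(cfg.n_trials):
        events.append(
            StimulusEvent(t20 + k * cfg.isi_s, 20.0, cfg.train_duration_20_s, "assr20")
        )
    return SessionLayout(epochs=epochs, events=events)


def _state_gain_envelope(cfg: SimulationConfig, layout: SessionLayout, n: int) -> np.ndarray:
    """Per-sample background SD: quiescent vs stimulated with cosine crossfades."""
    t = np.arange(n) / cfg.fs
    gq, gs = cfg.background_gain_quiescent, cfg.background_gain_stimulated
    gain = np.full(n, gq)
    for label, start, end in layout.epochs:
        if label in ("assr40", "assr20"):
            gain[(t >= start) & (t < end)] = gs
    if cfg.crossfade_s > 0 and gq != gs:
        half = cfg.crossfade_s / 2.0
        boundaries = []
        for label, start, end in layout.epochs:
            if label == "assr40":
                boundaries.append((start, gq, gs))   # quiescent -> stimulated
            if label == "assr20":
                boundaries.append((end, gs, gq))     # stimulated -> quiescent
        for t_b, g_from, g_to in boundaries:
            mask = (t >= t_b - half) & (t < t_b + half)
            phase = (t[mask] - (t_b - half)) / cfg.crossfade_s  # 0 -> 1
            gain[mask] = g_from + (g_to - g_from) * 0.5 * (1 - np.cos(np.pi * phase))
    return gain


def _evoked_train(
    cfg: SimulationConfig, ev: StimulusEvent, theta: float, n: int
) -> tuple[slice, np.ndarray]:
    """Evoked waveform for one click train, returned as (slice, samples)."""
    fs = cfg.fs
    i0 = int(np.floor(ev.onset_s * fs))
    i1 = min(n, int(np.floor((ev.onset_s + ev.duration_s) * fs)))
    tt = np.arange(i0, i1) / fs - ev.onset_s  # time since train onset
    wave = -cfg.n1_amp * np.exp(-0.5 * ((tt - cfg.n1_latency_s) / cfg.n1_width_s) ** 2)
    amp = cfg.ss_amp_40 if ev.train_freq_hz == 40.0 else cfg.ss_amp_20
    if amp > 0:
        ramp = np.clip((tt - cfg.ss_onset_delay_s) / max(cfg.ss_ramp_s, 1e-9), 0.0, 1.0)
        env = amp * 0.5 * (1 - np.cos(np.pi * ramp))
        env[tt < cfg.ss_onset_delay_s] = 0.0
        f = ev.train_freq_hz
        wave = wave + env * (
            np.sin(2 * np.pi * f * tt + theta)
            + cfg.harmonic_frac * np.sin(2 * np.pi * 2 * f * tt + 2 * theta)
        )
    return slice(i0, i1), wave


def simulate_channel(
    cfg: SimulationConfig, layout: SessionLayout, rng: np.random.Generator
) -> np.ndarray:
    n = int(round((layout.epochs[-1][2]) * cfg.fs))
    signal = one_over_f_noise(n, cfg.background_exponent, rng, fs=cfg.fs)
    signal *= _state_gain_envelope(cfg, layout, n)
    for ev in layout.events:
        theta = rng.vonmises(0.0, cfg.phase_kappa) if cfg.phase_kappa > 0 else rng.uniform(
            -np.pi, np.pi
        )
        sl, wave = _evoked_train(cfg, ev, theta, n)
        signal[sl] += wave
    return signal


def simulate_session(
    cfg: SimulationConfig,
    n_channels: int = 1,
    animal_id: str = "sim",
    genotype: str = "unknown",
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[Recording, SessionLayout]:
    """Simulate one full recording session.

    Channels get independent noise and independent per-trial phases, each
    from its own spawned random stream, so the same seed always reproduces
    the same recording regardless of channel count requested elsewhere.
    """
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    layout = session_layout(cfg)
    streams = ss.spawn(n_channels)
    signals = np.stack(
        [
            simulate_channel(cfg, layout, np.random.default_rng(child))
            for child in streams
        ]
    )
    rec = Recording(
        signals=signals,
        fs=cfg.fs,
        channel_ids=[f"ch{i + 1}" for i in range(n_channels)],
        animal_id=animal_id,
        genotype=genotype,
    )
    return rec, layout


#: documented mutant-vs-control generator ratios (overridable)
MUTANT_SS_AMP_FACTOR = 0.5
MUTANT_PHASE_KAPPA_FACTOR = 0.25
MUTANT_QUIESCENT_GAIN_FACTOR = 1.5


def mutant_config(
    base: SimulationConfig,
    ss_amp_factor: float = MUTANT_SS_AMP_FACTOR,
    phase_kappa_factor: float = MUTANT_PHASE_KAPPA_FACTOR,
    quiescent_gain_factor: float = MUTANT_QUIESCENT_GAIN_FACTOR,
) -> SimulationConfig:
    """Derive the mutant generator from a control one.

    The stimulated background gain is left at the control value on purpose:
    the mutants' baseline elevation is specific to the quiescent state.
    """
    return replace(
        base,
        ss_amp_40=base.ss_amp_40 * ss_amp_factor,
        ss_amp_20=base.ss_amp_20 * ss_amp_factor,
        phase_kappa=base.phase_kappa * phase_kappa_factor,
        background_gain_quiescent=base.background_gain_quiescent * quiescent_gain_factor,
    )


def make_genotype_cohort(
    n_control: int,
    n_mutant: int,
    n_channels: int,
    base_cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> list[tuple[Recording, SessionLayout]]:
    """Simulate a cohort: ``n_control`` control + ``n_mutant`` mutant animals."""
    if n_control < 0 or n_mutant < 0 or n_control + n_mutant < 1:
        raise ValueError("need at least one animal")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    base_cfg = base_cfg or SimulationConfig()
    mut_cfg = mutant_config(base_cfg)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_control + n_mutant)
    cohort = []
    for i in range(n_control):
        cohort.append(
            simulate_session(
                base_cfg, n_channels, f"ctrl{i + 1:02d}", "control", seed=children[i]
            )
        )
    for j in range(n_mutant):
        cohort.append(
            simulate_session(
                mut_cfg,
                n_channels,
                f"mut{j + 1:02d}",
                "mutant",
                seed=children[n_control + j],
            )
        )
    return cohort
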