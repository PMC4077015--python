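"""Derived ASSR quantities: N1 amplitude, evoked/relative power, PLF peaks,
and the five-epoch state-transition table.

Per channel and ASSR session the evoked spectrum is the trial-average
periodogram of the last 200 ms before click-train cessation (after the N1
has decayed); the baseline spectrum comes from a 200-ms segment 10 s before
each train onset; relative power is their bin-wise difference and may be
negative.  Band summaries use one closed-interval bin convention
throughout (see :func:`assrlab.spectral.band_power`).

The state-transition table tracks spontaneous band power across the five
epochs Pre, ISI(first), ISI(middle), ISI(last) and Post — 50 bins of
200 ms per epoch — the readout in which the mutants' quiescent broadband
elevation normalizes during repetitive stimulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lfp_io import AnalysisConfig, Recording, SessionLayout, StimulusEvent
from .preprocess import Segment, extract_segments, n1_deflection, schedule_epoch_bins
from .spectral import PLFSpectrum, PowerSpectrum, band_power, mean_psd, phase_locking, subtract

logger = logging.getLogger(__name__)


@dataclass
class ChannelASSRResult:
    channel_id: str
    drive_hz: float
    n1_amp_z: float
    evoked_spectrum: PowerSpectrum
    baseline_spectrum: PowerSpectrum
    relative_spectrum: PowerSpectrum
    plf: PLFSpectrum
    band_values: dict[str, dict[str, float]] = field(default_factory=dict)
    animal_id: str = "unknown"
    genotype: str = "unknown"


def n1_amplitude(
    trial_segments: Sequence[Segment],
    window: tuple[float, float] = (0.0, 0.100),
    pre_s: float = 0.050,
) -> float:
    """Trial-averaged peak |deflection from pre-onset mean| in (0, 100 ms].

    Segments must span ``[-pre_s, >= window[1]]`` around train onset (their
    ``t_start_s`` is interpreted relative to onset, i.e. equals ``-pre_s``).
    """
    if not trial_segments:
        raise ValueError("need at least one trial")
    fs = trial_segments[0].fs
    avg = np.mean([seg.samples for seg in trial_segments], axis=0)
    t = np.arange(avg.size) / fs + trial_segments[0].t_start_s
    if t[-1] < window[1]:
        raise ValueError("trial window too short for the N1 search interval")
    baseline = avg[t < 0].mean() if np.any(t < 0) else 0.0
    mask = (t > window[0]) & (t <= window[1])
    return float(np.max(np.abs(avg[mask] - baseline)))


def _trial_windows(
    recording: Recording,
    events: Sequence[StimulusEvent],
    cfg: AnalysisConfig,
) -> tuple[list, list]:
    """(tail windows, baseline windows) for the given trains.

    The baseline segment sits ``cfg.baseline_offset_s`` before each train
    onset.  For the first train this lands in the pre-stimulus epoch, which
    is used when available; a trial whose baseline would fall before the
    recording start contributes no baseline segment (logged).
    """
    tails, bases = [], []
    for k, ev in enumerate(events):
        t1 = ev.offset_s
        tails.append((t1 - cfg.assr_tail_s, t1, f"trial {k + 1} tail"))
        b0 = ev.onset_s - cfg.baseline_offset_s
        if b0 >= recording.t0:
            bases.append((b0, b0 + cfg.assr_tail_s, f"trial {k + 1} baseline"))
        else:
            logger.info("trial %d has no in-range baseline segment; skipped", k + 1)
    return tails, bases


def evoked_assr_analysis(
    recording_z: Recording,
    events: Sequence[StimulusEvent],
    cfg: AnalysisConfig,
    channel_id: str,
) -> ChannelASSRResult:
    """Full evoked analysis of one channel for one ASSR session."""
    if len(events) < 2:
        raise ValueError("need at least 2 trains in the session")
    drives = {ev.train_freq_hz for ev in events}
    if len(drives) != 1:
        raise ValueError("events mix drive frequencies; pass one session at a time")
    drive = drives.pop()

    tails, bases = _trial_windows(recording_z, events, cfg)
    tail_segs = extract_segments(recording_z, tails, channel_id)
    base_segs = extract_segments(recording_z, bases, channel_id)
    if not base_segs:
        raise ValueError("no baseline segment lies inside the recording")

    kw = dict(fmin=cfg.fmin_hz, fmax=cfg.fmax_hz, bin_count=cfg.bin_count)
    evoked = mean_psd(tail_segs, **kw)
    baseline = mean_psd(base_segs, **kw)
    relative = subtract(evoked, baseline)
    plf = phase_locking(
        tail_segs,
        window_s=cfg.plf_window_s,
        overlap_frac=cfg.plf_overlap_frac,
        **kw,
    )

    n1_windows = [
        (ev.onset_s - 0.050, ev.onset_s + 0.150, f"trial {k + 1} n1")
        for k, ev in enumerate(events)
        if ev.onset_s - 0.050 >= recording_z.t0
    ]
    n1_segs = extract_segments(recording_z, n1_windows, channel_id)
    for seg in n1_segs:
        seg.t_start_s = -0.050  # re-reference to train onset
    n1 = n1_amplitude(n1_segs, window=cfg.n1_window_s)

    band_values = {
        name: {
            "relative_power": band_power(relative, lo, hi, cfg.line_notch_hz),
            "evoked_power": band_power(evoked, lo, hi, cfg.line_notch_hz),
            "plf": band_power(plf_as_spectrum(plf), lo, hi, cfg.line_notch_hz),
        }
        for name, (lo, hi) in cfg.bands.items()
        if hi <= cfg.fmax_hz
    }
    return ChannelASSRResult(
        channel_id=channel_id,
        drive_hz=drive,
        n1_amp_z=n1,
        evoked_spectrum=evoked,
        baseline_spectrum=baseline,
        relative_spectrum=relative,
        plf=plf,
        band_values=band_values,
        animal_id=recording_z.animal_id,
        genotype=recording_z.genotype,
    )


def plf_as_spectrum(plf: PLFSpectrum) -> PowerSpectrum:
    """View a PLF spectrum through the band-averaging machinery."""
    return PowerSpectrum(plf.freqs_hz, plf.plf, n_segments=plf.n_trials)


def plf_peaks(
    plf: PLFSpectrum,
    bands: dict[str, tuple[float, float]],
    notch_hz: float | None = None,
) -> dict[str, float]:
    """Mean PLF per named band (closed-interval convention)."""
    spec = plf_as_spectrum(plf)
    return {name: band_power(spec, lo, hi, notch_hz) for name, (lo, hi) in bands.items()}


STATE_COLUMNS = ["animal_id", "channel_id", "genotype", "epoch", "band", "mean_power"]


def state_transition_table(
    recording_z: Recording,
    layout: SessionLayout,
    cfg: AnalysisConfig,
    bands: dict[str, tuple[float, float]] | None = None,
    channel_ids: Sequence[str] | None = None,
    session_label: str = "assr40",
) -> pd.DataFrame:
    """Tidy table of spontaneous band power per channel and state epoch.

    One row per (channel, epoch, band); epochs ordered Pre, ISI..., Post.
    A scheduled epoch whose bins fall outside the recording is omitted with
    a warning rather than aborting the whole table.
    """
    bands = bands if bands is not None else cfg.bands
    channel_ids = list(channel_ids) if channel_ids is not None else recording_z.channel_ids
    schedule = schedule_epoch_bins(layout, cfg, session_label)
    rows = []
    for cid in channel_ids:
        for epoch, windows in schedule.items():
            try:
                segs = extract_segments(recording_z, windows, cid)
            except ValueError as err:
                logger.warning("epoch %s omitted for channel %s: %s", epoch, cid, err)
                continue
            spec = mean_psd(segs, fmin=cfg.fmin_hz, fmax=cfg.fmax_hz, bin_count=cfg.bin_count)
            for name, (lo, hi) in bands.items():
                if hi > cfg.fmax_hz:
                    continue
                rows.append(
                    {
                        "animal_id": recording_z.animal_id,
                        "channel_id": cid,
                        "genotype": recording_z.genotype,
                        "epoch": epoch,
                        "band": name,
                        "mean_power": band_power(spec, lo, hi, cfg.line_notch_hz),
                    }
                )
    return pd.DataFrame(rows, columns=STATE_COLUMNS)


def isi_epoch_labels(table: pd.DataFrame) -> list[str]:
    """The ISI epoch labels present in a state table, in trial order."""
    labels = sorted(
        {e for e in table["epoch"].unique() if e.startswith("ISI")},
        key=lambda s: int(s[3:]),
    )
    return labels


def combined_isi_power(table: pd.DataFrame, band: str) -> pd.DataFrame:
    """Per-channel spontaneous power averaged over the ISI probe epochs.

    The combination is the mean of epoch means (not a pooled bin set).
    Returns tidy rows (animal_id, channel_id, genotype, mean_power).
    """
    isi = table[table["epoch"].isin(isi_epoch_labels(table)) & (table["band"] == band)]
    out = (
        isi.groupby(["animal_id", "channel_id", "genotype"], as_index=False)["mean_power"]
        .mean()
    )
    return out
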