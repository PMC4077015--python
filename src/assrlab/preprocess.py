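"""Normalization, channel screening and segment extraction.

Conventions fixed here and used everywhere downstream:

* z-scoring uses the mean and *population* SD over the entire recording
  epoch, per channel;
* the N1 inclusion screen is applied to the raw (volt) trial-averaged
  response — a channel survives iff the peak absolute deflection from the
  pre-onset mean within (0, 100 ms] after 40-Hz train onset exceeds the
  0.1-mV threshold;
* all extraction windows are half-open ``[t0, t1)`` in seconds, mapped to
  samples with floor, so 200-ms bins tile a 10-s span exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .lfp_io import AnalysisConfig, Recording, SessionLayout, StimulusEvent

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """A windowed slice of one channel."""

    samples: np.ndarray
    fs: float
    t_start_s: float
    label: str = ""


def zscore_normalize(recording: Recording) -> Recording:
    """Per-channel z-score over the full recording (population SD)."""
    mean = recording.signals.mean(axis=1, keepdims=True)
    sd = recording.signals.std(axis=1, keepdims=True)  # ddof=0
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance channel(s): {[recording.channel_ids[i] for i in flat]}"
        )
    return Recording(
        signals=(recording.signals - mean) / sd,
        fs=recording.fs,
        channel_ids=list(recording.channel_ids),
        animal_id=recording.animal_id,
        genotype=recording.genotype,
        t0=recording.t0,
        units="z",
    )


def _trial_average(
    channel: np.ndarray,
    fs: float,
    onsets: Sequence[float],
    t_before: float,
    t_after: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Average channel snippets aligned at the given onsets.

    Returns (time axis relative to onset, averaged trace).  Trials whose
    window falls outside the recording are skipped.
    """
    n_before = int(round(t_before * fs))
    n_after = int(round(t_after * fs))
    traces = []
    for onset in onsets:
        i0 = int(np.floor(onset * fs)) - n_before
        i1 = i0 + n_before + n_after
        if i0 < 0 or i1 > channel.size:
            continue
        traces.append(channel[i0:i1])
    if not traces:
        raise ValueError("no trial fits inside the recording")
    avg = np.mean(traces, axis=0)
    t = (np.arange(n_before + n_after) - n_before) / fs
    return t, avg


def n1_deflection(
    channel: np.ndarray,
    fs: float,
    onsets: Sequence[float],
    window: tuple[float, float] = (0.0, 0.100),
    pre_s: float = 0.050,
) -> float:
    """Peak |deflection from pre-onset mean| of the trial-averaged response.

    The extremum is searched in the half-open-from-below interval
    ``(window[0], window[1]]`` after onset.  Absolute value, not the signed
    trough, so the measure is robust to electrode polarity.
    """
    t, avg = _trial_average(channel, fs, onsets, pre_s, window[1] + 1.0 / fs)
    baseline = avg[t < 0].mean() if np.any(t < 0) else 0.0
    mask = (t > window[0]) & (t <= window[1])
    if not np.any(mask):
        raise ValueError("N1 window too short")
    return float(np.max(np.abs(avg[mask] - baseline)))


def screen_channels(
    recording_raw: Recording,
    events: Sequence[StimulusEvent],
    cfg: AnalysisConfig,
) -> list[str]:
    """Channels whose trial-averaged raw 40-Hz N1 exceeds the voltage screen."""
    if recording_raw.units != "V":
        raise ValueError("channel screening operates on the raw (volt) recording")
    onsets = [ev.onset_s for ev in events if ev.session_label == "assr40"]
    if not onsets:
        raise ValueError("no assr40 events to screen against")
    included = []
    for cid in recording_raw.channel_ids:
        amp = n1_deflection(
            recording_raw.channel(cid), recording_raw.fs, onsets, cfg.n1_window_s
        )
        if amp > cfg.n1_threshold_v:
            included.append(cid)
    return included


def extract_segments(
    recording: Recording,
    windows: Sequence[tuple[float, float, str]],
    channel_id: str,
) -> list[Segment]:
    """Half-open window slices of one channel, labels preserved.

    The start sample is floor-mapped and the slice length is
    ``round((t1 - t0) * fs)``, so equal windows always yield equal-length
    segments regardless of their sub-sample alignment.
    """
    channel = recording.channel(channel_id)
    out = []
    for t0, t1, label in windows:
        i0 = recording.sample_index(t0)
        n = int(round((t1 - t0) * recording.fs))
        i1 = i0 + n
        if i0 < 0 or i1 > channel.size or n < 1:
            raise ValueError(f"window [{t0}, {t1}) out of recording range")
        out.append(Segment(channel[i0:i1].copy(), recording.fs, t0, label))
    return out


def _bin_windows(start: float, span: float, bin_s: float, label: str):
    n_bins = int(round(span / bin_s))
    return [
        (start + k * bin_s, start + (k + 1) * bin_s, f"{label} bin {k + 1}")
        for k in range(n_bins)
    ]


def probe_trials(n_trials: int) -> tuple[int, ...]:
    """1-based ISI probe trials: first, middle and last train.

    For the full 50-train protocol this is (1, 25, 50), the probes used in
    the study; shorter simulated sessions scale proportionally.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    probes = sorted({1, (n_trials + 1) // 2, n_trials})
    return tuple(probes)


def schedule_epoch_bins(
    layout: SessionLayout,
    cfg: AnalysisConfig,
    session_label: str = "assr40",
) -> dict[str, list[tuple[float, float, str]]]:
    """200-ms bin schedules for the five state epochs.

    * ``Pre``   — the last 10 s before the first train of the session;
    * ``ISI{k}`` — 5-15 s after the k-th train onset, for the first, middle
      and last train;
    * ``Post``  — a 10-s span starting ``cfg.post_offset_s`` after the end
      of the final train, clipped back to the last available 10 s of the
      post epoch (logged) when the recording is shorter than the full
      20-min protocol.
    """
    events = layout.session_events(session_label)
    if not events:
        raise ValueError(f"layout has no {session_label} events")
    span, bin_s = cfg.epoch_span_s, cfg.epoch_bin_s
    first_onset = events[0].onset_s
    pre_start, pre_end = layout.epoch_span("pre")
    if first_onset - span < pre_start - 1e-9:
        raise ValueError(f"pre epoch shorter than {span} s")
    schedule = {"Pre": _bin_windows(first_onset - span, span, bin_s, "Pre")}

    iso_lo, iso_hi = cfg.isi_power_window_s
    for k in probe_trials(len(events)):
        onset = events[k - 1].onset_s
        schedule[f"ISI{k}"] = _bin_windows(onset + iso_lo, iso_hi - iso_lo, bin_s, f"ISI{k}")

    last_end = max(ev.offset_s for ev in layout.events)
    post_start, post_end = layout.epoch_span("post")
    want = last_end + cfg.post_offset_s
    if want + span > post_end:
        fallback = post_end - span
        if fallback < post_start:
            raise ValueError(f"post epoch shorter than {span} s")
        logger.info(
            "post epoch too short for offset %.0f s; using last available "
            "10 s [%.1f, %.1f)",
            cfg.post_offset_s,
            fallback,
            post_end,
        )
        want = fallback
    schedule["Post"] = _bin_windows(want, span, bin_s, "Post")
    return schedule
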