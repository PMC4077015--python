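"""Data model and I/O for continuous LFP recordings, stimulus events and analysis config.

Containers
----------
``Recording``
    Multi-channel continuous signal in volts with sampling rate and
    animal/genotype metadata.
``StimulusEvent`` / ``SessionLayout``
    Click-train events and the partition of a recording into named epochs
    (pre-stimulus, 40-Hz ASSR session, 20-Hz ASSR session, post-stimulus).
``AnalysisConfig``
    Every analysis window and threshold used downstream, with defaults set
    to the published protocol (0.1-mV N1 screen, 200-ms analysis bins,
    10-s baseline offset, 256 frequency bins over 0-100 Hz, 60 %
    overlapping phase-locking windows).

On disk a recording is either an EDF file (16-bit interchange, see
:mod:`assrlab.edf`) or a native pair of a raw little-endian float64
channel-major ``.bin`` plus a JSON sidecar; the native pair is lossless.
Events travel as TSV with seconds-based columns.  All window-to-sample
mapping is half-open ``[t0, t1)`` via ``floor(t * fs)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

GENOTYPES = ("control", "mutant", "unknown")
EPOCH_LABELS = ("pre", "assr40", "assr20", "post")

#: band name -> (lo, hi) in Hz; the bands reported in the study
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "15-24": (15.0, 24.0),
    "21-30": (21.0, 30.0),
    "35-44": (35.0, 44.0),
    "55-64": (55.0, 64.0),
    "71-80": (71.0, 80.0),
    "75-84": (75.0, 84.0),
    "30-50": (30.0, 50.0),
    "50-100": (50.0, 100.0),
    "100-120": (100.0, 120.0),
}


@dataclass
class Recording:
    """Multi-channel continuous signal.

    ``signals`` is an ``(n_channels, n_samples)`` float64 array.  ``units``
    is 'V' for raw recordings and 'z' after z-score normalization.
    """

    signals: np.ndarray
    fs: float
    channel_ids: list[str]
    animal_id: str = "unknown"
    genotype: str = "unknown"
    t0: float = 0.0
    units: str = "V"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim == 1:
            self.signals = self.signals[np.newaxis, :]
        if self.signals.ndim != 2 or self.signals.shape[1] < 1:
            raise ValueError("signals must be (n_channels, n_samples) with >= 1 sample")
        if not self.fs > 0:
            raise ValueError("invalid sampling rate")
        if len(self.channel_ids) != self.signals.shape[0]:
            raise ValueError("channel_ids length does not match signal channel count")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signal values must be finite")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.signals[self.channel_ids.index(channel_id)]

    def sample_index(self, t_s: float) -> int:
        """Map a time in seconds to a sample index: floor((t - t0) * fs)."""
        return int(math.floor((t_s - self.t0) * self.fs))


@dataclass(frozen=True)
class StimulusEvent:
    """One click train: onset (s), drive frequency (Hz), duration (s)."""

    onset_s: float
    train_freq_hz: float
    duration_s: float
    session_label: str
    n_clicks: int = 0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.session_label not in ("assr40", "assr20"):
            raise ValueError(f"bad session_label {self.session_label!r}")
        expected = int(round(self.train_freq_hz * self.duration_s))
        if self.n_clicks == 0:
            object.__setattr__(self, "n_clicks", expected)
        elif self.n_clicks != expected:
            raise ValueError(
                f"n_clicks {self.n_clicks} inconsistent with "
                f"{self.train_freq_hz} Hz x {self.duration_s} s"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SessionLayout:
    """Ordered, non-overlapping named epochs plus the stimulus events."""

    epochs: list[tuple[str, float, float]]
    events: list[StimulusEvent]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.epochs:
            if label not in EPOCH_LABELS:
                raise ValueError(f"unknown epoch label {label!r}")
            if not (end > start >= prev_end):
                raise ValueError("epochs must be non-overlapping and ordered")
            prev_end = end
        for ev in self.events:
            if self.epoch_of(ev.onset_s) not in ("assr40", "assr20"):
                raise ValueError(f"event at {ev.onset_s} s lies outside ASSR epochs")

    def epoch_of(self, t_s: float) -> str | None:
        for label, start, end in self.epochs:
            if start <= t_s < end:
                return label
        return None

    def epoch_span(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.epochs:
            if lab == label:
                return (start, end)
        raise KeyError(label)

    def session_events(self, session_label: str) -> list[StimulusEvent]:
        return [ev for ev in self.events if ev.session_label == session_label]


@dataclass
class AnalysisConfig:
    """Analysis windows, thresholds and bands (defaults = published protocol)."""

    n1_threshold_v: float = 1e-4          # 0.1 mV channel-inclusion screen
    n1_window_s: tuple[float, float] = (0.0, 0.100)
    assr_tail_s: float = 0.200            # last 200 ms before train cessation
    baseline_offset_s: float = 10.0       # baseline segment 10 s before onset
    isi_power_window_s: tuple[float, float] = (5.0, 15.0)
    post_offset_s: float = 1200.0         # post spectra 20 min after last train
    epoch_span_s: float = 10.0
    bin_count: int = 256
    epoch_bin_s: float = 0.200
    plf_window_s: float = 0.200
    plf_overlap_frac: float = 0.60
    fmin_hz: float = 0.0
    fmax_hz: float = 100.0
    line_notch_hz: float | None = None    # e.g. 60.0 excludes 58-62 Hz from bands
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if self.assr_tail_s <= 0 or self.epoch_bin_s <= 0 or self.plf_window_s <= 0:
            raise ValueError("all analysis windows must be positive")
        if not 0 < self.plf_overlap_frac < 1:
            raise ValueError("plf_overlap_frac must be in (0, 1)")
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} must have lo < hi")


# ---------------------------------------------------------------------------
# Native .bin + .json container (lossless float64, channel-major)

def write_recording(recording: Recording, signal_path, header_path) -> None:
    """Write a recording as raw little-endian float64 (channel-major) + JSON sidecar."""
    signal_path, header_path = Path(signal_path), Path(header_path)
    recording.signals.astype("<f8").tofile(signal_path)
    header = {
        "format": "assrlab-raw-v1",
        "dtype": "<f8",
        "order": "channel-major",
        "fs": recording.fs,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "channel_ids": recording.channel_ids,
        "animal_id": recording.animal_id,
        "genotype": recording.genotype,
        "t0": recording.t0,
        "units": recording.units,
        "units_scale_to_v": 1.0,
    }
    header_path.write_text(json.dumps(header, indent=2) + "\n")


def read_recording(signal_path, header_path=None) -> Recording:
    """Read a recording from native .bin+.json or from an EDF file.

    For the native pair ``header_path`` is required; EDF is self-describing.
    """
    signal_path = Path(signal_path)
    if not signal_path.exists():
        raise FileNotFoundError(signal_path)
    if signal_path.suffix.lower() == ".edf":
        from . import edf

        return edf.read_edf(signal_path)
    if header_path is None:
        raise ValueError("native raw recordings need a JSON header path")
    header = json.loads(Path(header_path).read_text())
    for key in ("fs", "n_channels", "n_samples", "channel_ids"):
        if key not in header:
            raise ValueError(f"header missing field {key!r}")
    fs = float(header["fs"])
    if not fs > 0:
        raise ValueError("invalid sampling rate")
    n_ch, n_s = int(header["n_channels"]), int(header["n_samples"])
    data = np.fromfile(signal_path, dtype=header.get("dtype", "<f8"))
    if data.size != n_ch * n_s:
        raise ValueError(
            f"channel length mismatch: file has {data.size} samples, "
            f"header declares {n_ch} x {n_s}"
        )
    scale = float(header.get("units_scale_to_v", 1.0))
    return Recording(
        signals=data.reshape(n_ch, n_s) * scale,
        fs=fs,
        channel_ids=[str(c) for c in header["channel_ids"]],
        animal_id=str(header.get("animal_id", "unknown")),
        genotype=str(header.get("genotype", "unknown")),
        t0=float(header.get("t0", 0.0)),
        units=str(header.get("units", "V")),
    )


# ---------------------------------------------------------------------------
# Events TSV

EVENT_COLUMNS = ["onset_s", "train_freq_hz", "duration_s", "session_label"]


def write_events(events: Iterable[StimulusEvent], tsv_path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_s": ev.onset_s,
                "train_freq_hz": ev.train_freq_hz,
                "duration_s": ev.duration_s,
                "session_label": ev.session_label,
            }
            for ev in events
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def read_events(tsv_path) -> list[StimulusEvent]:
    """Read and validate a stimulus-event TSV; returns events sorted by onset."""
    df = pd.read_csv(tsv_path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    for col in ("onset_s", "train_freq_hz", "duration_s"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col!r}")
    events = [
        StimulusEvent(
            onset_s=float(row.onset_s),
            train_freq_hz=float(row.train_freq_hz),
            duration_s=float(row.duration_s),
            session_label=str(row.session_label),
        )
        for row in df.itertuples()
    ]
    return sorted(events, key=lambda ev: ev.onset_s)


def write_layout(layout: SessionLayout, json_path) -> None:
    payload = {
        "epochs": [[label, start, end] for label, start, end in layout.epochs],
        "events": [
            [ev.onset_s, ev.train_freq_hz, ev.duration_s, ev.session_label]
            for ev in layout.events
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_layout(json_path) -> SessionLayout:
    payload = json.loads(Path(json_path).read_text())
    return SessionLayout(
        epochs=[(str(l), float(a), float(b)) for l, a, b in payload["epochs"]],
        events=[
            StimulusEvent(float(t), float(f), float(d), str(lab))
            for t, f, d, lab in payload["events"]
        ],
    )


# ---------------------------------------------------------------------------
# Config files (flat YAML)

def load_analysis_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat YAML mapping.

    Unknown keys are rejected so typos fail loudly; ``bands`` may be a
    nested ``name: [lo, hi]`` mapping.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return analysis_config_from_dict(raw)


def analysis_config_from_dict(raw: dict) -> AnalysisConfig:
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "bands" in kwargs:
        kwargs["bands"] = {
            str(name): (float(lo), float(hi))
            for name, (lo, hi) in kwargs["bands"].items()
        }
    for key in ("n1_window_s", "isi_power_window_s"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    return AnalysisConfig(**kwargs)


def with_bands(cfg: AnalysisConfig, bands: dict[str, tuple[float, float]]) -> AnalysisConfig:
    return replace(cfg, bands=dict(bands))
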