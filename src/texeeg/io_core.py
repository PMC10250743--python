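"""Domain containers and file I/O for forehead-EEG recordings.

The data model is deliberately small: a :class:`Recording` is a channels x
samples array in microvolts with a sampling rate and metadata, an
:class:`EventList` marks task events by sample index, and an
:class:`EpochSet` holds event-locked trials with a time axis anchored at the
cue (t=0). Recordings travel as CSV (canonical, human-readable) or EDF/EDF+
(interoperability with amplifier exports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Forehead montage used throughout: sub-hairline 10/20 positions.
DEFAULT_CHANNELS = ("F7", "Fp1", "Fp2", "F8")

DEVICES = ("garment", "dry")
TASKS = ("ec_rest", "eo_rest", "movement", "artifact")

# Tolerated spellings of the four montage labels (vendor exports differ).
_CHANNEL_ALIASES = {
    "F7": "F7", "FP1": "Fp1", "FP2": "Fp2", "F8": "F8",
    "EEG F7": "F7", "EEG FP1": "Fp1", "EEG FP2": "Fp2", "EEG F8": "F8",
}


class SchemaError(ValueError):
    """A file or table does not match the expected layout."""


class PairingError(ValueError):
    """Paired data is incomplete or mismatched across conditions."""


def normalize_channel(name: str) -> str:
    """Map a channel label alias (e.g. ``"FP1"``, ``"EEG Fp1"``) to its
    canonical montage spelling, or return the stripped name unchanged."""
    key = name.strip().upper()
    return _CHANNEL_ALIASES.get(key, _CHANNEL_ALIASES.get(key.removeprefix("EEG").strip(), name.strip()))


@dataclass
class Recording:
    """Multichannel EEG time series in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in uV.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered labels, one per data row.
    subject_id, device, task : str
        Session metadata. ``device`` in {"garment", "dry"}; ``task`` in
        {"ec_rest", "eo_rest", "movement", "artifact"}; empty string when
        not applicable.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple = DEFAULT_CHANNELS
    subject_id: str = ""
    device: str = ""
    task: str = ""
    action: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains missing values")
        if self.device and self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}")
        if self.task and self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        """Return a copy with selected fields replaced (data is copied)."""
        kwargs.setdefault("data", self.data.copy())
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Event:
    """One task event, located by 0-based sample index."""

    onset_sample: int
    label: str
    duration_samples: int

    def __post_init__(self):
        if self.onset_sample < 0:
            raise ValueError("onset_sample must be >= 0")
        if self.duration_samples <= 0:
            raise ValueError("duration_samples must be > 0")


class EventList:
    """Ordered list of events with strictly increasing onsets."""

    def __init__(self, events: Iterable[Event]):
        evs = sorted(events, key=lambda e: e.onset_sample)
        onsets = [e.onset_sample for e in evs]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        self._events = tuple(evs)

    def __iter__(self):
        return iter(self._events)

    def __len__(self):
        return len(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __eq__(self, other):
        return isinstance(other, EventList) and self._events == other._events

    def select(self, label: str) -> "EventList":
        return EventList(e for e in self._events if e.label == label)

    def validate_against(self, rec: Recording) -> None:
        """Raise if any event extends past the end of the recording."""
        for e in self._events:
            if e.onset_sample + e.duration_samples > rec.n_samples:
                raise ValueError(
                    f"event {e.label!r} at sample {e.onset_sample} runs past "
                    f"recording end ({rec.n_samples} samples)"
                )


@dataclass
class EpochSet:
    """Event-locked trials: trials x channels x samples, t=0 at the cue."""

    data: np.ndarray
    fs: float
    time_axis: np.ndarray
    event_label: str = ""
    channel_names: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if len(self.time_axis) != self.data.shape[2]:
            raise ValueError("time axis length must match sample dimension")
        steps = np.diff(self.time_axis)
        if len(steps) and not np.allclose(steps, 1.0 / self.fs):
            raise ValueError("time axis must increase in steps of 1/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with the study's defaults.

    Spectral estimation uses a 1 s Hamming window zero-padded to 1024
    points (0.25 Hz bins at 256 Hz) with 30 ms of overlap between
    consecutive windows. Band power is summarized in five bands; 45-55 Hz
    tracks mains contamination as an impedance surrogate. The outlier
    detector high-passes at 60 Hz and flags Hilbert-envelope z-scores
    above 5; trials exceeding 250 uV are discarded before time-frequency
    analysis. ERD/ERS maps span 5-30 Hz at 0.25 Hz against a [-5, -2] s
    pre-cue baseline.
    """

    psd_window_s: float = 1.0
    psd_nfft: int = 1024
    psd_overlap_s: float = 0.030
    psd_fmax_hz: float = 60.0
    bands: dict = field(default_factory=lambda: {
        "delta": (0.0, 3.0),
        "theta": (4.0, 7.0),
        "alpha": (8.0, 12.0),
        "beta": (13.0, 30.0),
        "mains": (45.0, 55.0),
    })
    broadband_filter: tuple = (0.1, 100.0)
    movement_filter: tuple = (0.3, 30.0)
    display_filter: tuple = (0.5, 30.0)
    filter_order: int = 4
    outlier_hp_hz: float = 60.0
    outlier_z: float = 5.0
    trial_reject_uv: float = 250.0
    tfr_fmin: float = 5.0
    tfr_fmax: float = 30.0
    tfr_df: float = 0.25
    tfr_n_cycles: float = 7.0
    baseline_s: tuple = (-5.0, -2.0)
    epoch_window_s: tuple = (-7.0, 5.0)
    alpha_binwise: float = 0.05
    alpha_band: float = 0.05
    wet_impedance_threshold_ohm: float = 5000.0
    power_floor: float = 1e-20

    def __post_init__(self):
        if not (self.psd_window_s > 0 and self.psd_overlap_s >= 0):
            raise ValueError("window and overlap must be positive")
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi):
                raise ValueError(f"band {name} bounds must be ordered, got {(lo, hi)}")
        if not self.baseline_s[1] <= 0:
            raise ValueError("baseline interval must lie before t=0")
        if not self.baseline_s[0] < self.baseline_s[1]:
            raise ValueError("baseline interval must be ordered")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_recording_csv(path, fs: float | None = None, subject_id: str = "",
                       device: str = "", task: str = "") -> Recording:
    """Read a recording from CSV (header row; optional ``time_s`` column
    plus one column per channel, body in uV).

    ``fs`` may be given explicitly; otherwise it is inferred as the
    reciprocal of the median step of the ``time_s`` column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise SchemaError(
                f"{path.name}: non-numeric value in column {col!r} at data "
                f"line {row + 2}"  # +1 header, +1 one-based
            )
    cols = {normalize_channel(c): c for c in df.columns}
    if fs is None:
        if "time_s" not in df.columns:
            raise SchemaError(f"{path.name}: no fs given and no time_s column")
        steps = np.diff(df["time_s"].to_numpy())
        if len(steps) == 0 or np.median(steps) <= 0:
            raise SchemaError(f"{path.name}: cannot infer fs from time_s")
        fs = 1.0 / float(np.median(steps))
        # time columns carry limited decimals; snap to an integer rate
        if abs(fs - round(fs)) / fs < 0.005:
            fs = float(round(fs))
    missing = [ch for ch in DEFAULT_CHANNELS if ch not in cols]
    chan_cols = [c for c in df.columns if c != "time_s"]
    if not missing:
        names = DEFAULT_CHANNELS
        data = df[[cols[ch] for ch in DEFAULT_CHANNELS]].to_numpy(float).T
    elif len(missing) < len(DEFAULT_CHANNELS):
        raise SchemaError(f"{path.name}: missing channel column(s) {missing}")
    else:
        # Non-montage file: accept any numeric channel columns as-is.
        names = tuple(normalize_channel(c) for c in chan_cols)
        data = df[chan_cols].to_numpy(float).T
    return Recording(data=data, fs=fs, channel_names=names,
                     subject_id=subject_id, device=device, task=task)


def write_recording_csv(rec: Recording, path, include_time: bool = True) -> Path:
    path = Path(path)
    cols = {}
    if include_time:
        cols["time_s"] = rec.times
    for i, name in enumerate(rec.channel_names):
        cols[name] = rec.data[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    return path


def read_events_csv(path) -> EventList:
    """Read an events table with columns onset_sample,label,duration_samples."""
    df = pd.read_csv(path)
    required = {"onset_sample", "label", "duration_samples"}
    if not required.issubset(df.columns):
        raise SchemaError(f"events file must have columns {sorted(required)}")
    return EventList(
        Event(int(r.onset_sample), str(r.label), int(r.duration_samples))
        for r in df.itertuples()
    )


def write_events_csv(events: EventList, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(e.onset_sample, e.label, e.duration_samples) for e in events],
        columns=["onset_sample", "label", "duration_samples"],
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_recording_edf(path, subject_id: str = "", device: str = "",
                       task: str = "") -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (uV).

    All EEG signals must share one sampling rate; the header's physical
    dimension drives the unit conversion (handled by the mne reader, which
    yields volts).
    """
    import mne

    path = Path(path)
    _check_common_rate(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    names = tuple(normalize_channel(n) for n in raw.ch_names)
    return Recording(data=data_uv, fs=float(raw.info["sfreq"]),
                     channel_names=names, subject_id=subject_id,
                     device=device, task=task)


def _check_common_rate(path: Path) -> None:
    """Reject EDF files whose signals are stored at mixed sampling rates."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise SchemaError(f"{path.name}: truncated EDF header")
        ns = int(hdr[252:256].decode("ascii", "replace").strip() or 0)
        sig = fh.read(256 * ns)
    # samples-per-record block sits after 216 bytes/signal of other fields
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = {int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
           for i in range(ns)}
    if len(spr) > 1:
        raise SchemaError(
            f"{path.name}: mixed sampling rates {sorted(spr)} per record are "
            "not supported"
        )


def write_recording_edf(rec: Recording, path) -> Path:
    """Write a recording as EDF+C with 16-bit samples and uV units."""
    from ._edf import write_edf

    return write_edf(Path(path), rec.data, rec.fs, rec.channel_names,
                     units="uV")


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def extract_epochs(rec: Recording, events: Sequence[Event] | EventList,
                   label: str, tmin_s: float, tmax_s: float) -> EpochSet:
    """Cut event-locked epochs of window [tmin_s, tmax_s) around each event
    onset with the given label.

    Epochs that would extend past either end of the recording are dropped
    (the dropped count is logged). The time axis has t=0 exactly at the
    cue sample.
    """
    if not tmin_s < tmax_s:
        raise ValueError(f"tmin_s ({tmin_s}) must be < tmax_s ({tmax_s})")
    matching = [e for e in events if e.label == label]
    if not matching:
        raise ValueError(f"no events labelled {label!r}")
    i0 = int(round(tmin_s * rec.fs))
    i1 = int(round(tmax_s * rec.fs))
    rel = np.arange(i0, i1)
    trials, dropped = [], 0
    for e in sorted(matching, key=lambda e: e.onset_sample):
        lo, hi = e.onset_sample + i0, e.onset_sample + i1
        if lo < 0 or hi > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, lo:hi])
    if dropped:
        logger.info("extract_epochs: dropped %d/%d out-of-bounds epochs",
                    dropped, len(matching))
    if not trials:
        raise ValueError(f"all {len(matching)} epochs fell outside the recording")
    return EpochSet(data=np.stack(trials), fs=rec.fs,
                    time_axis=rel / rec.fs, event_label=label,
                    channel_names=rec.channel_names)
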