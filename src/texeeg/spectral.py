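"""Power spectral density estimation and band-power summaries.

The PSD estimator is Welch's method with the study settings: 1 s Hamming
windows zero-padded to 1024 points (0.25 Hz bins at 256 Hz) and 30 ms of
overlap between consecutive windows. The overlap is honoured literally —
8 samples at 256 Hz, i.e. near-disjoint windows — and is configurable for
anyone preferring the conventional 30-50%. Segment periodograms are
averaged in linear power; log10 is applied last; the grid is truncated to
the analyzed 0-60 Hz range.

Band power collapses the spectrum twice: log-power is first averaged over
the four electrodes per frequency bin (the "average electrode"), then
over the bins of each named band. Device comparisons are paired Wilcoxon
tests across subjects on these band means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .io_core import AnalysisConfig, Event, EventList, PairingError, Recording
from .stats import median_direction, wilcoxon_signed_rank

KEY_COLS = ["subject", "device", "task", "action"]


@dataclass
class Spectrum:
    """Per-channel log10 power vs frequency (0-60 Hz analyzed range)."""

    freqs: np.ndarray
    log_power: np.ndarray  # channels x freqs
    channel_names: tuple

    def __post_init__(self):
        if self.log_power.shape != (len(self.channel_names), len(self.freqs)):
            raise ValueError("log_power must be channels x freqs")
        if not np.isfinite(self.log_power).all():
            raise ValueError("log power must be finite (power is floored before log)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.log_power.T, columns=list(self.channel_names))
        df.insert(0, "freq_hz", self.freqs)
        return df


def compute_psd(rec: Recording, cfg: AnalysisConfig | None = None) -> Spectrum:
    """Welch PSD of a recording with the study's spectral settings.

    The recording is expected to be band-pass filtered (0.1-100 Hz broadband
    for the resting/artifact pipeline) before this call; the estimator does
    not filter. Raises if the recording is shorter than one window.
    """
    cfg = cfg or AnalysisConfig()
    nperseg = int(round(cfg.psd_window_s * rec.fs))
    noverlap = int(round(cfg.psd_overlap_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one "
            f"{cfg.psd_window_s} s window ({nperseg} samples)"
        )
    freqs, pxx = welch(rec.data, fs=rec.fs, window="hamming", nperseg=nperseg,
                       noverlap=noverlap, nfft=cfg.psd_nfft, detrend=False,
                       scaling="density", axis=1)
    keep = freqs <= cfg.psd_fmax_hz
    log_power = np.log10(np.maximum(pxx[:, keep], cfg.power_floor))
    return Spectrum(freqs=freqs[keep], log_power=log_power,
                    channel_names=rec.channel_names)


def band_means(spectrum: Spectrum, cfg: AnalysisConfig | None = None) -> dict:
    """Mean log power of the electrode-average in each configured band.

    A bin belongs to a band iff band_lo <= bin_center <= band_hi, so at
    0.25 Hz spacing adjacent bands (e.g. delta 0-3 and theta 4-7) share no
    bins.
    """
    cfg = cfg or AnalysisConfig()
    avg_electrode = spectrum.log_power.mean(axis=0)
    out = {}
    for name, (lo, hi) in cfg.bands.items():
        sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name} [{lo},{hi}] Hz contains no bins")
        out[name] = float(avg_electrode[sel].mean())
    return out


def band_power_table(spectra: dict, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Tabulate band means for spectra keyed by (subject, device, task) or
    (subject, device, task, action).

    Returns a DataFrame with one row per key and one column per band. All
    spectra must share a single frequency grid.
    """
    cfg = cfg or AnalysisConfig()
    ref_freqs = None
    rows = []
    for key, spec in spectra.items():
        if ref_freqs is None:
            ref_freqs = spec.freqs
        elif len(spec.freqs) != len(ref_freqs) or not np.allclose(spec.freqs, ref_freqs):
            raise ValueError(f"spectrum {key}: frequency grid mismatch")
        key = tuple(key) + ("",) * (4 - len(key))
        rows.append(dict(zip(KEY_COLS, key)) | band_means(spec, cfg))
    df = pd.DataFrame(rows)
    if df.duplicated(KEY_COLS).any():
        raise ValueError("duplicate (subject, device, task, action) keys")
    return df.sort_values(KEY_COLS).reset_index(drop=True)


def segment_by_action(rec: Recording, events: EventList) -> list:
    """Split an artifact-induction recording into one sub-recording per
    scripted action segment. Segments must not overlap and must lie inside
    the recording."""
    out = []
    prev_end = 0
    for e in events:
        if e.onset_sample < prev_end:
            raise ValueError(
                f"segment {e.label!r} at sample {e.onset_sample} overlaps "
                "the previous segment"
            )
        end = e.onset_sample + e.duration_samples
        if end > rec.n_samples:
            raise ValueError(
                f"segment {e.label!r} runs past the recording end "
                f"({end} > {rec.n_samples})"
            )
        sub = rec.copy_with(data=rec.data[:, e.onset_sample:end].copy(),
                            action=e.label)
        out.append((e.label, sub))
        prev_end = end
    return out


def compare_devices_by_band(table: pd.DataFrame, band: str, task: str,
                            action: str = "") -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank comparison garment vs dry of one band's
    power for one task, across subjects.

    Returns (W, two-sided p, direction) where direction is the sign of the
    median paired difference (garment - dry). Every subject must appear
    under both devices.
    """
    if band not in table.columns:
        raise ValueError(f"band {band!r} not in table")
    sel = (table["task"] == task) & (table.get("action", "") == action)
    sub = table[sel]
    piv = sub.pivot(index="subject", columns="device", values=band)
    for dev in ("garment", "dry"):
        if dev not in piv.columns:
            raise PairingError(f"no {dev} rows for task {task!r}")
    if piv.isna().any().any():
        missing = piv[piv.isna().any(axis=1)].index.tolist()
        raise PairingError(f"subjects missing one device: {missing}")
    g = piv["garment"].to_numpy()
    d = piv["dry"].to_numpy()
    w, p = wilcoxon_signed_rank(g, d)
    return w, p, median_direction(g, d)


def band_comparison_table(table: pd.DataFrame, task: str, action: str = "",
                          cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """All-band garment-vs-dry comparison for one task (and optional
    action): rows (band, W, p, direction)."""
    cfg = cfg or AnalysisConfig()
    rows = []
    for band in cfg.bands:
        w, p, direction = compare_devices_by_band(table, band, task, action)
        rows.append({"task": task, "action": action, "band": band,
                     "W": w, "p": p, "direction": direction})
    return pd.DataFrame(rows)


def action_schedule_events(fs: float, labels, duration_s: float = 10.0) -> EventList:
    """Events partitioning a recording into consecutive fixed-length action
    segments (the artifact-induction script)."""
    n = int(round(duration_s * fs))
    return EventList(Event(i * n, lab, n) for i, lab in enumerate(labels))
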