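"""Skin-electrode impedance modeling, synthesis, and summaries.

Measured skin-electrode interfaces are dispersive: |Z| falls with
frequency from a low-frequency plateau R_s + R_p toward the series
resistance R_s. A single-dispersion Cole model captures this:

    Z(f) = R_s + R_p / (1 + (i * 2*pi*f * tau)^alpha),   0 < alpha <= 1

Only impedance magnitudes are modeled, which is what impedance meters
report for electrode quality checks. Technology profiles (textile
garment, dry metal, gel-prepped wet) are calibrated so the model
reproduces each technology's average |Z| at 1 Hz and 10 Hz; a synthetic
study draws repeated measurements (subjects x electrodes x repetitions)
around the calibrated curve with multiplicative log-normal noise.

The 5 kOhm line is the conventional wet-EEG quality threshold; dry and
textile interfaces sit orders of magnitude above it and rely on
high-input-impedance amplifiers instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import stats as _stats

TECHNOLOGIES = ("garment", "dry", "wet")

#: Average |Z| anchors per technology at (1 Hz, 10 Hz), in Ohm.
TECHNOLOGY_ANCHORS_OHM = {
    "garment": (368e3, 171e3),
    "dry": (110e3, 78e3),
    "wet": (3.2e3, 3.05e3),
}

WET_THRESHOLD_OHM = 5000.0


def default_grid() -> np.ndarray:
    """The measurement grid: 10 log-spaced frequencies from 0.1 to 30 Hz."""
    return np.logspace(np.log10(0.1), np.log10(30.0), 10)


@dataclass
class ColeParams:
    """Single-dispersion Cole model parameters.

    R_s : series (high-frequency) resistance, Ohm.
    R_p : dispersion magnitude, Ohm; |Z| spans ~[R_s, R_s + R_p].
    tau : characteristic time, s (dispersion centered near 1/(2*pi*tau)).
    alpha : dispersion exponent in (0, 1]; 1 recovers a Debye relaxation.
    sigma_log : log-normal spread of repeated measurements (dimensionless).
    """

    R_s: float
    R_p: float
    tau: float = 0.16
    alpha: float = 0.8
    sigma_log: float = 0.2

    def __post_init__(self):
        if self.R_s <= 0 or self.R_p < 0 or self.tau <= 0:
            raise ValueError("R_s, tau must be > 0 and R_p >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


@dataclass
class ImpedanceMeasurement:
    """One |Z| sweep: 10 log-spaced frequencies in 0.1-30 Hz, Ohm."""

    technology: str
    subject_id: str
    electrode: str
    repetition: int
    freqs: np.ndarray
    z_mag: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.z_mag = np.asarray(self.z_mag, float)
        if self.technology not in TECHNOLOGIES:
            raise ValueError(f"unknown technology {self.technology!r}")
        if len(self.freqs) != 10 or len(self.z_mag) != 10:
            raise ValueError("a sweep has exactly 10 frequency points")
        if (self.z_mag <= 0).any():
            raise ValueError("impedance magnitudes must be positive")
        steps = np.diff(np.log(self.freqs))
        if not np.allclose(steps, steps[0], rtol=1e-3):
            raise ValueError("frequencies must be log-spaced")


def cole_magnitude(params: ColeParams, f_hz) -> np.ndarray:
    """|Z(f)| of the Cole model, principal branch of (i*2*pi*f*tau)^alpha."""
    f = np.asarray(f_hz, dtype=float)
    if (f <= 0).any():
        raise ValueError("frequency must be positive")
    jw_tau = (1j * 2 * np.pi * f * params.tau) ** params.alpha
    z = params.R_s + params.R_p / (1.0 + jw_tau)
    out = np.abs(z)
    return out if out.ndim else float(out)


def calibrate_profile(z_at_1hz: float, z_at_10hz: float, alpha: float = 0.8,
                      tau: float = 0.16, sigma_log: float = 0.2,
                      rtol: float = 0.005) -> ColeParams:
    """Solve for (R_s, R_p) so the Cole curve passes through the 1 Hz and
    10 Hz anchors (within ``rtol``), with alpha and tau held fixed.

    Raises a calibration error (with residuals) if no bounded solution
    reproduces the anchors.
    """
    if not z_at_1hz >= z_at_10hz > 0:
        raise ValueError("anchors must satisfy z(1 Hz) >= z(10 Hz) > 0")
    targets = np.array([z_at_1hz, z_at_10hz])
    f_anchor = np.array([1.0, 10.0])

    def resid(x):
        p = ColeParams(R_s=x[0], R_p=x[1], tau=tau, alpha=alpha,
                       sigma_log=sigma_log)
        return (cole_magnitude(p, f_anchor) - targets) / targets

    x0 = np.array([z_at_10hz, max(z_at_1hz - z_at_10hz, 1e-6 * z_at_1hz)])
    sol = least_squares(resid, x0, bounds=([1e-9, 0.0], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14)
    params = ColeParams(R_s=sol.x[0], R_p=max(sol.x[1], 0.0), tau=tau,
                        alpha=alpha, sigma_log=sigma_log)
    rel = np.abs(cole_magnitude(params, f_anchor) - targets) / targets
    if (rel > rtol).any():
        raise RuntimeError(
            f"calibration failed: relative residuals {rel} exceed {rtol} "
            f"for anchors ({z_at_1hz}, {z_at_10hz})"
        )
    return params


def default_technology_params(sigma_log: float = 0.2) -> dict:
    """Cole profiles calibrated to each technology's 1/10 Hz anchors."""
    return {tech: calibrate_profile(*TECHNOLOGY_ANCHORS_OHM[tech],
                                    sigma_log=sigma_log)
            for tech in TECHNOLOGIES}


def simulate_impedance_study(params_by_tech: dict | None = None,
                             n_subjects: int = 6, n_electrodes: int = 4,
                             n_reps: int = 3, seed: int = 0) -> list:
    """Draw a full impedance study: for each technology, ``n_subjects`` x
    ``n_electrodes`` x ``n_reps`` sweeps around the model curve with
    multiplicative log-normal noise (normalized to unit mean so averages
    are unbiased). Deterministic per seed."""
    from .io_core import DEFAULT_CHANNELS

    params_by_tech = params_by_tech or default_technology_params()
    rng = np.random.default_rng(seed)
    freqs = default_grid()
    electrodes = DEFAULT_CHANNELS[:n_electrodes]
    out = []
    for tech, params in params_by_tech.items():
        curve = cole_magnitude(params, freqs)
        s = params.sigma_log
        for subj in range(1, n_subjects + 1):
            for elec in electrodes:
                for rep in range(1, n_reps + 1):
                    noise = np.exp(rng.normal(0.0, s, len(freqs)) - s * s / 2)
                    out.append(ImpedanceMeasurement(
                        technology=tech, subject_id=f"S{subj:02d}",
                        electrode=elec, repetition=rep,
                        freqs=freqs.copy(), z_mag=curve * noise))
    return out


def average_impedance(measurements: Iterable[ImpedanceMeasurement],
                      technology: str):
    """Mean and SEM of |Z| per frequency over all of a technology's sweeps
    (all subjects, electrodes and repetitions pooled)."""
    ms = [m for m in measurements if m.technology == technology]
    if len(ms) < 2:
        raise ValueError(f"need >= 2 measurements for {technology!r}")
    freqs = ms[0].freqs
    for m in ms[1:]:
        if not np.allclose(m.freqs, freqs):
            raise ValueError("mixed frequency grids")
    z = np.stack([m.z_mag for m in ms])
    mean = z.mean(axis=0)
    sem = np.array([_stats.sem(z[:, j]) for j in range(z.shape[1])])
    return freqs.copy(), mean, sem


def impedance_at(freqs: np.ndarray, curve: np.ndarray, f_hz: float) -> float:
    """Log-log linear interpolation of an impedance curve; exact at grid
    points, error outside [min, max] of the grid."""
    freqs = np.asarray(freqs, float)
    curve = np.asarray(curve, float)
    if not (freqs.min() <= f_hz <= freqs.max()):
        raise ValueError(
            f"{f_hz} Hz outside the measured range "
            f"[{freqs.min():.3g}, {freqs.max():.3g}] Hz"
        )
    hit = np.isclose(freqs, f_hz, rtol=1e-9)
    if hit.any():
        return float(curve[hit][0])
    return float(np.exp(np.interp(np.log(f_hz), np.log(freqs), np.log(curve))))


def below_threshold(curve: np.ndarray,
                    threshold_ohm: float = WET_THRESHOLD_OHM):
    """Strict per-point comparison against the wet-EEG quality threshold,
    plus the all-points verdict."""
    per_point = np.asarray(curve, float) < threshold_ohm
    return per_point, bool(per_point.all())


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements: Iterable[ImpedanceMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for f, z in zip(m.freqs, m.z_mag):
            rows.append((m.technology, m.subject_id, m.electrode,
                         m.repetition, f, z))
    return pd.DataFrame(rows, columns=["technology", "subject", "electrode",
                                       "repetition", "freq_hz", "z_ohm"])


def frame_to_measurements(df: pd.DataFrame) -> list:
    out = []
    keys = ["technology", "subject", "electrode", "repetition"]
    for (tech, subj, elec, rep), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("freq_hz")
        out.append(ImpedanceMeasurement(
            technology=tech, subject_id=str(subj), electrode=elec,
            repetition=int(rep), freqs=grp["freq_hz"].to_numpy(),
            z_mag=grp["z_ohm"].to_numpy()))
    return out
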