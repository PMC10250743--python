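"""Seeded synthetic forehead-EEG sessions and cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes, for both device profiles:

* a 1/f^gamma pink background shared across the four frontal channels
  (inter-channel correlation rho, default 0.7, mimicking shared sources);
* a ~10 Hz alpha rhythm whose amplitude drops from eyes-closed to
  eyes-open (alpha reactivity);
* 50 Hz mains contamination whose amplitude depends on the device —
  higher for the textile headband, whose contact impedance is larger;
* eyes-open blink transients on the frontopolar channels (300 ms
  raised-cosine pulses, Fp:F amplitude ratio 3:1);
* a cued reaching session (4 blocks x 20 trials; rest 7 +/- 1 s, movement
  5 s) in which the 8-30 Hz content is attenuated by sqrt(1-d) during
  movement so band power drops by the fractional ERD depth d;
* a scripted artifact-induction session (9 actions x 10 s) whose artifact
  amplitude scales with the device's artifact gain.

Everything is deterministic given (profiles, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io_core import DEFAULT_CHANNELS, Event, EventList, Recording

#: The scripted artifact-induction actions, in fixed order.
ACTIONS = (
    "experimenter_hands", "tongue", "jaw", "blink", "eye_movement",
    "head_vertical", "head_horizontal", "shoulder", "arm",
)

FS_DEFAULT = 256.0

# Fp channels carry ocular activity ~3x stronger than the lateral F sites.
_OCULAR_WEIGHTS = np.array([1 / 3, 1.0, 1.0, 1 / 3])


@dataclass
class SubjectProfile:
    """Per-subject signal parameters (amplitudes in uV)."""

    alpha_freq_hz: float = 10.0
    alpha_amp_closed_uv: float = 8.0
    alpha_amp_open_uv: float = 2.5
    pink_slope: float = 1.0
    pink_scale_uv: float = 10.0
    blink_rate_hz: float = 0.25
    blink_amp_uv: float = 60.0
    erd_depth: float = 0.3

    def __post_init__(self):
        if not self.alpha_amp_open_uv < self.alpha_amp_closed_uv:
            raise ValueError("eyes-open alpha amplitude must be below eyes-closed")
        if not 0 <= self.erd_depth < 1:
            raise ValueError("erd_depth must be in [0, 1)")


@dataclass
class DeviceProfile:
    """Per-device contamination parameters."""

    name: str
    mains_amp_uv: float
    artifact_gain: float
    broadband_noise_uv: float = 1.0

    def __post_init__(self):
        if min(self.mains_amp_uv, self.artifact_gain,
               self.broadband_noise_uv) < 0:
            raise ValueError("device amplitudes must be >= 0")


def default_device_profiles() -> dict:
    """Calibrated device contrast: the textile headband picks up ~2x the
    mains amplitude and ~2.5x the scripted-artifact amplitude of the dry
    metal baseline; the sub-30 Hz background is shared physiology and is
    identical by construction."""
    return {
        "garment": DeviceProfile("garment", mains_amp_uv=3.0, artifact_gain=2.5),
        "dry": DeviceProfile("dry", mains_amp_uv=1.5, artifact_gain=1.0),
    }


@dataclass
class ActionSchedule:
    """The 9-action x 10 s artifact-induction script."""

    labels: tuple = ACTIONS
    duration_s: float = 10.0

    def __post_init__(self):
        if tuple(self.labels) != ACTIONS:
            raise ValueError(f"schedule must be the fixed 9 actions {ACTIONS}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float, gamma: float = 1.0, scale_uv: float = 10.0,
               rho: float = 0.7) -> np.ndarray:
    """Correlated 1/f^gamma noise, channels x samples, each channel
    normalized to RMS ``scale_uv``.

    Spectral shaping of white Gaussian noise in the frequency domain;
    channels mix a shared source with independent ones so that pairwise
    correlation is ~``rho``.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-gamma / 2.0)

    def one():
        spec = shaping * (rng.standard_normal(len(freqs))
                          + 1j * rng.standard_normal(len(freqs)))
        return np.fft.irfft(spec, n=n_samples)

    shared = one()
    out = np.empty((n_channels, n_samples))
    for c in range(n_channels):
        x = np.sqrt(rho) * shared + np.sqrt(1 - rho) * one()
        out[c] = x / x.std() * scale_uv
    return out


def _mains(rng, n_samples, fs, amp_uv, f_mains=50.0):
    t = np.arange(n_samples) / fs
    return amp_uv * np.sin(2 * np.pi * f_mains * t + rng.uniform(0, 2 * np.pi))


def _raised_cosine(n):
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def _blink_train(rng, n_samples, fs, rate_hz, amp_uv, width_s=0.3):
    """Ocular pulse train on one template channel (weighted per site later)."""
    x = np.zeros(n_samples)
    if rate_hz <= 0 or amp_uv <= 0:
        return x
    w = int(round(width_s * fs))
    pulse = _raised_cosine(w)
    t = rng.exponential(1.0 / rate_hz)
    while t * fs + w < n_samples:
        i = int(t * fs)
        x[i:i + w] += amp_uv * rng.uniform(0.7, 1.3) * pulse
        t += rng.exponential(1.0 / rate_hz)
    return x


def _smooth_gate(n_samples, fs, intervals, low_value, ramp_s=0.2):
    """Envelope equal to 1 outside ``intervals`` (sample index pairs) and
    ``low_value`` inside, with raised-cosine ramps."""
    env = np.ones(n_samples)
    for lo, hi in intervals:
        env[lo:hi] = low_value
    w = int(round(ramp_s * fs))
    if w > 1:
        kernel = np.hanning(w)
        kernel /= kernel.sum()
        env = np.convolve(env, kernel, mode="same")
    return env


def _bandsplit(x, fs, lo=8.0, hi=30.0):
    """Split channels x samples into (inside, outside) the [lo, hi] band
    with a zero-phase brick-wall FFT mask, so the in-band component holds
    exactly the band's power."""
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(x.shape[-1], 1.0 / fs)
    sel = (freqs >= lo) & (freqs <= hi)
    band = np.fft.irfft(np.where(sel, spec, 0), n=x.shape[-1], axis=-1)
    return band, x - band


# ---------------------------------------------------------------------------
# session generators
# ---------------------------------------------------------------------------

def _background(rng, profile, device, n, fs, alpha_amp, n_ch=4, rho=0.7):
    """Pink background + alpha rhythm + mains + white sensor noise."""
    x = pink_noise(rng, n_ch, n, fs, gamma=profile.pink_slope,
                   scale_uv=profile.pink_scale_uv, rho=rho)
    t = np.arange(n) / fs
    alpha = alpha_amp * np.sin(2 * np.pi * profile.alpha_freq_hz * t
                               + rng.uniform(0, 2 * np.pi))
    x += alpha  # coherent across the four forehead sites
    x += _mains(rng, n, fs, device.mains_amp_uv)
    x += device.broadband_noise_uv * rng.standard_normal((n_ch, n))
    return x


def simulate_resting(profile: SubjectProfile, device: DeviceProfile,
                     state: str, duration_s: float = 180.0,
                     seed: int = 0, fs: float = FS_DEFAULT,
                     rho: float = 0.7) -> Recording:
    """Resting-state recording with eyes closed or open.

    Eyes-closed uses the subject's full alpha amplitude; eyes-open uses
    the reduced one and adds frontopolar-dominant blink transients.
    """
    if state not in ("closed", "open"):
        raise ValueError(f"state must be 'closed' or 'open', got {state!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    alpha_amp = (profile.alpha_amp_closed_uv if state == "closed"
                 else profile.alpha_amp_open_uv)
    x = _background(rng, profile, device, n, fs, alpha_amp, rho=rho)
    if state == "open":
        blinks = _blink_train(rng, n, fs, profile.blink_rate_hz,
                              profile.blink_amp_uv)
        x += _OCULAR_WEIGHTS[:, None] * blinks
    task = "ec_rest" if state == "closed" else "eo_rest"
    return Recording(data=x, fs=fs, channel_names=DEFAULT_CHANNELS,
                     device=device.name, task=task)


def simulate_movement_session(profile: SubjectProfile, device: DeviceProfile,
                              n_blocks: int = 4, trials_per_block: int = 20,
                              seed: int = 0, fs: float = FS_DEFAULT,
                              rho: float = 0.7,
                              lead_in_s: float = 4.0,
                              inter_block_rest_s: float = 10.0,
                              movement_s: float = 5.0):
    """Cued reaching session: alternating rest (7 +/- 1 s, uniform) and
    movement (5 s) periods, with a post-movement blink/adjustment artifact
    at each movement->rest transition.

    During movement the 8-30 Hz content (band-filtered pink background plus
    the alpha rhythm) is scaled by sqrt(1-d), so its power drops by the
    fractional ERD depth ``d = profile.erd_depth``. Returns (Recording,
    EventList) with one 5 s ``movement`` event per trial.
    """
    if n_blocks < 1 or trials_per_block < 1:
        raise ValueError("n_blocks and trials_per_block must be >= 1")
    rng = np.random.default_rng(seed)

    # Lay out the schedule first so total length is known.
    movement_n = int(round(movement_s * fs))
    cursor = int(round(lead_in_s * fs))
    intervals, events = [], []
    for b in range(n_blocks):
        if b > 0:
            cursor += int(round(inter_block_rest_s * fs))
        for _ in range(trials_per_block):
            cursor += int(round(rng.uniform(6.0, 8.0) * fs))  # rest 7 +/- 1 s
            intervals.append((cursor, cursor + movement_n))
            events.append(Event(cursor, "movement", movement_n))
            cursor += movement_n
    n = cursor + int(round(3.0 * fs))  # trailing rest

    d = profile.erd_depth
    x = pink_noise(rng, 4, n, fs, gamma=profile.pink_slope,
                   scale_uv=profile.pink_scale_uv, rho=rho)
    t = np.arange(n) / fs
    alpha = profile.alpha_amp_open_uv * np.sin(
        2 * np.pi * profile.alpha_freq_hz * t + rng.uniform(0, 2 * np.pi))
    band, rest_of_spectrum = _bandsplit(x, fs)
    gate = _smooth_gate(n, fs, intervals, np.sqrt(1 - d))
    x = rest_of_spectrum + gate * (band + alpha)
    x += _mains(rng, n, fs, device.mains_amp_uv)
    x += device.broadband_noise_uv * rng.standard_normal((4, n))

    # Instructed blink/adjustment right after each movement ends.
    w = int(round(0.3 * fs))
    pulse = _raised_cosine(w)
    for _, hi in intervals:
        i = hi + int(round(rng.uniform(0.1, 0.6) * fs))
        if i + w < n:
            x[:, i:i + w] += (_OCULAR_WEIGHTS[:, None]
                              * profile.blink_amp_uv
                              * rng.uniform(0.7, 1.3) * pulse)

    rec = Recording(data=x, fs=fs, channel_names=DEFAULT_CHANNELS,
                    device=device.name, task="movement")
    return rec, EventList(events)


# Per-action artifact styles: (center frequency band, base amplitude uV,
# ocular-weighted?) — free parameters of the generator, not estimates of
# the real per-action amplitudes.
_ACTION_MODELS = {
    "experimenter_hands": (0.5, 45.0, 80.0, False),
    "tongue": (0.3, 2.0, 35.0, False),
    "jaw": (15.0, 60.0, 30.0, False),
    "blink": (None, None, 60.0, True),
    "eye_movement": (0.2, 1.5, 45.0, True),
    "head_vertical": (0.5, 45.0, 70.0, False),
    "head_horizontal": (0.5, 45.0, 50.0, False),
    "shoulder": (0.5, 45.0, 30.0, False),
    "arm": (0.5, 45.0, 55.0, False),
}


def _action_waveform(rng, label, n, fs, amp_scale):
    lo, hi, amp, ocular = _ACTION_MODELS[label]
    amp = amp * amp_scale
    if label == "blink":
        x = _blink_train(rng, n, fs, rate_hz=1.0, amp_uv=amp)
    else:
        sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(n))
        x = x / x.std() * amp
        # intermittent bursts rather than continuous contamination
        burst = _smooth_gate(n, fs, [], 1.0)
        n_bursts = rng.integers(3, 6)
        mask = np.zeros(n)
        for _ in range(n_bursts):
            b0 = rng.integers(0, max(n - int(fs), 1))
            mask[b0:b0 + int(rng.uniform(0.5, 2.0) * fs)] = 1.0
        kernel = np.hanning(int(0.2 * fs))
        mask = np.convolve(mask, kernel / kernel.sum(), mode="same")
        x = x * np.maximum(mask, 0.15) * burst
    weights = _OCULAR_WEIGHTS if ocular else np.full(4, 1.0)
    return weights[:, None] * x


def simulate_artifact_session(profile: SubjectProfile, device: DeviceProfile,
                              schedule: ActionSchedule | None = None,
                              seed: int = 0, fs: float = FS_DEFAULT,
                              rho: float = 0.7,
                              action_amp_scale: float = 1.0):
    """Artifact-induction session: eyes-open background plus one scripted
    artifact waveform per 10 s action segment, scaled by the device's
    artifact gain. Returns (Recording, EventList) with one event per
    action."""
    schedule = schedule or ActionSchedule()
    rng = np.random.default_rng(seed)
    seg_n = int(round(schedule.duration_s * fs))
    n = seg_n * len(schedule.labels)
    x = _background(rng, profile, device, n, fs,
                    profile.alpha_amp_open_uv, rho=rho)
    events = []
    for i, label in enumerate(schedule.labels):
        lo = i * seg_n
        if action_amp_scale > 0:
            x[:, lo:lo + seg_n] += device.artifact_gain * _action_waveform(
                rng, label, seg_n, fs, action_amp_scale)
        events.append(Event(lo, label, seg_n))
    rec = Recording(data=x, fs=fs, channel_names=DEFAULT_CHANNELS,
                    device=device.name, task="artifact")
    return rec, EventList(events)


def make_cohort(n_subjects: int, seed: int = 0) -> list:
    """Draw ``n_subjects`` subject profiles from documented realistic
    ranges (alpha frequency 9-11 Hz, eyes-closed alpha 6-12 uV, eyes-open
    at 20-50% of that, pink slope 0.8-1.2, ERD depth 0.2-0.4),
    deterministically per seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        closed = rng.uniform(6.0, 12.0)
        cohort.append(SubjectProfile(
            alpha_freq_hz=rng.uniform(9.0, 11.0),
            alpha_amp_closed_uv=closed,
            alpha_amp_open_uv=closed * rng.uniform(0.2, 0.5),
            pink_slope=rng.uniform(0.8, 1.2),
            pink_scale_uv=rng.uniform(8.0, 14.0),
            blink_rate_hz=rng.uniform(0.15, 0.3),
            blink_amp_uv=rng.uniform(40.0, 80.0),
            erd_depth=rng.uniform(0.2, 0.4),
        ))
    return cohort
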