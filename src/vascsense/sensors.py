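"""Simulated physiological / telemetry streams and confidence weighting.

Channels and rates follow common MR-suite monitoring setups: ECG at 1000 Hz,
PPG and respiration at 100 Hz, gradient-current and RF-power telemetry at
1 kHz, table encoder at 10 Hz, ambient temperature at 1 Hz.  Preprocessing is
channel-specific and zero-phase (forward-backward filtering): ECG gets a
0.5 Hz high-pass plus a mains notch, PPG an 8 Hz low-pass, respiration a 2 Hz
low-pass, telemetry is z-score normalized.

Instability scoring turns synchronized channel deviations into a per-readout
score in [0, 1]; the confidence-weighting operator maps the score affinely to
weights in [0.7, 1.0] — moderate down-weighting of corrupted readouts rather
than rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SensorStream",
    "generate_streams",
    "preprocess",
    "synchronize",
    "instability_score",
    "confidence_weights",
    "CHANNEL_RATES_HZ",
]

CHANNEL_RATES_HZ = {
    "ecg": 1000.0,
    "ppg": 100.0,
    "resp": 100.0,
    "gradient": 1000.0,
    "rf": 1000.0,
    "table": 10.0,
    "temp": 1.0,
}

# nominal amplitude and baseline noise std per channel (arbitrary units,
# calibration-residual scale 0.3-0.6% of nominal for telemetry)
_NOMINAL = {
    "ecg": (1.0, 0.010),
    "ppg": (1.0, 0.080),
    "resp": (1.0, 0.050),
    "gradient": (1.0, 0.004),
    "rf": (1.0, 0.005),
    "table": (1.0, 0.003),
    "temp": (1.0, 0.004),
}

_TELEMETRY = ("gradient", "rf", "table", "temp")


@dataclass
class SensorStream:
    channel: str
    rate_hz: float
    timestamps: np.ndarray
    values: np.ndarray
    noise_std: float = 0.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        dt = np.diff(self.timestamps)
        if len(dt) and not np.all(dt > 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(dt):
            expected = 1.0 / self.rate_hz
            if abs(np.mean(dt) - expected) > expected * 1e-6:
                raise ValueError("sample rate does not match timestamp spacing")


def generate_streams(duration_s: float, instability_schedule=(), seed: int = 0,
                     heart_rate_bpm: float = 70.0,
                     channels=("ecg", "ppg", "resp", "gradient", "rf")):
    """Synthetic sensor streams with optional instability epochs.

    ``instability_schedule`` is a sequence of ``(start_s, end_s)`` epochs in
    which channels receive motion-burst artifacts (amplified noise plus
    low-frequency excursions).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    streams = []
    for ch in channels:
        rate = CHANNEL_RATES_HZ[ch]
        n = int(round(duration_s * rate))
        t = np.arange(n) / rate
        nominal, noise = _NOMINAL[ch]
        if ch == "ecg":
            # pulse train: Gaussian R-waves on the cardiac grid + drift
            rr = 60.0 / heart_rate_bpm
            phase = (t % rr) / rr
            v = nominal * np.exp(-((phase - 0.5) ** 2) / (2 * 0.02**2))
            v += 0.10 * np.sin(2 * np.pi * 0.2 * t)
        elif ch == "ppg":
            f = heart_rate_bpm / 60.0
            v = nominal * (0.6 * np.sin(2 * np.pi * f * t)
                           + 0.2 * np.sin(4 * np.pi * f * t))
        elif ch == "resp":
            v = nominal * np.sin(2 * np.pi * 0.25 * t)
        else:
            v = np.full(n, nominal)
        v = v + rng.normal(0.0, noise, size=n)
        for (a, b) in instability_schedule:
            sel = (t >= a) & (t < b)
            if not sel.any():
                continue
            v[sel] += rng.normal(0.0, 12 * noise + 0.15 * nominal, size=sel.sum())
            v[sel] += 0.3 * nominal * np.sin(
                2 * np.pi * 1.3 * (t[sel] - a) + rng.uniform(0, 2 * np.pi)
            )
        streams.append(SensorStream(ch, rate, t, v, noise))
    return streams


def preprocess(stream: SensorStream, mains_hz: float = 50.0) -> SensorStream:
    """Channel-specific zero-phase filter chain."""
    ch, fs, v = stream.channel, stream.rate_hz, stream.values
    if ch == "ecg":
        sos = signal.butter(4, 0.5, "highpass", fs=fs, output="sos")
        v = signal.sosfiltfilt(sos, v)
        b, a = signal.iirnotch(mains_hz, Q=30.0, fs=fs)
        v = signal.filtfilt(b, a, v)
    elif ch == "ppg":
        sos = signal.butter(4, 8.0, "lowpass", fs=fs, output="sos")
        v = signal.sosfiltfilt(sos, v)
    elif ch == "resp":
        sos = signal.butter(4, 2.0, "lowpass", fs=fs, output="sos")
        v = signal.sosfiltfilt(sos, v)
    elif ch in _TELEMETRY:
        if ch == "rf":  # temporal smoothing before normalization
            v = uniform_filter1d(v, size=max(3, int(fs * 0.05)))
        sd = v.std()
        v = (v - v.mean()) / (sd if sd > 0 else 1.0)
    else:
        raise ValueError(f"unknown channel {ch!r}")
    return replace(stream, values=np.asarray(v))


def synchronize(streams, readout_timestamps):
    """Linear interpolation of every channel onto the readout clock.

    Returns ``(state, channels)`` with ``state`` of shape
    ``(n_readouts, n_channels)``.
    """
    rt = np.asarray(readout_timestamps, dtype=float)
    cols, names = [], []
    for s in streams:
        t0, t1 = s.timestamps[0], s.timestamps[-1]
        if rt[-1] < t0 or rt[0] > t1:
            raise ValueError(
                f"channel {s.channel!r} [{t0}, {t1}] does not overlap the "
                f"readout window [{rt[0]}, {rt[-1]}]"
            )
        cols.append(np.interp(rt, s.timestamps, s.values))
        names.append(s.channel)
    return np.column_stack(cols), names


def instability_score(state: np.ndarray, window: int = 9,
                      saturation: float = 5.0) -> np.ndarray:
    """Per-readout instability in [0, 1] from short-window signal variance.

    Each channel's local variance is converted to a robust z-score
    (median/MAD) over readouts, divided by ``saturation``, clipped to [0, 1];
    channels combine by maximum.
    """
    state = np.atleast_2d(np.asarray(state, dtype=float))
    if state.shape[1] == 0:
        raise ValueError("need at least one channel")
    scores = np.zeros(state.shape[0])
    for j in range(state.shape[1]):
        x = state[:, j]
        mu = uniform_filter1d(x, size=window, mode="nearest")
        var = uniform_filter1d((x - mu) ** 2, size=window, mode="nearest")
        med = np.median(var)
        mad = np.median(np.abs(var - med))
        scale = 1.4826 * mad
        if scale <= 0:
            z = np.zeros_like(var)
        else:
            z = np.maximum(0.0, (var - med) / scale)
        scores = np.maximum(scores, np.clip(z / saturation, 0.0, 1.0))
    return scores


def confidence_weights(score: np.ndarray) -> np.ndarray:
    """Affine map from instability score to measurement weight.

    ``w = 1.0 - 0.3 * score`` so that a quiet readout keeps full weight 1.0
    and a saturated one is moderately down-weighted to 0.7.
    """
    score = np.asarray(score, dtype=float)
    if np.any(score < 0) or np.any(score > 1):
        raise ValueError("scores must lie in [0, 1]")
    return 1.0 - 0.3 * score
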