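"""Surface-EMG conditioning and per-phase feature extraction.

Processing chain: band-pass filtering (20-450 Hz, zero-phase 4th-order
Butterworth), full-wave rectification, 50 ms moving-RMS smoothing. Per
phase and channel three features are extracted: integrated EMG
(iEMG, mV.s, time integral of the rectified signal), RMS amplitude (mV)
and median frequency (MF, Hz, the frequency splitting the Welch power
spectrum of the 20-450 Hz band into equal halves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

logger = logging.getLogger(__name__)

#: Default processing band, Hz.
PROCESS_BAND: tuple[float, float] = (20.0, 450.0)
#: Default RMS smoothing window, ms.
RMS_WINDOW_MS: float = 50.0
#: Canonical channel order: rectus femoris, biceps femoris, tibialis
#: anterior, lateral gastrocnemius.
CHANNELS: tuple[str, ...] = ("RA", "BF", "TA", "GL")
#: Minimum phase duration (s) for a reliable median-frequency estimate.
MIN_SPAN_S: float = 0.5


@dataclass
class EMGRecording:
    """Multichannel sampled EMG signal.

    data has shape (n_samples, n_channels) in mV; markers are phase
    boundary sample indices (start inclusive, end exclusive).
    """

    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    markers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise ValueError("data must be (n_samples, n_channels)")
        if list(self.markers) != sorted(self.markers):
            raise ValueError("markers must be sorted")
        if self.markers and (self.markers[0] < 0 or self.markers[-1] > len(self)):
            raise ValueError("markers out of range")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self)) / self.fs
        df = pd.DataFrame({"time_s": t})
        for i, ch in enumerate(self.channels):
            df[ch] = self.data[:, i]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "EMGRecording":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        chans = tuple(c for c in df.columns if c != "time_s")
        return cls(fs=round(fs, 6), channels=chans,
                   data=df[list(chans)].to_numpy())


def bandpass(x: np.ndarray, fs: float, low: float = PROCESS_BAND[0],
             high: float = PROCESS_BAND[1]) -> np.ndarray:
    """Zero-phase (forward-backward) 4th-order Butterworth band-pass."""
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high corner {high} Hz must be below Nyquist {fs / 2} Hz")
    sos = _sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(x, dtype=float))


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def rms_smooth(x: np.ndarray, fs: float, window_ms: float = RMS_WINDOW_MS) -> np.ndarray:
    """Centred moving RMS envelope; edges use shrinking windows (no padding)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    w = int(round(window_ms * fs / 1000.0))
    if w < 1:
        raise ValueError("window shorter than one sample")
    half_lo, half_hi = (w - 1) // 2 + 1, w // 2  # w samples total when interior
    csum = np.concatenate([[0.0], np.cumsum(x ** 2)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo + 1, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def median_frequency(x: np.ndarray, fs: float,
                     band: tuple[float, float] = PROCESS_BAND,
                     segment_s: float = 0.5) -> float:
    """Median frequency of the Welch PSD restricted to ``band``.

    Uses 0.5 s Hann segments with 50 % overlap; spans shorter than one
    segment fall back to a single full-span periodogram. The half-mass
    crossing is located with linear interpolation between bins.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(segment_s * fs)), x.size)
    f, pxx = _sig.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend="constant")
    mask = (f >= band[0]) & (f <= band[1])
    f, pxx = f[mask], pxx[mask]
    total = pxx.sum()
    if total <= 0:
        raise ValueError("median frequency undefined for all-zero span")
    cum = np.cumsum(pxx)
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    # each bin's mass is treated as uniform over the bin width centred on
    # its frequency; the median interpolates linearly inside the crossing bin
    df = float(f[1] - f[0]) if f.size > 1 else 0.0
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (half - prev) / max(cum[k] - prev, 1e-300)
    return float(f[k] - df / 2.0 + frac * df)


@dataclass
class EMGFeatures:
    """Per-channel per-phase feature triple."""

    iemg: float  # mV.s
    rms: float   # mV
    mf: float    # Hz


def features_for_phase(recording: EMGRecording, channel: str,
                       span: tuple[int, int] | None = None,
                       band: tuple[float, float] = PROCESS_BAND) -> EMGFeatures:
    """iEMG, RMS and MF of one channel over one phase span.

    The whole channel is band-pass filtered first (avoiding filter
    transients at span boundaries), then the span is sliced. iEMG is the
    rectangle-rule integral of the rectified filtered signal; RMS and MF
    are computed on the filtered (unrectified) signal.
    """
    if span is None:
        span = (0, len(recording))
    start, end = span
    if not (0 <= start < end <= len(recording)):
        raise ValueError(f"span {span} outside recording of length {len(recording)}")
    if (end - start) / recording.fs < MIN_SPAN_S:
        raise ValueError(f"span shorter than {MIN_SPAN_S} s: MF unreliable")
    filt = bandpass(recording.channel(channel), recording.fs, *band)[start:end]
    if not np.any(filt):
        raise ValueError("all-zero span: MF undefined")
    iemg = float(np.sum(np.abs(filt)) / recording.fs)
    rms = float(np.sqrt(np.mean(filt ** 2)))
    mf = median_frequency(filt, recording.fs, band)
    return EMGFeatures(iemg=iemg, rms=rms, mf=mf)


def feature_table(dataset, channels: tuple[str, ...] = CHANNELS) -> pd.DataFrame:
    """Long-format feature table for a cohort dataset.

    Columns: participant, condition, phase, channel, iemg, rms, mf.
    """
    rows = []
    for trial in dataset.rows:
        for ch in channels:
            feats = features_for_phase(trial.recording, ch)
            rows.append({
                "participant": trial.participant,
                "condition": trial.condition,
                "phase": trial.phase,
                "channel": ch,
                "iemg": feats.iemg,
                "rms": feats.rms,
                "mf": feats.mf,
            })
    return pd.DataFrame(rows)
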