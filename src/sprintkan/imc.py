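"""Intermuscular coherence (IMC).

Magnitude-squared coherence between two surface-EMG channels,

    Coherence(f) = |Sxy(f)|^2 / (Sxx(f) * Syy(f)),

estimated with Welch-averaged auto/cross spectra (Hann windows, 0.5 s
segments, 50 % overlap by default), band-averaged in the alpha (8-15 Hz),
beta (15-30 Hz) and gamma (30-50 Hz) bands, and flagged for significance
either against a fixed threshold of 0.5 or against the analytic 95 %
confidence limit ``1 - alpha**(1/(L-1))`` for ``L`` averaged segments.

One coherence estimate is produced per (trial, phase); the sprint phase is
the time resolution of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

logger = logging.getLogger(__name__)

#: EMG coherence bands, Hz (half-open intervals [low, high)).
ALPHA_BAND: tuple[float, float] = (8.0, 15.0)
BETA_BAND: tuple[float, float] = (15.0, 30.0)
GAMMA_BAND: tuple[float, float] = (30.0, 50.0)
BANDS: dict[str, tuple[float, float]] = {
    "alpha": ALPHA_BAND,
    "beta": BETA_BAND,
    "gamma": GAMMA_BAND,
}

#: Muscle pairs analysed (rectus femoris-biceps femoris and tibialis
#: anterior-lateral gastrocnemius).
PAIRS: tuple[tuple[str, str], ...] = (("RA", "BF"), ("TA", "GL"))

#: Fixed significance threshold used in the headline tables.
FIXED_THRESHOLD: float = 0.5


@dataclass
class CrossSpectra:
    """Welch-averaged auto- and cross-power spectral densities."""

    freqs: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray  # complex
    n_segments: int

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    coh: np.ndarray
    n_segments: int


@dataclass
class BandCoherence:
    pair: tuple[str, str]
    alpha: float
    beta: float
    gamma: float
    n_segments: int
    significant: dict[str, bool] = field(default_factory=dict)


def segment_count(n: int, nperseg: int, noverlap: int) -> int:
    """Number of (possibly overlapping) Welch segments for a signal of length n."""
    if n < nperseg:
        raise ValueError(f"signal length {n} shorter than one segment ({nperseg})")
    step = nperseg - noverlap
    return (n - nperseg) // step + 1


def cross_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    segment_s: float = 0.5,
    overlap_frac: float = 0.5,
) -> CrossSpectra:
    """Welch auto/cross spectra with Hann windows.

    Parameters
    ----------
    segment_s : segment length in seconds (default 0.5 s).
    overlap_frac : fractional overlap between consecutive segments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    nperseg = int(round(segment_s * fs))
    noverlap = int(round(nperseg * overlap_frac))
    n_seg = segment_count(x.size, nperseg, noverlap)
    kw = dict(fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
              detrend="constant", scaling="density", average="mean")
    f, sxx = _sig.welch(x, **kw)
    _, syy = _sig.welch(y, **kw)
    _, sxy = _sig.csd(x, y, **kw)
    return CrossSpectra(freqs=f, sxx=sxx, syy=syy, sxy=sxy, n_segments=n_seg)


def coherence_spectrum(cs: CrossSpectra) -> CoherenceSpectrum:
    """Pointwise |Sxy|^2 / (Sxx Syy); zero-power bins map to coherence 0."""
    denom = cs.sxx * cs.syy
    coh = np.zeros_like(denom)
    ok = denom > 0
    if not ok.all():
        logger.warning("coherence: %d zero-power bins set to 0", (~ok).sum())
    coh[ok] = np.abs(cs.sxy[ok]) ** 2 / denom[ok]
    # Cauchy-Schwarz bounds the true ratio by 1; clip float round-off only.
    coh = np.clip(coh, 0.0, 1.0)
    return CoherenceSpectrum(freqs=cs.freqs, coh=coh, n_segments=cs.n_segments)


def band_average(spec: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Unweighted mean coherence over bins with low <= f < high."""
    low, high = band
    mask = (spec.freqs >= low) & (spec.freqs < high)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(spec.coh[mask].mean())


def significance_threshold(
    n_segments: int, alpha_level: float = 0.05, mode: str = "fixed"
) -> float:
    """Significance threshold for band coherence.

    mode="fixed" returns the conventional 0.5 flag threshold used in the
    summary tables; mode="analytic" returns the 95 % (by default) confidence
    limit ``1 - alpha_level**(1/(L-1))`` for an L-segment estimate under the
    hypothesis of independence.
    """
    if mode == "fixed":
        return FIXED_THRESHOLD
    if mode == "analytic":
        if n_segments < 2:
            raise ValueError("analytic threshold requires at least 2 segments")
        return 1.0 - alpha_level ** (1.0 / (n_segments - 1))
    raise ValueError(f"unknown mode {mode!r}")


def pair_band_coherence(
    recording,
    pair: tuple[str, str],
    segment_s: float = 0.5,
    overlap_frac: float = 0.5,
    threshold_mode: str = "fixed",
) -> BandCoherence:
    """Band-averaged coherence for one muscle pair of a recording."""
    x = recording.channel(pair[0])
    y = recording.channel(pair[1])
    cs = cross_spectra(x, y, recording.fs, segment_s, overlap_frac)
    spec = coherence_spectrum(cs)
    vals = {name: band_average(spec, band) for name, band in BANDS.items()}
    thr = significance_threshold(cs.n_segments, mode=threshold_mode)
    sig = {name: v > thr for name, v in vals.items()}
    return BandCoherence(pair=pair, alpha=vals["alpha"], beta=vals["beta"],
                         gamma=vals["gamma"], n_segments=cs.n_segments,
                         significant=sig)


def coherence_table(
    dataset,
    pairs: tuple[tuple[str, str], ...] = PAIRS,
    segment_s: float = 0.5,
    overlap_frac: float = 0.5,
    threshold_mode: str = "fixed",
) -> pd.DataFrame:
    """Long-format IMC table for a cohort dataset.

    Columns: participant, condition, phase, pair, band, coherence,
    n_segments, significant.
    """
    rows = []
    for trial in dataset.rows:
        for pair in pairs:
            bc = pair_band_coherence(trial.recording, pair, segment_s,
                                     overlap_frac, threshold_mode)
            for band in BANDS:
                rows.append({
                    "participant": trial.participant,
                    "condition": trial.condition,
                    "phase": trial.phase,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "band": band,
                    "coherence": getattr(bc, band),
                    "n_segments": bc.n_segments,
                    "significant": bc.significant[band],
                })
    return pd.DataFrame(rows)
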