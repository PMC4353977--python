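"""Per-second normalized cross-correlation of theta-filtered LFP pairs.

For each non-overlapping 1-s window of a region pair, the normalized
('coeff') cross-correlation is computed over lags |l| <= max_lag and its peak
value and peak lag recorded; the mean peak across all seconds of a period is
the period's cross-correlation value.  Positive lag means the second signal
lags the first.  Signals are band-pass filtered (5-11 Hz default) once over
the whole period before windowing, so per-window filter transients cannot
contaminate the peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import FilterSpec, design_bandpass, filter_zero_phase
from .signal_io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class XcorrSeries:
    """Per-second cross-correlation peaks for one region pair."""

    second_index: np.ndarray   # 0-based window index
    peak_r: np.ndarray         # normalized correlation peak, in [-1, 1]
    peak_lag_s: np.ndarray     # lag of the peak (positive: second signal lags first)
    max_lag_s: float
    n_skipped: int = 0         # zero-energy windows dropped


@dataclass
class XcorrSummary:
    mean_peak_r: float
    sd_peak_r: float
    mean_lag_s: float
    sd_lag_s: float
    n_seconds: int


def normalized_xcorr(x: np.ndarray, y: np.ndarray,
                     max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """'coeff'-normalized cross-correlation r(l) for |l| <= max_lag.

    ``r(l) = sum_t x(t) y(t+l) / sqrt(sum x^2 * sum y^2)``, so r(0) = 1 when
    x == y.  Returns ``(lags, r)`` with lags in samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("inputs must be equal-length 1-D signals of length >= 2")
    ex, ey = np.dot(x, x), np.dot(y, y)
    if ex == 0 or ey == 0:
        raise ValidationError("zero-energy input: normalized correlation undefined")
    # correlate(y, x)[k] = sum_t y(t + k - (n-1)) x(t)  ->  lag l = k - (n-1)
    full = sps.correlate(y, x, mode="full", method="auto")
    lags = np.arange(-(len(x) - 1), len(x))
    keep = np.abs(lags) <= max_lag
    return lags[keep], full[keep] / np.sqrt(ex * ey)


def _peak_with_ties(lags: np.ndarray, r: np.ndarray) -> tuple[float, int]:
    """Peak of r; exact ties resolved toward smaller |lag|, then negative lag."""
    rmax = r.max()
    tied = np.flatnonzero(r == rmax)
    best = min(tied, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    return float(rmax), int(lags[best])


def per_second_peaks(x: np.ndarray, y: np.ndarray, fs: float,
                     filt: FilterSpec | None = None,
                     max_lag_s: float = 0.5) -> XcorrSeries:
    """Filter, window into non-overlapping 1-s pieces, and extract xcorr peaks.

    Windows align to the start of the provided signals (the period start).
    Zero-energy windows are skipped and counted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"signal length mismatch: {x.shape} vs {y.shape}")
    win = int(round(fs))
    if len(x) < win:
        raise ValidationError("signals must be at least 1 s long")
    filt = filt or FilterSpec()
    coeffs = design_bandpass(filt, fs)
    xf = filter_zero_phase(x, coeffs)
    yf = filter_zero_phase(y, coeffs)

    max_lag = int(round(max_lag_s * fs))
    seconds, peaks, lags_out = [], [], []
    n_skipped = 0
    for i in range(len(x) // win):
        xs = xf[i * win:(i + 1) * win]
        ys = yf[i * win:(i + 1) * win]
        if np.dot(xs, xs) == 0 or np.dot(ys, ys) == 0:
            n_skipped += 1
            continue
        lags, r = normalized_xcorr(xs, ys, max_lag)
        peak, lag = _peak_with_ties(lags, r)
        seconds.append(i)
        peaks.append(peak)
        lags_out.append(lag / fs)
    if n_skipped:
        logger.info("per_second_peaks: skipped %d zero-energy windows", n_skipped)
    return XcorrSeries(
        np.asarray(seconds, dtype=int),
        np.asarray(peaks, dtype=float),
        np.asarray(lags_out, dtype=float),
        max_lag_s,
        n_skipped,
    )


def summarize_peaks(series: XcorrSeries) -> XcorrSummary:
    """Mean and sample SD (n-1) of per-second peaks and lags."""
    n = len(series.peak_r)
    if n < 1:
        raise ValidationError("empty cross-correlation series")
    sd_r = float(np.std(series.peak_r, ddof=1)) if n > 1 else 0.0
    sd_l = float(np.std(series.peak_lag_s, ddof=1)) if n > 1 else 0.0
    return XcorrSummary(
        float(series.peak_r.mean()), sd_r,
        float(series.peak_lag_s.mean()), sd_l, n,
    )
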