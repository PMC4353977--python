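"""Multitaper cross-spectra, magnitude coherence, coherograms and coherence change.

Coherence between two LFP channels x, y is ``|S_xy(f)| / sqrt(S_xx(f) S_yy(f))``
with the spectra estimated by the multitaper method: K dpss tapers with
time-bandwidth product TW (K <= 2 TW - 1), Chronux-style defaults TW=3, K=5,
a 2-s moving window stepped by 200 ms.  Full-period coherence averages the
taper-by-window cross-spectral estimates across every window position of the
period (segmented multitaper), giving n_avg = K * n_windows elementary
estimates; a coherogram keeps window positions separate and averages over
tapers only.

A single elementary estimate gives coherence identically 1 regardless of the
data, so coherence with fewer than two averaged estimates is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import windows as spw

from .signal_io import ValidationError


@dataclass(frozen=True)
class MultitaperParams:
    """Taper count/bandwidth and moving-window geometry for coherence estimation."""

    tw: float = 3.0
    k: int = 5
    window_s: float = 2.0
    step_s: float = 0.2

    def __post_init__(self) -> None:
        if self.k > int(2 * self.tw - 1):
            raise ValidationError(
                f"k={self.k} tapers exceeds 2*TW-1={int(2 * self.tw - 1)} "
                "well-concentrated Slepian sequences"
            )
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        if not 0 < self.step_s <= self.window_s:
            raise ValidationError("need 0 < step_s <= window_s")


@dataclass
class CrossSpectra:
    freqs: np.ndarray
    sxx: np.ndarray            # real auto-density of x
    syy: np.ndarray            # real auto-density of y
    sxy: np.ndarray            # complex cross-density
    n_avg: int                 # taper x window estimates averaged
    params: MultitaperParams


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coh: np.ndarray            # magnitude coherence in [0, 1]
    params: MultitaperParams
    n_avg: int


@dataclass
class CoherogramResult:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    coh: np.ndarray            # shape (len(freqs_hz), len(times_s))
    params: MultitaperParams


def _window_starts(n: int, wlen: int, step: int) -> np.ndarray:
    if n < wlen:
        raise ValidationError(f"signal of {n} samples shorter than {wlen}-sample window")
    return np.arange(0, n - wlen + 1, step)


def _tapered_ffts(x: np.ndarray, starts: np.ndarray, tapers: np.ndarray,
                  wlen: int) -> np.ndarray:
    """FFTs of every (window, taper) combination: shape (n_win, k, n_freq)."""
    segs = np.stack([x[s:s + wlen] for s in starts])          # (n_win, wlen)
    return rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)


def multitaper_cross_spectra(x: np.ndarray, y: np.ndarray, fs: float,
                             params: MultitaperParams | None = None) -> CrossSpectra:
    """Taper- and window-averaged auto/cross spectral densities of x and y.

    Densities carry the same one-sided 1/fs scaling as the Welch PSD, so
    ``sxx`` here matches ``welch_psd`` run with the same window geometry.
    """
    params = params or MultitaperParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"signal length mismatch: {x.shape} vs {y.shape}")
    wlen = int(round(params.window_s * fs))
    step = max(1, int(round(params.step_s * fs)))
    starts = _window_starts(len(x), wlen, step)
    tapers = np.atleast_2d(spw.dpss(wlen, params.tw, Kmax=params.k, norm=2))

    fx = _tapered_ffts(x, starts, tapers, wlen)
    fy = _tapered_ffts(y, starts, tapers, wlen)

    # one-sided density scaling; interior bins carry the doubled power
    scale = np.full(fx.shape[-1], 2.0 / fs)
    scale[0] = 1.0 / fs
    if wlen % 2 == 0:
        scale[-1] = 1.0 / fs

    sxx = (np.abs(fx) ** 2).mean(axis=(0, 1)) * scale
    syy = (np.abs(fy) ** 2).mean(axis=(0, 1)) * scale
    sxy = (fx * np.conj(fy)).mean(axis=(0, 1)) * scale
    freqs = rfftfreq(wlen, d=1.0 / fs)
    return CrossSpectra(freqs, sxx, syy, sxy, int(len(starts) * params.k), params)


def coherence_spectrum(cs: CrossSpectra) -> CoherenceResult:
    """Magnitude coherence |S_xy| / sqrt(S_xx S_yy); zero where power vanishes.

    Refuses cross-spectra averaged over fewer than two elementary estimates
    (the single-estimate coherence is identically 1).
    """
    if cs.n_avg < 2:
        raise ValidationError(
            f"coherence undefined for n_avg={cs.n_avg} < 2 averaged estimates"
        )
    denom = cs.sxx * cs.syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(cs.sxy) / np.sqrt(np.maximum(denom, 0)), 0.0)
    return CoherenceResult(cs.freqs, np.clip(coh, 0.0, 1.0), cs.params, cs.n_avg)


def coherence(x: np.ndarray, y: np.ndarray, fs: float,
              params: MultitaperParams | None = None) -> CoherenceResult:
    """Full-period multitaper coherence (taper- and window-averaged)."""
    return coherence_spectrum(multitaper_cross_spectra(x, y, fs, params))


def coherogram(x: np.ndarray, y: np.ndarray, fs: float,
               params: MultitaperParams | None = None) -> CoherogramResult:
    """Time-resolved coherence: per window position, averaged over tapers only."""
    params = params or MultitaperParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"signal length mismatch: {x.shape} vs {y.shape}")
    if params.k < 2:
        raise ValidationError("coherogram needs k >= 2 tapers per window")
    wlen = int(round(params.window_s * fs))
    step = max(1, int(round(params.step_s * fs)))
    starts = _window_starts(len(x), wlen, step)
    tapers = np.atleast_2d(spw.dpss(wlen, params.tw, Kmax=params.k, norm=2))

    fx = _tapered_ffts(x, starts, tapers, wlen)
    fy = _tapered_ffts(y, starts, tapers, wlen)
    sxx = (np.abs(fx) ** 2).mean(axis=1)                      # (n_win, n_freq)
    syy = (np.abs(fy) ** 2).mean(axis=1)
    sxy = (fx * np.conj(fy)).mean(axis=1)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) / np.sqrt(np.maximum(denom, 0)), 0.0)
    times = (starts + wlen / 2) / fs
    freqs = rfftfreq(wlen, d=1.0 / fs)
    return CoherogramResult(times, freqs, np.clip(coh.T, 0.0, 1.0), params)


def band_coherence(res: CoherenceResult, band: tuple[float, float] = (7.0, 9.0),
                   mode: str = "at-frequency") -> float:
    """Scalar coherence for a band: value at the band-center grid frequency,
    or the band maximum."""
    low, high = band
    if mode == "at-frequency":
        center = 0.5 * (low + high)
        i = int(np.argmin(np.abs(res.freqs - center)))
        return float(res.coh[i])
    if mode == "band-max":
        mask = (res.freqs >= low) & (res.freqs <= high)
        if not mask.any():
            raise ValidationError(f"no grid frequencies inside band {band}")
        return float(res.coh[mask].max())
    raise ValidationError(f"unknown mode {mode!r}")


def coherence_change(coh_stim: CoherenceResult, coh_base: CoherenceResult,
                     band: tuple[float, float]) -> float:
    """Signed peak of (stimulus - base) coherence within ``band``; in [-1, 1]."""
    if coh_stim.freqs.shape != coh_base.freqs.shape or not np.allclose(
        coh_stim.freqs, coh_base.freqs
    ):
        raise ValidationError("coherence frequency grids differ; cannot subtract")
    low, high = band
    mask = (coh_stim.freqs >= low) & (coh_stim.freqs <= high)
    if not mask.any():
        raise ValidationError(f"no grid frequencies inside band {band}")
    return float(np.max(coh_stim.coh[mask] - coh_base.coh[mask]))
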