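"""PSD estimation, spectrograms and theta-power statistics.

Power spectral densities use Welch's method with a single dpss (Slepian)
taper as the window — 1-s windows, 50% overlap, time-bandwidth NW=3 by
default — returned as one-sided densities in dB/Hz.  Theta power (TP) is the
peak of the PSD within a search band; ΔTP subtracts the no-stimulus baseline
(Base / "Enc. 0") peak from every period's TP.  Spectrograms share the window
and scaling so that averaging spectrogram columns over a period reproduces
that period's Welch PSD.

The taper is unit-energy, so scipy's density scaling reduces to 1/fs and the
integral of the linear one-sided PSD over [0, fs/2] recovers the signal
variance for long stationary inputs (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal import windows as spw

from .signal_io import ValidationError

#: floor applied before 10*log10 so arithmetic on dB values stays finite
DB_FLOOR = -300.0

#: default TP search band (Hz) for the social-recognition analyses
TP_BAND = (5.0, 11.0)
#: generic theta search band (Hz)
THETA_BAND = (3.0, 12.0)
#: low/high theta sub-bands (Hz) for the fear-vs-social contrast
LOW_BAND = (4.0, 8.0)
HIGH_BAND = (8.0, 12.0)


def to_db(linear: np.ndarray) -> np.ndarray:
    """10*log10 with a -300 dB floor instead of -inf."""
    linear = np.asarray(linear, dtype=float)
    floor = 10.0 ** (DB_FLOOR / 10.0)
    return 10.0 * np.log10(np.maximum(linear, floor))


@dataclass(frozen=True)
class TaperParams:
    """Welch/spectrogram windowing: dpss taper choice, window length, overlap."""

    window_s: float = 1.0
    overlap_frac: float = 0.5
    nw: float = 3.0
    taper_index: int = 0
    pad_factor: int = 1  # FFT length = pad_factor * window length

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ValidationError(f"overlap_frac must be in [0,1), got {self.overlap_frac}")
        if self.nw < 1:
            raise ValidationError(f"nw must be >= 1, got {self.nw}")
        if self.taper_index < 0:
            raise ValidationError(f"taper_index must be >= 0, got {self.taper_index}")
        if self.pad_factor < 1:
            raise ValidationError(f"pad_factor must be >= 1, got {self.pad_factor}")


@dataclass
class PsdResult:
    freqs: np.ndarray          # Hz, 0 .. fs/2
    power_db: np.ndarray       # dB/Hz
    params: TaperParams
    n_windows: int

    def linear(self) -> np.ndarray:
        return 10.0 ** (self.power_db / 10.0)


@dataclass
class ThetaPowerResult:
    """Peak of the PSD within the theta search band."""

    tp_db: float
    peak_freq_hz: float
    band: tuple[float, float]
    period_name: str = ""


@dataclass
class DeltaTp:
    dtp_db: float
    reference_period: str


@dataclass
class SpectrogramResult:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    power_db: np.ndarray       # shape (len(freqs_hz), len(times_s))
    params: TaperParams


def make_dpss_window(window_s: float, fs: float, nw: float = 3.0,
                     taper_index: int = 0) -> np.ndarray:
    """The ``taper_index``-th Slepian sequence, unit energy, length round(window_s*fs).

    Sequences with index >= 2*NW-1 have poor spectral concentration and are
    refused.
    """
    m = int(round(window_s * fs))
    if m < 8:
        raise ValidationError(f"window of {m} samples is too short (need >= 8)")
    if taper_index >= int(2 * nw - 1):
        raise ValidationError(
            f"taper_index {taper_index} >= 2*nw-1 = {int(2 * nw - 1)}: "
            "poorly concentrated Slepian sequence"
        )
    tapers = spw.dpss(m, nw, Kmax=taper_index + 1, norm=2)
    return np.atleast_2d(tapers)[taper_index]


def _welch_args(fs: float, params: TaperParams) -> dict:
    win = make_dpss_window(params.window_s, fs, params.nw, params.taper_index)
    m = len(win)
    return dict(
        window=win,
        nperseg=m,
        noverlap=int(round(params.overlap_frac * m)),
        nfft=m * params.pad_factor,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )


def welch_psd(x: np.ndarray, fs: float, params: TaperParams | None = None) -> PsdResult:
    """One-sided Welch PSD with a dpss window, in dB/Hz."""
    params = params or TaperParams()
    x = np.asarray(x, dtype=float)
    kw = _welch_args(fs, params)
    if len(x) < kw["nperseg"]:
        raise ValidationError(
            f"signal of {len(x)} samples shorter than one {kw['nperseg']}-sample window"
        )
    freqs, pxx = sps.welch(x, fs=fs, **kw)
    step = kw["nperseg"] - kw["noverlap"]
    n_windows = (len(x) - kw["noverlap"]) // step
    return PsdResult(freqs, to_db(pxx), params, int(n_windows))


def theta_power(psd: PsdResult, band: tuple[float, float] = TP_BAND,
                period_name: str = "") -> ThetaPowerResult:
    """Peak PSD value (dB/Hz) over grid frequencies within ``band``.

    Ties break toward the lower frequency.
    """
    low, high = band
    mask = (psd.freqs >= low) & (psd.freqs <= high)
    if not mask.any():
        raise ValidationError(f"no grid frequencies inside band {band}")
    sub = psd.power_db[mask]
    i = int(np.argmax(sub))  # first max -> lowest frequency on ties
    return ThetaPowerResult(float(sub[i]), float(psd.freqs[mask][i]), band, period_name)


def delta_tp(tp_by_period: dict[str, ThetaPowerResult],
             reference: str = "Base") -> dict[str, DeltaTp]:
    """ΔTP: subtract the reference period's TP from every period's TP."""
    if reference not in tp_by_period:
        raise KeyError(f"reference period {reference!r} not in {sorted(tp_by_period)}")
    ref = tp_by_period[reference].tp_db
    return {
        name: DeltaTp(tp.tp_db - ref, reference) for name, tp in tp_by_period.items()
    }


def spectrogram(x: np.ndarray, fs: float,
                params: TaperParams | None = None) -> SpectrogramResult:
    """Sliding dpss-tapered periodograms with the Welch density scaling."""
    params = params or TaperParams()
    x = np.asarray(x, dtype=float)
    kw = _welch_args(fs, params)
    if len(x) < kw["nperseg"]:
        raise ValidationError(
            f"signal of {len(x)} samples shorter than one {kw['nperseg']}-sample window"
        )
    freqs, times, sxx = sps.spectrogram(x, fs=fs, mode="psd", **kw)
    return SpectrogramResult(times, freqs, to_db(sxx), params)


def instantaneous_tp(spec: SpectrogramResult, band: tuple[float, float] = TP_BAND,
                     reference_db: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-column theta-band peak minus a reference level (mean Base TP).

    Returns ``(times_s, dtp_db)`` on the spectrogram's time base.
    """
    low, high = band
    mask = (spec.freqs_hz >= low) & (spec.freqs_hz <= high)
    if not mask.any():
        raise ValidationError(f"no grid frequencies inside band {band}")
    peaks = spec.power_db[mask].max(axis=0)
    return spec.times_s, peaks - reference_db


def mean_base_tp(spec: SpectrogramResult, band: tuple[float, float] = TP_BAND) -> float:
    """Mean per-column TP of a (Base-period) spectrogram — the ΔTP reference."""
    _, tp = instantaneous_tp(spec, band, reference_db=0.0)
    return float(tp.mean())


def psd_change(psd_stim: PsdResult, psd_base: PsdResult) -> np.ndarray:
    """Stimulus-minus-Base PSD difference, pointwise in dB."""
    if psd_stim.freqs.shape != psd_base.freqs.shape or not np.allclose(
        psd_stim.freqs, psd_base.freqs
    ):
        raise ValidationError("PSD frequency grids differ; cannot subtract")
    return psd_stim.power_db - psd_base.power_db


def band_peak_change(change: np.ndarray, freqs: np.ndarray,
                     band: tuple[float, float]) -> float:
    """Maximum of a PSD change-spectrum over ``band`` (negative if the band only fell)."""
    low, high = band
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValidationError(f"no grid frequencies inside band {band}")
    return float(np.max(change[mask]))
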