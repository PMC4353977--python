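"""Theta-band FIR filtering of LFP signals.

The analysis band-pass is a windowed-sinc (Hamming) FIR filter, 5-11 Hz by
default — the high-theta band used for per-second cross-correlation.  The
filter is applied forward-backward so group delay is exactly zero; a
single-pass FIR would shift every cross-correlation lag estimate by a
constant half the filter length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import ValidationError


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR design: edges in Hz and number of taps minus one.

    ``order`` must be even so the impulse response is exactly symmetric
    about its midpoint (type-I linear phase).
    """

    low_hz: float = 5.0
    high_hz: float = 11.0
    order: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.order % 2 != 0:
            raise ValidationError(f"filter order must be even, got {self.order}")


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the linear-phase band-pass; returns ``order + 1`` coefficients.

    The response is scaled to unit gain at the band center (firwin's passband
    scaling), so theta amplitudes pass unchanged.
    """
    if spec.high_hz >= fs / 2:
        raise ValidationError(
            f"high edge {spec.high_hz} Hz must be below Nyquist {fs / 2} Hz"
        )
    return sps.firwin(
        spec.order + 1,
        [spec.low_hz, spec.high_hz],
        pass_zero=False,
        window="hamming",
        fs=fs,
    )


def filter_zero_phase(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Apply the FIR forward and backward (zero net group delay).

    Edges are reflect-padded by the filter length before the two passes, which
    suppresses onset transients in 1-s analysis windows adjacent to segment
    boundaries.  Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    n_taps = len(coeffs)
    if x.shape[-1] <= 3 * n_taps:
        raise ValidationError(
            f"signal length {x.shape[-1]} too short for {n_taps}-tap zero-phase "
            f"filtering (need > {3 * n_taps} samples)"
        )
    return sps.filtfilt(coeffs, [1.0], x, axis=-1, padtype="even", padlen=n_taps)
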