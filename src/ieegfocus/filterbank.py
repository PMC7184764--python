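"""High-frequency Butterworth filter bank.

The analysis band 100-600 Hz (ripple 100-250 Hz, fast ripple 250-600 Hz)
is split into N contiguous subbands of equal width (default 50 Hz, so
N = 10) and each segment is band-passed with a 3rd-order Butterworth
design per subband.  Filters are applied forward-backward by default
(zero phase), so subband signals stay time-aligned across bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["BandDefinition", "make_filterbank", "bandpass", "decompose"]

DEFAULT_LOW = 100.0
DEFAULT_HIGH = 600.0
DEFAULT_WIDTH = 50.0
DEFAULT_ORDER = 3


@dataclass(frozen=True)
class BandDefinition:
    """One subband: [low_edge, high_edge) Hz, Butterworth order, 1-based index."""

    low_edge: float
    high_edge: float
    order: int
    index: int

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-sections bandpass design for sampling rate ``fs``."""
        if self.high_edge >= fs / 2:
            raise ValueError(
                f"band {self.low_edge}-{self.high_edge} Hz exceeds Nyquist ({fs / 2} Hz)"
            )
        return signal.butter(
            self.order, [self.low_edge, self.high_edge], btype="bandpass",
            fs=fs, output="sos",
        )


def make_filterbank(
    global_low: float = DEFAULT_LOW,
    global_high: float = DEFAULT_HIGH,
    width: float = DEFAULT_WIDTH,
    order: int = DEFAULT_ORDER,
) -> list[BandDefinition]:
    """Build the ordered list of contiguous subbands covering the range.

    ``(global_high - global_low)`` must be an integer multiple of
    ``width``; the default 100-600 Hz range at 50 Hz width yields the
    ten subbands 100-150, 150-200, ..., 550-600 Hz.
    """
    if global_low <= 0 or global_high <= global_low:
        raise ValueError("need 0 < global_low < global_high")
    span = global_high - global_low
    n = span / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"range {global_low}-{global_high} Hz is not divisible into "
            f"{width}-Hz subbands"
        )
    n = int(round(n))
    return [
        BandDefinition(
            low_edge=global_low + i * width,
            high_edge=global_low + (i + 1) * width,
            order=order,
            index=i + 1,
        )
        for i in range(n)
    ]


def _min_length(sos: np.ndarray) -> int:
    # sosfiltfilt needs > 3 * (number of section taps) samples to pad
    return 3 * (2 * sos.shape[0] + 1) + 1


def bandpass(
    x: np.ndarray,
    low: float,
    high: float,
    fs: float,
    order: int = DEFAULT_ORDER,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth bandpass of a 1-D signal (global 100-600 Hz pre-filter)."""
    band = BandDefinition(low, high, order, 0)
    sos = band.sos(fs)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < _min_length(sos):
        raise ValueError(
            f"signal of length {x.shape[-1]} too short for stable filtering"
        )
    return signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)


def decompose(
    x: np.ndarray,
    bands: list[BandDefinition],
    fs: float,
    zero_phase: bool = True,
) -> np.ndarray:
    """Filter a segment through every subband.

    Returns an array of shape ``(len(bands), L)``; row ``n`` is the
    segment filtered to band ``bands[n]``.  Decomposition is linear in
    the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("decompose expects a 1-D segment")
    out = np.empty((len(bands), x.shape[0]))
    for i, band in enumerate(bands):
        sos = band.sos(fs)
        if x.shape[0] < _min_length(sos):
            raise ValueError(
                f"segment length {x.shape[0]} too short for band "
                f"{band.low_edge}-{band.high_edge} Hz"
            )
        out[i] = signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)
    return out
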