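"""Signal conditioning applied to each ROI channel before the FFT.

The chain is fixed: (1) shift the segment so its minimum is zero, (2)
smooth with a 10-point moving average, (3) taper with a symmetric Hanning
window so the segment can be treated as one period without edge
discontinuities.  Order is recorded in the output's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from larcfft.errors import ParameterError
from larcfft.roi import ROISegment

SMOOTH_WINDOW = 10


@dataclass
class ConditionedSegment:
    """A conditioned ROI channel, same length as its source."""

    source: ROISegment
    values: np.ndarray
    steps_applied: list[str] = field(default_factory=list)

    @property
    def sample_rate(self) -> float:
        return self.source.sample_rate

    @property
    def channel_name(self) -> str:
        return self.source.channel_name


def shift_to_min(values: np.ndarray) -> np.ndarray:
    """Subtract the minimum so the segment's floor sits at zero."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot shift an empty series")
    return values - values.min()


def moving_average(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges.

    For the even default window of 10 points the mask cannot be exactly
    symmetric; interior sample ``i`` averages indices ``i-4 .. i+5`` (a
    half-sample group delay, negligible against the ~0.3 cycles/min bin
    width).  Edge samples average whatever part of the mask is in range, so
    output length equals input length.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > n:
        raise ParameterError(f"window {window} exceeds series length {n}")
    left = (window - 1) // 2  # 4 for window=10
    right = window - left  # 5 (slice end is exclusive: i+5 included)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.maximum(np.arange(n) - left, 0)
    hi = np.minimum(np.arange(n) + right, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def hann_window(values: np.ndarray) -> np.ndarray:
    """Apply the symmetric Hanning taper 0.5*(1 - cos(2*pi*n/(N-1))).

    Endpoints are exactly zero, which removes the wrap-around discontinuity
    when the DFT treats the segment as periodic.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("Hanning window needs at least 2 samples")
    return values * np.hanning(values.size)


def condition(
    seg: ROISegment, smooth_window: int = SMOOTH_WINDOW
) -> ConditionedSegment:
    """Run the full shift -> smooth -> window chain on one ROI channel."""
    v = shift_to_min(seg.values)
    v = moving_average(v, window=smooth_window)
    v = hann_window(v)
    return ConditionedSegment(
        source=seg, values=v, steps_applied=["shift", "smooth", "window"]
    )
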