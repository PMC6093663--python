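"""Region-of-interest extraction relative to void onset.

The analysis window is a fixed run of 2048 samples (204.8 s at 10 Hz)
ending 0, 30, or 60 seconds before the onset of voiding.  The power-of-two
length fixes the FFT bin width at 600/2048 ~ 0.293 cycles/min for every
study, which keeps the spectral thresholds comparable across patients.
Studies without a void anchor the window to the end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from larcfft.errors import EligibilityError
from larcfft.io_uds import UDSRecording

ROI_SAMPLES = 2048
CANONICAL_OFFSETS_S = (0.0, 30.0, 60.0)


@dataclass
class ROISegment:
    """A fixed-length single-channel excerpt tied to its void-relative position."""

    channel_name: str
    values: np.ndarray
    start_time: float
    end_offset_s: float
    void_onset_time: float | None
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s


def detect_void_onset(
    rec: UDSRecording, volume_threshold: float = 1.0
) -> float | None:
    """Time at which voided volume first exceeds the threshold and stays there.

    The sustained-exceedance requirement rejects isolated flowmeter jitter
    blips.  Returns ``None`` for no-void studies.
    """
    v = rec.voided_volume
    above = v > volume_threshold
    if not above.any():
        return None
    # first index from which every later sample is above threshold
    below_idx = np.nonzero(~above)[0]
    start = 0 if below_idx.size == 0 else int(below_idx[-1]) + 1
    if start >= v.size:
        return None  # exceeded only transiently, never sustained
    return float(rec.time[start])


def extract_roi(
    rec: UDSRecording,
    channel: str,
    end_offset_s: float = 30.0,
    roi_samples: int = ROI_SAMPLES,
    volume_threshold: float = 1.0,
) -> ROISegment:
    """Cut the fixed-length window ending ``end_offset_s`` before void onset.

    The window is a pure slice — never padded or interpolated.  The sample
    at the window end is excluded, so the slice covers
    ``[end - roi_samples/rate, end)``.  For no-void studies the end is
    anchored ``end_offset_s`` before the final sample.
    """
    onset = detect_void_onset(rec, volume_threshold=volume_threshold)
    anchor = onset if onset is not None else float(rec.time[-1])
    end_time = anchor - end_offset_s
    t0 = float(rec.time[0])
    end_idx = int(round((end_time - t0) * rec.sample_rate))
    start_idx = end_idx - roi_samples
    if start_idx < 0 or end_idx > rec.n_samples:
        need = roi_samples / rec.sample_rate + end_offset_s
        have = anchor - t0
        raise EligibilityError(
            f"{rec.study_id!r}: window needs {need:.1f} s before the "
            f"{'void' if onset is not None else 'recording end'}, "
            f"only {have:.1f} s available"
        )
    return ROISegment(
        channel_name=channel,
        values=rec.channel(channel)[start_idx:end_idx].copy(),
        start_time=float(rec.time[start_idx]),
        end_offset_s=float(end_offset_s),
        void_onset_time=onset,
        sample_rate=rec.sample_rate,
    )
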