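"""Peak significance and independence testing — the study classifier.

Within the 1.75-6 cycles/min band the three largest local maxima of the
vesical spectrum are evaluated.  A peak is *significant* when its
normalized amplitude exceeds 0.45 (1.8 cm-H2O in model peak-to-peak
units) and it is prominent on both sides: on each side, at least one of
the two nearest neighbors must fall on or below a line descending from
the peak at 20% of the peak amplitude per frequency step.  A significant
peak is *independent* of the abdominal channel when the vesical amplitude
exceeds 1.5x the abdominal amplitude at that bin and both its nearest
neighbors while the abdominal bin is below 133% of its neighbors' maximum
(no sharp abdominal peak), or — regardless of abdominal peak shape — when
the vesical amplitude exceeds 2x all three abdominal values.

A study is classified significant-and-independent (S&I) if any of its top
three vesical peaks passes both tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from larcfft.errors import DataError
from larcfft.io_uds import UDSRecording, validate_for_analysis
from larcfft.preprocess import condition
from larcfft.roi import CANONICAL_OFFSETS_S, ROI_SAMPLES, extract_roi
from larcfft.spectrum import AmplitudeSpectrum, SineModel, amplitude_spectrum, band_bins, sine_model

NO_SIGNIFICANT = "no_significant"
SIGNIFICANT_NOT_INDEPENDENT = "significant_not_independent"
SIGNIFICANT_AND_INDEPENDENT = "significant_and_independent"


@dataclass(frozen=True)
class DetectionConfig:
    """All pipeline thresholds; the defaults are the canonical configuration."""

    band_lo_cpm: float = 1.75
    band_hi_cpm: float = 6.0
    amp_threshold: float = 0.45  # normalized spectrum units (= 1.8 cm-H2O p2p)
    slope_fraction: float = 0.20  # prominence grade per frequency step
    ratio1: float = 1.5  # vesical vs abdominal floor (with flatness rule)
    flatness: float = 1.33  # abdominal peak-shape ceiling
    ratio2: float = 2.0  # unconditional vesical dominance
    n_peaks: int = 3
    roi_samples: int = ROI_SAMPLES
    offsets_s: tuple[float, ...] = CANONICAL_OFFSETS_S
    smooth_window: int = 10
    void_threshold_ml: float = 1.0
    min_fill_s: float = 420.0


@dataclass
class PeakEvaluation:
    """One candidate vesical peak with neighbor context and rule outcomes.

    ``neighbors_left``/``neighbors_right`` hold the vesical amplitudes two
    and one bins away (and one and two bins away); ``pabd_neighbors`` are
    the abdominal amplitudes one bin to each side.  ``None`` marks a
    neighbor that falls outside the spectrum.
    """

    rank: int
    bin: int
    frequency: float
    pves_amplitude: float
    neighbors_left: tuple[float | None, float | None] = (None, None)
    neighbors_right: tuple[float | None, float | None] = (None, None)
    pabd_at_bin: float | None = None
    pabd_neighbors: tuple[float | None, float | None] = (None, None)
    significant: bool = False
    independent: bool = False
    criterion_detail: dict = field(default_factory=dict)


@dataclass
class LARCResult:
    """Classification of one study at one ROI offset."""

    study_id: str
    roi_offset_s: float
    category: str
    peaks: list[PeakEvaluation]
    slowest_si_frequency: float | None = None
    slowest_si_model: SineModel | None = None

    @property
    def is_si(self) -> bool:
        return self.category == SIGNIFICANT_AND_INDEPENDENT


@dataclass
class RecordingAnalysis:
    """Per-offset results for one recording plus the any-offset S&I flag."""

    study_id: str
    results: dict[float, LARCResult]
    any_si: bool


def _amp(spec: AmplitudeSpectrum, k: int) -> float | None:
    """Amplitude at bin ``k``, or None outside the spectrum (bin 0 = DC excluded)."""
    if 1 <= k < spec.n_bins:
        return float(spec.amplitudes[k])
    return None


def find_top_peaks(
    spec: AmplitudeSpectrum,
    band: Sequence[int],
    n: int = 3,
) -> list[PeakEvaluation]:
    """Up to ``n`` largest in-band local maxima, descending amplitude.

    A bin is a local maximum when its amplitude strictly exceeds the
    nearest distinct value on each side; a plateau of equal bins counts
    once, at its lowest-frequency bin.  Bins at the edge of the *spectrum*
    compare only against their available neighbor.  Ties in amplitude rank
    the lower frequency first.
    """
    a = spec.amplitudes
    band = np.asarray(band, dtype=int)
    peaks: list[PeakEvaluation] = []
    for k in band:
        # a plateau of equal bins is attributed to its lowest-frequency bin
        if k - 1 >= 1 and a[k - 1] == a[k]:
            continue
        # nearest distinct value on the left (DC bin excluded)
        if k - 1 >= 1 and a[k - 1] > a[k]:
            continue
        # nearest distinct value on the right, skipping the plateau
        j = k + 1
        while j < a.size and a[j] == a[k]:
            j += 1
        if j < a.size and a[j] >= a[k]:
            continue
        peaks.append(
            PeakEvaluation(
                rank=0,
                bin=int(k),
                frequency=float(spec.frequencies[k]),
                pves_amplitude=float(a[k]),
                neighbors_left=(_amp(spec, k - 2), _amp(spec, k - 1)),
                neighbors_right=(_amp(spec, k + 1), _amp(spec, k + 2)),
            )
        )
    peaks.sort(key=lambda p: (-p.pves_amplitude, p.frequency))
    peaks = peaks[:n]
    for rank, p in enumerate(peaks, start=1):
        p.rank = rank
    return peaks


def test_significance(
    peak: PeakEvaluation,
    amp_threshold: float = 0.45,
    slope_fraction: float = 0.20,
) -> PeakEvaluation:
    """Apply the amplitude floor and two-sided prominence (slope) criterion.

    A neighbor at distance ``d`` is "in region" when its amplitude is at or
    below ``peak * (1 - slope_fraction * d)``; each side passes if either
    of its two neighbors is in region.  A side with no in-spectrum
    neighbors fails and the reason is recorded.
    """
    a = peak.pves_amplitude
    amp_ok = a > amp_threshold

    def side_ok(neigh: tuple[float | None, float | None], dists: tuple[int, int]) -> tuple[bool, str]:
        available = [(v, d) for v, d in zip(neigh, dists) if v is not None]
        if not available:
            return False, "no in-spectrum neighbors on this side"
        ok = any(v <= a * (1.0 - slope_fraction * d) for v, d in available)
        return ok, ""

    left_ok, left_reason = side_ok(peak.neighbors_left, (2, 1))
    right_ok, right_reason = side_ok(peak.neighbors_right, (1, 2))
    peak.significant = bool(amp_ok and left_ok and right_ok)
    peak.criterion_detail["significance"] = {
        "amplitude": bool(amp_ok),
        "amp_threshold": amp_threshold,
        "left_prominence": bool(left_ok),
        "right_prominence": bool(right_ok),
        **({"left_reason": left_reason} if left_reason else {}),
        **({"right_reason": right_reason} if right_reason else {}),
    }
    return peak


def test_independence(
    peak: PeakEvaluation,
    pabd_spec: AmplitudeSpectrum,
    ratio1: float = 1.5,
    flatness: float = 1.33,
    ratio2: float = 2.0,
) -> PeakEvaluation:
    """Compare a significant vesical peak against the abdominal spectrum.

    With ``a`` the vesical amplitude, ``b0`` the abdominal amplitude at the
    same bin and ``bL, bR`` its nearest neighbors (points Q, R):

    * rule A: ``a > ratio1 * max(b0, bL, bR)``
    * rule B: ``b0 < flatness * max(bL, bR)`` (no sharp abdominal peak)
    * rule C: ``a > ratio2 * max(b0, bL, bR)`` (dominance regardless of
      abdominal peak shape)

    independent = (A and B) or C.
    """
    if not peak.significant:
        raise DataError("independence is only tested on significant peaks")
    k = peak.bin
    b0 = _amp(pabd_spec, k)
    bl = _amp(pabd_spec, k - 1)
    br = _amp(pabd_spec, k + 1)
    peak.pabd_at_bin = b0
    peak.pabd_neighbors = (bl, br)
    a = peak.pves_amplitude
    present = [v for v in (b0, bl, br) if v is not None]
    bmax = max(present) if present else 0.0
    rule_a = a > ratio1 * bmax
    nmax = max((v for v in (bl, br) if v is not None), default=0.0)
    rule_b = (b0 if b0 is not None else 0.0) < flatness * nmax
    rule_c = a > ratio2 * bmax
    peak.independent = bool((rule_a and rule_b) or rule_c)
    peak.criterion_detail["independence"] = {
        "rule_a_ratio": bool(rule_a),
        "rule_b_flatness": bool(rule_b),
        "rule_c_dominance": bool(rule_c),
    }
    return peak


def classify_study(
    pves_spec: AmplitudeSpectrum,
    pabd_spec: AmplitudeSpectrum,
    config: DetectionConfig = DetectionConfig(),
    study_id: str = "",
    roi_offset_s: float = 30.0,
) -> LARCResult:
    """Run peak finding, significance, and independence; assign the category."""
    band = band_bins(pves_spec, config.band_lo_cpm, config.band_hi_cpm)
    peaks = find_top_peaks(pves_spec, band, n=config.n_peaks)
    for p in peaks:
        test_significance(p, config.amp_threshold, config.slope_fraction)
        if p.significant:
            test_independence(p, pabd_spec, config.ratio1, config.flatness, config.ratio2)
    si_peaks = [p for p in peaks if p.independent]
    if si_peaks:
        category = SIGNIFICANT_AND_INDEPENDENT
        slowest = min(si_peaks, key=lambda p: p.frequency)
        freq = slowest.frequency
        model = sine_model(slowest.frequency, slowest.pves_amplitude)
    else:
        category = (
            SIGNIFICANT_NOT_INDEPENDENT
            if any(p.significant for p in peaks)
            else NO_SIGNIFICANT
        )
        freq = None
        model = None
    return LARCResult(
        study_id=study_id,
        roi_offset_s=roi_offset_s,
        category=category,
        peaks=peaks,
        slowest_si_frequency=freq,
        slowest_si_model=model,
    )


def analyze_recording(
    rec: UDSRecording,
    config: DetectionConfig = DetectionConfig(),
    offsets: Sequence[float] | None = None,
) -> RecordingAnalysis:
    """Classify one eligible recording at every requested ROI offset."""
    report = validate_for_analysis(
        rec, min_fill_s=config.min_fill_s, volume_threshold_ml=config.void_threshold_ml
    )
    if not report.eligible:
        raise DataError(
            f"{rec.study_id!r} ineligible: " + "; ".join(report.reasons)
        )
    offsets = tuple(offsets) if offsets is not None else config.offsets_s
    results: dict[float, LARCResult] = {}
    for off in offsets:
        specs = {}
        for ch in ("p_ves", "p_abd"):
            seg = extract_roi(
                rec,
                ch,
                end_offset_s=off,
                roi_samples=config.roi_samples,
                volume_threshold=config.void_threshold_ml,
            )
            specs[ch] = amplitude_spectrum(condition(seg, config.smooth_window))
        results[off] = classify_study(
            specs["p_ves"], specs["p_abd"], config, rec.study_id, off
        )
    return RecordingAnalysis(
        study_id=rec.study_id,
        results=results,
        any_si=any(r.is_si for r in results.values()),
    )
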