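"""Normalized single-sided amplitude spectra and the sine LARC model.

The spectrum convention is ``2*|X_k|/N`` with no compensation for the
Hanning window's coherent gain of 1/2.  A windowed sine of amplitude A
therefore shows ~A/2 at its bin, and the physical peak-to-peak amplitude
of a detected rhythm is 4x the spectrum value: one factor of 2 undoes the
window gain, the other converts amplitude to peak-to-peak.  All detection
thresholds are stated in these normalized units (0.45 normalized units =
1.8 cm-H2O model peak-to-peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from larcfft.errors import ParameterError
from larcfft.preprocess import ConditionedSegment

BAND_LO_CPM = 1.75
BAND_HI_CPM = 6.0

#: peak-to-peak pressure per normalized spectrum unit
PEAK_TO_PEAK_FACTOR = 4.0


@dataclass
class AmplitudeSpectrum:
    """Single-sided amplitude spectrum of one conditioned ROI channel.

    ``amplitudes[k]`` holds bin ``k`` for ``k = 0 .. N/2``; bin 0 (DC) is
    normalized ``|X_0|/N`` and excluded from every band query.  Frequencies
    are in cycles/min: ``f_k = k * sample_rate * 60 / n_samples``.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    n_samples: int
    sample_rate: float
    channel_name: str

    @property
    def bin_width_cpm(self) -> float:
        return self.sample_rate * 60.0 / self.n_samples

    @property
    def n_bins(self) -> int:
        return int(self.amplitudes.size)

    def to_tsv(self, path: str | Path) -> None:
        """Export as two-column TSV (cycles/min, normalized amplitude)."""
        arr = np.column_stack([self.frequencies, self.amplitudes])
        header = "frequency_cpm\tamplitude"
        np.savetxt(path, arr, fmt="%.10g", delimiter="\t", header=header, comments="")


@dataclass
class SineModel:
    """Ideal sine reconstruction of a detected rhythm.

    ``peak_to_peak`` (cm-H2O) is exactly 4x the normalized spectrum
    amplitude at the peak bin.
    """

    frequency: float  # cycles/min
    peak_to_peak: float  # cm-H2O
    fft_amplitude: float  # normalized spectrum units

    def evaluate(self, t: np.ndarray, phase: float = 0.0) -> np.ndarray:
        """Sample the model sine at times ``t`` (seconds), for overlays."""
        return (self.peak_to_peak / 2.0) * np.sin(
            2.0 * np.pi * self.frequency / 60.0 * np.asarray(t, dtype=float) + phase
        )


def amplitude_spectrum(seg: ConditionedSegment) -> AmplitudeSpectrum:
    """Normalized single-sided amplitude spectrum of a conditioned segment.

    Requires a power-of-two length so the bin grid is identical across
    studies.  No window-gain correction is applied (see module docstring).
    """
    v = np.asarray(seg.values, dtype=float)
    n = v.size
    if n < 2 or n & (n - 1):
        raise ParameterError(f"segment length {n} is not a power of two")
    x = np.fft.rfft(v)
    amps = 2.0 * np.abs(x) / n
    amps[0] = np.abs(x[0]) / n  # DC is not doubled
    k = np.arange(amps.size)
    freqs = k * seg.sample_rate * 60.0 / n
    return AmplitudeSpectrum(
        frequencies=freqs,
        amplitudes=amps,
        n_samples=n,
        sample_rate=seg.sample_rate,
        channel_name=seg.channel_name,
    )


def band_bins(
    spec: AmplitudeSpectrum,
    lo: float = BAND_LO_CPM,
    hi: float = BAND_HI_CPM,
) -> np.ndarray:
    """Indices of bins whose frequency lies in ``[lo, hi]`` (inclusive), bin 0 excluded."""
    if not lo < hi:
        raise ParameterError(f"band lo {lo} must be < hi {hi}")
    k = np.nonzero((spec.frequencies >= lo) & (spec.frequencies <= hi))[0]
    k = k[k > 0]
    if k.size == 0:
        raise ParameterError(
            f"band {lo}-{hi} cycles/min contains no bins at spacing "
            f"{spec.bin_width_cpm:.4f}"
        )
    return k


def sine_model(frequency: float, fft_amplitude: float) -> SineModel:
    """Build the ideal-sine model for a detected peak.

    Peak-to-peak = 4 x normalized amplitude: a factor of 2 for the Hanning
    window's coherent gain and a factor of 2 from amplitude to peak-to-peak.
    """
    if frequency <= 0 or fft_amplitude <= 0:
        raise ParameterError("frequency and fft_amplitude must be positive")
    return SineModel(
        frequency=float(frequency),
        peak_to_peak=PEAK_TO_PEAK_FACTOR * float(fft_amplitude),
        fft_amplitude=float(fft_amplitude),
    )
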