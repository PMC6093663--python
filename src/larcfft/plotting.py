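"""Diagnostic plot bundle: pressure tracings, sine overlay, paired spectra."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from larcfft.io_uds import UDSRecording
from larcfft.larc_detect import DetectionConfig, LARCResult
from larcfft.preprocess import condition
from larcfft.roi import extract_roi
from larcfft.spectrum import amplitude_spectrum


def plot_study(
    rec: UDSRecording,
    result: LARCResult,
    out_path: str | Path,
    config: DetectionConfig = DetectionConfig(),
) -> Path:
    """Save a three-panel figure for one study at one ROI offset.

    Top: full-fill vesical/abdominal tracings with the ROI shaded.
    Middle: ROI tracing with the fitted sine model overlaid (S&I only).
    Bottom: vesical and abdominal amplitude spectra with the analysis band.
    """
    off = result.roi_offset_s
    segs = {
        ch: extract_roi(rec, ch, end_offset_s=off, roi_samples=config.roi_samples,
                        volume_threshold=config.void_threshold_ml)
        for ch in ("p_ves", "p_abd")
    }
    specs = {ch: amplitude_spectrum(condition(s, config.smooth_window))
             for ch, s in segs.items()}

    fig, axes = plt.subplots(3, 1, figsize=(9, 10))
    ax = axes[0]
    ax.plot(rec.time, rec.p_ves, lw=0.6, label="P_ves")
    ax.plot(rec.time, rec.p_abd, lw=0.6, label="P_abd")
    ax.axvspan(segs["p_ves"].start_time, segs["p_ves"].end_time, alpha=0.2,
               color="green", label="ROI")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (cm-H2O)")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(f"{rec.study_id} — offset {off:g} s — {result.category}")

    ax = axes[1]
    seg = segs["p_ves"]
    t = seg.start_time + np.arange(seg.n_samples) / seg.sample_rate
    ax.plot(t, seg.values, lw=0.6, label="P_ves (ROI)")
    if result.slowest_si_model is not None:
        m = result.slowest_si_model
        ax.plot(t, np.median(seg.values) + m.evaluate(t - seg.start_time), "--",
                label=f"sine model {m.frequency:.2f} cpm, p2p {m.peak_to_peak:.1f}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (cm-H2O)")
    ax.legend(loc="upper left", fontsize=8)

    ax = axes[2]
    for ch, spec in specs.items():
        ax.plot(spec.frequencies, spec.amplitudes, marker=".", lw=0.8, label=ch)
    ax.axvspan(config.band_lo_cpm, config.band_hi_cpm, alpha=0.15, color="gray")
    for p in result.peaks:
        ax.annotate("S&I" if p.independent else ("S" if p.significant else ""),
                    (p.frequency, p.pves_amplitude), fontsize=8)
    ax.set_xlim(0, 12)
    ax.set_xlabel("frequency (cycles/min)")
    ax.set_ylabel("normalized amplitude")
    ax.legend(fontsize=8)

    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
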