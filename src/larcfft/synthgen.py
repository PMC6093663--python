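"""Synthetic multichannel UDS recordings with known ground truth.

The generator emulates the signal classes a filling-phase urodynamic
trace contains: slowly drifting baseline pressures, broadband sensor
noise, an optional sinusoidal low-amplitude rhythm in the 1.75-6
cycles/min band (vesical only, or translated into both channels),
respiration-band oscillation, transient abdominal events that either do
(cough, Valsalva) or do not (rectal contraction) translate into the
vesical channel, and a terminal void visible in the voided-volume
channel.  Every recording is deterministic under its seed and ships with
a ground-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from larcfft.errors import ParameterError
from larcfft.io_uds import UDSRecording, write_uds_export

SAMPLE_RATE_HZ = 10.0

#: event type -> (translated into P_ves?, default duration s)
_EVENT_KINDS = {
    "cough": (True, 1.5),
    "valsalva": (True, 8.0),
    "rectal_contraction": (False, 20.0),
}


@dataclass
class LarcSpec:
    """An injected rhythmic contraction: pure sine, half-p2p amplitude."""

    frequency_cpm: float = 3.0
    peak_to_peak: float = 10.0  # cm-H2O
    start_s: float = 0.0
    stop_s: float | None = None  # None = through the void onset
    channel: str = "vesical"  # "vesical" or "both"


@dataclass
class RespirationSpec:
    """Respiratory oscillation, above the analysis band (>= 10 cycles/min)."""

    frequency_cpm: float = 15.0
    amplitude: float = 1.0  # cm-H2O


@dataclass
class EventSpec:
    """A transient: cough/valsalva hit both channels, rectal only abdominal."""

    type: str = "cough"
    time_s: float = 100.0
    amplitude: float = 40.0  # cm-H2O
    duration_s: float | None = None


@dataclass
class VoidSpec:
    """Terminal void: smooth voided-volume ramp plus a voiding contraction."""

    onset_s: float = 520.0
    voided_ml: float = 300.0
    flow_delay_s: float = 0.0
    ramp_s: float = 30.0


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic recording.

    Defaults emulate a typical adult cystometry fill: ~600 s at a 42
    ml/min pump rate, resting vesical/abdominal baselines around 10/8
    cm-H2O, a small compliance-related vesical rise per 100 ml infused,
    and ~1 cm-H2O sensor noise.
    """

    duration_s: float = 600.0
    fill_rate_ml_min: float = 42.0
    baseline_pves: float = 10.0
    baseline_pabd: float = 8.0
    compliance_drift: float = 2.0  # cm-H2O per 100 ml infused
    noise_sd: float = 1.0
    larc: LarcSpec | None = None
    respiration: RespirationSpec | None = None
    events: list[EventSpec] = field(default_factory=list)
    void: VoidSpec | None = field(default_factory=VoidSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.respiration is not None and self.respiration.frequency_cpm < 10.0:
            raise ParameterError("respiration frequency must be >= 10 cycles/min")
        for ev in self.events:
            if ev.type not in _EVENT_KINDS:
                raise ParameterError(f"unknown event type {ev.type!r}")
            if not 0.0 <= ev.time_s <= self.duration_s:
                raise ParameterError(f"event at {ev.time_s} s outside recording")
        if self.void is not None and self.void.onset_s > self.duration_s:
            raise ParameterError("void onset outside recording")


def _raised_cosine(t: np.ndarray, center: float, duration: float) -> np.ndarray:
    """Unit-height smooth bump supported on [center-d/2, center+d/2]."""
    x = (t - center) / duration
    out = np.zeros_like(t)
    mask = np.abs(x) <= 0.5
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[mask]))
    return out


def generate_recording(
    spec: SyntheticSpec, study_id: str = "synthetic"
) -> tuple[UDSRecording, dict]:
    """Build one deterministic recording and its ground-truth sidecar."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * SAMPLE_RATE_HZ))
    t = np.arange(n) / SAMPLE_RATE_HZ

    onset = spec.void.onset_s if spec.void is not None else None
    fill_end = onset if onset is not None else spec.duration_s
    infused = spec.fill_rate_ml_min / 60.0 * np.minimum(t, fill_end)

    p_ves = spec.baseline_pves + spec.compliance_drift * infused / 100.0
    p_abd = np.full(n, spec.baseline_pabd)

    if spec.larc is not None:
        stop = spec.larc.stop_s if spec.larc.stop_s is not None else fill_end
        active = (t >= spec.larc.start_s) & (t < stop)
        sine = (spec.larc.peak_to_peak / 2.0) * np.sin(
            2.0 * np.pi * spec.larc.frequency_cpm / 60.0 * t
        )
        p_ves = p_ves + np.where(active, sine, 0.0)
        if spec.larc.channel == "both":
            p_abd = p_abd + np.where(active, sine, 0.0)
        elif spec.larc.channel != "vesical":
            raise ParameterError(f"unknown larc channel {spec.larc.channel!r}")

    if spec.respiration is not None:
        resp = spec.respiration.amplitude * np.sin(
            2.0 * np.pi * spec.respiration.frequency_cpm / 60.0 * t
        )
        p_ves = p_ves + resp
        p_abd = p_abd + resp

    for ev in spec.events:
        translated, default_dur = _EVENT_KINDS[ev.type]
        dur = ev.duration_s if ev.duration_s is not None else default_dur
        bump = ev.amplitude * _raised_cosine(t, ev.time_s, dur)
        p_abd = p_abd + bump
        if translated:
            p_ves = p_ves + bump

    voided = np.zeros(n)
    flow = np.zeros(n)
    if spec.void is not None:
        v = spec.void
        ramp_start = v.onset_s + v.flow_delay_s
        x = np.clip((t - ramp_start) / v.ramp_s, 0.0, 1.0)
        voided = v.voided_ml * 0.5 * (1.0 - np.cos(np.pi * x))
        flow = np.gradient(voided, t)
        # voiding contraction: smooth vesical pressure rise through the void
        p_ves = p_ves + 40.0 * 0.5 * (1.0 - np.cos(np.pi * np.clip(
            (t - v.onset_s) / v.ramp_s, 0.0, 1.0
        ))) * (t >= v.onset_s)

    if spec.noise_sd > 0:
        p_ves = p_ves + rng.normal(0.0, spec.noise_sd, n)
        p_abd = p_abd + rng.normal(0.0, spec.noise_sd, n)

    rec = UDSRecording(
        study_id=study_id,
        sample_rate=SAMPLE_RATE_HZ,
        time=t,
        p_ves=p_ves,
        p_abd=p_abd,
        p_det=p_ves - p_abd,
        infused_volume=infused,
        voided_volume=voided,
        flow=flow,
    )
    truth = {
        "study_id": study_id,
        "spec": _spec_to_dict(spec),
        "void_onset_s": onset,
        "larc_frequency_cpm": spec.larc.frequency_cpm if spec.larc else None,
        "larc_peak_to_peak": spec.larc.peak_to_peak if spec.larc else None,
        "larc_channel": spec.larc.channel if spec.larc else None,
    }
    return rec, truth


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)


# ---------------------------------------------------------------------------
# cohorts


#: ground-truth category -> generator scenario
COHORT_CATEGORIES = ("si", "translated", "none")


def generate_cohort(
    n: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    do_sporadic_fraction: float = 0.0,
    noise_sd: float = 1.0,
    freq_range_cpm: tuple[float, float] = (2.0, 5.5),
    p2p_range: tuple[float, float] = (8.0, 14.0),
) -> tuple[list[tuple[UDSRecording, dict]], pd.DataFrame]:
    """Generate a reproducible cohort with a stated DO-label rule.

    ``mix`` gives the proportion of studies per ground-truth scenario:
    ``"si"`` (vesical-only rhythm), ``"translated"`` (the same rhythm in
    both channels), ``"none"`` (no rhythm).  The DO label rule, recorded in
    each sidecar: every rhythm-bearing study is labelled DO, plus a
    ``do_sporadic_fraction`` of the rhythm-free studies (sporadic detrusor
    contractions the spectral detector is blind to) — so cohorts with
    sensitivity < 1 and specificity = 1 are constructible.
    """
    if n <= 0:
        raise ParameterError("cohort size must be positive")
    mix = mix or {"si": 0.3, "translated": 0.2, "none": 0.5}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ParameterError("mix proportions must sum to 1")
    if any(k not in COHORT_CATEGORIES for k in mix):
        raise ParameterError(f"mix keys must be among {COHORT_CATEGORIES}")

    counts = {k: int(round(v * n)) for k, v in mix.items()}
    # rounding drift absorbed by the largest class
    drift = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    rng = np.random.default_rng(seed)
    studies: list[tuple[UDSRecording, dict]] = []
    rows = []
    i = 0
    for cat in COHORT_CATEGORIES:
        for _ in range(counts.get(cat, 0)):
            study_seed = int(rng.integers(0, 2**31 - 1))
            larc = None
            if cat in ("si", "translated"):
                larc = LarcSpec(
                    frequency_cpm=float(rng.uniform(*freq_range_cpm)),
                    peak_to_peak=float(rng.uniform(*p2p_range)),
                    channel="vesical" if cat == "si" else "both",
                )
            do = cat in ("si", "translated") or (
                cat == "none" and rng.random() < do_sporadic_fraction
            )
            spec = SyntheticSpec(noise_sd=noise_sd, larc=larc, seed=study_seed)
            sid = f"synth{i:03d}"
            rec, truth = generate_recording(spec, study_id=sid)
            truth["category"] = cat
            truth["do_label"] = "yes" if do else "no"
            truth["do_rule"] = (
                "all rhythm-bearing studies labelled DO, plus a "
                f"{do_sporadic_fraction:g} fraction of rhythm-free studies"
            )
            rec.do_label = "yes" if do else "no"
            studies.append((rec, truth))
            rows.append({"study_id": sid, "do_label": truth["do_label"], "category": cat})
            i += 1
    return studies, pd.DataFrame(rows)


def write_study(rec: UDSRecording, truth: dict, out_dir: str | Path) -> Path:
    """Write the canonical TSV plus its JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{rec.study_id}.tsv"
    write_uds_export(rec, tsv)
    (out_dir / f"{rec.study_id}.truth.json").write_text(
        json.dumps(truth, indent=2, default=float) + "\n"
    )
    return tsv
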