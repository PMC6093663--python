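"""Reading, validation, and resampling of multichannel urodynamics exports.

A urodynamic study (UDS) export is a delimited text table with one row per
sample and one column per channel.  The canonical dialect written and read
by this package is tab-delimited with a single header row and a ``time``
column in seconds; a column-mapping config adapts other dialects.  All
analysis assumes (or resamples to) a uniform 10 Hz grid, the rate the
fixed 2048-sample analysis window is defined at.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from larcfft.errors import DataError, FormatError

TARGET_RATE_HZ = 10.0

#: internal channel name -> required?
CHANNELS = {
    "p_ves": True,
    "p_abd": True,
    "voided_volume": True,
    "p_det": False,
    "infused_volume": False,
    "flow": False,
}

_OPTIONAL = [c for c, req in CHANNELS.items() if not req]


@dataclass
class UDSRecording:
    """One uniformly sampled multichannel urodynamic study.

    Pressures are in cm-H2O, volumes in ml, flow in ml/s, time in seconds.
    ``do_label`` is the clinician detrusor-overactivity call ("yes", "no",
    or "unknown"); ``etiology_label`` is "neurogenic", "idiopathic", or
    "unknown".  Optional channels are ``None`` when absent.
    """

    study_id: str
    sample_rate: float
    time: np.ndarray
    p_ves: np.ndarray
    p_abd: np.ndarray
    voided_volume: np.ndarray
    p_det: np.ndarray | None = None
    infused_volume: np.ndarray | None = None
    flow: np.ndarray | None = None
    do_label: str = "unknown"
    etiology_label: str = "unknown"
    volume_slack_ml: float = 0.5  # tolerated sensor jitter in voided volume

    def __post_init__(self) -> None:
        for name in ("time", "p_ves", "p_abd", "voided_volume"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in _OPTIONAL:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        n = self.time.size
        if n < 1:
            raise DataError("recording is empty")
        for name, series in self.channels().items():
            if series.size != n:
                raise DataError(
                    f"channel {name!r} has {series.size} samples, expected {n}"
                )
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise DataError("time is not strictly increasing")
        dv = np.diff(self.voided_volume)
        if np.any(self.voided_volume < -self.volume_slack_ml) or np.any(
            dv < -self.volume_slack_ml
        ):
            raise DataError("voided volume decreases beyond jitter tolerance")

    # -- accessors ---------------------------------------------------------

    def channels(self) -> dict[str, np.ndarray]:
        """All present series keyed by internal name (time excluded)."""
        out = {"p_ves": self.p_ves, "p_abd": self.p_abd}
        for name in _OPTIONAL:
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        out["voided_volume"] = self.voided_volume
        return out

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name; ``p_det`` is derived if absent."""
        if name == "p_det" and self.p_det is None:
            return self.p_ves - self.p_abd
        v = getattr(self, name, None)
        if v is None:
            raise DataError(f"channel {name!r} not present in {self.study_id!r}")
        return v

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    def is_uniform(self, tol_s: float = 1e-6) -> bool:
        if self.n_samples < 2:
            return True
        dt = np.diff(self.time)
        return bool(np.max(np.abs(dt - 1.0 / self.sample_rate)) <= tol_s)


@dataclass
class EligibilityReport:
    """Outcome of pre-analysis screening for one recording."""

    study_id: str
    eligible: bool
    reasons: list[str] = field(default_factory=list)
    fill_duration_s: float = math.nan
    void_onset_time: float | None = None
    n_void_events: int = 0


# ---------------------------------------------------------------------------
# format configuration


DEFAULT_FORMAT = {
    "delimiter": "\t",
    "columns": {
        "time": "time",
        "p_ves": "p_ves",
        "p_abd": "p_abd",
        "p_det": "p_det",
        "infused_volume": "infused_volume",
        "voided_volume": "voided_volume",
        "flow": "flow",
    },
    "missing": "error",  # or "ffill"
}


def load_format_config(path: str | Path) -> dict:
    """Read a column-mapping config (YAML) and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_FORMAT, **user}
    cfg["columns"] = {**DEFAULT_FORMAT["columns"], **user.get("columns", {})}
    return cfg


def read_uds_export(
    path: str | Path,
    format_config: Mapping | None = None,
    study_id: str | None = None,
) -> UDSRecording:
    """Parse a delimited-text UDS export into a :class:`UDSRecording`.

    ``format_config`` maps internal channel names to column headers and
    sets the delimiter and missing-value policy (``"error"`` or
    ``"ffill"``).  ``time``, ``p_ves``, ``p_abd`` and ``voided_volume``
    must be mapped and present; other channels are optional.
    """
    cfg = {**DEFAULT_FORMAT, **(format_config or {})}
    cols = {**DEFAULT_FORMAT["columns"], **cfg.get("columns", {})}
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=cfg["delimiter"])
    except pd.errors.EmptyDataError:
        raise DataError(f"empty file: {path}") from None
    if df.empty:
        raise DataError(f"no data rows in {path}")

    for internal in ("time", "p_ves", "p_abd", "voided_volume"):
        header = cols.get(internal)
        if header is None or header not in df.columns:
            raise FormatError(
                f"required column {internal!r} (header {header!r}) missing in {path}"
            )

    def get(internal: str) -> np.ndarray | None:
        header = cols.get(internal)
        if header is None or header not in df.columns:
            return None
        s = pd.to_numeric(df[header], errors="coerce")
        if s.isna().any():
            if cfg.get("missing") == "ffill":
                s = s.ffill().bfill()
            else:
                raise DataError(
                    f"non-numeric or missing cells in column {header!r} of {path}"
                )
        return s.to_numpy(dtype=float)

    time = get("time")
    if time.size > 1 and not np.all(np.diff(time) > 0):
        raise DataError(f"time column not strictly increasing in {path}")
    dt = np.median(np.diff(time)) if time.size > 1 else 1.0 / TARGET_RATE_HZ
    return UDSRecording(
        study_id=study_id or path.stem,
        sample_rate=1.0 / dt,
        time=time,
        p_ves=get("p_ves"),
        p_abd=get("p_abd"),
        voided_volume=get("voided_volume"),
        p_det=get("p_det"),
        infused_volume=get("infused_volume"),
        flow=get("flow"),
    )


_FLOAT_FMT = "%.6f"


def write_uds_export(rec: UDSRecording, path: str | Path) -> None:
    """Write the canonical tab-delimited export (header row, time in s).

    Values are printed at fixed 6-decimal precision so that a
    write -> read -> write round trip is byte-stable.
    """
    order = ["time"] + list(rec.channels().keys())
    data = {"time": rec.time, **rec.channels()}
    buf = io.StringIO()
    buf.write("\t".join(order) + "\n")
    arr = np.column_stack([data[c] for c in order])
    np.savetxt(buf, arr, fmt=_FLOAT_FMT, delimiter="\t")
    Path(path).write_text(buf.getvalue())


def resample_uniform(rec: UDSRecording, target_rate: float = TARGET_RATE_HZ) -> UDSRecording:
    """Linearly interpolate every channel onto a uniform grid.

    The grid spans the original time range at ``target_rate``; the first
    sample coincides with the original start.  Already-uniform input at the
    target rate is returned unchanged (idempotence).  No anti-alias filter
    is applied: the analysis band tops out at 0.1 Hz, far below the Nyquist
    frequency of any plausible export rate.
    """
    if rec.n_samples < 2:
        raise DataError("resampling requires at least 2 samples")
    if abs(rec.sample_rate - target_rate) < 1e-9 and rec.is_uniform():
        return rec
    dt = 1.0 / target_rate
    n = int(math.floor((rec.time[-1] - rec.time[0]) / dt + 1e-9)) + 1
    grid = rec.time[0] + dt * np.arange(n)

    def interp(v: np.ndarray | None) -> np.ndarray | None:
        return None if v is None else np.interp(grid, rec.time, v)

    return replace(
        rec,
        sample_rate=target_rate,
        time=grid,
        p_ves=interp(rec.p_ves),
        p_abd=interp(rec.p_abd),
        voided_volume=interp(rec.voided_volume),
        p_det=interp(rec.p_det),
        infused_volume=interp(rec.infused_volume),
        flow=interp(rec.flow),
    )


# ---------------------------------------------------------------------------
# eligibility screening


def count_void_events(
    rec: UDSRecording,
    volume_threshold_ml: float = 1.0,
    second_rise_ml: float = 10.0,
    flat_s: float = 30.0,
) -> int:
    """Count distinct void events in the voided-volume channel.

    An event starts when volume first exceeds ``volume_threshold_ml``.  A
    further rise of more than ``second_rise_ml`` after the volume has been
    flat (within jitter) for more than ``flat_s`` counts as a new event —
    the signature of a leak followed by a terminal void, or of multiple
    voids, both of which break the single fill-void cycle assumption.
    """
    v = rec.voided_volume
    jitter = rec.volume_slack_ml
    events = 0
    ref = float(v[0])
    flat_start: float | None = None
    flat_level = 0.0
    had_flat = False  # a >flat_s flat period seen since the last counted event
    for i in range(v.size):
        t = float(rec.time[i])
        if events == 0:
            if v[i] > volume_threshold_ml:
                events = 1
                ref = float(v[i])
            continue
        if v[i] <= ref + jitter:
            if flat_start is None:
                flat_start = t
                flat_level = ref
            if t - flat_start > flat_s:
                had_flat = True
        else:
            ref = float(v[i])
            flat_start = None
            if had_flat and v[i] > flat_level + second_rise_ml:
                events += 1
                had_flat = False
    return events


def validate_for_analysis(
    rec: UDSRecording,
    min_fill_s: float = 420.0,
    volume_threshold_ml: float = 1.0,
) -> EligibilityReport:
    """Screen a recording for pipeline eligibility (report-only).

    Eligible recordings have at least ``min_fill_s`` seconds of filling
    (default 7 minutes) before the void (or in total, when no void occurs)
    and at most one void event; leaks or multiple voiding events break the
    single fill-void cycle the analysis window assumes.
    """
    from larcfft.roi import detect_void_onset  # local import: no cycle at runtime

    reasons: list[str] = []
    onset = detect_void_onset(rec, volume_threshold=volume_threshold_ml)
    fill_s = (onset - rec.time[0]) if onset is not None else rec.duration_s
    if fill_s < min_fill_s:
        reasons.append(f"fill shorter than {min_fill_s:g} s (got {fill_s:.1f} s)")
    n_events = count_void_events(rec, volume_threshold_ml=volume_threshold_ml)
    if n_events > 1:
        reasons.append("multiple voiding events")
    return EligibilityReport(
        study_id=rec.study_id,
        eligible=not reasons,
        reasons=reasons,
        fill_duration_s=float(fill_s),
        void_onset_time=onset,
        n_void_events=n_events,
    )


def load_label_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a study-id -> DO label table (TSV with header)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "study_id" not in df.columns or "do_label" not in df.columns:
        raise FormatError("label table needs 'study_id' and 'do_label' columns")
    return df


def channel_names(rec: UDSRecording) -> Sequence[str]:
    return list(rec.channels().keys())
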