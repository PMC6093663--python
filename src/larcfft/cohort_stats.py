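"""Cohort-level statistics: confusion counts, diagnostic metrics, exact tests.

The central comparison is a 2x2 cross-tabulation of the algorithm's
significant-and-independent (S&I) flag against the clinician
detrusor-overactivity (DO) label, with sensitivity, specificity, and a
two-sided Fisher exact test of association.  Continuous descriptives are
reported as mean +/- standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from larcfft.errors import DataError, ParameterError
from larcfft.larc_detect import LARCResult

#: relative tolerance treating near-equal hypergeometric point
#: probabilities as ties in the two-sided Fisher sum
_FISHER_TIE_RTOL = 1e-12


@dataclass
class SubgroupSummary:
    """Mean +/- standard error of slowest S&I frequency and model amplitude."""

    n: int
    mean_frequency: float | None = None
    se_frequency: float | None = None
    mean_amplitude: float | None = None
    se_amplitude: float | None = None
    single_observation: bool = False  # SE reported as 0 by convention


@dataclass
class CohortSummary:
    """Aggregated diagnostics for one ROI offset (or the any-offset union)."""

    roi_offset_s: float | str
    counts: np.ndarray  # rows: S&I / not-S&I; cols: DO / not-DO
    sensitivity: float
    specificity: float
    fisher_p: float
    subgroup_stats: SubgroupSummary


def _norm_do(label: object) -> str:
    if isinstance(label, bool):
        return "yes" if label else "no"
    s = str(label).strip().lower()
    if s in {"yes", "y", "do", "true", "1"}:
        return "yes"
    if s in {"no", "n", "false", "0"}:
        return "no"
    return "unknown"


def confusion_counts(
    results: Sequence[LARCResult | bool],
    labels: Mapping[str, object] | Sequence[object],
) -> np.ndarray:
    """Cross-tabulate the S&I flag against DO labels.

    ``results`` may be :class:`LARCResult` objects or plain booleans;
    ``labels`` is either a parallel sequence or a mapping from study id.
    Returns ``[[S&I∩DO, S&I∩notDO], [notS&I∩DO, notS&I∩notDO]]``.
    """
    if len(results) == 0:
        raise DataError("empty cohort")
    flags: list[bool] = []
    dos: list[str] = []
    ids: list[str] = []
    for i, r in enumerate(results):
        if isinstance(r, LARCResult):
            sid = r.study_id
            flags.append(r.is_si)
        else:
            sid = str(i)
            flags.append(bool(r))
        ids.append(sid)
        lab = labels[sid] if isinstance(labels, Mapping) else labels[i]
        dos.append(_norm_do(lab))
    unknown = [sid for sid, d in zip(ids, dos) if d == "unknown"]
    if unknown:
        raise DataError(f"unknown DO label for studies: {', '.join(unknown)}")
    table = np.zeros((2, 2), dtype=int)
    for si, do in zip(flags, dos):
        table[0 if si else 1, 0 if do == "yes" else 1] += 1
    return table


def sensitivity_specificity(table: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity) from the S&I-vs-DO 2x2 table."""
    t = np.asarray(table)
    do_total = t[:, 0].sum()
    not_do_total = t[:, 1].sum()
    if do_total == 0 or not_do_total == 0:
        raise DataError("a label column is empty; metric undefined")
    return float(t[0, 0] / do_total), float(t[1, 1] / not_do_total)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_two_sided(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value, computed from first principles.

    With the margins fixed, the hypergeometric point probability of every
    achievable table is computed via log-factorials; the p-value sums the
    probabilities of all tables at most as probable as the observed one
    (point-probability two-sided rule).  A relative tolerance of 1e-12
    treats numerically equal probabilities as ties.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DataError("need a non-negative 2x2 table")
    if not np.allclose(t, np.round(t)):
        raise DataError("table cells must be integers")
    a, b = int(round(t[0, 0])), int(round(t[0, 1]))
    c, d = int(round(t[1, 0])), int(round(t[1, 1]))
    n = a + b + c + d
    if n == 0:
        raise DataError("table total must be positive")
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    denom = _log_comb(n, c1)
    logp = np.array(
        [_log_comb(r1, x) + _log_comb(n - r1, c1 - x) - denom for x in range(lo, hi + 1)]
    )
    log_obs = logp[a - lo]
    p = float(np.exp(logp[logp <= log_obs + _FISHER_TIE_RTOL]).sum())
    return min(p, 1.0)


def two_sample_t(a: Iterable[float], b: Iterable[float]) -> float:
    """Two-tailed pooled-variance (equal-variance) two-sample t-test p-value.

    Degenerate inputs with zero pooled variance return 1 when the group
    means are equal and 0 otherwise.
    """
    from scipy import stats

    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def summarize_subgroup(results: Sequence[LARCResult]) -> SubgroupSummary:
    """Mean +/- SE of slowest S&I frequency and model peak-to-peak amplitude.

    Only S&I studies contribute.  With a single observation the SE is
    reported as 0 and flagged; with none, an empty summary is returned.
    """
    freqs = [
        r.slowest_si_frequency for r in results if r.is_si and r.slowest_si_frequency
    ]
    amps = [
        r.slowest_si_model.peak_to_peak
        for r in results
        if r.is_si and r.slowest_si_model is not None
    ]
    n = len(freqs)
    if n == 0:
        return SubgroupSummary(n=0)

    def mean_se(x: list[float]) -> tuple[float, float]:
        arr = np.asarray(x)
        if arr.size == 1:
            return float(arr[0]), 0.0
        return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))

    mf, sf = mean_se(freqs)
    ma, sa = mean_se(amps)
    return SubgroupSummary(
        n=n,
        mean_frequency=mf,
        se_frequency=sf,
        mean_amplitude=ma,
        se_amplitude=sa,
        single_observation=(n == 1),
    )


def cohort_summary(
    results: Sequence[LARCResult],
    labels: Mapping[str, object],
    roi_offset_s: float | str,
) -> CohortSummary:
    """Full per-offset cohort row: counts, metrics, exact test, descriptives."""
    counts = confusion_counts(results, labels)
    sens, spec = sensitivity_specificity(counts)
    return CohortSummary(
        roi_offset_s=roi_offset_s,
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        fisher_p=fisher_exact_two_sided(counts),
        subgroup_stats=summarize_subgroup(results),
    )
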