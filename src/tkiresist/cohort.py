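"""Cohort-level statistics: RECIST response, Kaplan–Meier survival, tests.

RECIST 1.1 best-response classes are derived from the signed percent change
in tumor burden: more than 30% shrinkage is a partial response (PR), more
than 20% growth is progressive disease (PD), anything in between is stable
disease (SD). The objective response rate (ORR) counts CR+PR; the disease
control rate (DCR) adds SD.

Progression-free survival (PFS) runs from treatment start to progression or
death; overall survival (OS) to death or loss to follow-up; patients without
an event are censored at last follow-up. Curves are product-limit
(Kaplan–Meier) estimates via lifelines, compared with the log-rank test;
2x2 group comparisons use Pearson chi-square (no continuity correction) or
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

RESPONSE_LABELS = ("CR", "PR", "SD", "PD")


@dataclass
class CohortRecord:
    """One patient of the cohort table."""

    patient_id: str
    egfr_status: str = ""
    t790m: Optional[bool] = None
    prior_tki: Optional[str] = None  # erlotinib | gefitinib | both
    best_tumor_change: Optional[float] = None  # signed percent, negative = shrinkage
    response: Optional[str] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        for t in (self.pfs_months, self.os_months):
            if t is not None and t < 0:
                raise ValueError("survival times must be >= 0")


def classify_recist(best_change: Optional[float]) -> Optional[str]:
    """RECIST 1.1 class from signed percent change; None when unmeasured.

    PR iff change < -30 (strict), PD iff change > +20 (strict), SD otherwise
    — the boundaries -30 and +20 are SD.
    """
    if best_change is None or (isinstance(best_change, float) and math.isnan(best_change)):
        return None
    if best_change < -30:
        return "PR"
    if best_change > 20:
        return "PD"
    return "SD"


def response_rates(responses: Iterable[Optional[str]]) -> Dict[str, float]:
    """ORR (CR+PR) and DCR (CR+PR+SD) over classified patients."""
    labels = [r for r in responses if r is not None]
    if not labels:
        raise ValueError("no classified responses")
    n = len(labels)
    orr = sum(r in ("CR", "PR") for r in labels) / n
    dcr = sum(r in ("CR", "PR", "SD") for r in labels) / n
    return {"n": n, "orr": orr, "dcr": dcr}


@dataclass
class SurvivalCurve:
    """Product-limit estimate with the at-risk table and median."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median: Optional[float]
    median_ci: Tuple[Optional[float], Optional[float]] = (None, None)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_median_survival(
    records: Sequence[CohortRecord],
    time_field: str = "pfs_months",
    event_field: str = "pfs_event",
) -> SurvivalCurve:
    """Kaplan–Meier curve and median for one cohort.

    The median is the earliest time at which S(t) <= 0.5 and is undefined
    (None) when the curve never reaches 0.5, e.g. under heavy censoring.
    Confidence limits for the median use the Brookmeyer–Crowley (log-log)
    interval as computed by lifelines.
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([getattr(r, time_field) for r in records], dtype=float)
    events = np.array([bool(getattr(r, event_field)) for r in records])
    if np.isnan(times).any():
        raise ValueError(f"missing {time_field} values")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)

    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    try:
        from lifelines.utils import median_survival_times

        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        median_ci = (None if math.isinf(lo) else lo, None if math.isinf(hi) else hi)
    except Exception:  # pragma: no cover - CI is informational
        median_ci = (None, None)
    return SurvivalCurve(times=grid, survival=surv, n_at_risk=at_risk, median=median, median_ci=median_ci)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    defined: bool = True
    method: str = ""


def logrank_test(
    group_a: Sequence[CohortRecord],
    group_b: Sequence[CohortRecord],
    time_field: str = "pfs_months",
    event_field: str = "pfs_event",
) -> TestResult:
    """Two-group log-rank test (observed minus expected chi-square, 1 df).

    With zero events in both groups the statistic is undefined and reported
    as such rather than as a numeric 0.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta = np.array([getattr(r, time_field) for r in group_a], dtype=float)
    ea = np.array([bool(getattr(r, event_field)) for r in group_a])
    tb = np.array([getattr(r, time_field) for r in group_b], dtype=float)
    eb = np.array([bool(getattr(r, event_field)) for r in group_b])
    if ea.sum() + eb.sum() == 0:
        return TestResult(math.nan, math.nan, defined=False, method="logrank")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(float(res.test_statistic), float(res.p_value), method="logrank")


def contingency_test(table, method: str = "chisq") -> TestResult:
    """2x2 association test: Pearson chi-square (uncorrected) or Fisher exact.

    A zero row/column margin leaves the chi-square undefined; Fisher's exact
    test is still defined there (p = 1).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if method == "chisq":
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            return TestResult(math.nan, math.nan, defined=False, method="chisq")
        chi2, p, _dof, _exp = stats.chi2_contingency(arr, correction=False)
        return TestResult(float(chi2), float(p), method="chisq")
    if method == "fisher":
        odds, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
        return TestResult(float(odds), float(p), method="fisher")
    raise ValueError(f"unknown method {method!r}; use 'chisq' or 'fisher'")


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def _pct(numer: int, denom: int) -> int:
    """Percentage rounded to the nearest integer (reporting convention)."""
    if denom == 0:
        raise ValueError("empty denominator")
    return round(100 * numer / denom)


def summarize_cohort(records: Sequence[CohortRecord]) -> Dict[str, object]:
    """Cohort-level mutation summary.

    Computes counts per EGFR-status category, the T790M percentage among
    patients with a known activating EGFR mutation, and per-prior-TKI T790M
    rates (patients who received both TKIs sequentially are excluded from
    the per-drug comparison, with the 2x2 table reported alongside).
    """
    if not records:
        raise ValueError("empty cohort")
    status_counts: Dict[str, int] = {}
    for r in records:
        status_counts[r.egfr_status] = status_counts.get(r.egfr_status, 0) + 1

    egfr_pos = [r for r in records if r.egfr_status and r.t790m is not None]
    summary: Dict[str, object] = {"egfr_status_counts": status_counts}
    if egfr_pos:
        n_t790m = sum(bool(r.t790m) for r in egfr_pos)
        summary.update(
            n_egfr_positive=len(egfr_pos),
            n_t790m_positive=n_t790m,
            t790m_pct=_pct(n_t790m, len(egfr_pos)),
        )

    rates: Dict[str, object] = {}
    table = np.zeros((2, 2), dtype=int)  # rows: erlotinib, gefitinib; cols: T790M+, T790M-
    for i, tki in enumerate(("erlotinib", "gefitinib")):
        grp = [r for r in egfr_pos if r.prior_tki == tki]
        pos = sum(bool(r.t790m) for r in grp)
        table[i] = (pos, len(grp) - pos)
        if grp:
            rates[f"{tki}_t790m_pct"] = _pct(pos, len(grp))
            rates[f"{tki}_n"] = len(grp)
    if rates:
        summary["per_tki"] = rates
        summary["tki_t790m_table"] = table
    return summary


def records_from_cohort_csv(path) -> List[CohortRecord]:
    """Load a cohort CSV (one row per patient, columns as CohortRecord)."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(name, cast=float):
            v = d.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return cast(v)

        out.append(
            CohortRecord(
                patient_id=str(d["patient_id"]),
                egfr_status=str(d.get("egfr_status", "") or ""),
                t790m=opt("t790m", lambda x: bool(int(x))),
                prior_tki=opt("prior_tki", str),
                best_tumor_change=opt("best_tumor_change"),
                response=opt("response", str),
                pfs_months=opt("pfs_months"),
                pfs_event=opt("pfs_event", lambda x: bool(int(x))),
                os_months=opt("os_months"),
                os_event=opt("os_event", lambda x: bool(int(x))),
                group=opt("group", str),
            )
        )
    return out
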