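"""Kaplan-Meier / log-rank comparison of prognostic groupings.

The discovered pattern (present vs absent) is compared against the three
classical dichotomized PSA prognostic factors — pretreatment PSA
(>= 100 ng/ml), PSA nadir (>= 0.2 ng/ml) and time to nadir (>= 12 months) —
by two-group log-rank tests on progression-free survival, with
product-limit curves as the canonical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .cohort import PatientRecord
from .transform import find_nadir

logger = logging.getLogger(__name__)

#: Default dichotomization thresholds for the classical factors.
DEFAULT_THRESHOLDS = {
    "pretreatment_psa": 100.0,  # ng/ml
    "nadir_psa": 0.2,           # ng/ml
    "time_to_nadir": 12.0,      # months
}


@dataclass
class SurvivalComparison:
    """One two-group survival comparison with its curves and log-rank test."""

    grouping_name: str
    threshold: float | None
    group_sizes: tuple[int, int]
    logrank_statistic: float
    p_value: float
    # per group: list of (time, survival probability, at-risk count)
    curve_points: dict[str, list[tuple[float, float, int]]] = field(default_factory=dict)


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> list[tuple[float, float, int]]:
    """Product-limit survival curve as (time, survival, at-risk) tuples.

    Censored-only input yields the constant curve at 1.0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if (times <= 0).any():
        raise ValueError("all times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"]
    out = []
    for t in surv.index:
        n_risk = int(at_risk.loc[t]) if t in at_risk.index else 0
        out.append((float(t), float(surv.loc[t]), n_risk))
    return out


def logrank(times: Sequence[float], events: Sequence[bool],
            group: Sequence[int]) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 df): returns (statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group).astype(bool)
    if group.all() or not group.any():
        raise ValueError("both groups must be nonempty")
    res = logrank_test(times[~group], times[group],
                       event_observed_A=events[~group], event_observed_B=events[group])
    return float(res.test_statistic), float(res.p_value)


def _grouped_comparison(name: str, threshold: float | None,
                        times: np.ndarray, events: np.ndarray,
                        group: np.ndarray, group_labels: tuple[str, str]) -> SurvivalComparison | None:
    if group.all() or not group.any():
        logger.info("comparison %r skipped: one group is empty "
                    "(threshold=%s)", name, threshold)
        return None
    stat, p = logrank(times, events, group)
    curves = {
        group_labels[0]: km_estimate(times[~group.astype(bool)], events[~group.astype(bool)]),
        group_labels[1]: km_estimate(times[group.astype(bool)], events[group.astype(bool)]),
    }
    return SurvivalComparison(
        grouping_name=name, threshold=threshold,
        group_sizes=(int((~group.astype(bool)).sum()), int(group.astype(bool).sum())),
        logrank_statistic=stat, p_value=p, curve_points=curves,
    )


def compare_prognostics(records: Sequence[PatientRecord],
                        pattern_indicator: Sequence[int],
                        thresholds: dict | None = None) -> list[SurvivalComparison]:
    """Compare the final pattern against the classical dichotomized factors.

    ``pattern_indicator`` marks pattern presence per patient (patients
    without an evaluable sequence count as pattern-absent). Nadir and time
    to nadir are derived from each patient's measurement series; patients
    without measurements are excluded from those comparisons (logged).
    A comparison whose dichotomization empties one group is skipped with a
    logged reason.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    times = np.array([r.event_time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    ind = np.asarray(pattern_indicator).astype(bool)

    out: list[SurvivalComparison] = []
    c = _grouped_comparison("pattern", None, times, events, ind,
                            ("pattern_absent", "pattern_present"))
    if c:
        out.append(c)

    pre = np.array([r.covariates.pretreatment_psa for r in records], dtype=float)
    c = _grouped_comparison("pretreatment_psa", thr["pretreatment_psa"], times, events,
                            pre >= thr["pretreatment_psa"], ("low", "high"))
    if c:
        out.append(c)

    has_meas = np.array([len(r.measurements) > 0 for r in records])
    if not has_meas.all():
        logger.info("%d patients without measurements excluded from nadir-based "
                    "comparisons", int((~has_meas).sum()))
    nadir_vals, nadir_times_ = [], []
    for r in records:
        if r.measurements:
            v, t = find_nadir(r.measurements)
        else:
            v, t = np.nan, np.nan
        nadir_vals.append(v)
        nadir_times_.append(t)
    nadir_vals = np.array(nadir_vals)
    nadir_times_ = np.array(nadir_times_)

    m = has_meas
    c = _grouped_comparison("nadir_psa", thr["nadir_psa"], times[m], events[m],
                            nadir_vals[m] >= thr["nadir_psa"], ("low", "high"))
    if c:
        out.append(c)
    c = _grouped_comparison("time_to_nadir", thr["time_to_nadir"], times[m], events[m],
                            nadir_times_[m] >= thr["time_to_nadir"], ("short", "long"))
    if c:
        out.append(c)
    return out
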