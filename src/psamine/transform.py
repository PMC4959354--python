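"""Velocity transformation and discretization of PSA series.

A PSA series (ng/ml vs months) is converted to a velocity (PSAV) sequence
over consecutive measurement pairs::

    PSAV = (PSA_t2 - PSA_t1) / (t2 - t1)      [ng/(ml*mo)]

(no log transform: the absolute monthly change is the quantity of
interest), split at the nadir (the series minimum, earliest tie), and
discretized into ordinal states by one of two schemes:

* equal-frequency binning (unsupervised, fixed number of bins), and
* Fayyad-Irani entropy/MDLP discretization (supervised on the outcome
  class attached to each velocity instance).

Intervals are left-open right-closed with unbounded ends, so a value lying
exactly on a boundary belongs to the lower state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Measurement

BEFORE_NADIR = "before_nadir"
AFTER_NADIR = "after_nadir"

_BASE_LABELS = {
    1: ("M",),
    2: ("L", "H"),
    3: ("L", "M", "H"),
    4: ("L", "ML", "MH", "H"),
    5: ("L", "ML", "M", "MH", "H"),
}


def _default_labels(k: int, suffix: str) -> tuple[str, ...]:
    base = _BASE_LABELS.get(k, tuple(f"S{i+1}" for i in range(k)))
    return tuple(f"{b}_{suffix}" if suffix else b for b in base)


@dataclass(frozen=True)
class VelocityPoint:
    """PSAV over one consecutive measurement pair."""

    start_time: float
    end_time: float
    psav: float

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")


@dataclass
class VelocitySequence:
    """Ordered PSAV points for one patient and one nadir segment."""

    patient_id: str
    segment: str
    points: list[VelocityPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def psav_values(self) -> np.ndarray:
        return np.array([p.psav for p in self.points], dtype=float)


@dataclass
class StateSequence:
    """Discretized state labels for one patient/segment, tagged with class."""

    patient_id: str
    segment: str
    states: tuple[str, ...] = ()
    class_label: str = "nonevent"  # {event, nonevent}

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DiscretizationScheme:
    """Ordered interval boundaries and state labels for one method.

    ``boundaries`` are strictly ascending; intervals are
    ``(-inf, b0], (b0, b1], ..., (b_{m-1}, +inf)`` with one label each.
    ``frequencies`` optionally records the fraction of fitted instances per
    state.
    """

    method: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    frequencies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need exactly len(boundaries)+1 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be distinct")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly ascending")

    def assign(self, values) -> list[str]:
        """Map each value to the label of its (left-open, right-closed] interval."""
        idx = np.searchsorted(np.asarray(self.boundaries), np.asarray(values, dtype=float),
                              side="left")
        return [self.labels[i] for i in np.atleast_1d(idx)]

    def interval_of(self, label: str) -> tuple[float, float]:
        """(lo, hi] interval of a state; unbounded ends are +-inf."""
        i = self.labels.index(label)
        lo = -math.inf if i == 0 else self.boundaries[i - 1]
        hi = math.inf if i == len(self.boundaries) else self.boundaries[i]
        return (lo, hi)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "boundaries": list(self.boundaries),
            "labels": list(self.labels),
            "frequencies": list(self.frequencies) if self.frequencies else None,
        }


def find_nadir(measurements: list[Measurement]) -> tuple[float, float]:
    """Return (nadir value, nadir time); ties broken by earliest time."""
    if not measurements:
        raise ValueError("cannot find nadir of empty series")
    values = np.array([m.value for m in measurements])
    i = int(np.argmin(values))  # argmin returns first minimum: earliest tie
    return float(measurements[i].value), float(measurements[i].time)


def compute_velocities(measurements: list[Measurement]) -> list[VelocityPoint]:
    """PSAV over consecutive measurement pairs (n measurements -> n-1 points)."""
    points = []
    for m1, m2 in zip(measurements, measurements[1:]):
        dt = m2.time - m1.time
        if dt <= 0:
            raise ValueError(f"non-increasing measurement times at t={m1.time}")
        points.append(VelocityPoint(m1.time, m2.time, (m2.value - m1.value) / dt))
    return points


def split_at_nadir(
    points: list[VelocityPoint], nadir_time: float, patient_id: str = ""
) -> tuple[VelocitySequence, VelocitySequence]:
    """Partition velocity points at the nadir.

    A point belongs to the before segment iff its interval ends at or before
    the nadir, and to the after segment iff it starts at or after the nadir.
    Because the nadir is itself a measurement time, the two sets partition
    all points; either side may be empty.
    """
    before = [p for p in points if p.end_time <= nadir_time]
    after = [p for p in points if p.start_time >= nadir_time]
    return (
        VelocitySequence(patient_id, BEFORE_NADIR, before),
        VelocitySequence(patient_id, AFTER_NADIR, after),
    )


class EqualFrequencyDiscretizer(BaseEstimator, TransformerMixin):
    """Unsupervised equal-frequency binning of velocity values.

    Boundaries sit at the 1/k ... (k-1)/k empirical quantiles (type-1 /
    inverse-CDF definition, for exact small-sample reproducibility), so bin
    occupancies differ by at most one when values are distinct.

    Parameters
    ----------
    n_bins : int, default 5
        Number of states (>= 2).
    label_suffix : str, default "q"
        Suffix appended to the ordinal base labels (L, ML, M, MH, H).
    """

    def __init__(self, n_bins: int = 5, label_suffix: str = "q"):
        self.n_bins = n_bins
        self.label_suffix = label_suffix

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if np.unique(x).size < self.n_bins:
            raise ValueError(
                f"only {np.unique(x).size} distinct values; "
                f"use a smaller n_bins than {self.n_bins}"
            )
        qs = np.arange(1, self.n_bins) / self.n_bins
        bounds = np.quantile(x, qs, method="inverted_cdf")
        if np.unique(bounds).size != bounds.size:
            raise ValueError(
                "tied values collapse equal-frequency boundaries; "
                "use a smaller n_bins"
            )
        freqs = []
        edges = [-np.inf, *bounds, np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            freqs.append(float(np.mean((x > lo) & (x <= hi))))
        self.scheme_ = DiscretizationScheme(
            method="equal_frequency",
            boundaries=tuple(float(b) for b in bounds),
            labels=_default_labels(self.n_bins, self.label_suffix),
            frequencies=tuple(freqs),
        )
        return self

    def transform(self, X) -> list[str]:
        return self.scheme_.assign(np.asarray(X, dtype=float).ravel())


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


class MDLPDiscretizer(BaseEstimator, TransformerMixin):
    """Fayyad-Irani entropy-based discretization with the MDL stopping rule.

    Recursively picks the cut minimizing the class-weighted entropy among
    midpoints between adjacent distinct values whose class composition
    differs, accepting a cut only if the information gain exceeds

        [log2(N-1) + log2(3^k - 2) - k*Ent(S) + k1*Ent(S1) + k2*Ent(S2)] / N.

    May return a single-label scheme when no cut is accepted (including the
    single-class case).
    """

    def __init__(self, label_suffix: str = "e"):
        self.label_suffix = label_suffix

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y)
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        if x.size < 2:
            raise ValueError("need at least 2 values")
        classes, yi = np.unique(y, return_inverse=True)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], yi[order]
        cuts: list[float] = []
        if classes.size > 1:
            self._recurse(xs, ys, classes.size, cuts)
        cuts.sort()
        bounds = tuple(cuts)
        labels = _default_labels(len(bounds) + 1, self.label_suffix)
        freqs = []
        edges = [-np.inf, *bounds, np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            freqs.append(float(np.mean((x > lo) & (x <= hi))))
        self.scheme_ = DiscretizationScheme(
            method="entropy_mdlp", boundaries=bounds, labels=labels,
            frequencies=tuple(freqs),
        )
        return self

    def transform(self, X) -> list[str]:
        return self.scheme_.assign(np.asarray(X, dtype=float).ravel())

    # --- recursion over sorted (values, class indices) ------------------------

    @staticmethod
    def _candidate_cuts(xs: np.ndarray, ys: np.ndarray, n_classes: int):
        """Indices i such that a cut between xs[i-1] and xs[i] is a candidate.

        Candidates are midpoints between adjacent distinct values whose class
        composition differs (counting ties at each value together).
        """
        # group by distinct value
        uniq, starts = np.unique(xs, return_index=True)
        if uniq.size < 2:
            return []
        bounds_idx = list(starts[1:]) + [len(xs)]
        comps = []
        s = 0
        for e in bounds_idx:
            comps.append(np.bincount(ys[s:e], minlength=n_classes))
            s = e
        cands = []
        for j in range(len(uniq) - 1):
            if not np.array_equal(comps[j] * comps[j + 1].sum(),
                                  comps[j + 1] * comps[j].sum()):
                cands.append((int(starts[j + 1]), 0.5 * (uniq[j] + uniq[j + 1])))
        return cands

    def _recurse(self, xs: np.ndarray, ys: np.ndarray, n_classes: int,
                 cuts: list[float]) -> None:
        n = xs.size
        cands = self._candidate_cuts(xs, ys, n_classes)
        if not cands:
            return
        total_counts = np.bincount(ys, minlength=n_classes)
        ent_s = _entropy(total_counts)
        best = None
        for split_idx, cut in cands:
            c1 = np.bincount(ys[:split_idx], minlength=n_classes)
            c2 = total_counts - c1
            w_ent = (split_idx * _entropy(c1) + (n - split_idx) * _entropy(c2)) / n
            if best is None or w_ent < best[0] - 1e-12:
                best = (w_ent, split_idx, cut, c1, c2)
        w_ent, split_idx, cut, c1, c2 = best
        gain = ent_s - w_ent
        k = int((total_counts > 0).sum())
        k1 = int((c1 > 0).sum())
        k2 = int((c2 > 0).sum())
        delta = (math.log2(3**k - 2)
                 - (k * ent_s - k1 * _entropy(c1) - k2 * _entropy(c2)))
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        cuts.append(float(cut))
        self._recurse(xs[:split_idx], ys[:split_idx], n_classes, cuts)
        self._recurse(xs[split_idx:], ys[split_idx:], n_classes, cuts)


def fit_equal_frequency(values, k: int = 5, label_suffix: str = "q") -> DiscretizationScheme:
    """Fit equal-frequency binning on pooled PSAV values."""
    return EqualFrequencyDiscretizer(n_bins=k, label_suffix=label_suffix).fit(values).scheme_


def fit_entropy_mdlp(values, labels, label_suffix: str = "e") -> DiscretizationScheme:
    """Fit Fayyad-Irani MDLP on pooled PSAV values with per-instance classes."""
    return MDLPDiscretizer(label_suffix=label_suffix).fit(values, labels).scheme_


def discretize(sequence: VelocitySequence, scheme: DiscretizationScheme,
               class_label: str = "nonevent") -> StateSequence:
    """Map a velocity sequence to its state sequence under a fitted scheme."""
    if len(sequence) == 0:
        states: tuple[str, ...] = ()
    else:
        states = tuple(scheme.assign(sequence.psav_values))
    return StateSequence(sequence.patient_id, sequence.segment, states, class_label)
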