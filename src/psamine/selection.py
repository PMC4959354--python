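"""Predictive and informative pattern selection.

Each candidate pattern is turned into a per-patient binary feature
(present/absent in the patient's state sequence) and added to the baseline
covariate set B. Predictive value is the cross-validated net improvement

    dAUC     = AUC(B u {p}) - AUC(B)          (logistic regression)
    dC-index = C(B u {p})   - C(B)            (Cox proportional hazards)

over stratified 10-fold cross-validation, with one-sided paired t-tests
(alternative: augmented > baseline) across folds. Patterns with positive
mean improvements and p <= alpha on both metrics are retained.

Among the retained patterns the most informative one is selected under a
partial order: a pattern dominates (is more informative than) another if
the other is a sub-pattern of it, if its state intervals are elementwise
subsets of the other's, or — when neither structural rule applies — if it
is rarer (lower class support).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .cohort import CATEGORICAL_FIELDS, COVARIATE_FIELDS, PatientRecord
from .mining import Pattern, contains
from .transform import DiscretizationScheme, StateSequence

logger = logging.getLogger(__name__)

_ONE_HOT = ("drug_order", "clinical_stage")


def build_design_matrix(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Baseline design matrix: numeric covariates plus one-hot categories."""
    df = pd.DataFrame([r.covariates.asdict() for r in records])
    if df.isna().any().any():
        raise ValueError("missing covariates; run impute_missing first")
    numeric = [f for f in COVARIATE_FIELDS if f not in _ONE_HOT]
    out = df[numeric].astype(float)
    for f in _ONE_HOT:
        dummies = pd.get_dummies(df[f], prefix=f, drop_first=True, dtype=float)
        out = pd.concat([out, dummies], axis=1)
    out.index = [r.id for r in records]
    return out


def pattern_feature(state_sequences: Mapping[str, StateSequence] | Sequence[StateSequence],
                    pattern: Pattern,
                    patient_ids: Sequence[str]) -> np.ndarray:
    """Binary indicator: 1 iff the patient's state sequence contains the pattern.

    Patients without a sequence (or with an empty one) get 0.
    """
    if not isinstance(state_sequences, Mapping):
        state_sequences = {s.patient_id: s for s in state_sequences}
    out = np.zeros(len(patient_ids), dtype=float)
    for i, pid in enumerate(patient_ids):
        seq = state_sequences.get(pid)
        if seq is not None and len(seq) > 0 and contains(seq, pattern):
            out[i] = 1.0
    return out


@dataclass
class EvaluationResult:
    """Fold-wise AUC/C-index of baseline vs baseline+pattern, with paired tests."""

    pattern: Pattern
    fold_auc_baseline: list[float] = field(default_factory=list)
    fold_auc_augmented: list[float] = field(default_factory=list)
    fold_cindex_baseline: list[float] = field(default_factory=list)
    fold_cindex_augmented: list[float] = field(default_factory=list)
    mean_delta_auc: float = 0.0
    mean_delta_cindex: float = 0.0
    p_auc: float = 1.0
    p_cindex: float = 1.0
    accepted: bool = False
    reject_reasons: list[str] = field(default_factory=list)


def _paired_p_greater(augmented: Sequence[float], baseline: Sequence[float]) -> float:
    """One-sided paired t-test p-value for augmented > baseline."""
    d = np.asarray(augmented, dtype=float) - np.asarray(baseline, dtype=float)
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        return 0.0 if d.mean() > 0 else 1.0
    return float(stats.ttest_rel(augmented, baseline, alternative="greater").pvalue)


class _CVEvaluator:
    """Shared CV machinery: fixed stratified folds and cached baseline metrics."""

    MAX_REFOLDS = 10

    def __init__(self, records: Sequence[PatientRecord], n_folds: int, seed: int):
        self.records = list(records)
        self.ids = [r.id for r in self.records]
        self.X = build_design_matrix(self.records).to_numpy()
        self.y = np.array([r.event for r in self.records], dtype=int)
        self.time = np.array([r.event_time for r in self.records], dtype=float)
        self.n_folds = n_folds
        self.folds = self._make_folds(seed)
        self._baseline = None

    def _make_folds(self, seed: int):
        for attempt in range(self.MAX_REFOLDS):
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=seed + attempt)
            folds = list(skf.split(self.X, self.y))
            ok = all(len(np.unique(self.y[te])) == 2 and len(np.unique(self.y[tr])) == 2
                     for tr, te in folds)
            if ok:
                if attempt:
                    logger.info("refolded %d time(s) to avoid single-class folds", attempt)
                return folds
        raise ValueError("could not build folds with both outcome classes present")

    def _fold_metrics(self, X: np.ndarray) -> tuple[list[float], list[float]]:
        aucs, cidx = [], []
        for tr, te in self.folds:
            scaler = StandardScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])

            clf = LogisticRegression(max_iter=2000)
            clf.fit(Xtr, self.y[tr])
            aucs.append(float(roc_auc_score(self.y[te], clf.predict_proba(Xte)[:, 1])))

            ytr = Surv.from_arrays(self.y[tr].astype(bool), self.time[tr])
            # ridge keeps coefficients finite when a pattern indicator
            # (nearly) separates the classes; the held-out risk ranking is
            # what the C-index uses
            cox = CoxPHSurvivalAnalysis(alpha=1.0)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.filterwarnings("ignore", message="overflow encountered")
                    cox.fit(Xtr, ytr)
                risk = cox.predict(Xte)
                c = concordance_index_censored(
                    self.y[te].astype(bool), self.time[te], risk)[0]
            except (ValueError, ArithmeticError) as exc:  # no comparable pairs etc.
                logger.warning("Cox fold failed (%s); recording C-index 0.5", exc)
                c = 0.5
            cidx.append(float(c))
        return aucs, cidx

    def baseline_metrics(self) -> tuple[list[float], list[float]]:
        if self._baseline is None:
            self._baseline = self._fold_metrics(self.X)
        return self._baseline

    def evaluate(self, pattern: Pattern, indicator: np.ndarray) -> EvaluationResult:
        base_auc, base_c = self.baseline_metrics()
        if np.all(indicator == indicator[0]):
            # constant feature: augmented model is the baseline model
            aug_auc, aug_c = list(base_auc), list(base_c)
        else:
            key = indicator.tobytes()
            if not hasattr(self, "_aug_cache"):
                self._aug_cache: dict = {}
            if key not in self._aug_cache:
                Xa = np.column_stack([self.X, indicator])
                self._aug_cache[key] = self._fold_metrics(Xa)
            aug_auc, aug_c = self._aug_cache[key]
        res = EvaluationResult(
            pattern=pattern,
            fold_auc_baseline=base_auc,
            fold_auc_augmented=aug_auc,
            fold_cindex_baseline=base_c,
            fold_cindex_augmented=aug_c,
            mean_delta_auc=float(np.mean(aug_auc) - np.mean(base_auc)),
            mean_delta_cindex=float(np.mean(aug_c) - np.mean(base_c)),
            p_auc=_paired_p_greater(aug_auc, base_auc),
            p_cindex=_paired_p_greater(aug_c, base_c),
        )
        return res


def _indicator_for(pattern: Pattern, sequences, ids) -> np.ndarray:
    if isinstance(sequences, Mapping) and pattern.scheme in sequences:
        seqs = sequences[pattern.scheme]
    else:
        seqs = sequences
    return pattern_feature(seqs, pattern, ids)


def evaluate_pattern(records: Sequence[PatientRecord], pattern: Pattern,
                     sequences, n_folds: int = 10, seed: int = 0) -> EvaluationResult:
    """Evaluate a single pattern by stratified CV (see module docstring).

    ``sequences`` is either a list of :class:`StateSequence` (one segment,
    one scheme) or a mapping of scheme name to such lists when patterns from
    several discretizations are in play.
    """
    ev = _CVEvaluator(records, n_folds, seed)
    return ev.evaluate(pattern, _indicator_for(pattern, sequences, ev.ids))


def select_predictive(candidates: Sequence[Pattern], records: Sequence[PatientRecord],
                      sequences, alpha: float = 0.05, n_folds: int = 10,
                      seed: int = 0) -> tuple[list[EvaluationResult], list[EvaluationResult]]:
    """Evaluate deduplicated candidates; return (accepted, all results).

    A pattern is accepted if both mean improvements are positive and both
    paired-test p-values are <= alpha; otherwise its result records the
    rejection reasons.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    ev = _CVEvaluator(records, n_folds, seed)

    seen: set[tuple] = set()
    results: list[EvaluationResult] = []
    for pat in candidates:
        key = (pat.states, pat.scheme)
        if key in seen:
            continue
        seen.add(key)
        res = ev.evaluate(pat, _indicator_for(pat, sequences, ev.ids))
        reasons = []
        if res.mean_delta_auc <= 0:
            reasons.append("mean_delta_auc <= 0")
        if res.mean_delta_cindex <= 0:
            reasons.append("mean_delta_cindex <= 0")
        if res.p_auc > alpha:
            reasons.append(f"p_auc {res.p_auc:.4g} > alpha")
        if res.p_cindex > alpha:
            reasons.append(f"p_cindex {res.p_cindex:.4g} > alpha")
        res.accepted = not reasons
        res.reject_reasons = reasons
        results.append(res)
    accepted = [r for r in results if r.accepted]
    return accepted, results


# --- informative selection (Lemma-style partial order) -------------------------


@dataclass(frozen=True)
class InformationRelation:
    """Outcome of comparing the relative information of two patterns."""

    p1: Pattern
    p2: Pattern
    relation: str  # {p1_ge_p2, p2_ge_p1, incomparable}
    rule_used: str  # {subpattern, interval_subset, frequency, none}


def _is_subseq(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    it = iter(b)
    return all(any(x == y for y in it) for x in a)


def _intervals(p: Pattern, scheme: DiscretizationScheme) -> list[tuple[float, float]]:
    return [scheme.interval_of(s) for s in p.states]


def _interval_subset(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] >= b[0] and a[1] <= b[1]


def _frequency(p: Pattern, scheme: DiscretizationScheme, basis: str) -> float:
    if basis == "pattern_support":
        return p.support
    if basis == "state_instance":
        if scheme.frequencies is None:
            raise ValueError("scheme has no state instance frequencies")
        f = 1.0
        for s in p.states:
            f *= scheme.frequencies[scheme.labels.index(s)]
        return f
    raise ValueError(f"unknown frequency_basis {basis!r}")


def lemma1_compare(p1: Pattern, p2: Pattern,
                   scheme1: DiscretizationScheme, scheme2: DiscretizationScheme,
                   frequency_basis: str = "pattern_support") -> InformationRelation:
    """Compare relative information of two patterns of similar accuracy.

    Structural rules take precedence: a pattern carries at least as much
    information as any of its sub-patterns (same scheme), and as any
    equal-length pattern whose state intervals elementwise contain its own.
    When neither applies in either direction, the rarer pattern (lower
    frequency) is the more informative; equal frequencies are incomparable.
    """
    s1, s2 = p1.states, p2.states
    same_scheme = scheme1 is scheme2 or scheme1 == scheme2
    if same_scheme and s1 == s2:
        return InformationRelation(p1, p2, "incomparable", "none")

    # rule 1: sub-pattern (within one scheme)
    if same_scheme:
        if _is_subseq(s2, s1) and len(s2) < len(s1):
            return InformationRelation(p1, p2, "p1_ge_p2", "subpattern")
        if _is_subseq(s1, s2) and len(s1) < len(s2):
            return InformationRelation(p1, p2, "p2_ge_p1", "subpattern")

    # rule 2: elementwise interval subset (equal lengths)
    if len(s1) == len(s2):
        i1, i2 = _intervals(p1, scheme1), _intervals(p2, scheme2)
        if i1 != i2:
            if all(_interval_subset(a, b) for a, b in zip(i1, i2)):
                return InformationRelation(p1, p2, "p1_ge_p2", "interval_subset")
            if all(_interval_subset(b, a) for a, b in zip(i1, i2)):
                return InformationRelation(p1, p2, "p2_ge_p1", "interval_subset")

    # rule 3: frequency (rarer is more informative)
    f1 = _frequency(p1, scheme1, frequency_basis)
    f2 = _frequency(p2, scheme2, frequency_basis)
    if f1 < f2:
        return InformationRelation(p1, p2, "p1_ge_p2", "frequency")
    if f2 < f1:
        return InformationRelation(p1, p2, "p2_ge_p1", "frequency")
    return InformationRelation(p1, p2, "incomparable", "none")


def select_informative(predictive, schemes: Mapping[str, DiscretizationScheme],
                       frequency_basis: str = "pattern_support") -> tuple[Pattern, dict]:
    """Prune dominated patterns; return the maximal one and a decision log.

    ``predictive`` is a nonempty list of :class:`EvaluationResult` or
    :class:`Pattern`. Ties among maximal patterns break by lowest support,
    then greatest length, then lexicographic state order (path logged).
    """
    patterns = [r.pattern if isinstance(r, EvaluationResult) else r for r in predictive]
    if not patterns:
        raise ValueError("no predictive patterns to select from")

    def scheme_of(p: Pattern) -> DiscretizationScheme:
        if p.scheme is None and len(schemes) == 1:
            return next(iter(schemes.values()))
        return schemes[p.scheme]

    relations: list[InformationRelation] = []
    dominated = [False] * len(patterns)
    for i, pi in enumerate(patterns):
        for j in range(i + 1, len(patterns)):
            pj = patterns[j]
            rel = lemma1_compare(pi, pj, scheme_of(pi), scheme_of(pj), frequency_basis)
            relations.append(rel)
            if rel.relation == "p1_ge_p2":
                dominated[j] = True
            elif rel.relation == "p2_ge_p1":
                dominated[i] = True

    maximal = [p for p, d in zip(patterns, dominated) if not d]
    log: dict = {
        "relations": [
            {"p1": str(r.p1), "p2": str(r.p2), "relation": r.relation,
             "rule": r.rule_used}
            for r in relations
        ],
        "maximal": [str(p) for p in maximal],
        "tie_break": None,
    }
    if not maximal:  # only possible through rule-3 cycles; fall back to all
        maximal = patterns
        log["maximal"] = [str(p) for p in maximal]
        log["tie_break"] = "all patterns dominated (frequency cycle); tie-breaking over all"
    if len(maximal) > 1:
        maximal = sorted(maximal, key=lambda p: (p.support, -len(p.states), p.states))
        log["tie_break"] = (
            "multiple maximal patterns; tie-break by lowest support, "
            f"greatest length, lexicographic -> {maximal[0]}"
        )
        logger.info(log["tie_break"])
    final = maximal[0]
    log["final"] = str(final)
    return final, log


class PredictivePatternSelector(BaseEstimator):
    """Estimator bundling predictive evaluation and informative selection.

    ``fit(records, candidates=..., sequences=..., schemes=...)`` populates
    ``results_`` (all evaluations), ``predictive_`` (accepted), and — when
    any pattern is accepted — ``final_pattern_`` and ``selection_log_``.
    """

    def __init__(self, alpha: float = 0.05, n_folds: int = 10,
                 random_state: int = 0, frequency_basis: str = "pattern_support"):
        self.alpha = alpha
        self.n_folds = n_folds
        self.random_state = random_state
        self.frequency_basis = frequency_basis

    def fit(self, X, y=None, *, candidates, sequences, schemes=None):
        accepted, results = select_predictive(
            candidates, X, sequences, alpha=self.alpha,
            n_folds=self.n_folds, seed=self.random_state)
        self.results_ = results
        self.predictive_ = accepted
        self.final_pattern_ = None
        self.selection_log_ = {}
        if accepted and schemes is not None:
            self.final_pattern_, self.selection_log_ = select_informative(
                accepted, schemes, self.frequency_basis)
        return self
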