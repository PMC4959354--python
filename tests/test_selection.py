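import numpy as np
import pytest

from psamine import (Pattern, PredictivePatternSelector, evaluate_pattern,
                     generate_cohort, lemma1_compare, pattern_feature,
                     select_informative, select_predictive, SimConfig)
from psamine.mining import contains
from psamine.selection import _paired_p_greater
from psamine.transform import DiscretizationScheme, StateSequence


def _class_of(r):
    return "event" if r.event else "nonevent"


def _planted_sequences(records):
    """Nonevent patients carry L->L; event patients only M."""
    return [StateSequence(r.id, "after_nadir",
                          ("M", "L", "L") if not r.event else ("M", "M"),
                          _class_of(r)) for r in records]


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SimConfig(n_patients=120, seed=11))


def test_pattern_feature_matches_construction(cohort):
    seqs = _planted_sequences(cohort)
    ind = pattern_feature(seqs, Pattern(("L", "L")), [r.id for r in cohort])
    assert np.array_equal(ind, 1.0 - np.array([r.event for r in cohort]))
    # absent pattern -> all-zero vector
    zero = pattern_feature(seqs, Pattern(("H",)), [r.id for r in cohort])
    assert not zero.any()
    # patients with empty sequences count as pattern-absent
    seqs[0] = StateSequence(seqs[0].patient_id, "after_nadir", (), seqs[0].class_label)
    ind2 = pattern_feature(seqs, Pattern(("L", "L")), [r.id for r in cohort])
    assert ind2[0] == 0.0


def test_indicator_invariant_to_appended_states(rng):
    pat = Pattern(("A", "B"))
    for _ in range(50):
        seq = tuple(rng.choice(["A", "B", "C"], size=rng.integers(0, 7)))
        extra = seq + tuple(rng.choice(["C"], size=2))  # C never completes A->B
        assert contains(seq, pat) == contains(extra, pat)


def test_perfect_separator_gives_unit_auc(cohort):
    seqs = _planted_sequences(cohort)
    res = evaluate_pattern(cohort, Pattern(("L", "L")), seqs, n_folds=10, seed=0)
    assert all(a == 1.0 for a in res.fold_auc_augmented)
    assert res.mean_delta_auc > 0 and res.p_auc < 0.05


def test_select_predictive_accepts_signal_rejects_noise(cohort, rng):
    seqs = _planted_sequences(cohort)
    noise = Pattern(("M", "M"), scheme=None)  # present in every event patient
    planted = Pattern(("L", "L"))
    accepted, results = select_predictive([planted, noise], cohort, seqs,
                                          alpha=0.05, n_folds=10, seed=0)
    states = {r.pattern.states for r in accepted}
    assert ("L", "L") in states
    rejected = [r for r in results if not r.accepted]
    assert all(r.reject_reasons for r in rejected)


def test_select_predictive_alpha_bounds(cohort):
    seqs = _planted_sequences(cohort)
    pats = [Pattern(("L", "L")), Pattern(("M",))]
    acc0, _ = select_predictive(pats, cohort, seqs, alpha=0.0, n_folds=10, seed=0)
    assert acc0 == []  # vacuous threshold
    acc1, res1 = select_predictive(pats, cohort, seqs, alpha=1.0, n_folds=10, seed=0)
    # alpha=1 keeps exactly the positive mean-delta patterns
    assert {r.pattern.states for r in acc1} == {
        r.pattern.states for r in res1
        if r.mean_delta_auc > 0 and r.mean_delta_cindex > 0}


def test_duplicate_candidates_deduplicated(cohort):
    seqs = _planted_sequences(cohort)
    pats = [Pattern(("L", "L")), Pattern(("L", "L")), Pattern(("L", "L"))]
    _, results = select_predictive(pats, cohort, seqs, n_folds=10, seed=0)
    assert len(results) == 1


def test_paired_test_helper_degenerate_cases():
    assert _paired_p_greater([0.7] * 10, [0.7] * 10) == 1.0
    assert _paired_p_greater([0.8] * 10, [0.7] * 10) == 0.0


# --- informative selection ------------------------------------------------------


def test_lemma_rules_reproduce_published_ordering(published_schemes,
                                                  published_predictive_patterns):
    eq = published_schemes["equal_frequency"]
    en = published_schemes["entropy_mdlp"]
    L_q, LL_q, L_e, LL_e, ML_e = published_predictive_patterns

    r = lemma1_compare(LL_e, L_e, en, en)
    assert (r.relation, r.rule_used) == ("p1_ge_p2", "subpattern")
    r = lemma1_compare(ML_e, L_e, en, en)
    assert (r.relation, r.rule_used) == ("p1_ge_p2", "subpattern")
    r = lemma1_compare(LL_q, L_q, eq, eq)
    assert (r.relation, r.rule_used) == ("p1_ge_p2", "subpattern")
    # equal-length interval subset across schemes: (,-0.048] subset of (,-0.005]
    r = lemma1_compare(LL_e, LL_q, en, eq)
    assert (r.relation, r.rule_used) == ("p1_ge_p2", "interval_subset")
    # frequency: the rarer pattern carries more information
    r = lemma1_compare(LL_e, ML_e, en, en)
    assert (r.relation, r.rule_used) == ("p1_ge_p2", "frequency")


def test_informative_selection_returns_repeated_decline(published_schemes,
                                                        published_predictive_patterns):
    final, log = select_informative(published_predictive_patterns, published_schemes)
    assert final.states == ("L_e", "L_e")
    assert log["final"] == "L_e→L_e"


def test_informative_selection_single_and_tiebreak(published_schemes):
    p = Pattern(("L_e",), "nonevent", 0.4, scheme="entropy_mdlp")
    final, _ = select_informative([p], published_schemes)
    assert final is p
    # incomparable equal-support patterns: longer one wins, logged
    a = Pattern(("L_e",), "nonevent", 0.4, scheme="entropy_mdlp")
    b = Pattern(("M_e", "H_e"), "nonevent", 0.4, scheme="entropy_mdlp")
    final, log = select_informative([a, b], published_schemes)
    assert final.states == ("M_e", "H_e")
    assert log["tie_break"]


def test_lemma_antisymmetry_and_subpattern_transitivity(published_schemes, rng):
    en = published_schemes["entropy_mdlp"]
    labels = list(en.labels)
    pats = [Pattern(tuple(rng.choice(labels, size=rng.integers(1, 4))),
                    "nonevent", float(rng.uniform(0.3, 1.0)), scheme="entropy_mdlp")
            for _ in range(12)]
    for p1 in pats:
        for p2 in pats:
            if p1 is p2:
                continue
            r12 = lemma1_compare(p1, p2, en, en)
            r21 = lemma1_compare(p2, p1, en, en)
            flip = {"p1_ge_p2": "p2_ge_p1", "p2_ge_p1": "p1_ge_p2",
                    "incomparable": "incomparable"}
            assert r21.relation == flip[r12.relation]
    # transitivity of the sub-pattern rule on a chain
    chain = [Pattern(("L_e",) * k, "nonevent", 0.9 - 0.1 * k, scheme="entropy_mdlp")
             for k in (1, 2, 3)]
    r13 = lemma1_compare(chain[2], chain[0], en, en)
    assert (r13.relation, r13.rule_used) == ("p1_ge_p2", "subpattern")


def test_state_instance_frequency_basis(published_schemes):
    en = published_schemes["entropy_mdlp"]
    # L_e instances are rare (14.1%) vs M_e (85.1%): L_e more informative
    L_e = Pattern(("L_e",), "nonevent", 0.49, scheme="entropy_mdlp")
    M_e = Pattern(("M_e",), "nonevent", 0.95, scheme="entropy_mdlp")
    r = lemma1_compare(L_e, M_e, en, en, frequency_basis="state_instance")
    assert (r.relation, r.rule_used) == ("p1_ge_p2", "frequency")


def test_selector_estimator_interface(cohort, published_schemes):
    seqs = _planted_sequences(cohort)
    sel = PredictivePatternSelector(alpha=0.05, n_folds=10, random_state=0)
    sel.fit(cohort, candidates=[Pattern(("L", "L")), Pattern(("M",))],
            sequences=seqs, schemes={"s": DiscretizationScheme(
                "equal_frequency", (0.0,), ("L", "M"))})
    assert sel.final_pattern_ is not None
    assert sel.get_params()["alpha"] == 0.05
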