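"""ROC/cutoff calibration, KM, Cox and nested-model LR machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from bap1scan.errors import ValidationError
from bap1scan.prognostics import (
    HIGH_BAP1,
    LOW_BAP1,
    auc_rank,
    compartment_comparison,
    cox_univariate,
    dichotomize,
    km_logrank,
    lr_chisq_change,
    roc_with_cutoff,
    sensitivity_specificity,
)
from bap1scan.synthetic import CohortSpec, generate_cohort


class TestAuc:
    def test_perfect_separation(self):
        r = roc_with_cutoff([90, 80, 20, 10], [True, True, False, False])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0
        assert r.specificity == 1.0

    def test_all_tied_scores(self):
        assert auc_rank([50, 50, 50, 50], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_pair_count_oracle(self):
        scores = np.array([90.0, 60.0, 80.0, 70.0])
        state = np.array([1, 0, 1, 0], bool)
        wins = sum(
            1.0 if s1 > s0 else 0.5 if s1 == s0 else 0.0
            for s1 in scores[state]
            for s0 in scores[~state]
        )
        assert auc_rank(scores, state) == pytest.approx(wins / 4)

    @given(st.data())
    @settings(max_examples=50, derandomize=True)
    def test_complement_symmetry(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(data.draw(
            st.lists(st.integers(0, 10), min_size=n, max_size=n)), float)
        state = np.zeros(n, bool)
        k = data.draw(st.integers(1, n - 1))
        state[:k] = True
        assert auc_rank(scores, state) + auc_rank(-scores, state) == pytest.approx(1.0)

    def test_trapezoid_equivalence(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = rng.integers(0, 15, n).astype(float)  # many ties
            state = rng.uniform(size=n) < 0.5
            if state.all() or not state.any():
                continue
            assert auc_rank(scores, state) == pytest.approx(
                roc_auc_score(state, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_with_cutoff([1, 2, 3], [True, True, True])


class TestCutoff:
    def test_cutoff_reproduced_by_dichotomize(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 100, 40)
        state = rng.uniform(size=40) < 0.4
        if not (state.any() and not state.all()):
            pytest.skip("degenerate draw")
        r = roc_with_cutoff(scores, state)
        groups = dichotomize(scores, r.cutoff_pct_negative)
        pred_low = groups == LOW_BAP1
        sens = (pred_low & state).sum() / state.sum()
        spec = (~pred_low & ~state).sum() / (~state).sum()
        assert sens == pytest.approx(r.sensitivity)
        assert spec == pytest.approx(r.specificity)

    def test_cutoff_maximizes_youden(self):
        scores = np.array([10.0, 30.0, 50.0, 70.0, 90.0, 95.0])
        state = np.array([0, 0, 0, 1, 1, 1], bool)
        r = roc_with_cutoff(scores, state)
        best_j = max(
            sum(sensitivity_specificity(scores, state, c)) - 1
            for c in np.unique(scores)
        )
        assert r.sensitivity + r.specificity - 1 == pytest.approx(best_j)
        assert r.cutoff_pct_negative == 70.0

    def test_boundary_score_in_low_group(self):
        assert dichotomize([68.0], 68.0)[0] == LOW_BAP1
        assert dichotomize([0.0], 68.0)[0] == HIGH_BAP1
        assert list(dichotomize([95.0, 10.0], 46.0)) == [LOW_BAP1, HIGH_BAP1]


class TestKaplanMeier:
    def test_product_limit_hand_check(self):
        grp = np.array(["a", "a", "a", "a", "b", "b"])
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 0, 0], bool)
        res = km_logrank(grp, times, events)
        curve = res.curves["a"].set_index("timeline")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.75)
        assert curve.loc[2.0] == pytest.approx(0.50)
        assert curve.loc[3.0] == pytest.approx(0.50)
        assert curve.loc[4.0] == pytest.approx(0.0)

    def test_no_events_reports_p_one_with_warning(self):
        grp = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="no events"):
            res = km_logrank(grp, [5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0])
        assert res.p_value == 1.0
        assert all((c["survival"] == 1.0).all() for c in res.curves.values())

    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(50):
            n = 40
            grp = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            rate = np.where(grp == 1, 0.10, 0.01)
            t = rng.exponential(1 / rate)
            events = t <= 120
            t = np.minimum(t, 120)
            res = km_logrank(np.where(grp == 1, "hi", "lo"), t, events)
            hits += res.p_value < 0.01
        assert hits >= 48  # HR 10 at n=40: essentially always detected


def cox_loglik_two_group(b, times, events, groups):
    """Direct Breslow/Efron partial log-likelihood for a binary covariate
    with untied event times (independent oracle)."""
    ll = 0.0
    for t, e, g in zip(times, events, groups):
        if not e:
            continue
        risk = [gj for tj, gj in zip(times, groups) if tj >= t]
        ll += b * g - np.log(sum(np.exp(b * gj) for gj in risk))
    return ll


class TestCox:
    def test_constant_indicator_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_univariate([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 0, 0])

    def test_four_subject_toy_matches_newton_oracle(self):
        """Hand-written partial likelihood for the 4-subject toy
        (times 1..4, all events, groups 1,0,1,0):
        ll(b) = 2b − ln(2e^b + 2) − ln(e^b + 2) − ln(e^b + 1);
        the oracle solves ll'(b) = 0 by safeguarded Newton (Brent on the
        hand-derived score)."""
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1], bool)
        groups = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_univariate(groups, times, events)

        def score(b):
            eb = np.exp(b)
            return 2 - 2 * eb / (2 * eb + 2) - eb / (eb + 2) - eb / (eb + 1)

        root = optimize.brentq(score, -5, 5, xtol=1e-14)
        # sanity: the hand score is the derivative of the hand log-likelihood
        h = 1e-6
        num = (cox_loglik_two_group(1.0 + h, times, events, groups)
               - cox_loglik_two_group(1.0 - h, times, events, groups)) / (2 * h)
        assert score(1.0) == pytest.approx(num, abs=1e-8)

        assert not res.unstable
        assert res.b == pytest.approx(root, abs=1e-8)
        assert res.hr == pytest.approx(np.exp(root), rel=1e-6)

    def test_two_subject_monotone_likelihood_flagged(self):
        # event in group 1 at t=1, event in group 0 at t=2: the partial
        # likelihood increases monotonically in b, so no finite MLE exists
        res = cox_univariate([1.0, 0.0], [1.0, 2.0], [1, 1])
        assert res.unstable

    def test_ci_invariants(self):
        rng = np.random.default_rng(2)
        n = 60
        grp = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(1 / np.where(grp == 1, 0.05, 0.01))
        events = t <= 100
        res = cox_univariate(grp, np.minimum(t, 100), events)
        assert res.hr == pytest.approx(np.exp(res.b))
        assert res.ci_low == pytest.approx(np.exp(res.b - 1.959963984540054 * res.se))
        assert res.ci_high == pytest.approx(np.exp(res.b + 1.959963984540054 * res.se))
        assert res.ci_low < res.hr < res.ci_high


class TestLrChange:
    @staticmethod
    def _sim(rng, n=80, beta=0.0):
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.02 * np.exp(beta * x)))
        events = t <= 120
        return x, np.minimum(t, 120), events

    def test_constant_added_covariate(self):
        rng = np.random.default_rng(1)
        _, t, e = self._sim(rng)
        res = lr_chisq_change(None, np.full(len(t), 3.0), t, e)
        assert res.lr_chi2 == 0.0
        assert res.p_value == 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        x, t, e = self._sim(rng, beta=0.5)
        base = pd.DataFrame({"z": rng.normal(size=len(t))})
        a = lr_chisq_change(base, x, t, e)
        b = lr_chisq_change(base, 10.0 * x - 3.0, t, e)
        assert a.lr_chi2 == pytest.approx(b.lr_chi2, abs=1e-5)

    def test_duplicate_covariate_rejected(self):
        rng = np.random.default_rng(7)
        x, t, e = self._sim(rng)
        with pytest.raises(ValidationError):
            lr_chisq_change(pd.DataFrame({"x": x}), x, t, e)

    def test_null_model_base_uses_null_loglik(self):
        """LRΔχ² over an empty base equals lifelines' own LR test."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        x, t, e = self._sim(rng, beta=0.7)
        res = lr_chisq_change(None, x, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"duration": t, "event": e.astype(int), "x": x}),
            "duration", "event")
        lrt = cph.log_likelihood_ratio_test()
        assert res.lr_chi2 == pytest.approx(lrt.test_statistic, abs=1e-6)

    def test_planted_strong_covariate_significant(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            n = 60
            grp = (rng.uniform(size=n) < 0.5).astype(float)
            t = rng.exponential(1 / (0.01 * np.exp(np.log(10) * grp)))
            e = t <= 120
            weak = rng.normal(size=n)
            res = lr_chisq_change(pd.DataFrame({"w": weak}), grp,
                                  np.minimum(t, 120), e)
            hits += res.p_value < 0.001
        assert hits >= 18


class TestCompartmentComparison:
    def test_schema_matches_report_tables(self):
        cohort = generate_cohort(CohortSpec(n_patients=40, seed=42))
        res = compartment_comparison(cohort)
        assert set(res.roc_table.columns) == {
            "compartment", "state_variable", "auc", "se", "p", "ci_low",
            "ci_high", "cutoff_pct_negative", "sensitivity", "specificity"}
        assert set(res.cox_table["compartment"]) == {"full", "hot", "cold", "scleral"}
        assert len(res.lr_tcat) == 4
        assert len(res.lr_region) == 12
        assert "ROC" in res.summary()

    def test_roc_cutoffs_attained_on_cohort(self):
        cohort = generate_cohort(CohortSpec(n_patients=40, seed=11))
        res = compartment_comparison(cohort)
        events = cohort["metastasis_event"].to_numpy(bool)
        for comp in ("full", "hot", "cold", "scleral"):
            r = res.roc[(comp, "metastasis")]
            scores = 100.0 - cohort[f"{comp}_pct"].to_numpy(float)
            sens, spec = sensitivity_specificity(scores, events,
                                                 r.cutoff_pct_negative)
            assert sens == pytest.approx(r.sensitivity)
            assert spec == pytest.approx(r.specificity)

    def test_no_metastases_flagged_not_estimable(self):
        cohort = generate_cohort(CohortSpec(n_patients=20, seed=3,
                                            horizon_months=0.0))
        assert not cohort["metastasis_event"].any()
        res = compartment_comparison(cohort)
        assert res.cox == {}
        assert res.km == {}
        assert any("not estimable" in n for n in res.notes)
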