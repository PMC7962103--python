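"""ROC cutoff calibration, dichotomization, Kaplan–Meier / log-rank,
univariate Cox, and likelihood-ratio χ² change for nested Cox models.

The prognostic score of a tumor compartment is its **percent BAP-1
negative cells** (``100 − percent positive``): loss of nuclear BAP-1
marks high metastatic risk, so a higher negative-cell score means a
worse prognosis.

ROC analysis uses the tie-corrected ranking (Mann–Whitney) definition of
the AUC with the Hanley–McNeil nonparametric standard error and an
asymptotic-normal 95 % CI; the p-value is a Hanley–McNeil z-test of
AUC = 0.5.  "Equal emphasis on sensitivity and specificity" is
operationalized as the cutoff maximizing Youden's J = sensitivity +
specificity − 1, ties broken toward higher specificity and then the lower
cutoff.  A tumor whose score is greater than or equal to the cutoff falls
in the BAP-1 *low* (high-risk) group, so the attained sensitivity and
specificity are reproduced exactly by :func:`dichotomize`.

Survival machinery (product-limit estimates, log-rank, Cox partial
likelihood with Efron tie handling) is delegated to lifelines; this
module owns the cutoff logic, the nested-model LRΔχ² bookkeeping and the
compartment-by-compartment orchestration that emits the ROC / Cox /
LRΔχ² tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceWarning
from scipy import stats

from .errors import ValidationError
from .io_formats import COMPARTMENTS

LOW_BAP1 = "low_bap1"    # score >= cutoff: high metastatic risk
HIGH_BAP1 = "high_bap1"


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff_pct_negative: float
    sensitivity: float
    specificity: float
    state_variable: str = "metastasis"


@dataclass(frozen=True)
class CoxResult:
    b: float
    se: float
    wald: float
    p_value: float
    hr: float
    ci_low: float
    ci_high: float
    unstable: bool = False


@dataclass(frozen=True)
class KmResult:
    curves: dict           # group -> survival DataFrame (timeline, survival)
    logrank_chi2: float
    p_value: float
    warning: str = ""


@dataclass(frozen=True)
class LrChange:
    base_model: tuple[str, ...]
    added: str
    lr_chi2: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# ROC

def auc_rank(scores: np.ndarray, state: np.ndarray) -> float:
    """Tie-corrected ranking AUC: the probability that a state-positive
    case out-scores a state-negative one, ties counting one half."""
    scores = np.asarray(scores, float)
    state = np.asarray(state, bool)
    n1 = int(state.sum())
    n0 = int((~state).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both state classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[state].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc) + (n0 - 1) * (q2 - auc * auc))
    return float(np.sqrt(max(var, 0.0) / (n1 * n0)))


def sensitivity_specificity(
    scores: np.ndarray, state: np.ndarray, cutoff: float
) -> tuple[float, float]:
    """Operating point of the rule ``score >= cutoff → predicted positive``."""
    scores = np.asarray(scores, float)
    state = np.asarray(state, bool)
    pred = scores >= cutoff
    sens = float((pred & state).sum() / state.sum())
    spec = float((~pred & ~state).sum() / (~state).sum())
    return sens, spec


def roc_with_cutoff(
    scores, state, state_variable: str = "metastasis"
) -> RocResult:
    """AUC with Hanley–McNeil SE/CI plus the Youden-optimal cutoff.

    ``scores`` are percent-negative-cell values in [0, 100]; ``state`` is
    the boolean outcome.  Candidate cutoffs are the unique observed
    scores (the rule is ``>=``, so these exhaust the distinct operating
    points); the returned cutoff maximizes J, ties broken toward higher
    specificity then the lower cutoff value.
    """
    scores = np.asarray(scores, float)
    state = np.asarray(state, bool)
    if scores.ndim != 1 or scores.shape != state.shape:
        raise ValidationError("scores and state must be 1-D and aligned")
    n1 = int(state.sum())
    n0 = int((~state).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both state classes must be present")

    auc = auc_rank(scores, state)
    se = _hanley_mcneil_se(auc, n1, n0)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    ci_low = max(0.0, auc - 1.959963984540054 * se)
    ci_high = min(1.0, auc + 1.959963984540054 * se)

    best = None  # (J, spec, -cutoff) maximized
    for c in np.unique(scores):
        sens, spec = sensitivity_specificity(scores, state, c)
        key = (sens + spec - 1.0, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    return RocResult(
        auc=auc, se=se, ci_low=ci_low, ci_high=ci_high, p_value=p,
        cutoff_pct_negative=float(cutoff), sensitivity=sens, specificity=spec,
        state_variable=state_variable,
    )


def dichotomize(scores, cutoff: float) -> np.ndarray:
    """Split tumors into BAP-1 low / high groups on the negative-cell score.

    ``score >= cutoff`` → ``low_bap1`` (loss of BAP-1, high risk), else
    ``high_bap1``; the boundary falls in the low group so the ROC's
    attained operating point is reproduced exactly.
    """
    scores = np.asarray(scores, float)
    if not 0 <= cutoff <= 100:
        raise ValidationError("cutoff must lie in [0, 100]")
    return np.where(scores >= cutoff, LOW_BAP1, HIGH_BAP1)


# ---------------------------------------------------------------------------
# survival

def km_logrank(groups, durations, events) -> KmResult:
    """Product-limit curves per group plus the two-sided log-rank test.

    With no events anywhere both curves are identically 1 and the log-rank
    statistic is undefined; the p-value is then reported as 1 with a
    warning note.
    """
    groups = np.asarray(groups)
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    if (durations < 0).any():
        raise ValidationError("durations must be nonnegative")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(labels)}")
    if min((groups == g).sum() for g in labels) == 0:  # pragma: no cover
        raise ValidationError("empty group")

    curves = {}
    for g in labels:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(durations[m], events[m], label=str(g))
        curves[str(g)] = kmf.survival_function_.reset_index().set_axis(
            ["timeline", "survival"], axis=1
        )
    if not events.any():
        note = "no events observed; log-rank undefined, p reported as 1"
        warnings.warn(note, stacklevel=2)
        return KmResult(curves=curves, logrank_chi2=float("nan"), p_value=1.0,
                        warning=note)
    m0 = groups == labels[0]
    res = logrank_test(durations[m0], durations[~m0], events[m0], events[~m0])
    return KmResult(curves=curves, logrank_chi2=float(res.test_statistic),
                    p_value=float(res.p_value))


def _check_ties(ties: str) -> None:
    if ties != "efron":
        raise ValidationError(
            "only Efron tie handling is available; it coincides with the "
            "Breslow approximation whenever event times are untied"
        )


def _fit_cox(df: pd.DataFrame, ties: str = "efron") -> tuple[CoxPHFitter, bool]:
    """Fit a Cox model on ``df`` (duration, event + covariates); returns
    the fitter and an instability flag (monotone likelihood / convergence
    trouble)."""
    _check_ties(ties)
    cph = CoxPHFitter()
    unstable = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="duration", event_col="event")
        except ConvergenceError as err:
            raise ValidationError(f"Cox model failed to converge: {err}") from err
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                unstable = True
    return cph, unstable


def _efron_score_info(b: float, x: np.ndarray, t: np.ndarray, e: np.ndarray
                      ) -> tuple[float, float]:
    """Score (d ll/db) and observed information (−d² ll/db²) of the
    univariate Efron partial likelihood at ``b``."""
    theta = np.exp(b * x)
    xt = x * theta
    xxt = x * xt
    score = 0.0
    info = 0.0
    for tt in np.unique(t[e]):
        tied = (t == tt) & e
        risk = t >= tt
        d = int(tied.sum())
        s0_r, s1_r, s2_r = theta[risk].sum(), xt[risk].sum(), xxt[risk].sum()
        s0_d, s1_d, s2_d = theta[tied].sum(), xt[tied].sum(), xxt[tied].sum()
        score += float(x[tied].sum())
        for l in range(d):
            f = l / d
            s0 = s0_r - f * s0_d
            s1 = s1_r - f * s1_d
            s2 = s2_r - f * s2_d
            score -= s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
    return score, info


def _polish_univariate(b: float, x: np.ndarray, t: np.ndarray, e: np.ndarray,
                       max_iter: int = 25) -> tuple[float, float]:
    """Newton refinement of a univariate Cox estimate to the score root
    (the generic solver stops on log-likelihood flatness, which in double
    precision leaves ~1e-7 in the parameter).  Returns (b, se)."""
    for _ in range(max_iter):
        score, info = _efron_score_info(b, x, t, e)
        if info <= 0:
            break
        step = score / info
        if abs(step) > 1.0:  # safeguard: never polish across a unit step
            break
        b += step
        if abs(step) < 1e-13 * max(1.0, abs(b)):
            break
    _, info = _efron_score_info(b, x, t, e)
    se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    return float(b), float(se)


def cox_univariate(group_indicator, durations, events, ties: str = "efron") -> CoxResult:
    """Univariate Cox regression on a binary (or numeric) covariate.

    Efron tie handling (identical to Breslow when event times are
    untied, the generic case for continuous follow-up).  A monotone
    partial likelihood — e.g. one group entirely event-free — cannot have
    a finite maximizer; the result is flagged ``unstable`` and its numbers
    should not be quoted.
    """
    x = np.asarray(group_indicator, float)
    if np.ptp(x) == 0:
        raise ValidationError("covariate is constant: no contrast to estimate")
    df = pd.DataFrame({
        "duration": np.asarray(durations, float),
        "event": np.asarray(events, bool).astype(int),
        "x": x,
    })
    cph, unstable = _fit_cox(df, ties=ties)
    b = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not unstable:
        b, se = _polish_univariate(b, x, df["duration"].to_numpy(),
                                   df["event"].to_numpy(bool))
    wald = (b / se) ** 2 if se > 0 else float("inf")
    p = float(stats.chi2.sf(wald, 1))
    z975 = 1.959963984540054
    with np.errstate(over="ignore"):  # an unstable fit may have a huge se
        return CoxResult(b=b, se=se, wald=float(wald), p_value=p, hr=float(np.exp(b)),
                         ci_low=float(np.exp(b - z975 * se)),
                         ci_high=float(np.exp(b + z975 * se)),
                         unstable=unstable)


def lr_chisq_change(
    base_covariates: pd.DataFrame | None,
    added_covariate: pd.Series | np.ndarray,
    durations,
    events,
    ties: str = "efron",
    added_name: str = "added",
) -> LrChange:
    """Likelihood-ratio χ² change from adding one covariate to a nested
    Cox base model: ``LRΔχ² = 2 (LL_full − LL_base)``.

    ``base_covariates`` may be ``None`` / empty (the base is then the null
    model).  An added covariate with no variance contributes nothing by
    construction: LRΔχ² = 0, p = 1.  Raises when the added covariate is
    already part of the base (the models would not be nested by one term).
    """
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool).astype(int)
    added = np.asarray(added_covariate, float)
    if base_covariates is not None and added_name in getattr(base_covariates, "columns", []):
        raise ValidationError(f"covariate {added_name!r} already in base model")

    base_cols: list[str] = []
    data = {"duration": durations, "event": events}
    if base_covariates is not None and len(getattr(base_covariates, "columns", [])) > 0:
        for c in base_covariates.columns:
            col = np.asarray(base_covariates[c], float)
            if np.ptp(col) == 0:
                continue  # constant base column carries no information
            data[c] = col
            base_cols.append(c)
        for c in base_cols:
            if np.allclose(data[c], added):
                raise ValidationError("added covariate duplicates a base covariate")

    if np.ptp(added) == 0:
        return LrChange(base_model=tuple(base_cols), added=added_name,
                        lr_chi2=0.0, df=1, p_value=1.0)

    full_df = pd.DataFrame(data | {added_name: added})
    cph_full, _ = _fit_cox(full_df, ties=ties)
    ll_full = float(cph_full.log_likelihood_)
    if base_cols:
        cph_base, _ = _fit_cox(pd.DataFrame(data), ties=ties)
        ll_base = float(cph_base.log_likelihood_)
    else:
        # null model log-likelihood: no covariates
        ll_base = _null_log_likelihood(durations, events, ties=ties)
    lr = max(0.0, 2.0 * (ll_full - ll_base))
    p = float(stats.chi2.sf(lr, 1))
    return LrChange(base_model=tuple(base_cols), added=added_name,
                    lr_chi2=lr, df=1, p_value=p)


def _null_log_likelihood(durations: np.ndarray, events: np.ndarray,
                         ties: str = "efron") -> float:
    """Partial log-likelihood of the covariate-free model (Efron tie
    handling, matching the fitted models).

    With β ≡ 0 every subject has risk score 1, so the l-th of d tied
    events at a time with n subjects at risk contributes −ln(n − l);
    without ties this reduces to −ln(risk-set size) per event.
    """
    _check_ties(ties)
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    ll = 0.0
    for t in np.unique(durations[events]):
        n_risk = int(np.sum(durations >= t))
        d = int(np.sum((durations == t) & events))
        ll -= sum(np.log(n_risk - l) for l in range(d))
    return float(ll)


# ---------------------------------------------------------------------------
# compartment-level orchestration (statsmodels-style model / results)

class CompartmentPrognostics:
    """Prognostic comparison of the four tumor compartments on a cohort.

    Built from a validated cohort DataFrame (one row per patient with
    ``full_pct``/``hot_pct``/``cold_pct``/``scleral_pct`` positivity
    scores, follow-up and event data); ``fit()`` runs, per compartment,
    ROC cutoff calibration against metastasis (and gene expression
    class 2), dichotomization at the metastasis cutoff, Kaplan–Meier +
    log-rank, univariate Cox, and the nested-model LRΔχ² cross-tables
    (region over region, region over AJCC T-category, region over gene
    expression class).
    """

    def __init__(self, cohort: pd.DataFrame, ties: str = "efron"):
        from .io_formats import validate_cohort

        self.cohort = validate_cohort(cohort)
        self.ties = ties

    def _neg_scores(self, compartment: str) -> np.ndarray:
        return 100.0 - self.cohort[f"{compartment}_pct"].to_numpy(float)

    def fit(self) -> "CompartmentPrognosticsResults":
        cohort = self.cohort
        durations = cohort["follow_up_months"].to_numpy(float)
        events = cohort["metastasis_event"].to_numpy(bool)
        gep = cohort["gep_class"]
        class2 = (gep == "2").to_numpy(bool)
        estimable = bool(events.any()) and not bool(events.all())

        roc: dict[tuple[str, str], RocResult] = {}
        groups: dict[str, np.ndarray] = {}
        km: dict[str, KmResult] = {}
        cox: dict[str, CoxResult] = {}
        notes: list[str] = []

        for comp in COMPARTMENTS:
            scores = self._neg_scores(comp)
            if estimable:
                roc[(comp, "metastasis")] = roc_with_cutoff(scores, events, "metastasis")
                cutoff = roc[(comp, "metastasis")].cutoff_pct_negative
                grp = dichotomize(scores, cutoff)
                groups[comp] = grp
                if len(np.unique(grp)) == 2:
                    km[comp] = km_logrank(grp, durations, events)
                    indicator = (grp == LOW_BAP1).astype(float)
                    try:
                        cox[comp] = cox_univariate(indicator, durations, events,
                                                   ties=self.ties)
                    except ValidationError as err:
                        notes.append(f"{comp}: Cox not estimable ({err})")
                else:
                    notes.append(f"{comp}: dichotomization produced one group")
            else:
                notes.append(f"{comp}: no (or only) events; KM/Cox/ROC vs metastasis "
                             "not estimable")
            known = gep.notna().to_numpy()
            if known.sum() >= 2 and 0 < class2[known].sum() < known.sum():
                roc[(comp, "gep_class_2")] = roc_with_cutoff(
                    scores[known], class2[known], "gep_class_2"
                )

        lr_region = self._lr_region_table(groups, durations, events) if groups else None
        lr_tcat = self._lr_over_base_table(
            groups, durations, events,
            base=pd.DataFrame({"t_category": cohort["ajcc_t_category"].astype(float)}),
            base_name="ajcc_t_category",
        ) if groups else None
        lr_gep = None
        known = gep.notna().to_numpy()
        if groups and known.sum() >= 4 and events[known].any():
            lr_gep = self._lr_over_base_table(
                {c: g[known] for c, g in groups.items()},
                durations[known], events[known],
                base=pd.DataFrame({"gep_class_2": class2[known].astype(float)}),
                base_name="gep_class_2",
            )
        return CompartmentPrognosticsResults(
            model=self, roc=roc, groups=groups, km=km, cox=cox,
            lr_region=lr_region, lr_tcat=lr_tcat, lr_gep=lr_gep, notes=notes,
        )

    def _lr_region_table(self, groups, durations, events) -> pd.DataFrame:
        """LRΔχ² of adding each region's group indicator to each other
        region's single-indicator base model."""
        rows = []
        comps = [c for c in COMPARTMENTS if c in groups]
        ind = {c: (groups[c] == LOW_BAP1).astype(float) for c in comps}
        for base_c in comps:
            for add_c in comps:
                if add_c == base_c:
                    continue
                try:
                    res = lr_chisq_change(
                        pd.DataFrame({base_c: ind[base_c]}), ind[add_c],
                        durations, events, ties=self.ties, added_name=add_c,
                    )
                    rows.append({"base": base_c, "added": add_c,
                                 "lr_chi2": res.lr_chi2, "df": res.df,
                                 "p": res.p_value})
                except ValidationError as err:
                    rows.append({"base": base_c, "added": add_c,
                                 "lr_chi2": np.nan, "df": 1, "p": np.nan,
                                 "note": str(err)})
        return pd.DataFrame(rows)

    def _lr_over_base_table(self, groups, durations, events, base: pd.DataFrame,
                            base_name: str) -> pd.DataFrame:
        rows = []
        for comp in [c for c in COMPARTMENTS if c in groups]:
            indicator = (groups[comp] == LOW_BAP1).astype(float)
            try:
                res = lr_chisq_change(base, indicator, durations, events,
                                      ties=self.ties, added_name=comp)
                rows.append({"base": base_name, "added": comp,
                             "lr_chi2": res.lr_chi2, "df": res.df, "p": res.p_value})
            except ValidationError as err:
                rows.append({"base": base_name, "added": comp,
                             "lr_chi2": np.nan, "df": 1, "p": np.nan,
                             "note": str(err)})
        return pd.DataFrame(rows)


@dataclass
class CompartmentPrognosticsResults:
    """Fitted compartment-comparison results with table accessors."""

    model: CompartmentPrognostics
    roc: dict
    groups: dict
    km: dict
    cox: dict
    lr_region: pd.DataFrame | None
    lr_tcat: pd.DataFrame | None
    lr_gep: pd.DataFrame | None
    notes: list = field(default_factory=list)

    @property
    def roc_table(self) -> pd.DataFrame:
        """ROC results, one row per (compartment, state variable)."""
        rows = []
        for (comp, state), r in self.roc.items():
            rows.append({
                "compartment": comp, "state_variable": state, "auc": r.auc,
                "se": r.se, "p": r.p_value, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "cutoff_pct_negative": r.cutoff_pct_negative,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
            })
        return pd.DataFrame(rows)

    @property
    def cox_table(self) -> pd.DataFrame:
        rows = []
        for comp, r in self.cox.items():
            rows.append({"compartment": comp, "b": r.b, "se": r.se,
                         "wald": r.wald, "p": r.p_value, "hr": r.hr,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "unstable": r.unstable})
        return pd.DataFrame(rows)

    @property
    def km_table(self) -> pd.DataFrame:
        rows = []
        for comp, r in self.km.items():
            rows.append({"compartment": comp, "logrank_chi2": r.logrank_chi2,
                         "p": r.p_value, "warning": r.warning})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of all fitted tables."""
        parts = ["Compartment prognostics", "=" * 24]
        if len(self.roc):
            parts += ["", "ROC (percent BAP-1 negative cells):",
                      self.roc_table.round(3).to_string(index=False)]
        if len(self.cox):
            parts += ["", "Univariate Cox (low vs high BAP-1):",
                      self.cox_table.round(3).to_string(index=False)]
        if len(self.km):
            parts += ["", "Log-rank:", self.km_table.round(4).to_string(index=False)]
        if self.lr_region is not None:
            parts += ["", "LRdX2, region over region:",
                      self.lr_region.round(3).to_string(index=False)]
        if self.lr_tcat is not None:
            parts += ["", "LRdX2, region over AJCC T-category:",
                      self.lr_tcat.round(3).to_string(index=False)]
        if self.lr_gep is not None:
            parts += ["", "LRdX2, region over gene expression class:",
                      self.lr_gep.round(3).to_string(index=False)]
        for note in self.notes:
            parts += ["", f"note: {note}"]
        return "\n".join(parts)


def compartment_comparison(cohort: pd.DataFrame, ties: str = "efron"
                           ) -> CompartmentPrognosticsResults:
    """Convenience wrapper: build and fit :class:`CompartmentPrognostics`."""
    return CompartmentPrognostics(cohort, ties=ties).fit()
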