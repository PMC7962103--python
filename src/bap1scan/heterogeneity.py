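"""Per-tumor heterogeneity, tumor volume, group comparisons and the
curve-family screen of heterogeneity against tumor volume.

Intratumor heterogeneity is the hot-spot minus cold-spot positivity in
percentage points (pp).  Tumor volume assumes a semi-ellipsoid:
``V = π/6 · t · lbd²`` with apical thickness ``t`` and largest basal
diameter ``lbd`` in mm.

The curve screen regresses heterogeneity on volume under eleven classic
curve-estimation families (the definitions of the standard statistical
packages' "curve estimation" procedure).  Intrinsically linearizable
families are fitted by least squares on their transformed scale, and R²
and the overall-regression F-test are reported on that same scale:

=============  ==========================  ===========================
family         model                       fitted (linear) form
=============  ==========================  ===========================
linear         y = b0 + b1·x               y ~ x
logarithmic    y = b0 + b1·ln x            y ~ ln x
inverse        y = b0 + b1/x               y ~ 1/x
quadratic      y = b0 + b1·x + b2·x²       y ~ x + x²
cubic          y = b0 + … + b3·x³          y ~ x + x² + x³
compound       y = b0·b1^x                 ln y ~ x
power          y = b0·x^b1                 ln y ~ ln x
s_shaped       y = exp(b0 + b1/x)          ln y ~ 1/x
growth         y = exp(b0 + b1·x)          ln y ~ x
exponential    y = b0·exp(b1·x)            ln y ~ x
logistic       y = 1/(1/u + b0·b1^x)       ln(1/y − 1/u) ~ x
=============  ==========================  ===========================

The logistic upper bound ``u`` is not identified by the data; it is fixed
at ``1.01 · max(y)``.  Families requiring ``ln y`` (or the logistic
transform) are marked unfittable when any response is non-positive; the
other families are still returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

CURVE_FAMILIES = (
    "linear",
    "logarithmic",
    "inverse",
    "quadratic",
    "cubic",
    "compound",
    "power",
    "s_shaped",
    "growth",
    "exponential",
    "logistic",
)

#: number of slope parameters per family (intercept excluded)
_FAMILY_DF = {f: 1 for f in CURVE_FAMILIES} | {"quadratic": 2, "cubic": 3}

#: families whose response is fitted on a log (or logistic) scale
_LOG_Y_FAMILIES = {"compound", "power", "s_shaped", "growth", "exponential", "logistic"}


@dataclass(frozen=True)
class TumorMeasurements:
    """The four compartment scores plus heterogeneity for one tumor."""

    tumor_id: str
    full_pct: float
    hot_pct: float
    cold_pct: float
    scleral_pct: float
    heterogeneity_pp: float
    thickness_t: float | None = None   # mm
    diameter_lbd: float | None = None  # mm
    volume_mm3: float | None = None


@dataclass(frozen=True)
class CurveFitResult:
    family: str
    r_squared: float
    f_statistic: float
    p_value: float
    coefficients: tuple[float, ...] = ()
    fitted: bool = True
    note: str = ""


def heterogeneity(hot_pct: float, cold_pct: float) -> float:
    """Hot-spot minus cold-spot positivity, in percentage points.

    ``hot >= cold`` is guaranteed by the scan's ordering invariant, so a
    negative difference signals a scan bug and raises.
    """
    for v in (hot_pct, cold_pct):
        if not 0 <= v <= 100:
            raise ValidationError("compartment percentages must lie in [0, 100]")
    if hot_pct < cold_pct:
        raise ValidationError(
            f"hot spot ({hot_pct}) below cold spot ({cold_pct}): scan inconsistency"
        )
    return hot_pct - cold_pct


def tumor_volume(t: float, lbd: float) -> float:
    """Semi-ellipsoid tumor volume in mm³: ``π/6 · t · lbd²``.

    ``t`` is the apical thickness and ``lbd`` the largest basal diameter,
    both in mm.
    """
    if not (t > 0 and lbd > 0):
        raise ValidationError("thickness and basal diameter must be > 0")
    return math.pi / 6.0 * t * lbd * lbd


def _design(family: str, x: np.ndarray) -> np.ndarray:
    if family in ("linear", "compound", "growth", "exponential", "logistic"):
        cols = [x]
    elif family in ("logarithmic", "power"):
        cols = [np.log(x)]
    elif family in ("inverse", "s_shaped"):
        cols = [1.0 / x]
    elif family == "quadratic":
        cols = [x, x**2]
    elif family == "cubic":
        cols = [x, x**2, x**3]
    else:  # pragma: no cover
        raise ValidationError(f"unknown curve family {family!r}")
    return np.column_stack([np.ones_like(x)] + cols)


def _response(family: str, y: np.ndarray, u: float) -> np.ndarray:
    if family not in _LOG_Y_FAMILIES:
        return y
    if family == "logistic":
        return np.log(1.0 / y - 1.0 / u)
    return np.log(y)


def fit_curve_families(
    x: np.ndarray, y: np.ndarray, families: tuple[str, ...] = CURVE_FAMILIES
) -> list[CurveFitResult]:
    """Least-squares fit of each curve family, with R² and overall F-test
    on the family's fitted scale.

    Requires ``n >= 5`` observations.  Families whose design needs
    ``ln x`` or ``1/x`` (logarithmic, inverse, power, S-shaped) are marked
    unfittable when any predictor is non-positive; the rest are returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 5:
        raise ValidationError("need at least 5 observations")
    x_positive = bool((x > 0).all())
    _LOG_X_FAMILIES = {"logarithmic", "inverse", "power", "s_shaped"}

    u = 1.01 * float(np.max(y)) if np.max(y) > 0 else 1.0
    results: list[CurveFitResult] = []
    for family in families:
        k = _FAMILY_DF[family]
        if family in _LOG_X_FAMILIES and not x_positive:
            results.append(
                CurveFitResult(family, float("nan"), float("nan"), float("nan"),
                               fitted=False, note="non-positive predictor")
            )
            continue
        if family in _LOG_Y_FAMILIES and not (y > 0).all():
            results.append(
                CurveFitResult(family, float("nan"), float("nan"), float("nan"),
                               fitted=False, note="non-positive response")
            )
            continue
        X = _design(family, x)
        z = _response(family, y, u)
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
        sse = float(resid @ resid)
        sst = float(((z - z.mean()) ** 2).sum())
        if sst <= 1e-12 * max(1.0, abs(z.mean())) ** 2:
            # constant response on the fitted scale: no variance to explain
            r2, f, p = 0.0, 0.0, 1.0
        else:
            r2 = max(0.0, 1.0 - sse / sst)
            dfe = n - k - 1
            if dfe <= 0 or r2 >= 1.0:
                f, p = float("inf"), 0.0
            else:
                f = (r2 / k) / ((1.0 - r2) / dfe)
                p = float(stats.f.sf(f, k, dfe))
        results.append(
            CurveFitResult(family, float(r2), float(f), float(p),
                           coefficients=tuple(float(b) for b in beta))
        )
    return results


def compare_groups(values, grouping, test: str = "t") -> tuple[float, float]:
    """Two-group Student's t (equal variances) or one-way ANOVA.

    Returns ``(statistic, two-sided p)``.  Both are delegated to scipy;
    this wrapper only enforces the grouping contract.
    """
    values = np.asarray(values, float)
    grouping = np.asarray(grouping)
    groups = [values[grouping == g] for g in np.unique(grouping)]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs at least two observations")
    if test == "t":
        if len(groups) != 2:
            raise ValidationError("t-test requires exactly two groups")
        res = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    elif test == "anova":
        res = stats.f_oneway(*groups)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def measurements_table(measurements: list[TumorMeasurements]):
    """Per-tumor measurements as a CSV-ready DataFrame."""
    import pandas as pd

    return pd.DataFrame([vars(m) for m in measurements])
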