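"""Engraftment kinetics on log10 time: fits, T50 inversion, comparisons.

Donor-derived engraftment in each CNS border compartment is modelled as a
straight line in log10(days post-transplant),

    E[corrected_pct] = b0 + b1 * log10(t),

fitted by ordinary least squares per compartment. T50 — the time by which
half of a compartment's macrophages are donor-derived — is obtained by
inverse prediction, ``T50 = 10 ** ((50 - b0) / b1)``, defined only for a
positive slope. Its confidence interval inverts the level-confidence band of
the regression's *mean response*: the two log10-time abscissae where the band
crosses 50 %, back-transformed to days (a Fieller-type calibration interval).
When the slope is too shallow relative to its uncertainty the band never
re-crosses 50 and the upper bound is reported as +infinity.

Compartments are compared within one linear model of corrected percentage on
centred log10(time) crossed with compartment; estimated marginal means (EMMs)
are evaluated at the pooled mean log10-time and all pairwise contrasts are
adjusted with Tukey's studentized-range method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .errors import ExcludedGroupWarning, InsufficientDataError
from .multitest import stars

__all__ = [
    "KineticsFit",
    "fit_turnover",
    "t50_confidence_interval",
    "compare_compartments",
    "EngraftmentKinetics",
    "CompartmentComparison",
]

_T50_TARGET = 50.0  # percent engraftment defining T50


@dataclass(frozen=True)
class KineticsFit:
    """Per-compartment engraftment regression summary.

    ``t50_days`` and ``t50_ci`` are ``None`` when the slope is not positive
    (no crossing of 50 % in forward time); ``significant`` then reports the
    non-significance flag.
    """

    compartment: str
    n: int
    intercept: float
    slope: float
    adj_r2: float
    p_one_sided: float
    t50_days: "float | None"
    t50_ci: "tuple[float, float] | None"
    level: float = 0.95
    n_clamped: int = 0

    @property
    def significant(self) -> bool:
        return self.slope > 0

    def predict(self, days: "float | np.ndarray") -> np.ndarray:
        """Fitted mean engraftment percent at the given days."""
        return self.intercept + self.slope * np.log10(np.asarray(days, dtype=float))


def _prepare_points(points: pd.DataFrame, compartment: "str | None") -> pd.DataFrame:
    if compartment is not None and "compartment" in points.columns:
        points = points.loc[points["compartment"] == compartment]
    if (points["days_post_transplant"] <= 0).any():
        raise ValueError("days_post_transplant must be positive for log10 regression")
    return points


def _band_ci(
    x: np.ndarray, y: np.ndarray, res, level: float
) -> "tuple[float, float]":
    """Invert the mean-response confidence band at 50 % (log10-day scale).

    Returns the two crossings back-transformed to days; lower bound 0.0 and
    upper bound +inf when the band never closes on the respective side.
    """
    n = len(x)
    b0, b1 = res.params
    x_bar = float(x.mean())
    sxx = float(((x - x_bar) ** 2).sum())
    s2 = float(res.ssr / (n - 2))
    x0 = (_T50_TARGET - b0) / b1
    # a noiseless fit: the band collapses onto the line
    if s2 <= 1e-12 * max(1.0, float(np.var(y))):
        t50 = 10.0**x0
        return t50, t50
    t_crit = stats.t.ppf(0.5 + level / 2.0, n - 2)

    def half_width(xv: float) -> float:
        return t_crit * math.sqrt(s2 * (1.0 / n + (xv - x_bar) ** 2 / sxx))

    def upper_band(xv: float) -> float:  # upper band minus target
        return b0 + b1 * xv + half_width(xv) - _T50_TARGET

    def lower_band(xv: float) -> float:  # lower band minus target
        return b0 + b1 * xv - half_width(xv) - _T50_TARGET

    # lower limit: earliest time where the upper band reaches 50
    lo_days = 0.0
    step, left = 1.0, x0
    while step <= 64.0:
        if upper_band(x0 - step) < 0:
            left = x0 - step
            break
        step *= 2.0
    else:
        left = None
    if left is not None:
        lo_days = 10.0 ** brentq(upper_band, left, x0, xtol=1e-12)

    # upper limit: latest time where the lower band still reaches 50
    hi_days = math.inf
    step, right = 1.0, x0
    while step <= 64.0:
        if lower_band(x0 + step) > 0:
            right = x0 + step
            break
        step *= 2.0
    else:
        right = None
    if right is not None:
        hi_days = 10.0 ** brentq(lower_band, x0, right, xtol=1e-12)
    return lo_days, hi_days


def fit_turnover(
    points: pd.DataFrame, compartment: "str | None" = None, level: float = 0.95
) -> KineticsFit:
    """OLS fit of corrected engraftment percent on log10(days).

    ``points`` needs columns ``days_post_transplant`` and ``corrected_pct``
    (a ``clamped`` column, when present, is tallied into ``n_clamped``;
    clamped points are included in the fit, not excluded). At least three
    points with distinct days are required. The slope's p-value is one-sided
    (H1: slope > 0, engraftment increases with time); T50 and its interval
    are computed only for a positive slope.
    """
    pts = _prepare_points(points, compartment)
    days = pts["days_post_transplant"].to_numpy(dtype=float)
    y = pts["corrected_pct"].to_numpy(dtype=float)
    if len(pts) < 3 or len(np.unique(days)) < 3:
        raise InsufficientDataError(
            f"need >= 3 points with distinct days, got {len(np.unique(days))}"
        )
    x = np.log10(days)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    b0, b1 = (float(res.params[0]), float(res.params[1]))
    t_slope = float(res.tvalues[1])
    p_one_sided = float(stats.t.sf(t_slope, res.df_resid))
    n_clamped = int(pts["clamped"].sum()) if "clamped" in pts.columns else 0
    if b1 > 0:
        t50 = 10.0 ** ((_T50_TARGET - b0) / b1)
        ci = _band_ci(x, y, res, level)
    else:
        t50, ci = None, None
    return KineticsFit(
        compartment=compartment if compartment is not None else "all",
        n=len(pts),
        intercept=b0,
        slope=b1,
        adj_r2=float(res.rsquared_adj),
        p_one_sided=p_one_sided,
        t50_days=t50,
        t50_ci=ci,
        level=level,
        n_clamped=n_clamped,
    )


def t50_confidence_interval(
    fit: KineticsFit, points: pd.DataFrame, level: float = 0.95
) -> tuple[float, float]:
    """Recompute the T50 calibration interval from the underlying points."""
    if fit.slope <= 0:
        raise InsufficientDataError(
            "T50 interval is undefined for a non-positive slope"
        )
    pts = _prepare_points(points, fit.compartment if fit.compartment != "all" else None)
    x = np.log10(pts["days_post_transplant"].to_numpy(dtype=float))
    y = pts["corrected_pct"].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return _band_ci(x, y, res, level)


def compare_compartments(points: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """EMM pairwise contrasts between compartments with Tukey adjustment.

    Fits one OLS model ``corrected_pct ~ C(compartment) * centred_log10_days``
    over every compartment with at least ``min_points`` points (smaller
    compartments are excluded with :class:`ExcludedGroupWarning`), evaluates
    each compartment's estimated marginal mean at the pooled mean log10-time,
    and reports all pairwise differences with two-sided unadjusted and
    Tukey (studentized-range) adjusted p-values.
    """
    pts = _prepare_points(points, None).copy()
    sizes = pts.groupby("compartment")["corrected_pct"].size()
    small = sizes[sizes < min_points].index.tolist()
    for name in small:
        warnings.warn(
            f"compartment {name!r} excluded from comparison "
            f"(n={int(sizes[name])} < {min_points})",
            ExcludedGroupWarning,
            stacklevel=2,
        )
    pts = pts.loc[~pts["compartment"].isin(small)]
    comps = sorted(pts["compartment"].unique())
    k = len(comps)
    if k < 2:
        raise InsufficientDataError("need >= 2 compartments with enough points")

    logt = np.log10(pts["days_post_transplant"].to_numpy(dtype=float))
    xc = logt - logt.mean()
    # design: intercept + compartment dummies + slope + interaction slopes
    dummies = pd.get_dummies(pts["compartment"], dtype=float)[comps]
    X = np.column_stack(
        [np.ones(len(pts))]
        + [dummies[c].to_numpy() for c in comps[1:]]
        + [xc]
        + [dummies[c].to_numpy() * xc for c in comps[1:]]
    )
    res = sm.OLS(pts["corrected_pct"].to_numpy(dtype=float), X).fit()
    df_resid = res.df_resid

    # EMM design rows at the pooled mean log10-time (xc = 0)
    emm_rows = np.zeros((k, X.shape[1]))
    emm_rows[:, 0] = 1.0
    for i in range(1, k):
        emm_rows[i, i] = 1.0

    cov = res.cov_params()
    records = []
    for i in range(k):
        for j in range(i + 1, k):
            contrast = emm_rows[i] - emm_rows[j]
            estimate = float(contrast @ res.params)
            se = float(np.sqrt(contrast @ cov @ contrast))
            if se == 0:
                t_stat, p_raw, p_tukey = 0.0, 1.0, 1.0
            else:
                t_stat = estimate / se
                p_raw = float(2 * stats.t.sf(abs(t_stat), df_resid))
                p_tukey = float(
                    stats.studentized_range.sf(abs(t_stat) * math.sqrt(2.0), k, df_resid)
                )
            p_tukey = min(1.0, max(p_tukey, p_raw))  # adjusted never below raw
            records.append(
                {
                    "compartment_a": comps[i],
                    "compartment_b": comps[j],
                    "estimate": estimate,
                    "se": se,
                    "t": t_stat,
                    "df": float(df_resid),
                    "p_unadjusted": p_raw,
                    "p_tukey": p_tukey,
                    "stars": stars(p_tukey),
                }
            )
    return pd.DataFrame(records)


class EngraftmentKinetics(BaseEstimator):
    """Per-compartment engraftment kinetics, scikit-learn style.

    ``fit`` consumes a corrected-engraftment table (columns ``compartment``,
    ``days_post_transplant``, ``corrected_pct``, optional ``clamped``) and
    exposes:

    fits_ : dict of compartment -> :class:`KineticsFit`
    summary_ : one-row-per-compartment DataFrame of all fit fields
    """

    def __init__(self, level: float = 0.95):
        self.level = level

    def fit(self, points: pd.DataFrame, y=None) -> "EngraftmentKinetics":
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level: must lie in (0, 1), got {self.level}")
        fits: dict[str, KineticsFit] = {}
        for comp in sorted(points["compartment"].unique()):
            fits[comp] = fit_turnover(points, compartment=comp, level=self.level)
        self.fits_ = fits
        self.summary_ = pd.DataFrame(
            [
                {
                    "compartment": f.compartment,
                    "n": f.n,
                    "intercept": f.intercept,
                    "slope": f.slope,
                    "adj_r2": f.adj_r2,
                    "p_one_sided": f.p_one_sided,
                    "t50_days": np.nan if f.t50_days is None else f.t50_days,
                    "t50_ci_low": np.nan if f.t50_ci is None else f.t50_ci[0],
                    "t50_ci_high": np.nan if f.t50_ci is None else f.t50_ci[1],
                    "level": f.level,
                    "n_clamped": f.n_clamped,
                }
                for f in fits.values()
            ]
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted mean engraftment percent for rows of (compartment, days)."""
        out = np.empty(len(X), dtype=float)
        for i, (_, row) in enumerate(X.iterrows()):
            out[i] = float(self.fits_[row["compartment"]].predict(row["days_post_transplant"]))
        return out


class CompartmentComparison(BaseEstimator):
    """EMM + Tukey pairwise compartment contrasts as an estimator.

    Attributes
    ----------
    contrasts_ : DataFrame from :func:`compare_compartments`.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, points: pd.DataFrame, y=None) -> "CompartmentComparison":
        self.contrasts_ = compare_compartments(points, min_points=self.min_points)
        return self
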