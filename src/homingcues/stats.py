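"""Regression-stage glue and the power-analysis utility.

This module owns the transforms, codings and comparisons around the
condition-effect regressions - log transforms of the zero-bounded error
measures, ordinal condition coding with forward-difference contrasts, the
quadratic local-minimum check that separates low- from high-clutter
effects, and likelihood-ratio comparisons - while delegating the actual
mixed-model fitting to statsmodels.  It also computes the minimal
detectable difference of a one-sample t-test via the noncentral t
distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.api as sm

from .environment import CONDITIONS

__all__ = [
    "ConditionCoding",
    "PowerSpec",
    "ConditionModelReport",
    "QuadraticFit",
    "forward_difference_contrasts",
    "fit_condition_models",
    "quadratic_minimum",
    "likelihood_ratio_test",
    "one_sample_t_power",
    "minimal_detectable_difference",
]


def forward_difference_contrasts(k: int) -> np.ndarray:
    """Forward-difference contrast matrix for ``k`` ordered levels.

    Returns a ``(k, k-1)`` coding matrix such that, on balanced data, the
    OLS coefficient for column ``j`` equals ``mean(level j) - mean(level
    j+1)`` - i.e. each coefficient is an adjacent-level difference, which
    makes effect reversals across the ordinal conditions directly visible
    as sign changes.
    """
    if k < 2:
        raise ValueError("need at least 2 levels")
    mat = np.zeros((k, k - 1))
    for j in range(k - 1):
        mat[: j + 1, j] = (k - j - 1) / k
        mat[j + 1:, j] = -(j + 1) / k
    return mat


@dataclass(frozen=True)
class ConditionCoding:
    """Ordinal coding of the object-count conditions.

    Object counts are mapped to ordinal levels 0..k-1 in their fixed order;
    the contrast matrix codes the ordinal factor for regression.
    """

    conditions: tuple[int, ...] = CONDITIONS
    scheme: str = "forward_difference"
    contrasts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        k = len(self.conditions)
        if self.scheme == "forward_difference":
            mat = forward_difference_contrasts(k)
        elif self.scheme == "polynomial":
            # orthogonal polynomial coding of the ordinal factor
            raw = np.vander(np.arange(k, dtype=float), k, increasing=True)[:, 1:]
            q, _ = np.linalg.qr(raw - raw.mean(axis=0))
            mat = q
        else:
            raise ValueError(f"unknown coding scheme {self.scheme!r}")
        object.__setattr__(self, "contrasts", mat)

    def level(self, condition_values) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.conditions)}
        return np.asarray([lookup[c] for c in condition_values])

    def design(self, condition_values) -> np.ndarray:
        """Contrast-coded design columns (without intercept)."""
        return self.contrasts[self.level(condition_values)]


@dataclass(frozen=True)
class ConditionModelReport:
    """Coefficients and fit measures of the condition-effect regression,
    with the likelihood-ratio comparison of the participant random effect."""

    fe_params: pd.Series
    loglik: float
    aic: float
    bic: float
    includes_participant_effect: bool
    participant_var: float | None
    lrt_chi2: float | None
    lrt_p: float | None
    converged: bool


def fit_condition_models(summary: pd.DataFrame, response: str = "median",
                         coding: ConditionCoding | None = None,
                         include_participant_effect: bool = True
                         ) -> ConditionModelReport:
    """Fit ``ln(response) ~ condition`` with an optional participant random
    intercept, and compare the two by a likelihood-ratio test.

    ``response`` selects accuracy (``"median"`` -> median_error) or
    precision (``"sd"`` -> sd_error) from a performance summary.  Both are
    zero-bounded, so the model is fitted on the log scale; non-positive
    responses are an error naming the offending rows.  The mixed model is
    fitted by maximum likelihood via statsmodels so its log-likelihood is
    comparable with the fixed-effects-only fit.
    """
    column = {"median": "median_error", "sd": "sd_error"}.get(response)
    if column is None:
        raise ValueError("response must be 'median' or 'sd'")
    coding = coding or ConditionCoding()
    data = summary.dropna(subset=[column])
    y_raw = data[column].to_numpy(float)
    bad = np.flatnonzero(y_raw <= 0.0)
    if bad.size:
        raise ValueError(f"log transform requires positive responses; offending "
                         f"row index(es): {bad.tolist()}")
    y = np.log(y_raw)
    X = sm.add_constant(coding.design(data["condition"]), has_constant="add")
    names = ["intercept"] + [f"contrast_{j + 1}" for j in range(X.shape[1] - 1)]

    ols = sm.OLS(y, X).fit()
    if not include_participant_effect:
        k = X.shape[1] + 1  # coefficients + residual variance
        return ConditionModelReport(
            fe_params=pd.Series(ols.params, index=names),
            loglik=float(ols.llf), aic=float(2 * k - 2 * ols.llf),
            bic=float(k * math.log(len(y)) - 2 * ols.llf),
            includes_participant_effect=False, participant_var=None,
            lrt_chi2=None, lrt_p=None, converged=True)

    if data["participant"].nunique() < 2:
        raise ValueError("participant random effect requires >= 2 participants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = sm.MixedLM(y, X, groups=data["participant"].to_numpy()).fit(reml=False)
    # nested by construction; the boundary null can leave the ML fit a hair
    # below the OLS likelihood numerically, which reads as chi2 = 0
    chi2, p = likelihood_ratio_test(float(ols.llf), max(float(mixed.llf), float(ols.llf)),
                                    df_diff=1)
    k = X.shape[1] + 2  # coefficients + participant variance + residual variance
    return ConditionModelReport(
        fe_params=pd.Series(np.asarray(mixed.fe_params), index=names),
        loglik=float(mixed.llf), aic=float(2 * k - 2 * mixed.llf),
        bic=float(k * math.log(len(y)) - 2 * mixed.llf),
        includes_participant_effect=True,
        participant_var=float(np.asarray(mixed.cov_re)[0, 0]),
        lrt_chi2=chi2, lrt_p=p, converged=bool(mixed.converged))


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic fit of a response over ordinal levels, with
    the vertex location and an F-comparison against the linear fit."""

    a: float
    b: float
    c: float
    vertex: float
    is_minimum: bool
    f_stat: float
    p_value: float
    prefers_quadratic: bool


def quadratic_minimum(levels, response, alpha: float = 0.05) -> QuadraticFit:
    """Fit ``y = a x^2 + b x + c`` over ordinal levels and locate the vertex.

    The vertex ``-b/(2a)`` is a local minimum only when ``a > 0``; when
    ``a <= 0`` the extremum is still reported but flagged.  The nested
    F-test compares the quadratic against the linear fit.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct ordinal levels")
    a, b, c = np.polyfit(x, y, 2)
    lin = np.polyfit(x, y, 1)
    rss_quad = float(np.sum((y - np.polyval([a, b, c], x)) ** 2))
    rss_lin = float(np.sum((y - np.polyval(lin, x)) ** 2))
    df_resid = len(x) - 3
    if df_resid <= 0 or rss_quad == 0.0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (rss_lin - rss_quad) / (rss_quad / df_resid)
        p_value = float(sps.f.sf(f_stat, 1, df_resid))
    vertex = float("nan") if a == 0.0 else -b / (2.0 * a)
    return QuadraticFit(a=float(a), b=float(b), c=float(c), vertex=float(vertex),
                        is_minimum=a > 0.0, f_stat=float(f_stat), p_value=p_value,
                        prefers_quadratic=p_value < alpha)


def likelihood_ratio_test(loglik_reduced: float, loglik_full: float,
                          df_diff: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested models.

    ``chi2 = 2 (l_full - l_reduced)`` with ``df_diff`` degrees of freedom.
    A full model with lower likelihood than its reduced version breaks the
    nesting assumption and triggers a warning (chi2 clipped at 0).
    """
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    chi2 = 2.0 * (loglik_full - loglik_reduced)
    if chi2 < 0.0:
        warnings.warn("full model has lower log-likelihood than the reduced model; "
                      "models may not be nested", stacklevel=2)
        chi2 = 0.0
    return float(chi2), float(sps.chi2.sf(chi2, df_diff))


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a one-sample t-test power computation.

    ``sd`` is the expected standard deviation of the measure (vm), ``n``
    the sample size, ``alpha`` the significance level, ``power`` the target
    1-beta, ``tails`` 1 or 2.
    """

    sd: float
    n: int
    alpha: float = 0.05
    power: float = 0.95
    tails: int = 2

    def __post_init__(self):
        if not (self.sd > 0 and self.n > 1):
            raise ValueError("require sd > 0 and n > 1")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def one_sample_t_power(delta: float, spec: PowerSpec) -> float:
    """Power of a one-sample t-test to detect a true mean shift ``delta``
    at the spec's sd, n, alpha and tails, via the noncentral t
    distribution (both rejection tails counted for a two-sided test)."""
    df = spec.n - 1
    ncp = delta / (spec.sd / math.sqrt(spec.n))
    if spec.tails == 2:
        crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))
    crit = sps.t.ppf(1.0 - spec.alpha, df)
    return float(sps.nct.sf(crit, df, ncp))


def minimal_detectable_difference(spec: PowerSpec, tol: float = 1e-6) -> float:
    """Smallest true mean shift (vm) a one-sample t-test detects with the
    spec's power: root of ``power(delta) - target`` found by bisection,
    exploiting that power is strictly increasing in ``delta``."""
    hi = spec.sd
    while one_sample_t_power(hi, spec) < spec.power:
        hi *= 2.0
        if hi > 1e6 * spec.sd:  # pragma: no cover - unreachable for valid specs
            raise RuntimeError("power target not reachable")
    return float(optimize.brentq(lambda d: one_sample_t_power(d, spec) - spec.power,
                                 0.0, hi, xtol=tol))
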