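"""Logistic quantification of the drift-selection balance.

Along a line of constant K_s change, the thriving probability as a function
of the percent change in mu_max is sigmoid: flat near 0 (drift dominates),
flat near 1 (selection dominates), with a sharp transition between.  The
profile is fit by least squares to the two-parameter logistic

    p_thrive(mu) = 1 / (1 + exp(-k * (mu50 - mu)))

where ``mu50`` is the percent change in mu_max giving 50-50 odds of thriving
and ``k`` controls steepness.  As written the curve increases with mu when
``k`` is negative; ``k`` is stored with that sign convention and its
magnitude used for the spread widths.  Inverting the curve at probability q
gives ``mu(q) = mu50 + ln((1-q)/q) / k``, so the width of the mu_max domain
with p in [1-q, q] is ``2 ln(q/(1-q)) / |k|``:

    spread95 = 2 ln(0.975/0.025) / |k|      (p in [2.5%, 97.5%])
    spread68 = 2 ln(0.84/0.16)   / |k|      (p in [16%, 84%])

These widths measure the zone where neither drift nor selection dominates.
Per crowding condition, mu50 and the spreads are then regressed linearly on
the K_s change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "SpreadEstimate",
    "BalanceRegression",
    "logistic_pthrive",
    "fit_logistic",
    "fit_logistic_glm",
    "bootstrap_ci",
    "spread_from_fit",
    "fit_pmap",
    "regress_balance",
    "BALANCE_COLUMNS",
]

#: minimum observed p_thrive range for a profile to be considered fittable
DEGENERATE_RANGE = 0.1


def logistic_pthrive(mu, k: float, mu50: float):
    """The logistic threshold curve, maximum value 1.

    ``p = 1 / (1 + exp(-k (mu50 - mu)))``; increasing in mu for k < 0.
    """
    mu = np.asarray(mu, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates p to 0 exactly
        out = 1.0 / (1.0 + np.exp(-k * (mu50 - mu)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LogisticFit:
    k: float
    mu50: float
    converged: bool
    extrapolated: bool          # mu50 outside the swept dmu range
    residual_ss: float
    n_points: int
    n_initial: Optional[int] = None
    spacing: Optional[float] = None
    dKs_pct: Optional[float] = None

    def predict(self, mu):
        return logistic_pthrive(mu, self.k, self.mu50)


@dataclass(frozen=True)
class SpreadEstimate:
    spread95: float
    spread68: float


def fit_logistic(dmu_pct, p_thrive, n_initial: Optional[int] = None,
                 spacing: Optional[float] = None,
                 dKs_pct: Optional[float] = None) -> LogisticFit:
    """Least-squares logistic fit of a (dmu_pct, p_thrive) profile.

    Minimises ``sum (p_obs - p_model)^2`` over (k, mu50).  Profiles whose
    observed probability range is below 0.1 (all near 0 or all near 1) are
    degenerate: mu50 is unidentifiable and a non-converged fit is returned
    rather than an exception.
    """
    mu = np.asarray(dmu_pct, dtype=float)
    p = np.asarray(p_thrive, dtype=float)
    if mu.size != p.size:
        raise ValueError("dmu_pct and p_thrive must have equal length")
    if mu.size < 4:
        raise ValueError(f"need >= 4 profile points, got {mu.size}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_thrive values must lie in [0, 1]")
    order = np.argsort(mu)
    mu, p = mu[order], p[order]
    meta = dict(n_initial=n_initial, spacing=spacing, dKs_pct=dKs_pct)

    if p.max() - p.min() < DEGENERATE_RANGE:
        return LogisticFit(k=0.0, mu50=math.nan, converged=False,
                           extrapolated=False,
                           residual_ss=float(np.sum((p - p.mean()) ** 2)),
                           n_points=mu.size, **meta)

    # initial guess: mu50 from the interpolated 0.5 crossing, k from the
    # local slope there (dp/dmu = -k/4 at mu50)
    crossings = np.nonzero(np.diff(np.sign(p - 0.5)) != 0)[0]
    if crossings.size:
        i = crossings[0]
        frac = (0.5 - p[i]) / (p[i + 1] - p[i])
        mu50_0 = mu[i] + frac * (mu[i + 1] - mu[i])
    else:
        mu50_0 = float(mu[np.argmin(np.abs(p - 0.5))])
    span = mu.max() - mu.min()
    rise = p[-1] - p[0]
    slope = rise / span if span > 0 else 0.0
    k0 = -4.0 * slope if abs(slope) > 1e-8 else -0.1

    def residuals(theta):
        k, mu50 = theta
        return logistic_pthrive(mu, k, mu50) - p

    # profiles with a large observed rise are well identified; shallow ones
    # get extra starts to escape flat-gradient regions
    starts = (k0,) if p.max() - p.min() > 0.5 else (k0, k0 / 5.0, k0 * 5.0)
    best = None
    for k_start in starts:
        sol = least_squares(residuals, x0=[k_start, mu50_0], method="lm",
                            max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    k_hat, mu50_hat = best.x
    converged = bool(best.success) and abs(k_hat) > 1e-8
    extrapolated = bool(mu50_hat < mu.min() or mu50_hat > mu.max())
    return LogisticFit(k=float(k_hat), mu50=float(mu50_hat),
                       converged=converged, extrapolated=extrapolated,
                       residual_ss=float(2 * best.cost), n_points=mu.size,
                       **meta)


def fit_logistic_glm(dmu_pct, n_thrive, n_seeds,
                     n_initial: Optional[int] = None,
                     spacing: Optional[float] = None,
                     dKs_pct: Optional[float] = None) -> tuple[LogisticFit, dict]:
    """Binomial-GLM alternative to the least-squares profile fit.

    The threshold curve is a logit-link GLM in disguise:
    ``logit(p) = k*mu50 - k*mu``, so a binomial regression of the thrive
    counts on dmu gives ``k = -slope`` and ``mu50 = -intercept/slope`` with
    likelihood-based standard errors (delta method for mu50).  Useful for
    uncertainty quantification; the least-squares route remains the
    canonical profile fit.
    """
    mu = np.asarray(dmu_pct, dtype=float)
    y = np.column_stack([
        np.asarray(n_thrive, dtype=float),
        np.asarray(n_seeds, dtype=float) - np.asarray(n_thrive, dtype=float),
    ])
    X = sm.add_constant(mu)
    model = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    a, b = model.params
    if abs(b) < 1e-12:
        raise ValueError("flat profile: slope ~ 0, mu50 unidentifiable")
    k = -float(b)
    mu50 = -float(a / b)
    fit = LogisticFit(k=k, mu50=mu50, converged=bool(model.converged),
                      extrapolated=bool(mu50 < mu.min() or mu50 > mu.max()),
                      residual_ss=float(np.sum(
                          (logistic_pthrive(mu, k, mu50) - y[:, 0] / y.sum(1)) ** 2)),
                      n_points=mu.size, n_initial=n_initial, spacing=spacing,
                      dKs_pct=dKs_pct)
    cov = model.cov_params()
    var_k = float(cov[1, 1])
    # delta method for mu50 = -a/b
    grad = np.array([-1.0 / b, a / b**2])
    var_mu50 = float(grad @ cov @ grad)
    return fit, {"se_k": math.sqrt(var_k), "se_mu50": math.sqrt(var_mu50),
                 "deviance": float(model.deviance)}


def spread_from_fit(fit: LogisticFit) -> SpreadEstimate:
    """Closed-form spread widths from a converged fit.

    Derived by inverting the fitted curve: the mu at probability q is
    ``mu50 + ln((1-q)/q)/k``, so the [1-q, q] width is ``2 ln(q/(1-q))/|k|``.
    """
    if not fit.converged:
        raise ValueError("spreads are undefined for a non-converged fit")
    ak = abs(fit.k)
    return SpreadEstimate(
        spread95=2.0 * math.log(0.975 / 0.025) / ak,
        spread68=2.0 * math.log(0.84 / 0.16) / ak,
    )


def bootstrap_ci(dmu_pct, p_thrive, n_trials: int, n_boot: int = 199,
                 level: float = 0.95, rng: Optional[np.random.Generator] = None,
                 method: str = "normal") -> dict:
    """Parametric bootstrap confidence intervals for (k, mu50).

    The observed profile is fit, then ``n_boot`` profiles are redrawn as
    binomial(n_trials, fitted p) at each dmu level and refit.  The default
    interval is the normal-approximation bootstrap interval, estimate +/-
    t * bootstrap standard error with Student-t critical values at
    ``n_points - 2`` residual degrees of freedom (profiles have few points,
    so the asymptotic z value is optimistic).  In calibration experiments
    on this design the bootstrap standard errors are accurate while the
    percentile and basic intervals undercover the steepness parameter,
    whose bootstrap distribution is noticeably skewed.  ``percentile`` and
    ``basic`` variants remain available.  For joint statements about
    (k, mu50), apply a Bonferroni-adjusted ``level`` per parameter.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if method not in ("normal", "percentile", "basic"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    mu = np.asarray(dmu_pct, dtype=float)
    fit = fit_logistic(mu, p_thrive)
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    p_hat = np.clip(logistic_pthrive(mu, fit.k, fit.mu50), 0.0, 1.0)
    ks, mu50s = [], []
    for _ in range(n_boot):
        p_b = rng.binomial(n_trials, p_hat) / n_trials
        fb = fit_logistic(mu, p_b)
        if fb.converged:
            ks.append(fb.k)
            mu50s.append(fb.mu50)
    from scipy import stats as _stats

    alpha = 100.0 * (1.0 - level) / 2.0
    df = max(mu.size - 2, 1)
    z = _stats.t.ppf(1.0 - (1.0 - level) / 2.0, df=df)
    out = {"fit": fit, "n_boot_converged": len(ks)}
    for name, est, boots in (("k", fit.k, np.asarray(ks)),
                             ("mu50", fit.mu50, np.asarray(mu50s))):
        if method == "normal":
            se = float(boots.std(ddof=1))
            lo, hi = est - z * se, est + z * se
        else:
            lo, hi = np.percentile(boots, [alpha, 100.0 - alpha])
            if method == "basic":
                lo, hi = 2 * est - hi, 2 * est - lo
        out[name] = (float(lo), float(hi))
    return out


BALANCE_COLUMNS = [
    "n_initial", "spacing", "dKs_pct", "k", "mu50",
    "spread95", "spread68", "converged", "extrapolated", "residual_ss",
]


def fit_pmap(pmap: pd.DataFrame) -> pd.DataFrame:
    """Fit every (crowding, K_s-line) cross-section of a long-form map.

    Returns one row per (n_initial, spacing, dKs_pct) with the fitted
    parameters and spreads (NaN spreads for non-converged fits).
    """
    rows = []
    for (n0, sp_, dks), grp in pmap.groupby(["n_initial", "spacing", "dKs_pct"],
                                            sort=True):
        if len(grp) < 4:
            logger.warning(
                "fit_pmap: skipping (n=%s, spacing=%s, dKs=%s): only %d "
                "profile points (>= 4 required)", n0, sp_, dks, len(grp),
            )
            continue
        fit = fit_logistic(grp["dmu_pct"], grp["p_thrive"],
                           n_initial=int(n0), spacing=float(sp_),
                           dKs_pct=float(dks))
        if fit.converged:
            spread = spread_from_fit(fit)
            s95, s68 = spread.spread95, spread.spread68
        else:
            s95 = s68 = math.nan
        rows.append({
            "n_initial": int(n0), "spacing": float(sp_), "dKs_pct": float(dks),
            "k": fit.k, "mu50": fit.mu50, "spread95": s95, "spread68": s68,
            "converged": fit.converged, "extrapolated": fit.extrapolated,
            "residual_ss": fit.residual_ss,
        })
    return pd.DataFrame(rows, columns=BALANCE_COLUMNS)


@dataclass(frozen=True)
class BalanceRegression:
    response: str
    n_initial: int
    spacing: float
    slope: float
    intercept: float
    r_squared: float
    slope_pvalue: float
    n_used: int
    n_excluded: int


def regress_balance(balance: pd.DataFrame, response: str = "mu50"
                    ) -> list[BalanceRegression]:
    """OLS of a balance parameter on dKs_pct, per crowding condition.

    Non-converged fits are excluded (with a logged count); conditions with
    fewer than 3 usable K_s lines raise.
    """
    if response not in ("mu50", "spread95", "spread68"):
        raise ValueError(f"unsupported response {response!r}")
    out = []
    for (n0, sp_), grp in balance.groupby(["n_initial", "spacing"], sort=True):
        usable = grp[grp["converged"] & np.isfinite(grp[response])]
        n_excl = len(grp) - len(usable)
        if n_excl:
            logger.info(
                "regress_balance %s n=%s spacing=%s: excluded %d non-converged fits",
                response, n0, sp_, n_excl,
            )
        if len(usable) < 3:
            raise ValueError(
                f"crowding condition (n={n0}, spacing={sp_}) has only "
                f"{len(usable)} converged fits; >= 3 required"
            )
        X = sm.add_constant(usable["dKs_pct"].to_numpy())
        model = sm.OLS(usable[response].to_numpy(), X).fit()
        out.append(BalanceRegression(
            response=response, n_initial=int(n0), spacing=float(sp_),
            slope=float(model.params[1]), intercept=float(model.params[0]),
            r_squared=float(model.rsquared),
            slope_pvalue=float(model.pvalues[1]),
            n_used=len(usable), n_excluded=int(n_excl),
        ))
    return out
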