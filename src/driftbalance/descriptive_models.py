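"""Descriptive regression models of the p_thrive surface.

Two model families summarise how the thriving probability depends on the
kinetic alterations (``mu_p``, ``K_p``: percent changes in mu_max and K_s),
the initial population size ``N0`` and the spacing ``s_i``:

* a multiple linear regression (MLR) on the transformed response
  ``log(p/(1 - p + eps) + eps)`` with a small pseudo-probability
  ``eps = 1e-6`` guarding the log and the division at p = 0 and 1; and
* a generalized additive model (GAM) fitted directly to ``p_thrive`` with
  penalized-regression-spline smooths of the main effects and
  tensor-product smooths of the two- and three-way interactions, plus a
  factor-by smooth of ``N0`` within each spacing level.

The GAM is Gaussian on the probability scale and its predictions are
deliberately not clipped to [0, 1] (a clipping flag is reported instead);
the MLR's predictions are back-transformed and clipped before computing the
probability-scale RMSE so the two families are directly comparable.

The smoothing machinery is the standard penalized B-spline construction:
centred marginal bases with second-order difference penalties (so a fully
penalized smooth shrinks to a straight line, not to zero), ti()-style
tensor products of centred marginals for interactions, smoothing parameters
chosen by generalized cross-validation, and Wald-type term tests using the
Bayesian posterior covariance of the penalized coefficients.  Backward term
selection drops the least significant of the highest-order non-significant
terms, never removing a term nested inside a retained significant
interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "EPSILON",
    "logit_eps",
    "inv_logit_eps",
    "Term",
    "ModelSpec",
    "ModelFit",
    "mlr_spec_study",
    "mlr_spec_main_effects",
    "gam_spec_study",
    "gam_spec_main_effects",
    "factorial_spec",
    "fit_mlr",
    "fit_gam",
    "fit_model",
    "backward_select",
    "model_metrics",
    "VARIABLES",
]

#: pseudo-probability guarding the log transform
EPSILON = 1.0e-6

#: model variables -> columns of the long-form probability map
VARIABLES = {
    "mu_p": "dmu_pct",
    "K_p": "dKs_pct",
    "N0": "n_initial",
    "s_i": "spacing",
}


def logit_eps(p, eps: float = EPSILON):
    """``log(p / (1 - p + eps) + eps)``, exactly as defined for the MLR."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.log(p / (1.0 - p + eps) + eps)
    return float(out) if out.ndim == 0 else out


def inv_logit_eps(y, eps: float = EPSILON):
    """Exact inverse of :func:`logit_eps` (before any clipping)."""
    y = np.asarray(y, dtype=float)
    t = np.exp(y) - eps
    out = t * (1.0 + eps) / (1.0 + t)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One model term: a product of variables, linear or smoothed.

    ``smooth=False`` gives the plain product column (MLR term).  With
    ``smooth=True`` a univariate penalized spline (one variable) or a
    ti()-style tensor-product smooth (several variables) is built.  ``by``
    names a factor variable whose (non-reference) levels each get their own
    copy of the smooth.
    """

    vars: tuple[str, ...]
    smooth: bool = False
    by: Optional[str] = None
    k: int = 5                  # marginal basis dimension target

    def __post_init__(self):
        if not self.vars:
            raise ValueError("a term needs at least one variable")

    @property
    def order(self) -> int:
        return len(self.vars) + (1 if self.by else 0)

    @property
    def name(self) -> str:
        inner = ",".join(self.vars)
        if self.smooth:
            return f"s({inner},by={self.by})" if self.by else f"s({inner})"
        return ":".join(self.vars)

    def involves(self) -> frozenset[str]:
        s = set(self.vars)
        if self.by:
            s.add(self.by)
        return frozenset(s)


@dataclass(frozen=True)
class ModelSpec:
    kind: str                           # "mlr" | "gam"
    response: str                       # "logit_eps" | "identity"
    terms: tuple[Term, ...]
    dropped: tuple[str, ...] = ()       # selection trail
    eps: float = EPSILON                # pseudo-probability of the transform

    def without(self, term: Term) -> "ModelSpec":
        return replace(
            self,
            terms=tuple(t for t in self.terms if t != term),
            dropped=self.dropped + (term.name,),
        )


def mlr_spec_study() -> ModelSpec:
    """The published MLR term set: four mains plus mu_p:s_i and K_p:s_i."""
    return ModelSpec(
        kind="mlr", response="logit_eps",
        terms=(
            Term(("mu_p",)), Term(("K_p",)), Term(("N0",)), Term(("s_i",)),
            Term(("mu_p", "s_i")), Term(("K_p", "s_i")),
        ),
    )


def mlr_spec_main_effects() -> ModelSpec:
    return ModelSpec(
        kind="mlr", response="logit_eps",
        terms=tuple(Term((v,)) for v in VARIABLES),
    )


def gam_spec_study() -> ModelSpec:
    """The published GAM term set: smooth mains, tensor interactions and the
    factor-by smooth of N0 within spacing levels."""
    return ModelSpec(
        kind="gam", response="identity",
        terms=(
            Term(("mu_p",), smooth=True),
            Term(("K_p",), smooth=True),
            Term(("N0",), smooth=True),
            Term(("s_i",), smooth=True),
            Term(("mu_p", "K_p"), smooth=True),
            Term(("mu_p", "s_i"), smooth=True),
            Term(("K_p", "s_i"), smooth=True),
            Term(("N0",), smooth=True, by="s_i"),
            Term(("mu_p", "K_p", "N0"), smooth=True),
            Term(("mu_p", "K_p", "s_i"), smooth=True),
        ),
    )


def gam_spec_main_effects() -> ModelSpec:
    return ModelSpec(
        kind="gam", response="identity",
        terms=tuple(Term((v,), smooth=True) for v in VARIABLES),
    )


def factorial_spec(kind: str = "mlr", max_order: int = 3) -> ModelSpec:
    """Full factorial starting spec (all products up to ``max_order``-way)
    for backward selection."""
    from itertools import combinations

    names = list(VARIABLES)
    terms = []
    for r in range(1, max_order + 1):
        for combo in combinations(names, r):
            terms.append(Term(combo, smooth=(kind == "gam")))
    response = "logit_eps" if kind == "mlr" else "identity"
    return ModelSpec(kind=kind, response=response, terms=tuple(terms))


# --------------------------------------------------------------------------
# smooth bases
# --------------------------------------------------------------------------

@dataclass
class _MarginalBasis:
    """Centred penalized basis for one variable, frozen at fit time."""

    var: str
    kind: str                   # "bspline" | "poly"
    transform: np.ndarray       # centring constraint map Z (k x k-1)
    penalty: np.ndarray         # penalty on the constrained coefficients
    knots: Optional[np.ndarray] = None
    degree: int = 3
    x_mean: float = 0.0
    x_scale: float = 1.0
    n_poly: int = 0

    def raw(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "bspline":
            spl = BSpline.design_matrix(
                np.clip(x, self.knots[self.degree], self.knots[-self.degree - 1]),
                self.knots, self.degree,
            )
            return np.asarray(spl.todense())
        z = (x - self.x_mean) / self.x_scale
        return np.column_stack([z**d for d in range(1, self.n_poly + 1)])

    def design(self, x: np.ndarray) -> np.ndarray:
        return self.raw(np.asarray(x, dtype=float)) @ self.transform


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _build_marginal(var: str, x: np.ndarray, k: int) -> _MarginalBasis:
    """Centred basis + penalty whose null space is the (centred) linear
    trend, so lambda -> inf shrinks the smooth to a straight line."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError(f"variable {var!r} is constant; cannot smooth it")
    if uniq.size <= 4:
        # few distinct levels: polynomial basis of maximal identifiable degree
        n_poly = uniq.size - 1
        scale = x.std() or 1.0
        raw = np.column_stack(
            [((x - x.mean()) / scale) ** d for d in range(1, n_poly + 1)]
        )
        P = np.diag([0.0] + [1.0] * (n_poly - 1))  # penalize curvature only
        basis = _MarginalBasis(var=var, kind="poly", transform=np.eye(n_poly),
                               penalty=P, x_mean=float(x.mean()),
                               x_scale=float(scale), n_poly=n_poly)
        raw_cols = raw
    else:
        k = max(4, min(k, uniq.size))
        degree = 3
        # P-spline convention: uniform knots extended past the data range so
        # the coefficient-difference penalty's null space is exactly the
        # linear functions (clamped knots would break that)
        lo, hi = float(uniq.min()), float(uniq.max())
        n_intervals = k - degree
        h = (hi - lo) / n_intervals
        knots = lo + h * np.arange(-degree, n_intervals + degree + 1)
        basis = _MarginalBasis(var=var, kind="bspline", transform=np.eye(k),
                               penalty=_difference_penalty(k), knots=knots,
                               degree=degree)
        raw_cols = basis.raw(x)
    # sum-to-zero constraint: project out the constant direction
    c = raw_cols.mean(axis=0)
    norm = np.linalg.norm(c)
    if norm < 1e-12:
        Z = np.eye(raw_cols.shape[1])
    else:
        q, _ = np.linalg.qr(np.column_stack([c / norm,
                                             np.eye(len(c))]))
        Z = q[:, 1:len(c)]
    basis.transform = basis.transform @ Z
    basis.penalty = Z.T @ basis.penalty @ Z
    return basis


@dataclass
class _TermBlock:
    """Design columns + penalty for one fitted term."""

    term: Term
    builder: Callable[[pd.DataFrame], np.ndarray]
    penalty: Optional[np.ndarray]       # None for unpenalized (linear) terms
    ncol: int


def _column(df: pd.DataFrame, var: str) -> np.ndarray:
    col = VARIABLES.get(var, var)
    if col not in df.columns:
        raise ValueError(f"probability map lacks column {col!r} for variable {var!r}")
    return df[col].to_numpy(dtype=float)


def _rowwise_kron(mats: Sequence[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def _build_term_block(term: Term, df: pd.DataFrame) -> _TermBlock:
    if not term.smooth:
        def build_linear(d: pd.DataFrame, vars_=term.vars) -> np.ndarray:
            col = np.ones(len(d))
            for v in vars_:
                col = col * _column(d, v)
            return col[:, None]
        return _TermBlock(term=term, builder=build_linear, penalty=None, ncol=1)

    marginals = [_build_marginal(v, _column(df, v), term.k) for v in term.vars]

    def smooth_design(d: pd.DataFrame, margs=marginals) -> np.ndarray:
        return _rowwise_kron([m.design(_column(d, m.var)) for m in margs])

    # tensor penalty: sum over directions of P_j kron identities (single
    # smoothing parameter per term)
    sizes = [m.transform.shape[1] for m in marginals]
    P = np.zeros((int(np.prod(sizes)), int(np.prod(sizes))))
    for j, m in enumerate(marginals):
        mats = [np.eye(s) for s in sizes]
        mats[j] = m.penalty
        block = mats[0]
        for mm in mats[1:]:
            block = np.kron(block, mm)
        P += block

    if term.by is None:
        return _TermBlock(term=term, builder=smooth_design, penalty=P,
                          ncol=int(np.prod(sizes)))

    # factor-by smooth: one copy of the smooth per non-reference by-level
    by_levels = np.unique(_column(df, term.by))
    active = by_levels[1:]          # reference level absorbed by the main smooth

    def by_design(d: pd.DataFrame, margs=marginals, levels=active,
                  by_var=term.by) -> np.ndarray:
        base = _rowwise_kron([m.design(_column(d, m.var)) for m in margs])
        byc = _column(d, by_var)
        return np.hstack([base * (byc == lv)[:, None] for lv in levels])

    nb = len(active)
    Pby = np.kron(np.eye(nb), P)
    return _TermBlock(term=term, builder=by_design, penalty=Pby,
                      ncol=nb * int(np.prod(sizes)))


# --------------------------------------------------------------------------
# fitted model container
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    spec: ModelSpec
    coefficients: np.ndarray
    term_slices: dict[str, slice]
    term_pvalues: dict[str, float]
    term_edf: dict[str, float]
    rmse: float                     # probability scale
    r_squared: float                # probability scale
    aic: float
    edf_total: float
    sigma2: float
    lambdas: Optional[dict[str, float]]
    predictions_clipped: bool       # any raw prediction outside [0, 1]
    n_obs: int
    _blocks: list = field(default_factory=list, repr=False)

    def predict(self, df: pd.DataFrame, clip: Optional[bool] = None) -> np.ndarray:
        """Predicted p_thrive.  By default MLR predictions are clipped to
        [0, 1] after back-transform and GAM predictions are left unclipped."""
        X = _assemble_design(self._blocks, df)
        eta = X @ self.coefficients
        if self.spec.response == "logit_eps":
            p = inv_logit_eps(eta, self.spec.eps)
            if clip is None or clip:
                p = np.clip(p, 0.0, 1.0)
            return p
        if clip:
            return np.clip(eta, 0.0, 1.0)
        return eta


def _assemble_design(blocks: list[_TermBlock], df: pd.DataFrame) -> np.ndarray:
    cols = [np.ones((len(df), 1))]
    cols += [b.builder(df) for b in blocks]
    return np.hstack(cols)


def _response(spec: ModelSpec, pmap: pd.DataFrame) -> np.ndarray:
    p = pmap["p_thrive"].to_numpy(dtype=float)
    return logit_eps(p, spec.eps) if spec.response == "logit_eps" else p


def _prob_scale_metrics(p_obs: np.ndarray, p_hat_raw: np.ndarray,
                        clip_for_rmse: bool) -> tuple[float, float, bool]:
    outside = bool(np.any((p_hat_raw < 0) | (p_hat_raw > 1)))
    p_hat = np.clip(p_hat_raw, 0.0, 1.0) if clip_for_rmse else p_hat_raw
    rmse = float(np.sqrt(np.mean((p_obs - p_hat) ** 2)))
    ss_tot = float(np.sum((p_obs - p_obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum((p_obs - p_hat) ** 2)) / ss_tot if ss_tot > 0 else math.nan
    return rmse, r2, outside


# --------------------------------------------------------------------------
# MLR
# --------------------------------------------------------------------------

def fit_mlr(pmap: pd.DataFrame, spec: Optional[ModelSpec] = None) -> ModelFit:
    """OLS of the eps-guarded logit of p_thrive on the model's product terms.

    Predictions are back-transformed through the exact inverse of the
    transform and clipped to [0, 1] before the probability-scale RMSE, so
    MLR and GAM errors are commensurable.  A rank-deficient design raises,
    naming the aliased terms.
    """
    spec = spec or mlr_spec_study()
    if spec.kind != "mlr":
        raise ValueError("fit_mlr requires an MLR spec")
    blocks = [_build_term_block(t, pmap) for t in spec.terms]
    X = _assemble_design(blocks, pmap)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _find_aliased(blocks, X)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns); "
            f"aliased terms: {aliased}"
        )
    y = _response(spec, pmap)
    ols = sm.OLS(y, X).fit()
    term_slices, term_p = {}, {}
    pos = 1
    for b in blocks:
        sl = slice(pos, pos + b.ncol)
        term_slices[b.term.name] = sl
        term_p[b.term.name] = float(ols.pvalues[sl.start])  # single-column terms
        pos += b.ncol
    p_obs = pmap["p_thrive"].to_numpy(dtype=float)
    p_hat_raw = inv_logit_eps(X @ ols.params, spec.eps)
    rmse, r2, outside = _prob_scale_metrics(p_obs, p_hat_raw, clip_for_rmse=True)
    return ModelFit(
        spec=spec, coefficients=np.asarray(ols.params),
        term_slices=term_slices, term_pvalues=term_p,
        term_edf={b.term.name: float(b.ncol) for b in blocks},
        rmse=rmse, r_squared=r2, aic=float(ols.aic),
        edf_total=float(X.shape[1]), sigma2=float(ols.mse_resid),
        lambdas=None, predictions_clipped=outside, n_obs=len(pmap),
        _blocks=blocks,
    )


def _find_aliased(blocks: list[_TermBlock], X: np.ndarray) -> list[str]:
    names = []
    kept = [np.ones((X.shape[0], 1))]
    for b in blocks:
        cols = X[:, sum(k.shape[1] for k in kept):][:, : b.ncol]
        trial = np.hstack(kept + [cols])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            names.append(b.term.name)
        else:
            kept.append(cols)
    return names


# --------------------------------------------------------------------------
# GAM
# --------------------------------------------------------------------------

def _penalty_matrix(blocks: list[_TermBlock], lambdas: np.ndarray,
                    p_total: int) -> np.ndarray:
    P = np.zeros((p_total, p_total))
    pos = 1
    for b, lam in zip(blocks, lambdas):
        if b.penalty is not None:
            P[pos:pos + b.ncol, pos:pos + b.ncol] = lam * b.penalty
        pos += b.ncol
    return P


def _gam_solve(XtX, Xty, blocks, lambdas, ridge: float = 1e-10):
    p = XtX.shape[0]
    M = XtX + _penalty_matrix(blocks, lambdas, p) + ridge * np.eye(p)
    c, low = cho_factor(M)
    beta = cho_solve((c, low), Xty)
    A = cho_solve((c, low), XtX)            # influence-related matrix
    return beta, A, (c, low)


def _gcv_score(y, X, XtX, Xty, blocks, log_lambdas):
    beta, A, _ = _gam_solve(XtX, Xty, blocks, 10.0 ** log_lambdas)
    resid = y - X @ beta
    edf = float(np.trace(A))
    n = y.size
    denom = max(n - edf, 1e-6)
    return n * float(resid @ resid) / denom**2


def _pick_smoothest(grid: np.ndarray, scores: list[float]) -> float:
    """Largest log-lambda whose GCV ties the minimum (relative 1e-6): when
    the data cannot distinguish, prefer the smoother model."""
    sc = np.asarray(scores)
    thresh = sc.min() * (1.0 + 1e-6) + 1e-300
    return float(grid[np.nonzero(sc <= thresh)[0][-1]])


def fit_gam(pmap: pd.DataFrame, spec: Optional[ModelSpec] = None,
            lambdas: Optional[dict[str, float]] = None) -> ModelFit:
    """Penalized-spline additive model fitted directly to p_thrive.

    Smoothing parameters (one per term) are selected by generalized
    cross-validation via cyclic golden-section search on log10(lambda)
    unless supplied.  Reports effective degrees of freedom and Wald-type
    p-values per term.  Predictions are *not* constrained to [0, 1]; a flag
    records whether any fell outside.
    """
    spec = spec or gam_spec_study()
    if spec.kind != "gam":
        raise ValueError("fit_gam requires a GAM spec")
    blocks = [_build_term_block(t, pmap) for t in spec.terms]
    X = _assemble_design(blocks, pmap)
    y = _response(spec, pmap)
    XtX, Xty = X.T @ X, X.T @ y
    n, p = X.shape

    if lambdas is not None:
        loglam = np.array([math.log10(lambdas[b.term.name]) for b in blocks])
    else:
        loglam = np.zeros(len(blocks))
        lo, hi = -4.0, 9.0
        for _cycle in range(3):
            for j in range(len(blocks)):
                if blocks[j].penalty is None:
                    continue
                grid = np.linspace(lo, hi, 14)
                scores = []
                for g in grid:
                    trial = loglam.copy()
                    trial[j] = g
                    scores.append(_gcv_score(y, X, XtX, Xty, blocks, trial))
                best = _pick_smoothest(grid, scores)
                # local refinement around the best grid point
                fine = np.linspace(best - 0.6, best + 0.6, 7)
                fscores = []
                for g in fine:
                    trial = loglam.copy()
                    trial[j] = g
                    fscores.append(_gcv_score(y, X, XtX, Xty, blocks, trial))
                loglam[j] = _pick_smoothest(fine, fscores)

    lam = 10.0 ** loglam
    beta, A, chol = _gam_solve(XtX, Xty, blocks, lam)
    resid = y - X @ beta
    edf_total = float(np.trace(A))
    if not np.isfinite(edf_total):
        raise RuntimeError("GAM smoothing failed: non-finite effective dof")
    sigma2 = float(resid @ resid) / max(n - edf_total, 1e-6)
    Vb = cho_solve(chol, np.eye(p)) * sigma2    # Bayesian posterior covariance

    term_slices, term_edf, term_p = {}, {}, {}
    pos = 1
    diagA = np.diag(A)
    for b in blocks:
        sl = slice(pos, pos + b.ncol)
        term_slices[b.term.name] = sl
        edf_j = float(diagA[sl].sum())
        term_edf[b.term.name] = edf_j
        bj = beta[sl]
        Vj = Vb[sl, sl]
        # Wald-type test with the pseudoinverse at the term's effective rank
        Tstat = float(bj @ np.linalg.pinv(Vj, rcond=1e-10) @ bj)
        df = max(edf_j, 1e-3)
        term_p[b.term.name] = float(stats.chi2.sf(Tstat, df))
        pos += b.ncol

    p_obs = pmap["p_thrive"].to_numpy(dtype=float)
    p_hat = X @ beta
    rmse, r2, outside = _prob_scale_metrics(p_obs, p_hat, clip_for_rmse=False)
    rss = float(resid @ resid)
    aic = n * math.log(rss / n) + 2.0 * (edf_total + 1.0)
    return ModelFit(
        spec=spec, coefficients=beta, term_slices=term_slices,
        term_pvalues=term_p, term_edf=term_edf,
        rmse=rmse, r_squared=r2, aic=aic, edf_total=edf_total,
        sigma2=sigma2,
        lambdas={b.term.name: float(l) for b, l in zip(blocks, lam)},
        predictions_clipped=outside, n_obs=n, _blocks=blocks,
    )


def fit_model(pmap: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    return fit_mlr(pmap, spec) if spec.kind == "mlr" else fit_gam(pmap, spec)


# --------------------------------------------------------------------------
# backward selection
# --------------------------------------------------------------------------

def backward_select(pmap: pd.DataFrame, spec: ModelSpec,
                    alpha: float = 0.05,
                    fitter: Optional[Callable[[pd.DataFrame, ModelSpec], ModelFit]] = None
                    ) -> tuple[ModelSpec, ModelFit]:
    """Iterative backward elimination of non-significant terms.

    At each step the candidate set is the non-significant (p > alpha) terms
    of the highest order that has any; the least significant of those is
    dropped and the model refit.  A term is protected from removal while it
    is nested inside a retained significant term (in particular, main
    effects stay whenever part of a significant interaction).
    """
    fitter = fitter or (lambda d, s: fit_model(d, s))
    current = spec
    fit = fitter(pmap, current)
    while True:
        pvals = fit.term_pvalues
        protected = set()
        for t in current.terms:
            if pvals[t.name] <= alpha:
                for u in current.terms:
                    if u is not t and u.involves() < t.involves():
                        protected.add(u.name)
        candidates = [
            t for t in current.terms
            if pvals[t.name] > alpha and t.name not in protected
        ]
        if not candidates:
            return current, fit
        top_order = max(t.order for t in candidates)
        candidates = [t for t in candidates if t.order == top_order]
        victim = max(candidates, key=lambda t: pvals[t.name])
        logger.info("backward_select: dropping %s (p=%.3g)",
                    victim.name, pvals[victim.name])
        current = current.without(victim)
        fit = fitter(pmap, current)


def model_metrics(fit: ModelFit, pmap: pd.DataFrame) -> tuple[float, float, float]:
    """(RMSE, R^2, AIC): errors on the probability scale between predicted
    and simulated p_thrive, AIC from the fitted likelihood."""
    p_obs = pmap["p_thrive"].to_numpy(dtype=float)
    clip = fit.spec.response == "logit_eps"
    p_hat = fit.predict(pmap, clip=clip)
    rmse, r2, _ = _prob_scale_metrics(p_obs, p_hat, clip_for_rmse=False)
    return rmse, r2, fit.aic
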