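"""Gaussian linear mixed models with crossed/nested random intercepts.

The fitter handles the model y = X b + sum_k Z_k u_k + e with u_k ~
N(0, s_k^2 I) for each grouping factor (male, species, playback species) and
e ~ N(0, s^2 I).  It profiles the fixed effects and the residual variance
out of the (restricted) likelihood and optimizes over the variance ratios
g_k = s_k^2 / s^2 >= 0 with a bounded quasi-Newton search from several
starts.  Designs here are small (tens to a few hundred rows), so the n x n
marginal covariance is handled densely via Cholesky factorizations; a full
fit costs milliseconds, which is what makes the package's Monte-Carlo
calibration and recovery studies cheap.

Given the ratios g, with V0 = I + sum_k g_k Z_k Z_k':

* b_hat  = (X' V0^-1 X)^-1 X' V0^-1 y            (GLS)
* s^2    = r' V0^-1 r / (n - p)  (REML)  or  / n  (ML)
* REML loglik = -1/2 [(n-p)(log 2 pi s^2 + 1) + log|V0| + log|X' V0^-1 X|]
* ML   loglik = -1/2 [ n   (log 2 pi s^2 + 1) + log|V0|]

A variance ratio converging to the boundary 0 yields a singular fit, which
is reported with a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

_GAMMA_MAX = 1e5
_SINGULAR_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """REML/ML optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class LMMFit:
    """Result of one (RE)ML fit."""

    params: pd.Series              # fixed-effect estimates
    se: pd.Series                  # their standard errors
    vcov: pd.DataFrame             # fixed-effect covariance
    sigma2: float                  # residual variance
    varcomps: dict[str, float]     # variance components per grouping factor
    loglik: float                  # maximized REML or ML log-likelihood
    method: str                    # "reml" | "ml"
    n_obs: int
    rank: int                      # rank of the fixed design
    df_resid: int                  # n_obs - rank
    converged: bool
    singular: bool                 # any variance ratio at the 0 boundary
    gamma: np.ndarray = field(repr=False, default=None)

    @property
    def n_fixed(self) -> int:
        return len(self.params)


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _profiled_neg_loglik(
    gamma: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    G: list[np.ndarray],
    method: str,
) -> float:
    n, p = X.shape
    V0 = np.eye(n)
    for g, Gk in zip(gamma, G):
        if g > 0:
            V0 += g * Gk
    try:
        c, low = cho_factor(V0, check_finite=False)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.inf
    logdet_V0 = 2.0 * np.log(np.diag(c)).sum()
    Vi_X = cho_solve((c, low), X, check_finite=False)
    Vi_y = cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtViX, X.T @ Vi_y, rcond=None)[0]
    r = y - X @ beta
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    if quad <= 0:
        quad = 1e-12
    if method == "reml":
        sigma2 = quad / (n - p)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_V0 + logdet_XtViX
        )
    else:
        sigma2 = quad / n
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_V0)
    return -ll


def fit_lmm_arrays(
    y: np.ndarray,
    X: np.ndarray,
    param_names: list[str],
    random_codes: dict[str, np.ndarray],
    method: str = "reml",
    starts: tuple[float, ...] = (0.05, 0.5, 2.0),
    extra_df: int = 0,
) -> LMMFit:
    """Fit the LMM from raw arrays.

    ``random_codes`` maps each grouping-factor name to integer level codes
    per row (use :func:`pandas.factorize`).  Every grouping factor
    contributes one variance component (random intercept).

    ``extra_df`` charges additional degrees of freedom against the residual
    when the response was pre-processed by estimating means that are not in
    the design — e.g. within-individual centering, which estimates one mean
    per individual and would otherwise deflate the residual variance (and
    hence every fixed-effect SE) by roughly a factor (1 - 1/mean group
    size).  The likelihood itself (used for LRTs and oracle comparisons) is
    untouched; only the final residual-variance estimate, the fixed-effect
    covariance and ``df_resid`` use the reduced degrees of freedom.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"method must be 'reml' or 'ml', got {method!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    if rank < p:
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {rank} < {p} columns)"
        )
    for name, codes in random_codes.items():
        if len(np.unique(codes)) < 2:
            raise ValueError(f"random grouping {name!r} needs >= 2 levels")

    names = list(random_codes)
    G = []
    for name in names:
        codes = np.asarray(random_codes[name])
        Z = _indicator(codes, codes.max() + 1)
        G.append(Z @ Z.T)

    if names:
        obj = lambda g: _profiled_neg_loglik(g, y, X, G, method)
        best = None
        trace = []
        for s in starts:
            res = minimize(
                obj,
                np.full(len(names), s),
                method="L-BFGS-B",
                bounds=[(0.0, _GAMMA_MAX)] * len(names),
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
            )
            trace.append((s, res.fun, res.x, res.success))
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if not np.isfinite(best.fun):
            raise ConvergenceError("REML/ML optimization diverged", trace)
        gamma = best.x
        converged = bool(best.success)
    else:
        gamma = np.array([])
        converged = True

    # final quantities at the optimum
    V0 = np.eye(n)
    for g, Gk in zip(gamma, G):
        if g > 0:
            V0 += g * Gk
    c, low = cho_factor(V0, check_finite=False)
    Vi_X = cho_solve((c, low), X, check_finite=False)
    Vi_y = cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    dof = (n - p) if method == "reml" else n
    dof_adj = dof - extra_df
    if dof_adj <= 0:
        raise ValueError(f"extra_df={extra_df} leaves no residual degrees of freedom")
    sigma2 = max(quad / dof_adj, 1e-300)
    loglik = -_profiled_neg_loglik(gamma, y, X, G, method)
    vcov = sigma2 * XtViX_inv

    singular = bool(len(gamma) and (gamma < _SINGULAR_TOL).any())
    if singular:
        at_zero = [nm for nm, g in zip(names, gamma) if g < _SINGULAR_TOL]
        warnings.warn(
            f"singular fit: variance component(s) {at_zero} estimated at the "
            "zero boundary", stacklevel=2
        )

    params = pd.Series(beta, index=param_names)
    se = pd.Series(np.sqrt(np.diag(vcov)), index=param_names)
    return LMMFit(
        params=params,
        se=se,
        vcov=pd.DataFrame(vcov, index=param_names, columns=param_names),
        sigma2=sigma2,
        varcomps={nm: float(g * sigma2) for nm, g in zip(names, gamma)},
        loglik=float(loglik),
        method=method,
        n_obs=n,
        rank=rank,
        df_resid=n - rank - extra_df,
        converged=converged,
        singular=singular,
        gamma=gamma,
    )
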