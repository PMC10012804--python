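"""Binary logistic regression: Newton/IRLS fits, odds ratios, McFadden R2.

The fitter is deliberately lean because dominance analysis refits the same
outcome on up to 2^16 predictor subsets; the public API wraps a fast
array-level Newton core that is also used directly by the subset lattice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import DataError, DomainError, SeparationError

logger = logging.getLogger(__name__)

SCORE_TOL = 1e-8       # max absolute score at convergence
LL_RTOL = 1e-10        # relative log-likelihood change at convergence
MAX_ITER = 100
SEPARATION_COEF = 15.0  # |coef| beyond which divergence is suspected


@dataclass
class LogisticFit:
    """A fitted binary logit: estimates, covariance, likelihoods."""

    params: pd.Series          # includes "const"
    cov: pd.DataFrame
    llf: float
    llnull: float
    nobs: int
    converged: bool
    iterations: int
    ridge: float = 0.0

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def null_loglik(y: np.ndarray) -> float:
    """Intercept-only log-likelihood from the outcome prevalence."""
    y = np.asarray(y, dtype=float)
    p = y.mean()
    if p <= 0.0 or p >= 1.0:
        raise DataError("outcome takes a single value; null model degenerate")
    n = y.size
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def _newton(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
            max_iter: int = MAX_ITER, beta0: np.ndarray | None = None):
    """Newton-Raphson (IRLS) on the Bernoulli log-likelihood.

    Returns (beta, ll, H, converged, iterations). Raises SeparationError
    when coefficients diverge without likelihood improvement and ridge is 0.
    ``beta0`` warm-starts the iteration (used by the subset lattice).
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = X @ beta if beta0 is not None else np.zeros(n)
    ll = _loglik(eta, y)
    ridge_vec = np.full(k, ridge)
    ridge_vec[0] = 0.0  # never penalize the intercept
    converged = False
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        score = X.T @ (y - p) - ridge_vec * beta
        H = (X * w[:, None]).T @ X
        if ridge:
            H = H + np.diag(ridge_vec)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, score, rcond=None)[0]
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            eta_c = X @ cand
            ll_c = _loglik(eta_c, y) - 0.5 * float(ridge_vec @ cand**2)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        improved = ll_c - ll
        beta, eta, ll = cand, eta_c, ll_c
        if abs(improved) < LL_RTOL * (abs(ll) + 1e-12):
            converged = True
            break
    # under complete separation the score also vanishes as |beta| -> inf,
    # so divergence of the slope coefficients is the reliable signal
    slopes = beta[1:] if k > 1 else beta
    if ridge == 0.0 and slopes.size and np.max(np.abs(slopes)) > SEPARATION_COEF:
        raise SeparationError(np.flatnonzero(np.abs(beta) > SEPARATION_COEF))
    return beta, ll, H, converged, it


def fit_logistic(design, outcome, add_intercept: bool = True,
                 ridge: float = 0.0) -> LogisticFit:
    """Maximum-likelihood logistic regression of a 0/1 outcome.

    ``design`` may be a DataFrame or array of predictors (no intercept
    column; one is always added first). An optional tiny ridge exists only
    to rescue separated subset models; its use is logged.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        Xr = design.to_numpy(dtype=float)
    else:
        Xr = np.asarray(design, dtype=float)
        if Xr.ndim == 1:
            Xr = Xr[:, None]
        names = [f"x{i}" for i in range(Xr.shape[1])]
    y = np.asarray(outcome, dtype=float).ravel()
    if Xr.shape[0] != y.size:
        raise DataError("design and outcome lengths differ")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise DataError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DataError("outcome takes a single value; cannot fit")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), Xr])
        names = ["const"] + names
    else:
        X = Xr
    if y.size <= X.shape[1]:
        raise DataError(f"n_obs={y.size} must exceed {X.shape[1]} parameters")

    if ridge:
        logger.info("ridge rescue active (lambda=%g)", ridge)
    try:
        beta, ll, H, converged, it = _newton(X, y, ridge=ridge)
    except SeparationError as err:
        raise SeparationError([names[i] for i in err.columns]) from None
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=ll, llnull=null_loglik(y), nobs=int(y.size),
        converged=converged, iterations=it, ridge=ridge,
    )


def mcfadden_r2(fit: LogisticFit) -> float:
    """McFadden's pseudo-R2, 1 - llf/llnull."""
    if not fit.converged:
        raise DataError("fit did not converge; McFadden R2 undefined")
    if fit.llnull >= 0.0:
        raise DomainError("degenerate null log-likelihood")
    return 1.0 - fit.llf / fit.llnull


def odds_ratios(fit: LogisticFit, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios with Wald confidence intervals and two-sided p-values.

    Columns: term, or, ci_low, ci_high, p. Terms with non-finite standard
    errors are reported with NaN intervals and a warning, never dropped.
    """
    if not fit.converged:
        raise DataError("fit did not converge; odds ratios undefined")
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.bse
    bad = ~np.isfinite(se.to_numpy())
    if bad.any():
        warnings.warn(
            f"non-finite standard error for terms {list(se.index[bad])}; "
            "intervals reported as undefined", stacklevel=2)
    coef = fit.params
    with np.errstate(invalid="ignore"):
        tab = pd.DataFrame({
            "term": coef.index,
            "or": np.exp(coef.to_numpy()),
            "ci_low": np.exp(coef.to_numpy() - z * se.to_numpy()),
            "ci_high": np.exp(coef.to_numpy() + z * se.to_numpy()),
            "p": 2.0 * norm.sf(np.abs(coef.to_numpy() / se.to_numpy())),
        }).reset_index(drop=True)
    return tab
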