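"""Ridge smooth-thresholding logistic regression with EBIC model selection.

The d screened indicator predictors enter a logistic model.  A ridge fit at
``lambda2`` (initialized at 1/n, escalated tenfold whenever the Newton
linear solve fails) supplies initial coefficients ``b0``.  For a threshold
parameter ``lambda`` each coefficient gets

    delta_j = min(1, lambda / b0_j^2),

and the *active set* is {j : delta_j < 1} = {j : b0_j^2 > lambda}; inactive
coefficients are exactly zero.  The remaining coefficients minimize

    -loglik(beta) + 1/2 * sum_{j active} [lambda2 + delta_j/(1-delta_j)] beta_j^2

by damped Newton / IRLS (the intercept is never penalized).  Because the
per-coefficient penalty weight diverges as delta_j -> 1, the procedure
yields exact sparsity without convex-programming machinery.

``lambda`` is tuned by the extended BIC,

    EBIC(gamma) = -2 loglik(beta_hat) + (ln n + 2 gamma ln p) dim(beta_hat),

where p is the saturated predictor count *before* screening and dim counts
nonzero non-intercept coefficients.  The candidate lambdas are the active-set
breakpoints {0} + {b0_j^2 (1+eps)}, so every reachable model is visited
exactly once and selection is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import expit

__all__ = [
    "RidgeInit",
    "StFit",
    "EbicConfig",
    "ConvergenceError",
    "ridge_logistic",
    "adaptive_ridge_init",
    "st_weights",
    "st_fit",
    "fit_path",
    "lambda_path",
    "ebic",
    "select_model",
    "select_from_path",
]

_PATH_EPS = 1e-9


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the partial state in ``partial``."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class _SolveError(RuntimeError):
    """Newton linear solve failed (singular/ill-conditioned system)."""


@dataclass(frozen=True)
class RidgeInit:
    """Ridge-logistic initial estimates and the ridge value that produced them.

    ``beta0[0]`` is the intercept; ``beta0[1:]`` the d predictor coefficients.
    """

    beta0: np.ndarray
    lambda2: float
    converged: bool = True

    def __post_init__(self):
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive")
        if not np.all(np.isfinite(self.beta0)):
            raise ValueError("initial coefficients must be finite")


@dataclass(frozen=True)
class StFit:
    """A sparse smooth-thresholding fit at one lambda.

    ``beta`` (length d) has exact zeros off ``active_set``; ``loglik`` is the
    unpenalized log-likelihood at the solution and ``dim`` the number of
    nonzero non-intercept coefficients.
    """

    beta: np.ndarray
    intercept: float
    active_set: np.ndarray
    lam: float
    lambda2: float
    loglik: float
    dim: int
    delta: np.ndarray
    n_iter: int = 0


@dataclass(frozen=True)
class EbicConfig:
    """EBIC evaluation context: gamma in [0,1], saturated dimension, n."""

    gamma: float
    p_full: int
    n: int

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.p_full < 1 or self.n < 1:
            raise ValueError("p_full and n must be positive")


def _neg_loglik(eta, y):
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def _irls(X1, y, w_pen, beta, tol, max_iter):
    """Damped Newton on the penalized logistic objective.

    ``X1`` includes the intercept column; ``w_pen`` the per-coefficient
    quadratic penalty weights (0 for the intercept).  Step-halving
    guarantees the penalized objective never increases.  Returns
    ``(beta, eta, n_iter, converged)``; raises ``_SolveError`` when the
    Newton system cannot be solved.
    """
    beta = beta.copy()
    eta = X1 @ beta
    f = _neg_loglik(eta, y) + 0.5 * float(w_pen @ beta**2)
    for it in range(max_iter):
        mu = expit(eta)
        wv = mu * (1.0 - mu)
        grad = X1.T @ (mu - y) + w_pen * beta
        H = (X1 * wv[:, None]).T @ X1
        H[np.diag_indices_from(H)] += w_pen
        try:
            cf = cho_factor(H, lower=True, check_finite=False)
            step = -cho_solve(cf, grad, check_finite=False)
        except (LinAlgError, ValueError) as err:
            raise _SolveError(str(err)) from None
        if not np.all(np.isfinite(step)):
            raise _SolveError("non-finite Newton step")
        t = 1.0
        for _ in range(40):
            bn = beta + t * step
            en = X1 @ bn
            fn = _neg_loglik(en, y) + 0.5 * float(w_pen @ bn**2)
            if fn <= f + 1e-12 * (abs(f) + 1.0):
                break
            t *= 0.5
        moved = float(np.max(np.abs(t * step)))
        beta, eta, f = bn, en, fn
        if moved < tol:
            return beta, eta, it + 1, True
    return beta, eta, max_iter, False


def _with_intercept(X):
    return np.hstack([np.ones((X.shape[0], 1)), np.asarray(X, dtype=np.float64)])


def ridge_logistic(X, y, lambda2, *, tol=1e-8, max_iter=100, beta_start=None):
    """Ridge-penalized logistic fit; returns coefficients (intercept first).

    Maximizes ``loglik - (lambda2/2) * sum_j beta_j^2`` over the non-intercept
    coefficients by IRLS; warns if the iteration cap is hit.  Raises on a
    failed Newton solve (callers escalate lambda2 via
    :func:`adaptive_ridge_init`).
    """
    y = np.asarray(y, dtype=np.float64)
    X1 = _with_intercept(X)
    p1 = X1.shape[1]
    w_pen = np.full(p1, float(lambda2))
    w_pen[0] = 0.0
    if beta_start is None:
        beta_start = np.zeros(p1)
    beta, _, n_iter, converged = _irls(X1, y, w_pen, beta_start, tol, max_iter)
    if not converged:
        warnings.warn(
            f"ridge_logistic: IRLS hit the {max_iter}-iteration cap "
            f"(lambda2={lambda2:g})",
            stacklevel=2,
        )
    return beta


def adaptive_ridge_init(X, y, *, max_escalations=12) -> RidgeInit:
    """Ridge initial estimates with lambda2 starting at 1/n.

    Whenever the Newton linear solve fails, lambda2 is multiplied by 10 and
    the fit retried; after ``max_escalations`` escalations a hard error is
    raised (pathological design).
    """
    n = np.asarray(y).shape[0]
    lambda2 = 1.0 / n
    for attempt in range(max_escalations + 1):
        try:
            beta0 = ridge_logistic(X, y, lambda2)
            return RidgeInit(beta0=beta0, lambda2=lambda2)
        except _SolveError:
            lambda2 *= 10.0
    raise RuntimeError(
        f"ridge initialization failed after {max_escalations} lambda2 escalations "
        f"(final lambda2={lambda2:g}); the design is pathological"
    )


def st_weights(beta0, lam):
    """Per-coefficient delta_j = min(1, lambda / b0_j^2) and the active set.

    ``beta0`` holds the non-intercept initial coefficients.  A coefficient
    initialized exactly at zero is excluded (delta = 1) for any lambda > 0,
    by continuity; lambda = 0 activates everything with delta = 0.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    beta0 = np.asarray(beta0, dtype=np.float64)
    if lam == 0.0:
        delta = np.zeros_like(beta0)
    else:
        delta = np.ones_like(beta0)
        nz = beta0 != 0.0
        delta[nz] = np.minimum(1.0, lam / beta0[nz] ** 2)
    active = np.flatnonzero(delta < 1.0)
    return delta, active


def _null_fit(y, lam, lambda2, d, delta):
    """Closed-form intercept-only fit (empty active set)."""
    y = np.asarray(y, dtype=np.float64)
    pbar = float(y.mean())
    intercept = math.log(pbar / (1.0 - pbar))
    n = y.shape[0]
    ll = n * (pbar * math.log(pbar) + (1.0 - pbar) * math.log(1.0 - pbar))
    return StFit(
        beta=np.zeros(d), intercept=intercept,
        active_set=np.empty(0, dtype=np.int64), lam=lam, lambda2=lambda2,
        loglik=ll, dim=0, delta=delta, n_iter=0,
    )


def st_fit(X, y, init: RidgeInit, lam, *, tol=1e-8, max_iter=200,
           warm_start=None) -> StFit:
    """Smooth-thresholding fit at threshold ``lam`` from ridge init.

    Coefficients outside the active set are exact zeros; active coefficients
    minimize the penalized objective with weights
    ``lambda2 + delta_j/(1-delta_j)``.  Reports the unpenalized
    log-likelihood at the solution.  Raises :class:`ConvergenceError`
    (carrying partial state) if IRLS does not converge in ``max_iter``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    d = X.shape[1]
    delta, active = st_weights(init.beta0[1:], lam)
    if active.size == 0:
        return _null_fit(y, lam, init.lambda2, d, delta)
    w = init.lambda2 + delta[active] / (1.0 - delta[active])
    X1 = _with_intercept(X[:, active])
    w_pen = np.concatenate([[0.0], w])
    if warm_start is None:
        start = np.concatenate([[init.beta0[0]], init.beta0[1:][active]])
    else:
        start = np.concatenate([[warm_start[0]], warm_start[1:][active]])
    try:
        beta_a, eta, n_iter, converged = _irls(X1, y, w_pen, start, tol, max_iter)
    except _SolveError as err:
        raise ConvergenceError(f"Newton solve failed at lambda={lam:g}: {err}") from None
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations at lambda={lam:g}",
            partial=(beta_a, active),
        )
    beta = np.zeros(d)
    beta[active] = beta_a[1:]
    return StFit(
        beta=beta, intercept=float(beta_a[0]), active_set=active, lam=float(lam),
        lambda2=init.lambda2, loglik=-_neg_loglik(eta, y),
        dim=int(active.size), delta=delta, n_iter=n_iter,
    )


def lambda_path(init: RidgeInit) -> np.ndarray:
    """Active-set breakpoints {0} + {b0_j^2 (1+eps)}, ascending.

    Placing each candidate just above a squared initial coefficient means
    consecutive path points differ by exactly the coefficients they
    deactivate, so the path visits every threshold-reachable active set
    once.
    """
    sq = np.unique(init.beta0[1:] ** 2)
    sq = sq[sq > 0.0]
    return np.concatenate([[0.0], sq * (1.0 + _PATH_EPS)])


def ebic(fit: StFit, cfg: EbicConfig) -> float:
    """EBIC = -2 loglik + (ln n + 2 gamma ln p) dim; gamma=0 is the BIC."""
    return -2.0 * fit.loglik + (
        math.log(cfg.n) + 2.0 * cfg.gamma * math.log(cfg.p_full)
    ) * fit.dim


def fit_path(X, y, init: RidgeInit, *, tol=1e-8, max_iter=200):
    """Fit every lambda on the breakpoint path, warm-starting along the way.

    Non-convergent path points are skipped with a warning; at least the
    terminal (intercept-only) point always succeeds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    fits = []
    warm = init.beta0
    for lam in lambda_path(init):
        try:
            f = st_fit(X, y, init, lam, tol=tol, max_iter=max_iter, warm_start=warm)
        except ConvergenceError as err:
            warnings.warn(f"skipping path point lambda={lam:g}: {err}", stacklevel=2)
            continue
        fits.append(f)
        warm = np.concatenate([[f.intercept], f.beta])
    return fits


def select_from_path(fits, cfg: EbicConfig) -> StFit:
    """EBIC minimizer over fitted path points (ties: smaller dim, larger lambda)."""
    if not fits:
        raise ValueError("no fitted path points to select from")
    return min(fits, key=lambda f: (ebic(f, cfg), f.dim, -f.lam))


def select_model(X, y, cfg: EbicConfig) -> StFit:
    """Full selection: adaptive ridge init, breakpoint path, EBIC minimum."""
    init = adaptive_ridge_init(X, y)
    fits = fit_path(X, y, init)
    return select_from_path(fits, cfg)
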