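"""Proportional win-fractions model fitting.

The win/loss probability ratio for a comparable pair is modeled as
``exp(beta' (z_i - z_j))``.  Numerically this is a no-intercept logistic
regression of the win indicator ``delta`` on the covariate differences over
the comparable pairs, which makes elastic-net regularization available:

    l(beta; lambda) = -|R|^{-1} sum_{(i,j) in R} [delta_ij beta'z_ij
                        - log(1 + exp(beta'z_ij))]
                      + lambda [ (1-alpha) ||beta||_2^2 / 2
                                 + alpha ||beta||_1 ]

The pathwise minimizer over a decreasing lambda grid is computed by
majorization-minimization: the logistic curvature is globally bounded by
1/4, so the quadratic surrogate built from the fixed Gram matrix
``X'X/(4|R|)`` majorizes the loss and is minimized by cyclic coordinate
descent with soft-thresholding, warm-started from the previous grid point.
A terminal lambda of 0 (the unregularized fit) is solved by Newton-Raphson
instead, whose fast divergence under perfect separation makes that
condition detectable.

No intercept is ever fitted: every stored pair contains one win and one
loss and which subject is labelled "i" is arbitrary, so the objective must
be invariant to flipping ``(delta, z_diff) -> (1 - delta, -z_diff)``.  For
the same reason the internal standardization rescales each
covariate-difference column by its root mean square without centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .pairwise import PairSet

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


# Divergence cap on standardized coefficients: an unpenalized pairwise
# logistic fit walking past this norm is treated as perfectly separated.
_SEPARATION_CAP = 30.0


class ConvergenceError(RuntimeError):
    pass


class PerfectSeparationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for the penalized pairwise logistic path.

    alpha : elastic-net mixture in [0, 1]; 1 = lasso, 0 = ridge.
    lambda_grid : explicit decreasing grid, or None for the automatic
        log-spaced grid from lambda_max down to
        lambda_min_ratio * lambda_max.
    standardize : rescale covariate differences to unit root-mean-square
        internally (coefficients are reported on the original scale).
    tol : sup-norm coefficient-change convergence threshold.
    max_iter : surrogate-iteration budget per lambda.
    """

    alpha: float = 1.0
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    tol: float = 1e-7
    max_iter: int = 100_000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g < 0):
                raise ValueError("lambda values must be nonnegative")
            if np.any(np.diff(g) >= 0):
                raise ValueError("lambda grid must be strictly decreasing")
            object.__setattr__(self, "lambda_grid", g)


@dataclass
class ElasticNetPath:
    """Coefficient path over a decreasing lambda grid at fixed alpha.

    ``betas[k]`` is the minimizer at ``lambdas[k]`` on the ORIGINAL
    covariate scale; ``scale_factors`` are the internal per-column
    root-mean-square scalings (ones when standardization is off).
    """

    lambdas: np.ndarray
    betas: np.ndarray            # (n_lambda, p), original scale
    scale_factors: np.ndarray
    alpha: float
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.betas != 0).sum(axis=1)

    def beta_at(self, lam: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.lambdas - lam)))
        if not np.isclose(self.lambdas[k], lam, rtol=1e-10, atol=0):
            raise KeyError(f"lambda {lam} not on the fitted grid")
        return self.betas[k]

    def to_frame(self):
        import pandas as pd
        rows = []
        for lam, b in zip(self.lambdas, self.betas):
            for name, coef in zip(self.covariate_names, b):
                rows.append((lam, name, coef))
        return pd.DataFrame(rows, columns=["lambda", "covariate", "coefficient"])


def _design(pairs: PairSet, standardize: bool):
    X = pairs.z_diff
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    if standardize:
        scale = np.sqrt(np.mean(X * X, axis=0))
        scale = np.where(scale > 0, scale, 1.0)
    else:
        scale = np.ones(X.shape[1])
    return X / scale, scale


def objective(pairs: PairSet, beta: np.ndarray, lam: float,
              alpha: float) -> float:
    """Penalized negative average pairwise log-likelihood (original scale)."""
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    beta = np.asarray(beta, dtype=float)
    eta = pairs.z_diff @ beta
    loglik = np.mean(pairs.delta * eta - np.logaddexp(0.0, eta))
    penalty = lam * ((1 - alpha) * 0.5 * np.sum(beta**2)
                     + alpha * np.sum(np.abs(beta)))
    return float(-loglik + penalty)


def estimating_function(pairs: PairSet, beta: np.ndarray) -> np.ndarray:
    """Pairwise estimating function U_n(beta); equals the negative gradient
    of the unpenalized objective."""
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    beta = np.asarray(beta, dtype=float)
    resid = pairs.delta - expit(pairs.z_diff @ beta)
    return pairs.z_diff.T @ resid / len(pairs)


def lambda_max(pairs: PairSet, alpha: float, standardize: bool = True) -> float:
    """Smallest lambda at which the whole path is exactly zero (KKT bound on
    the standardized scale).  For alpha below 0.001 the 0.001 bound is used,
    since the ridge limit has no finite all-zero threshold."""
    Xs, _ = _design(pairs, standardize)
    g = Xs.T @ (pairs.delta - 0.5) / len(pairs)
    return float(np.max(np.abs(g)) / max(alpha, 1e-3))


@njit(cache=True)
def _path_core(Xs, y, grid, alpha, tol, max_iter):  # pragma: no cover - jitted
    """Warm-started proximal-Newton / coordinate-descent path for strictly
    positive lambdas on the standardized scale: at each outer step the
    IRLS quadratic (weights p(1-p), floored at 1e-5) is minimized by cyclic
    soft-threshold coordinate descent.  Returns (betas, n_bad) where n_bad
    counts grid points that failed to converge."""
    N, p = Xs.shape
    n_lam = grid.shape[0]
    betas = np.zeros((n_lam, p))
    beta = np.zeros(p)
    n_bad = 0
    max_outer = max_iter if max_iter < 100 else 100
    for k in range(n_lam):
        lam = grid[k]
        thr = lam * alpha
        ok = False
        for _it in range(max_outer):
            eta = Xs @ beta
            pvec = 1.0 / (1.0 + np.exp(-eta))
            w = pvec * (1.0 - pvec)
            for i in range(N):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            Xw = Xs * w.reshape(-1, 1)
            G = np.dot(Xs.T, Xw) / N
            b = np.dot(Xs.T, w * eta + (y - pvec)) / N
            denom = np.empty(p)
            for j in range(p):
                denom[j] = G[j, j] + lam * (1.0 - alpha)
            beta_old = beta.copy()
            for _cd in range(max_iter):
                dmax = 0.0
                for j in range(p):
                    old = beta[j]
                    r = b[j] - np.dot(G[j], beta) + G[j, j] * old
                    if r > thr:
                        new = (r - thr) / denom[j]
                    elif r < -thr:
                        new = (r + thr) / denom[j]
                    else:
                        new = 0.0
                    if new != old:
                        beta[j] = new
                        d = abs(new - old)
                        if d > dmax:
                            dmax = d
                if dmax < 0.1 * tol:
                    break
            big = 0.0
            for j in range(p):
                d = abs(beta[j] - beta_old[j])
                if d > big:
                    big = d
            if big < tol:
                ok = True
                break
        if not ok:
            n_bad += 1
        betas[k] = beta
    return betas, n_bad


def _newton_std(Xs, y, beta0, tol=1e-9, max_iter=100):
    """Newton-Raphson root of the standardized-scale estimating function."""
    beta = beta0.copy()
    N = len(y)
    for _ in range(max_iter):
        eta = Xs @ beta
        pvec = expit(eta)
        U = Xs.T @ (y - pvec) / N
        if np.max(np.abs(U)) < tol:
            # a root with every pair on the correct side of its margin means
            # the likelihood is unbounded and the apparent root an artifact
            # of the gradient flattening out
            margins = (2.0 * y - 1.0) * eta
            if np.all(margins > 0):
                raise PerfectSeparationError(
                    "unpenalized pairwise logistic fit is perfectly "
                    "separated; no finite estimate exists"
                )
            return beta
        w = np.maximum(pvec * (1 - pvec), 1e-12)
        H = (Xs * w[:, None]).T @ Xs / N
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular Hessian: {e}") from e
        beta = beta + step
        if np.max(np.abs(beta)) > _SEPARATION_CAP:
            raise PerfectSeparationError(
                "unpenalized pairwise logistic fit diverged: "
                "perfect separation of the comparable pairs"
            )
    raise ConvergenceError("Newton-Raphson did not converge")


def fit_path(pairs: PairSet, config: FitConfig = FitConfig()) -> ElasticNetPath:
    """Pathwise elastic-net solution of the penalized pairwise logistic
    objective over a decreasing lambda grid, warm-started.

    The automatic grid runs log-spaced from the KKT bound ``lambda_max``
    down to ``lambda_min_ratio * lambda_max``.  A terminal grid value of 0
    is allowed (unpenalized fit) and raises
    :class:`PerfectSeparationError` if the pairs are separable.
    """
    Xs, scale = _design(pairs, config.standardize)
    y = pairs.delta.astype(float)
    if config.lambda_grid is not None:
        grid = config.lambda_grid
    else:
        lmax = lambda_max(pairs, config.alpha, config.standardize)
        if lmax <= 0:
            grid = np.array([0.0])
        else:
            grid = np.geomspace(lmax, lmax * config.lambda_min_ratio,
                                config.n_lambda)
    pos = grid > 0
    betas_std = np.zeros((len(grid), Xs.shape[1]))
    if pos.any():
        core, n_bad = _path_core(np.ascontiguousarray(Xs, dtype=float), y,
                                 np.ascontiguousarray(grid[pos], dtype=float),
                                 float(config.alpha), float(config.tol),
                                 int(config.max_iter))
        if n_bad:
            raise ConvergenceError(
                f"{n_bad} lambda grid point(s) failed to converge "
                f"(smallest lambda {grid[pos][-1]:g})")
        betas_std[pos] = core
    if (~pos).any():
        warm = betas_std[pos][-1] if pos.any() else np.zeros(Xs.shape[1])
        betas_std[~pos] = _newton_std(Xs, y, warm)
    return ElasticNetPath(lambdas=np.asarray(grid, dtype=float),
                          betas=betas_std / scale,
                          scale_factors=scale, alpha=config.alpha,
                          covariate_names=list(pairs.covariate_names))


def fit_at(pairs: PairSet, lam: float,
           config: FitConfig = FitConfig()) -> ElasticNetPath:
    """Fit at a single target lambda, warm-starting along the portion of the
    automatic grid above it (so the result matches the corresponding
    :func:`fit_path` entry when ``lam`` lies on that grid)."""
    lmax = lambda_max(pairs, config.alpha, config.standardize)
    if lmax > 0 and lam < lmax:
        auto = np.geomspace(lmax, lmax * config.lambda_min_ratio,
                            config.n_lambda)
        grid = auto[auto > lam * (1 + 1e-12)]
        grid = np.append(grid, lam)
    else:
        grid = np.array([float(lam)])
    cfg = FitConfig(alpha=config.alpha, lambda_grid=grid,
                    standardize=config.standardize, tol=config.tol,
                    max_iter=config.max_iter)
    return fit_path(pairs, cfg)


def fit_unregularized(pairs: PairSet, tol: float = 1e-9,
                      max_iter: int = 100) -> np.ndarray:
    """Solve U_n(beta) = 0 by Newton-Raphson (the lambda = 0 minimizer).

    Raises :class:`PerfectSeparationError` when the likelihood is unbounded
    (standardized coefficient norm exceeding the divergence cap) and
    :class:`ConvergenceError` on a singular Hessian or iteration overrun.
    """
    Xs, scale = _design(pairs, standardize=True)
    y = pairs.delta.astype(float)
    beta = _newton_std(Xs, y, np.zeros(Xs.shape[1]), tol=tol,
                       max_iter=max_iter)
    return beta / scale
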