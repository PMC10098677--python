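"""Comparator estimators: mean imputation, soft/hard impute, missing-data EM.

These are the standard alternatives against which the iterative refinement
algorithm is benchmarked, re-implemented here:

* *mean imputation*: fill unobserved cells with the population column mean
  (zero in the mean-zero simulation models) or the observed column mean, and
  take the leading right singular vectors;
* *soft impute*: nuclear-norm-regularised matrix completion
  ``argmin_X 0.5 ||Y_Omega - X o Omega||_F^2 + lam ||X||_*`` solved by
  iterated singular-value soft-thresholding of the fill-in matrix, with the
  rank capped at ``rank_max``;
* *hard impute*: the ``lam = 0`` limit — alternate rank-K truncated SVD and
  restoration of the observed entries (may converge to a local optimum);
* *EM*: maximum likelihood for a multivariate normal under MAR missingness,
  imputing conditional means and adding conditional covariances via Schur
  complements in the E-step.  The Schur systems are ridge-regularised; if
  they are singular regardless the failure is raised rather than papered
  over, mirroring the instability this algorithm is known for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .estimators import ObservedData, init_estimator
from .metrics import Subspace, sin_theta_loss, top_k_right_singular

__all__ = [
    "ImputeConfig",
    "mean_impute_estimator",
    "soft_impute",
    "soft_impute_objective",
    "hard_impute",
    "oracle_lambda",
    "em_mvn",
    "em_mvn_estimator",
    "EMInstabilityError",
]

logger = logging.getLogger(__name__)


class EMInstabilityError(RuntimeError):
    """Raised when the EM Schur-complement systems are numerically singular."""


@dataclass(frozen=True)
class ImputeConfig:
    """Knobs for the SVD-imputation baselines."""

    rank_max: int = 20
    lam: float = 0.0
    max_iter: int = 500
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.rank_max < 1:
            raise ValueError("rank_max must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def mean_impute_estimator(
    data: ObservedData, K: int, empirical_means: bool = False
) -> Subspace:
    """Column-mean imputation followed by a rank-K SVD.

    In population mode (default) the fill value is 0, the true column mean of
    the mean-zero simulation models; ``empirical_means=True`` uses observed
    column means instead, for real data.
    """
    if empirical_means:
        counts = data.mask.sum(axis=0)
        means = np.where(counts > 0, data.y_obs.sum(axis=0) / np.maximum(counts, 1), 0.0)
        filled = np.where(data.mask == 1, data.y_obs, means[None, :])
    else:
        filled = data.y_obs
    return top_k_right_singular(filled, K)


def _svt(m: np.ndarray, lam: float, rank_max: int) -> np.ndarray:
    """Singular-value soft-thresholding truncated at ``rank_max``."""
    u, s, vt = scipy.linalg.svd(m, full_matrices=False)
    s = np.maximum(s - lam, 0.0)[:rank_max]
    r = int(np.count_nonzero(s))
    if r == 0:
        return np.zeros_like(m)
    return (u[:, :r] * s[:r]) @ vt[:r]


def soft_impute_objective(data: ObservedData, x: np.ndarray, lam: float) -> float:
    """``0.5 ||Y_Omega - X o Omega||_F^2 + lam ||X||_*``."""
    resid = (data.y_obs - x) * data.mask
    nuc = float(np.sum(scipy.linalg.svdvals(x)))
    return 0.5 * float(np.sum(resid * resid)) + lam * nuc


def soft_impute(
    data: ObservedData, cfg: ImputeConfig, x0: np.ndarray | None = None
) -> np.ndarray:
    """Nuclear-norm-regularised imputation by iterated soft-thresholded SVD.

    Repeats ``X <- SVT_lam(Y_Omega + X o Omega^c)`` until the relative
    Frobenius change falls below ``cfg.tol``; the objective is non-increasing
    along the iterates.  ``x0`` warm-starts the fill-in (zeros by default,
    the population column mean of the simulation models).
    """
    obs = data.mask == 1
    x = np.zeros_like(data.y_obs) if x0 is None else np.array(x0, dtype=float)
    for _ in range(cfg.max_iter):
        filled = np.where(obs, data.y_obs, x)
        x_new = _svt(filled, cfg.lam, cfg.rank_max)
        denom = max(float(np.linalg.norm(x)), 1e-12)
        rel = float(np.linalg.norm(x_new - x)) / denom
        x = x_new
        if rel <= cfg.tol:
            return x
    logger.warning("soft_impute reached max_iter=%d without converging", cfg.max_iter)
    return x


def hard_impute(data: ObservedData, K: int, cfg: ImputeConfig) -> np.ndarray:
    """Alternate rank-K SVD truncation and observed-entry restoration."""
    if K > cfg.rank_max:
        raise ValueError(f"K={K} exceeds rank_max={cfg.rank_max}")
    hard_cfg = ImputeConfig(rank_max=K, lam=0.0, max_iter=cfg.max_iter, tol=cfg.tol)
    return soft_impute(data, hard_cfg)


def oracle_lambda(
    data: ObservedData,
    truth: Subspace,
    K: int,
    grid: np.ndarray,
    cfg: ImputeConfig | None = None,
) -> tuple[float, float]:
    """Per-instance oracle tuning of the soft-impute penalty.

    Runs soft impute for every ``lam`` in the grid (warm-starting along the
    grid sorted descending, standard for regularisation paths), scores the
    sin-theta loss of the resulting rank-K right singular space against the
    known truth, and returns ``(best_lam, best_loss)``.  Not available to a
    practitioner — used to benchmark the method at its best.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    base = cfg or ImputeConfig()
    best_lam, best_loss = float("nan"), float("inf")
    x = None
    for lam in np.sort(grid)[::-1]:
        run_cfg = ImputeConfig(
            rank_max=base.rank_max, lam=float(lam), max_iter=base.max_iter, tol=base.tol
        )
        x = soft_impute(data, run_cfg, x0=x)
        loss = sin_theta_loss(top_k_right_singular(x, K), truth)
        if loss < best_loss:
            best_lam, best_loss = float(lam), float(loss)
    return best_lam, best_loss


def _pattern_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by identical missingness pattern."""
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    return [
        (patterns[g].astype(bool), np.flatnonzero(inverse == g))
        for g in range(patterns.shape[0])
    ]


def em_mvn(
    data: ObservedData,
    max_iter: int = 100,
    ridge: float | None = None,
    tol: float = 1e-8,
    fix_mean_zero: bool = True,
    init_cov: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """EM for the mean and covariance of a multivariate normal under MAR.

    E-step: for each missingness pattern, impute the conditional mean of the
    missing block given the observed block and add the conditional covariance
    (a Schur complement, ridge-regularised for invertibility) to the expected
    second moment.  M-step: update the mean (unless ``fix_mean_zero``) and
    covariance.  Returns ``(mu, sigma, loglik_trace)``; the observed-data
    log-likelihood is non-decreasing along the trace.
    """
    n, d = data.n, data.d
    y, mask = data.y_obs, data.mask
    if init_cov is None:
        sigma = (y.T @ y) / n
        sigma = sigma + 1e-6 * np.trace(sigma) / d * np.eye(d)
    else:
        sigma = np.array(init_cov, dtype=float)
    mu = np.zeros(d)
    groups = _pattern_groups(mask)
    trace: list[float] = []
    for _ in range(max_iter):
        if ridge is None:
            eps = 1e-8 * float(np.trace(sigma)) / d
        else:
            eps = ridge
        s_acc = np.zeros((d, d))
        mean_acc = np.zeros(d)
        loglik = 0.0
        for obs, rows in groups:
            miss = ~obs
            yo = y[np.ix_(rows, np.flatnonzero(obs))]
            s_oo = sigma[np.ix_(obs, obs)] + eps * np.eye(int(obs.sum()))
            try:
                chol = scipy.linalg.cho_factor(s_oo, lower=True)
            except scipy.linalg.LinAlgError as exc:
                raise EMInstabilityError(
                    "singular observed-block covariance in EM E-step "
                    f"(pattern with {int(obs.sum())} observed columns)"
                ) from exc
            resid = yo - mu[obs][None, :]
            solved = scipy.linalg.cho_solve(chol, resid.T).T
            # observed-data log-likelihood for this pattern
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            quad = float(np.sum(resid * solved))
            loglik += -0.5 * (
                rows.size * (logdet + int(obs.sum()) * np.log(2 * np.pi)) + quad
            )
            filled = np.tile(mu, (rows.size, 1))
            filled[:, obs] = yo
            if miss.any():
                s_mo = sigma[np.ix_(miss, obs)]
                filled[:, miss] = mu[miss][None, :] + solved @ s_mo.T
                cond_cov = sigma[np.ix_(miss, miss)] - s_mo @ scipy.linalg.cho_solve(
                    chol, s_mo.T
                )
            centered = filled  # second moment about the origin
            s_acc += centered.T @ centered
            if miss.any():
                block = np.zeros((d, d))
                block[np.ix_(miss, miss)] = cond_cov
                s_acc += rows.size * block
            mean_acc += filled.sum(axis=0)
        new_mu = np.zeros(d) if fix_mean_zero else mean_acc / n
        new_sigma = s_acc / n - np.outer(new_mu, new_mu)
        new_sigma = (new_sigma + new_sigma.T) / 2.0
        mu, sigma = new_mu, new_sigma
        trace.append(loglik)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) <= tol * (1.0 + abs(trace[-2])):
            break
    return mu, sigma, trace


def em_mvn_estimator(
    data: ObservedData,
    K: int,
    max_iter: int = 100,
    ridge: float | None = None,
    init_cov: np.ndarray | None = None,
    fix_mean_zero: bool = True,
) -> Subspace:
    """Top-K eigenvectors of the EM-estimated covariance."""
    _, sigma, _ = em_mvn(
        data,
        max_iter=max_iter,
        ridge=ridge,
        fix_mean_zero=fix_mean_zero,
        init_cov=init_cov,
    )
    return init_estimator(sigma, K)
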