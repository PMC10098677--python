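"""Iterative impute-project-refine estimation of a principal subspace.

Given a current loading estimate ``V`` (``d x K``, orthonormal columns), one
*refinement* step treats each row ``i`` of the data as a noisy point near the
span of ``V``: the observed coordinates ``y_{i,J_i}`` are regressed on the
corresponding rows ``V_{J_i}`` to get a score vector ``u_i`` (least squares),
the missing coordinates are imputed as ``V_{J_i^c} u_i`` while observed
entries are kept verbatim, and the next estimate is the top-K right singular
space of the imputed matrix.  Iterating this map contracts the estimate
towards the true subspace geometrically in the noiseless case, provided
enough data are observed and the rows retained carry enough information.

The latter proviso is enforced by *row screening*: row ``i`` participates in
the refinement only if it has strictly more than ``K`` observed entries and
``sigma_K(V_{J_i}) >= sqrt(|J_i| / d) / sigma_star``, i.e. the restriction of
the current loadings to the observed coordinates is well conditioned relative
to a uniformly spread pattern.  ``sigma_star`` (default 3) controls how
aggressive the screening is; performance is insensitive to it over a wide
range.  Screening is recomputed against the current iterate at every
iteration (a ``freeze_screening`` flag keeps the initial screen instead).

Convergence is declared when the sin-theta loss between successive iterates
drops below ``kappa_star`` (rotation-invariant, so the trace is identical for
initialisers spanning the same subspace).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .estimators import DegenerateDataError, ObservedData
from .metrics import Subspace, sin_theta_loss

__all__ = [
    "AlgoConfig",
    "ScreeningResult",
    "FitTrace",
    "impute_row",
    "refine",
    "screen_rows",
    "fit_primepca",
    "compute_scores",
]

logger = logging.getLogger(__name__)

# Above this size the top-K SVD of the imputed matrix goes through ARPACK
# (with a fixed start vector, so runs stay deterministic) instead of LAPACK.
_SVDS_MIN_DIM = 200


@dataclass(frozen=True)
class AlgoConfig:
    """Tuning knobs for the iterative fit."""

    K: int
    sigma_star: float = 3.0
    n_iter: int = 2000
    kappa_star: float = 1e-6
    center: bool = False
    freeze_screening: bool = False
    keep_iterates: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.sigma_star <= 0:
            raise ValueError("sigma_star must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.kappa_star < 0:
            raise ValueError("kappa_star must be nonnegative")


@dataclass(frozen=True)
class ScreeningResult:
    """Partition of the examined rows by screening outcome."""

    kept: np.ndarray
    dropped_small: np.ndarray
    dropped_sigma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("kept", "dropped_small", "dropped_sigma"):
            arr = np.sort(np.asarray(getattr(self, name), dtype=np.int64))
            object.__setattr__(self, name, arr)
            arr.setflags(write=False)

    @property
    def n_kept(self) -> int:
        return int(self.kept.size)


@dataclass
class FitTrace:
    """Full record of one iterative fit."""

    estimates: list[Subspace]
    successive_change: list[float]
    iterations_run: int
    converged: bool
    screening: list[ScreeningResult]

    @property
    def final(self) -> Subspace:
        return self.estimates[-1]


def _row_gram_and_proj(
    y_obs: np.ndarray, mask: np.ndarray, basis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched ``V_J' V_J`` (n,K,K) and ``V_J' y_J`` (n,K) for every row."""
    d, K = basis.shape
    outer = (basis[:, :, None] * basis[:, None, :]).reshape(d, K * K)
    grams = (mask.astype(float) @ outer).reshape(-1, K, K)
    proj = y_obs @ basis
    return grams, proj


def impute_row(
    y_obs_row: np.ndarray, observed_idx: np.ndarray, v: Subspace
) -> tuple[np.ndarray, np.ndarray]:
    """Score and impute a single row given the current loadings.

    ``scores`` is the least-squares solution of
    ``min_u || y_obs_row - V_{J} u ||_2`` over the observed index set ``J``;
    the returned d-vector keeps the observed entries verbatim and fills the
    rest with ``V_{J^c} scores``.  Rank-deficient ``V_J`` falls back to the
    minimum-norm solution with a warning (screening should prevent this).
    """
    observed_idx = np.asarray(observed_idx, dtype=np.int64)
    y_obs_row = np.asarray(y_obs_row, dtype=float)
    if y_obs_row.shape != observed_idx.shape:
        raise ValueError("y_obs_row and observed_idx must have equal length")
    v_sub = v.basis[observed_idx]
    if observed_idx.size >= v.K and np.linalg.matrix_rank(v_sub) == v.K:
        scores, *_ = scipy.linalg.lstsq(v_sub, y_obs_row)
    else:
        logger.warning(
            "rank-deficient restricted loadings (|J|=%d, K=%d); "
            "using minimum-norm solution",
            observed_idx.size,
            v.K,
        )
        scores = np.linalg.pinv(v_sub) @ y_obs_row
    imputed = v.basis @ scores
    imputed[observed_idx] = y_obs_row
    return scores, imputed


def _top_k_right(m: np.ndarray, K: int) -> Subspace:
    """Top-K right singular space; ARPACK for large inputs, LAPACK otherwise."""
    n, d = m.shape
    if min(n, d) >= _SVDS_MIN_DIM and K < min(n, d) - 1:
        v0 = np.full(min(n, d), 1.0 / np.sqrt(min(n, d)))
        _, s, vt = scipy.sparse.linalg.svds(m, k=K, v0=v0)
        return Subspace.from_matrix(vt.T, values=s)
    _, s, vt = scipy.linalg.svd(m, full_matrices=False)
    return Subspace.from_matrix(vt[:K].T, values=s[:K])


def refine(
    K: int, v_in: Subspace, data: ObservedData, rows: np.ndarray | None = None
) -> Subspace:
    """One refinement step: impute every supplied row, then project.

    The caller is responsible for screening: every row used should have more
    than ``K`` observed entries and a well-conditioned restricted loading
    matrix.  Observed entries are preserved verbatim in the imputed matrix.
    """
    if K != v_in.K:
        raise ValueError(f"v_in has K={v_in.K}, expected {K}")
    if rows is None:
        rows = np.arange(data.n)
    rows = np.asarray(rows, dtype=np.int64)
    if rows.size < K:
        raise ValueError(f"need at least K={K} rows, got {rows.size}")
    y = data.y_obs[rows]
    mask = data.mask[rows]
    grams, proj = _row_gram_and_proj(y, mask, v_in.basis)
    try:
        scores = np.linalg.solve(grams, proj[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # near-singular restricted loadings slipped past the caller
        logger.warning("singular row system in refine; using per-row lstsq")
        scores = np.empty((rows.size, K))
        for r in range(rows.size):
            idx = np.flatnonzero(mask[r])
            scores[r], _ = impute_row(y[r, idx], idx, v_in)
    imputed = np.where(mask == 1, y, scores @ v_in.basis.T)
    return _top_k_right(imputed, K)


def screen_rows(data: ObservedData, v: Subspace, cfg: AlgoConfig) -> ScreeningResult:
    """Partition rows into kept / too-few-observations / ill-conditioned."""
    grams, _ = _row_gram_and_proj(data.y_obs, data.mask, v.basis)
    counts = data.mask.sum(axis=1).astype(np.int64)
    sigma_min_sq = np.linalg.eigvalsh(grams)[:, 0]
    enough = counts > cfg.K
    threshold_sq = counts / (data.d * cfg.sigma_star**2)
    # tiny relative slack so exact boundary cases (e.g. full observation with
    # sigma_star = 1) are not dropped by eigenvalue round-off
    well_cond = sigma_min_sq >= threshold_sq * (1.0 - 1e-9)
    kept = np.flatnonzero(enough & well_cond)
    dropped_small = np.flatnonzero(~enough)
    dropped_sigma = np.flatnonzero(enough & ~well_cond)
    return ScreeningResult(kept, dropped_small, dropped_sigma)


def fit_primepca(data: ObservedData, v0: Subspace, cfg: AlgoConfig) -> FitTrace:
    """Iterate screen -> refine until convergence or the iteration cap.

    Returns the full trace: per-iteration estimates (unless
    ``cfg.keep_iterates`` is off), sin-theta changes between successive
    iterates, and the screening partition used at each iteration.
    """
    if v0.K != cfg.K or v0.d != data.d:
        raise ValueError("initialiser shape does not match data/config")
    if cfg.center:
        col_counts = data.mask.sum(axis=0)
        means = np.where(col_counts > 0, data.y_obs.sum(axis=0) / np.maximum(col_counts, 1), 0.0)
        data = ObservedData((data.y_obs - means[None, :]) * data.mask, data.mask)

    v = v0
    estimates: list[Subspace] = [v0] if cfg.keep_iterates else []
    changes: list[float] = []
    screenings: list[ScreeningResult] = []
    frozen = screen_rows(data, v0, cfg) if cfg.freeze_screening else None
    converged = False
    t = 0
    for t in range(1, cfg.n_iter + 1):
        scr = frozen if frozen is not None else screen_rows(data, v, cfg)
        if scr.n_kept < max(cfg.K, 1):
            raise DegenerateDataError(
                f"iteration {t}: screening kept {scr.n_kept} row(s), "
                f"need at least {max(cfg.K, 1)}"
            )
        v_new = refine(cfg.K, v, data, rows=scr.kept)
        change = sin_theta_loss(v_new, v)
        v = v_new
        changes.append(change)
        screenings.append(scr)
        if cfg.keep_iterates:
            estimates.append(v)
        if change <= cfg.kappa_star:
            converged = True
            break
    if not cfg.keep_iterates:
        estimates = [v]
    return FitTrace(
        estimates=estimates,
        successive_change=changes,
        iterations_run=t,
        converged=converged,
        screening=screenings,
    )


def compute_scores(data: ObservedData, v: Subspace) -> np.ndarray:
    """Post-hoc least-squares scores for *all* rows, screened or not.

    Rows that the fit excluded still get minimum-norm projections here so that
    downstream consumers (score plots, imputation) cover the full sample; rows
    with no observed entries get zero scores.
    """
    scores = np.zeros((data.n, v.K))
    for i in range(data.n):
        idx = data.row_observed_indices(i)
        if idx.size == 0:
            continue
        v_sub = v.basis[idx]
        scores[i] = np.linalg.pinv(v_sub) @ data.y_obs[i, idx]
    return scores
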