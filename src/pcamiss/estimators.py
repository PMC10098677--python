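"""Weighted-covariance spectral estimators for partially observed data.

With mask ``Omega`` and zero-filled data ``Y_Omega = Y o Omega``, the naive
second-moment matrix ``n^-1 Y_Omega' Y_Omega`` is biased: each entry is
attenuated by the (co-)observation probability of the columns involved.  The
estimators here undo that attenuation by an entrywise (Hadamard) reweighting:

* homogeneous ("OPW"): a single observed fraction ``p_hat`` is estimated and
  the weight matrix ``W_hat = p_hat^-2 (11' - (1 - p_hat) I)`` applied, i.e.
  ``p_hat^-1`` on the diagonal and ``p_hat^-2`` off it;
* heterogeneous: per-pair weight ``W~_jk = n / #{i : omega_ij omega_ik = 1}``
  (zero when columns j,k are never co-observed), valid under arbitrary
  column-wise heterogeneity;
* grouped ("OPWv"): when the missingness depends on a fully observed
  categorical covariate, per-group OPW covariances with group-specific
  ``p_hat_l`` are combined with weights ``n_l / n``.

The leading eigenvectors of these reweighted covariances are consistent
spectral estimates of the principal subspace and serve as initialisers for
the iterative refinement algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .metrics import Subspace

__all__ = [
    "ObservedData",
    "WeightMatrix",
    "GroupLabels",
    "observed_fraction",
    "opw_weight",
    "opw_covariance",
    "hetero_weight",
    "hetero_covariance",
    "opwv_covariance",
    "init_estimator",
    "DegenerateDataError",
]

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Raised when the observation pattern cannot support the computation."""


@dataclass(frozen=True)
class ObservedData:
    """The pair ``(Y o Omega, Omega)``: zero-filled data plus revelation mask."""

    y_obs: np.ndarray
    mask: np.ndarray
    n: int = field(init=False)
    d: int = field(init=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y_obs, dtype=float)
        m = np.asarray(self.mask)
        if y.ndim != 2 or m.shape != y.shape:
            raise ValueError("y_obs and mask must be matrices of equal shape")
        n, d = y.shape
        if n < 2 or d < 2:
            raise ValueError(f"need n >= 2 and d >= 2, got {n}x{d}")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        m = m.astype(np.int8)
        if np.any(y[m == 0] != 0.0):
            raise ValueError("y_obs must be exactly zero at unobserved cells")
        if not np.all(np.isfinite(y)):
            raise ValueError("observed values must be finite")
        object.__setattr__(self, "y_obs", y)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "d", d)
        self.y_obs.setflags(write=False)
        self.mask.setflags(write=False)

    @classmethod
    def from_full(cls, y: np.ndarray, mask: np.ndarray) -> "ObservedData":
        """Apply a mask to a complete matrix, zeroing the hidden cells."""
        mask = np.asarray(mask)
        return cls(np.asarray(y, dtype=float) * mask, mask)

    @classmethod
    def from_na(cls, y: np.ndarray) -> "ObservedData":
        """Build from a matrix whose missing cells are NaN."""
        y = np.asarray(y, dtype=float)
        mask = (~np.isnan(y)).astype(np.int8)
        return cls(np.nan_to_num(y, nan=0.0) * mask, mask)

    def row_observed_indices(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.mask[i])


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric nonnegative entrywise covariance reweighting."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")
        object.__setattr__(self, "w", w)
        self.w.setflags(write=False)


@dataclass(frozen=True)
class GroupLabels:
    """Length-n vector of category ids in ``{0, ..., L-1}``."""

    labels: np.ndarray
    L: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a vector")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(self.L)):
            raise ValueError(
                f"every category in 0..{self.L - 1} must occur at least once"
            )
        object.__setattr__(self, "labels", labels.astype(np.int64))
        self.labels.setflags(write=False)


def observed_fraction(data: ObservedData) -> float:
    """Proportion of observed entries, ``||Omega||_1 / (n d)``."""
    total = int(data.mask.sum())
    if total == 0:
        raise DegenerateDataError("mask has no observed entries")
    return total / (data.n * data.d)


def opw_weight(p_hat: float, d: int) -> WeightMatrix:
    """Homogeneous weight: ``p_hat^-1`` diagonal, ``p_hat^-2`` off-diagonal."""
    if not 0.0 < p_hat <= 1.0:
        raise ValueError(f"p_hat must lie in (0, 1], got {p_hat}")
    w = np.full((d, d), p_hat**-2)
    np.fill_diagonal(w, 1.0 / p_hat)
    return WeightMatrix(w)


def _centered(data: ObservedData, center: bool) -> np.ndarray:
    """Zero-filled data, optionally centred by per-column observed means."""
    if not center:
        return data.y_obs
    counts = data.mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, data.y_obs.sum(axis=0) / np.maximum(counts, 1), 0.0)
    return (data.y_obs - means[None, :]) * data.mask


def _warn_empty_columns(data: ObservedData) -> None:
    empty = int(np.sum(data.mask.sum(axis=0) == 0))
    if empty:
        logger.warning("%d all-missing column(s); their covariance rows are 0", empty)


def opw_covariance(data: ObservedData, center: bool = False) -> np.ndarray:
    """Observed-proportion weighted covariance ``(n^-1 Y_Omega' Y_Omega) o W_hat``."""
    _warn_empty_columns(data)
    y = _centered(data, center)
    second_moment = (y.T @ y) / data.n
    w = opw_weight(observed_fraction(data), data.d)
    return second_moment * w.w


def hetero_weight(mask: np.ndarray) -> WeightMatrix:
    """Per-pair weight ``n`` over the co-observation count (0 if never co-observed)."""
    mask = np.asarray(mask, dtype=float)
    n = mask.shape[0]
    counts = mask.T @ mask
    with np.errstate(divide="ignore"):
        w = np.where(counts > 0, n / np.maximum(counts, 1), 0.0)
    zeroed = int(np.sum(counts == 0))
    if zeroed:
        logger.warning(
            "%d column pair(s) never co-observed; their weights are 0 and the "
            "corresponding covariance entries are unidentified",
            zeroed,
        )
    return WeightMatrix(w)


def hetero_covariance(data: ObservedData, center: bool = False) -> np.ndarray:
    """Heterogeneity-adapted weighted covariance ``(n^-1 Y_Omega' Y_Omega) o W~``."""
    y = _centered(data, center)
    second_moment = (y.T @ y) / data.n
    return second_moment * hetero_weight(data.mask).w


def opwv_covariance(
    data: ObservedData,
    groups: GroupLabels,
    y0: np.ndarray,
    p_known: np.ndarray | None = None,
) -> np.ndarray:
    """Grouped OPW covariance for MAR-via-observed-category missingness.

    Combines per-group OPW covariances ``G(l)`` (group-specific observed
    fraction ``p_hat_l``, or known ``p_known[l]``) as ``sum_l (n_l/n) G(l)``,
    and embeds the result as the lower-right ``d x d`` block of a
    ``(d+1) x (d+1)`` matrix whose top-left cell is the empirical variance of
    the observed categorical/anchor variable ``y0`` (off-blocks zero, since
    the anchor is uncorrelated with the rest by construction).
    """
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (data.n,):
        raise ValueError("y0 must be a length-n vector")
    if groups.labels.shape != (data.n,):
        raise ValueError("group labels must have length n")
    d = data.d
    combined = np.zeros((d, d))
    for lab in range(groups.L):
        rows = np.flatnonzero(groups.labels == lab)
        if rows.size == 0:
            raise DegenerateDataError(f"group {lab} is empty")
        sub_mask = data.mask[rows]
        if p_known is not None:
            p_l = float(p_known[lab])
        else:
            p_l = float(sub_mask.sum()) / (rows.size * d)
        if p_l <= 0:
            raise DegenerateDataError(f"group {lab} has no observed entries")
        y_sub = data.y_obs[rows]
        g_l = (y_sub.T @ y_sub) / rows.size * opw_weight(p_l, d).w
        combined += (rows.size / data.n) * g_l
    out = np.zeros((d + 1, d + 1))
    out[0, 0] = float(np.mean(y0**2) - np.mean(y0) ** 2)
    out[1:, 1:] = combined
    return out


def init_estimator(cov: np.ndarray, K: int) -> Subspace:
    """Canonicalised top-K eigenvectors (by algebraic eigenvalue) of a symmetric matrix."""
    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    if cov.ndim != 2 or cov.shape[1] != d:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, float(np.abs(cov).max()))):
        raise ValueError("covariance is not symmetric")
    if not 1 <= K < d:
        raise ValueError(f"K={K} out of range for d={d}")
    sym = (cov + cov.T) / 2.0  # absorb floating-point asymmetry
    vals, vecs = scipy.linalg.eigh(sym, subset_by_index=[d - K, d - 1])
    return Subspace.from_matrix(vecs, values=vals)
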