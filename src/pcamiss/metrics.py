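"""Subspace containers and distances.

A *subspace* here is always represented by a ``d x K`` matrix with orthonormal
columns.  All comparisons between subspaces are rotation-invariant: the objects
of interest are column spans, not individual basis vectors.  Three notions of
discrepancy are provided:

* the Davis--Kahan sin-theta loss
  ``L(V1, V2) = 2**-0.5 * ||V1 V1' - V2 V2'||_F``, equal to the Frobenius norm
  of the vector of sines of the principal angles, with range ``[0, sqrt(K)]``;
* the two-to-infinity distance ``T(Vt, V) = ||Vt - V R||_{2->inf}`` where ``R``
  is the orthogonal Procrustes rotation aligning ``V`` with ``Vt`` -- the
  maximum row-wise Euclidean error after optimal alignment;
* the incoherence ``mu(V) = sqrt(d/K) * ||V||_{2->inf}``, which measures how
  concentrated the loadings are on individual coordinates
  (``1 <= mu <= sqrt(d/K)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "Subspace",
    "AlignmentRotation",
    "canonicalize_basis",
    "procrustes_align",
    "sin_theta_loss",
    "two_to_inf_distance",
    "incoherence",
    "top_k_right_singular",
]

_ORTHO_TOL = 1e-10


def canonicalize_basis(basis: np.ndarray, order: np.ndarray | None = None) -> np.ndarray:
    """Return a sign/order-canonical copy of an orthonormal basis.

    Columns are re-ordered by ``order`` (typically associated eigen/singular
    values, descending) if given, and each column is flipped so that its
    largest-magnitude entry is positive (ties broken by lowest row index).
    """
    basis = np.asarray(basis, dtype=float)
    if order is not None:
        basis = basis[:, np.argsort(-np.asarray(order), kind="stable")]
    basis = basis.copy()
    for k in range(basis.shape[1]):
        col = basis[:, k]
        i = int(np.argmax(np.abs(col)))  # argmax returns lowest index on ties
        if col[i] < 0:
            basis[:, k] = -col
    return basis


@dataclass(frozen=True)
class Subspace:
    """A ``d x K`` orthonormal loading matrix in canonical form.

    Canonical form: columns ordered by associated value descending (the order
    in which the constructor received them is trusted if no values are given)
    and each column's largest-magnitude entry positive.
    """

    basis: np.ndarray
    d: int = field(init=False)
    K: int = field(init=False)

    def __post_init__(self) -> None:
        basis = np.asarray(self.basis, dtype=float)
        if basis.ndim != 2:
            raise ValueError("basis must be a 2-d array")
        d, K = basis.shape
        if K < 1 or d <= K:
            raise ValueError(f"need d > K >= 1, got d={d}, K={K}")
        gram = basis.T @ basis
        if not np.allclose(gram, np.eye(K), atol=1e-8):
            raise ValueError("basis columns are not orthonormal")
        basis = canonicalize_basis(basis)
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "K", K)
        self.basis.setflags(write=False)

    @classmethod
    def from_matrix(cls, basis: np.ndarray, values: np.ndarray | None = None) -> "Subspace":
        """Build a Subspace, ordering columns by ``values`` (descending)."""
        return cls(canonicalize_basis(basis, order=values))

    def projector(self) -> np.ndarray:
        return self.basis @ self.basis.T


@dataclass(frozen=True)
class AlignmentRotation:
    """A K x K orthogonal change-of-basis matrix."""

    rotation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        k = rot.shape[0]
        if rot.ndim != 2 or rot.shape[1] != k:
            raise ValueError("rotation must be square")
        if not np.allclose(rot.T @ rot, np.eye(k), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthogonal")
        object.__setattr__(self, "rotation", rot)
        self.rotation.setflags(write=False)


def _check_shapes(v1: Subspace, v2: Subspace) -> None:
    if (v1.d, v1.K) != (v2.d, v2.K):
        raise ValueError(
            f"subspace shape mismatch: ({v1.d},{v1.K}) vs ({v2.d},{v2.K})"
        )


def procrustes_align(vtilde: Subspace, v: Subspace) -> AlignmentRotation:
    """Orthogonal rotation R minimising ``||vtilde - v R||_F``.

    If ``W1 D W2'`` is an SVD of ``vtilde' v`` the minimiser is ``W2 W1'``.
    For rank-deficient ``vtilde' v`` any completion of the orthogonal factors
    is a valid minimiser; the one induced by LAPACK's SVD is returned.
    """
    _check_shapes(vtilde, v)
    w1, _, w2t = scipy.linalg.svd(vtilde.basis.T @ v.basis)
    return AlignmentRotation(w2t.T @ w1.T)


def sin_theta_loss(v1: Subspace, v2: Subspace) -> float:
    """Davis--Kahan loss ``2**-0.5 ||P1 - P2||_F`` between column spans."""
    _check_shapes(v1, v2)
    # direct projector difference: the Gram identity 2K - 2||V1'V2||_F^2
    # cancels catastrophically for nearby subspaces
    diff = v1.projector() - v2.projector()
    return float(np.linalg.norm(diff) / np.sqrt(2.0))


def two_to_inf_distance(vtilde: Subspace, v: Subspace) -> float:
    """Max row-wise Euclidean error after Procrustes-aligning ``v`` to ``vtilde``."""
    rot = procrustes_align(vtilde, v)
    diff = vtilde.basis - v.basis @ rot.rotation
    return float(np.max(np.sqrt(np.sum(diff * diff, axis=1))))


def incoherence(v: Subspace) -> float:
    """``sqrt(d/K)`` times the largest row norm of the loading matrix."""
    row_norms = np.sqrt(np.sum(v.basis * v.basis, axis=1))
    return float(np.sqrt(v.d / v.K) * np.max(row_norms))


def top_k_right_singular(m: np.ndarray, K: int) -> Subspace:
    """Canonicalised top-K right singular vectors of a dense matrix."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("input must be a matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("input contains non-finite entries")
    n, d = m.shape
    if not 1 <= K <= min(n, d):
        raise ValueError(f"K={K} out of range for a {n}x{d} matrix")
    if K >= d:
        raise ValueError(f"subspace dimension K={K} must be < d={d}")
    _, s, vt = scipy.linalg.svd(m, full_matrices=False)
    return Subspace.from_matrix(vt[:K].T, values=s[:K])
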