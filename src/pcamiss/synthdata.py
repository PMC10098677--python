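"""Synthetic data generators: spiked factor model and missingness mechanisms.

The complete-data model is ``Y = U V_K' + noise_sd * Z`` with ``U`` having
i.i.d. ``N(0, Sigma_u)`` rows, ``V_K`` a fixed ``d x K`` orthonormal loading
matrix and ``Z`` i.i.d. standard Gaussian noise, so that
``Cov(y_1) = V_K Sigma_u V_K' + noise_sd**2 I`` is a K-spiked covariance whose
leading eigenspace is exactly ``Col(V_K)``.  The signal-to-noise ratio is
``SNR = tr(V Sigma_u V') / tr(noise_sd**2 I) = tr(Sigma_u) / (noise_sd**2 d)``.

Revelation masks come in three families:

* MCAR grids H1-H4 (independent Bernoulli cells): homogeneous 5%; mildly
  heterogeneous ``P_i Q_j`` with ``P_i ~ U[0, 0.2]``, ``Q_j ~ U[0.05, 0.95]``;
  column-heterogeneous 0.19/0.01 (odd/even columns, 1-based); and
  row-heterogeneous 0.18/0.02 (odd/even rows, 1-based);
* a MAR mechanism driven by a fully observed binary category: the category
  flips the data covariance between two spiked alternatives and tilts the
  per-column observation logit by ``alpha``, so at ``alpha = 0`` the mask is
  independent of the data;
* an MNAR mechanism on Gaussian random walks: each row is a d-step standard
  random walk (covariance ``min(j,k)``), and entry ``(i,j)`` is observed iff
  an independent ``Bern(p)`` coin lands heads *and* the walk has stayed
  strictly inside ``(-tau, tau)`` before step j (column 1 is never
  thresholded).  Observation thus depends on values that may themselves be
  unobserved whenever ``p < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .estimators import ObservedData
from .metrics import Subspace

__all__ = [
    "SpikedModelConfig",
    "MissingnessConfig",
    "make_vk_twospike",
    "haar_orthonormal",
    "generate_spiked",
    "generate_mask",
    "generate_mar_categorical",
    "generate_mnar_randomwalk",
    "randomwalk_covariance",
    "randomwalk_leading_subspace",
    "snr",
]

MECHANISMS = ("H1", "H2", "H3", "H4", "MAR_CAT", "MNAR_WALK")


@dataclass(frozen=True)
class SpikedModelConfig:
    """Parameters of the complete-data factor model."""

    n: int
    d: int
    K: int
    sigma_u: np.ndarray
    loadings: Subspace
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        su = np.asarray(self.sigma_u, dtype=float)
        if su.shape != (self.K, self.K):
            raise ValueError("sigma_u must be K x K")
        if not np.allclose(su, su.T):
            raise ValueError("sigma_u must be symmetric")
        if np.any(scipy.linalg.eigvalsh(su) < -1e-10):
            raise ValueError("sigma_u must be positive semidefinite")
        if self.loadings.d != self.d or self.loadings.K != self.K:
            raise ValueError("loadings shape does not match (d, K)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "sigma_u", su)
        su.setflags(write=False)


@dataclass(frozen=True)
class MissingnessConfig:
    """Mechanism id plus mechanism-specific parameters."""

    mechanism: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; choose from {MECHANISMS}"
            )
        for key, val in self.params.items():
            if key in ("p", "tau", "alpha"):
                continue
            raise ValueError(f"unknown parameter {key!r}")
        p = self.params.get("p")
        if p is not None and not 0.0 <= p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def make_vk_twospike(d: int, layout: str = "edges") -> Subspace:
    """The fixed two-spike ``d x 2`` loading matrix of the simulation design.

    Column 1 is the flat unit vector ``d**-0.5 * 1``.  Column 2 has entries
    ``+(d/2)**-0.5`` on d/4 coordinates and ``-(d/2)**-0.5`` on another d/4,
    zero elsewhere; the balanced signs make it orthogonal to column 1.  With
    ``layout='edges'`` (default) the positive block is the first quarter and
    the negative block the last quarter; ``layout='head'`` puts both blocks in
    the first half.  Either way the entry magnitudes are ``1/sqrt(d)`` and
    ``1/sqrt(d/2)`` (e.g. 1/sqrt(500) and 1/sqrt(250) at d=500).
    """
    if d % 4 != 0:
        raise ValueError(f"d must be divisible by 4, got {d}")
    q = d // 4
    col1 = np.full(d, d**-0.5)
    col2 = np.zeros(d)
    mag = (d / 2) ** -0.5
    if layout == "edges":
        col2[:q] = mag
        col2[-q:] = -mag
    elif layout == "head":
        col2[:q] = mag
        col2[q : 2 * q] = -mag
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return Subspace(np.column_stack([col1, col2]))


def haar_orthonormal(d: int, K: int, seed: int) -> Subspace:
    """A seeded Haar-random ``d x K`` orthonormal matrix."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((d, K))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))
    return Subspace(q)


def generate_spiked(cfg: SpikedModelConfig) -> np.ndarray:
    """Draw a complete ``n x d`` matrix from the spiked factor model."""
    rng = np.random.default_rng(cfg.seed)
    chol = scipy.linalg.cholesky(
        cfg.sigma_u + 1e-12 * np.eye(cfg.K), lower=True
    )
    u = rng.standard_normal((cfg.n, cfg.K)) @ chol.T
    y = u @ cfg.loadings.basis.T
    if cfg.noise_sd > 0:
        y = y + cfg.noise_sd * rng.standard_normal((cfg.n, cfg.d))
    return y


def snr(cfg: SpikedModelConfig) -> float:
    """Signal-to-noise ratio ``tr(Sigma_u) / (noise_sd**2 d)``."""
    if cfg.noise_sd == 0:
        return float("inf")
    return float(np.trace(cfg.sigma_u)) / (cfg.noise_sd**2 * cfg.d)


def _cell_probabilities(n: int, d: int, cfg: MissingnessConfig, rng) -> np.ndarray:
    mech = cfg.mechanism
    if mech == "H1":
        p = cfg.params.get("p", 0.05)
        return np.full((n, d), p)
    if mech == "H2":
        rows = rng.uniform(0.0, 0.2, size=n)
        cols = rng.uniform(0.05, 0.95, size=d)
        return np.outer(rows, cols)
    if mech == "H3":
        probs = np.where(np.arange(1, d + 1) % 2 == 1, 0.19, 0.01)
        return np.broadcast_to(probs, (n, d)).copy()
    if mech == "H4":
        probs = np.where(np.arange(1, n + 1) % 2 == 1, 0.18, 0.02)
        return np.broadcast_to(probs[:, None], (n, d)).copy()
    raise ValueError(f"mechanism {mech!r} is not an MCAR grid")


def generate_mask(n: int, d: int, cfg: MissingnessConfig) -> np.ndarray:
    """Independent Bernoulli revelation mask for the MCAR grids H1-H4.

    H2's row and column probability factors are redrawn on every call, i.e.
    per replicate, as in the simulation design.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = _cell_probabilities(n, d, cfg, rng)
    return (rng.random((n, d)) < probs).astype(np.int8)


def generate_mar_categorical(
    n: int,
    d: int,
    alpha: float,
    spikes_plus: Subspace,
    spikes_minus: Subspace,
    seed: int,
) -> tuple[np.ndarray, ObservedData]:
    """MAR mechanism driven by a fully observed binary category.

    ``y0 ~ Unif{-1, +1}``; given ``y0`` the remaining coordinates are
    ``N(0, V_{y0} diag(40, 10) V_{y0}' + I)`` and each is observed
    independently with probability ``1 / (1 + exp(j/d + y0 * alpha))``
    (1-based column index j).  Returns ``(y0, data)`` where ``data`` holds the
    ``n x d`` partially observed block; the category column itself is always
    observed and carried separately.
    """
    if spikes_plus.d != d or spikes_minus.d != d or spikes_plus.K != 2 or spikes_minus.K != 2:
        raise ValueError("spike matrices must be d x 2 orthonormal")
    rng = np.random.default_rng(seed)
    y0 = rng.choice([-1.0, 1.0], size=n)
    diag = np.sqrt(np.array([40.0, 10.0]))
    factors = rng.standard_normal((n, 2)) * diag
    noise = rng.standard_normal((n, d))
    bases = np.where(
        (y0 == 1.0)[:, None, None], spikes_plus.basis, spikes_minus.basis
    )
    y = np.einsum("nk,ndk->nd", factors, bases) + noise
    j_over_d = np.arange(1, d + 1) / d
    logits = j_over_d[None, :] + alpha * y0[:, None]
    probs = 1.0 / (1.0 + np.exp(logits))
    mask = (rng.random((n, d)) < probs).astype(np.int8)
    return y0, ObservedData.from_full(y, mask)


def randomwalk_covariance(d: int) -> np.ndarray:
    """Covariance ``min(j, k)`` of a d-step standard Gaussian random walk."""
    idx = np.arange(1, d + 1)
    return np.minimum.outer(idx, idx).astype(float)


def randomwalk_leading_subspace(d: int, K: int = 1) -> Subspace:
    """Top-K eigenvectors of the random-walk covariance (the MNAR-study truth)."""
    vals, vecs = scipy.linalg.eigh(randomwalk_covariance(d), subset_by_index=[d - K, d - 1])
    return Subspace.from_matrix(vecs, values=vals)


def generate_mnar_randomwalk(
    n: int, d: int, p: float, tau: float, seed: int
) -> ObservedData:
    """Bernoulli-thinned Gaussian random walks observed until threshold exit.

    Entry ``(i, j)`` is observed iff ``xi_ij = 1`` (``xi ~ Bern(p)`` i.i.d.)
    and ``max_{1 <= t < j} |y_it| < tau``; the empty maximum for j=1 is
    ``-inf``, so the first column is thresholded never (only thinned).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    y = np.cumsum(rng.standard_normal((n, d)), axis=1)
    xi = (rng.random((n, d)) < p).astype(np.int8)
    inside = np.abs(y) < tau
    # alive[:, j] == walk stayed strictly inside (-tau, tau) for all t < j
    alive = np.ones((n, d), dtype=bool)
    alive[:, 1:] = np.cumprod(inside[:, :-1], axis=1).astype(bool)
    mask = (xi.astype(bool) & alive).astype(np.int8)
    return ObservedData.from_full(y, mask)
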