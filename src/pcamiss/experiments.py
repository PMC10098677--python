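"""Replication harness, aggregation and file I/O.

A :class:`ScenarioConfig` names a data-generating process (the spiked factor
model with one of the MCAR masks, the categorical-MAR generator, or the
thresholded-random-walk MNAR generator), a list of estimation methods, and a
replication count.  :func:`run_scenario` draws each replicate from a seed
derived as ``base_seed + replicate_index``, runs every method against the
true leading subspace of the generating covariance, and aggregates the
sin-theta losses as mean +- SE and as RMSE.  Method failures in individual
replicates are recorded as NaN with a logged reason and excluded from the
aggregates (the exclusion count is reported).

File formats: dense delimited text with NA-coded missing cells, and
MatrixMarket coordinate triplets (1-based, absent cells missing, duplicate
entries summed).
"""

from __future__ import annotations

import io
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .baselines import (
    EMInstabilityError,
    ImputeConfig,
    em_mvn_estimator,
    hard_impute,
    mean_impute_estimator,
    oracle_lambda,
)
from .estimators import (
    DegenerateDataError,
    GroupLabels,
    ObservedData,
    hetero_covariance,
    init_estimator,
    opw_covariance,
    opwv_covariance,
)
from .metrics import Subspace, sin_theta_loss, top_k_right_singular
from .primepca import AlgoConfig, fit_primepca
from .synthdata import (
    MissingnessConfig,
    SpikedModelConfig,
    generate_mar_categorical,
    generate_mask,
    generate_mnar_randomwalk,
    generate_spiked,
    haar_orthonormal,
    make_vk_twospike,
    randomwalk_leading_subspace,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "read_matrix",
    "write_matrix",
    "KNOWN_METHODS",
]

logger = logging.getLogger(__name__)

KNOWN_METHODS = (
    "primepca",          # heterogeneous-weight spectral initialiser
    "primepca_init",     # the initialiser alone
    "primepca_mi",       # mean-imputation initialiser
    "primepca_opw",      # OPW initialiser
    "primepca_opwv",     # grouped-OPW initialiser (categorical-MAR only)
    "opw",
    "opwv",
    "mean_impute",
    "soft_impute_oracle",
    "hard_impute",
    "em",                # mean-imputation start
    "em_opw",            # OPW start
)

_METHOD_ERRORS = (
    DegenerateDataError,
    EMInstabilityError,
    np.linalg.LinAlgError,
    ValueError,
)


@dataclass(frozen=True)
class ScenarioConfig:
    """One named simulation scenario.

    ``generator`` is one of ``spiked``, ``mar_cat``, ``mnar_walk``;
    ``gen_params`` carries its parameters (see ``_draw_replicate``).
    """

    generator: str
    gen_params: dict
    methods: tuple[str, ...]
    reps: int
    K_hat: int
    loss: str = "mean_sintheta"
    base_seed: int = 0
    sigma_star: float = 3.0
    n_iter: int = 2000
    kappa_star: float = 1e-6

    def __post_init__(self) -> None:
        if self.generator not in ("spiked", "mar_cat", "mnar_walk"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.reps < 1 or self.K_hat < 1:
            raise ValueError("reps and K_hat must be >= 1")
        if self.loss not in ("mean_sintheta", "rmse_sintheta"):
            raise ValueError(f"unknown loss {self.loss!r}")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        object.__setattr__(self, "methods", tuple(self.methods))


@dataclass
class ScenarioResult:
    """Per-replicate losses and aggregates for every method."""

    config: ScenarioConfig
    losses: dict[str, np.ndarray]
    excluded: dict[str, int] = field(default_factory=dict)
    runtime_s: dict[str, float] = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for method, vec in self.losses.items():
            ok = vec[~np.isnan(vec)]
            rows.append(
                {
                    "method": method,
                    "mean": float(np.mean(ok)) if ok.size else float("nan"),
                    "se": float(np.std(ok, ddof=1) / np.sqrt(ok.size))
                    if ok.size > 1
                    else float("nan"),
                    "rmse": float(np.sqrt(np.mean(ok**2))) if ok.size else float("nan"),
                    "n_used": int(ok.size),
                    "n_excluded": int(np.isnan(vec).sum()),
                }
            )
        return pd.DataFrame(rows).set_index("method")


def _draw_replicate(cfg: ScenarioConfig, seed: int):
    """Return (data, truth, groups, y0) for one replicate.

    ``groups``/``y0`` are None except for the categorical-MAR generator,
    where the anchor column is prepended to the data matrix (always observed)
    and the truth is the leading subspace of the block covariance.
    """
    p = cfg.gen_params
    if cfg.generator == "spiked":
        n, d, K = p["n"], p["d"], p["K"]
        loadings = p.get("loadings") or make_vk_twospike(d)
        sigma_u = np.asarray(p.get("sigma_u", np.eye(K)), dtype=float)
        model = SpikedModelConfig(
            n=n, d=d, K=K, sigma_u=sigma_u, loadings=loadings,
            noise_sd=p.get("noise_sd", 1.0), seed=seed,
        )
        y = generate_spiked(model)
        miss = MissingnessConfig(
            mechanism=p["mechanism"], params=p.get("miss_params", {}), seed=seed + 1
        )
        mask = generate_mask(n, d, miss)
        return ObservedData.from_full(y, mask), loadings, None, None
    if cfg.generator == "mnar_walk":
        n, d = p["n"], p["d"]
        data = generate_mnar_randomwalk(
            n=n, d=d, p=p.get("p", 1.0), tau=p.get("tau", float(np.sqrt(d))), seed=seed
        )
        return data, randomwalk_leading_subspace(d, cfg.K_hat), None, None
    # mar_cat
    n, d, alpha = p["n"], p["d"], p.get("alpha", 0.0)
    vp = p.get("spikes_plus") or haar_orthonormal(d, 2, p.get("spike_seed", 7) * 2 + 1)
    vm = p.get("spikes_minus") or haar_orthonormal(d, 2, p.get("spike_seed", 7) * 2 + 2)
    y0, block = generate_mar_categorical(n, d, alpha, vp, vm, seed)
    diag = np.diag([40.0, 10.0])
    sigma_block = 0.5 * (vp.basis @ diag @ vp.basis.T + vm.basis @ diag @ vm.basis.T) + np.eye(d)
    sigma_full = np.zeros((d + 1, d + 1))
    sigma_full[0, 0] = 1.0
    sigma_full[1:, 1:] = sigma_block
    truth = init_estimator(sigma_full, cfg.K_hat)
    full_y = np.column_stack([y0, block.y_obs])
    full_mask = np.column_stack([np.ones(n, dtype=np.int8), block.mask])
    data = ObservedData(full_y * full_mask, full_mask)
    groups = GroupLabels(((y0 + 1) // 2).astype(np.int64), 2)
    return data, truth, groups, y0


def _initialiser(
    method: str, data: ObservedData, K: int, groups, y0
) -> Subspace:
    if method in ("primepca", "primepca_init"):
        return init_estimator(hetero_covariance(data), K)
    if method == "primepca_mi":
        return mean_impute_estimator(data, K)
    if method == "primepca_opw":
        return init_estimator(opw_covariance(data), K)
    if method == "primepca_opwv":
        if groups is None:
            raise ValueError("grouped initialiser needs the categorical-MAR generator")
        # anchor column is part of the data matrix here; grouped covariance is
        # built from the non-anchor block
        sub = ObservedData(data.y_obs[:, 1:], data.mask[:, 1:])
        return init_estimator(opwv_covariance(sub, groups, y0), K)
    raise ValueError(method)


def _run_method(
    method: str,
    data: ObservedData,
    truth: Subspace,
    cfg: ScenarioConfig,
    groups,
    y0,
) -> float:
    K = cfg.K_hat
    if method.startswith("primepca"):
        v0 = _initialiser(method if method != "primepca_init" else "primepca", data, K, groups, y0)
        if method == "primepca_init":
            return sin_theta_loss(v0, truth)
        algo = AlgoConfig(
            K=K, sigma_star=cfg.sigma_star, n_iter=cfg.n_iter,
            kappa_star=cfg.kappa_star, keep_iterates=False,
        )
        fit = fit_primepca(data, v0, algo)
        return sin_theta_loss(fit.final, truth)
    if method == "opw":
        return sin_theta_loss(init_estimator(opw_covariance(data), K), truth)
    if method == "opwv":
        if groups is None:
            raise ValueError("opwv needs the categorical-MAR generator")
        sub = ObservedData(data.y_obs[:, 1:], data.mask[:, 1:])
        est = init_estimator(opwv_covariance(sub, groups, y0), K)
        return sin_theta_loss(est, truth)
    if method == "mean_impute":
        return sin_theta_loss(mean_impute_estimator(data, K), truth)
    if method == "soft_impute_oracle":
        sigma1 = float(np.linalg.svd(data.y_obs, compute_uv=False)[0])
        grid = np.linspace(0.0, sigma1, 15)
        _, loss = oracle_lambda(data, truth, K, grid)
        return loss
    if method == "hard_impute":
        x = hard_impute(data, K, ImputeConfig())
        return sin_theta_loss(top_k_right_singular(x, K), truth)
    if method in ("em", "em_opw"):
        if method == "em_opw":
            init_cov = opw_covariance(data)
        else:
            init_cov = (data.y_obs.T @ data.y_obs) / data.n
        est = em_mvn_estimator(data, K, init_cov=init_cov)
        return sin_theta_loss(est, truth)
    raise ValueError(f"unknown method {method!r}")


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Run every configured method over ``cfg.reps`` seeded replicates."""
    losses = {m: np.full(cfg.reps, np.nan) for m in cfg.methods}
    excluded = {m: 0 for m in cfg.methods}
    runtime = {m: 0.0 for m in cfg.methods}
    for rep in range(cfg.reps):
        seed = cfg.base_seed + rep
        data, truth, groups, y0 = _draw_replicate(cfg, seed)
        for method in cfg.methods:
            tic = time.perf_counter()
            try:
                losses[method][rep] = _run_method(method, data, truth, cfg, groups, y0)
            except _METHOD_ERRORS as exc:
                excluded[method] += 1
                logger.warning(
                    "replicate %d: method %s failed (%s); recorded as NaN",
                    rep, method, exc,
                )
            runtime[method] += time.perf_counter() - tic
    return ScenarioResult(config=cfg, losses=losses, excluded=excluded, runtime_s=runtime)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, format: str = "dense_na") -> ObservedData:
    """Read a partially observed matrix from disk.

    ``dense_na``: delimited text (comma/tab/whitespace sniffed), optional
    header row, cells ``NA``/``NaN``/empty meaning missing.  ``triplet``:
    MatrixMarket coordinate format, 1-based, absent cells missing, duplicate
    entries summed.
    """
    path = Path(path)
    if format == "dense_na":
        first = ""
        with open(path) as fh:
            first = fh.readline()
        sep = "," if "," in first else ("\t" if "\t" in first else r"\s+")
        kwargs = dict(
            sep=sep, na_values=["NA", "NaN", ""], keep_default_na=True,
            float_precision="round_trip",
        )
        try:
            df = pd.read_csv(path, header=None, **kwargs)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
        if df.shape[0] and not all(
            pd.api.types.is_numeric_dtype(t) for t in df.dtypes
        ):
            # non-numeric first row: treat as header and retry
            try:
                df = pd.read_csv(path, header=0, **kwargs)
                values = df.to_numpy(dtype=float)
            except (pd.errors.ParserError, ValueError) as exc:
                raise ValueError(f"{path}: non-numeric observed cell: {exc}") from exc
        else:
            values = df.to_numpy(dtype=float)
        return ObservedData.from_na(values)
    if format == "triplet":
        try:
            m = scipy.io.mmread(str(path)).tocoo()
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise ValueError(f"{path}: malformed MatrixMarket file: {exc}") from exc
        m.sum_duplicates()
        y = np.zeros(m.shape)
        mask = np.zeros(m.shape, dtype=np.int8)
        y[m.row, m.col] = m.data
        mask[m.row, m.col] = 1
        return ObservedData(y, mask)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(data: ObservedData, path: str | Path, format: str = "dense_na") -> None:
    """Write an :class:`ObservedData` to disk in either text format."""
    path = Path(path)
    if format == "dense_na":
        full = np.where(data.mask == 1, data.y_obs, np.nan)
        df = pd.DataFrame(full)
        with io.StringIO() as buf:
            df.to_csv(buf, header=False, index=False, na_rep="NA", float_format="%.17g")
            path.write_text(buf.getvalue())
        return
    if format == "triplet":
        rows, cols = np.nonzero(data.mask)
        coo = scipy.sparse.coo_matrix(
            (data.y_obs[rows, cols], (rows, cols)), shape=(data.n, data.d)
        )
        scipy.io.mmwrite(str(path), coo)
        return
    raise ValueError(f"unknown format {format!r}")
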