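"""Weighted covariance estimators and their spectral initialisers."""

import numpy as np
import pytest

from pcamiss import (
    DegenerateDataError,
    GroupLabels,
    ObservedData,
    Subspace,
    hetero_covariance,
    hetero_weight,
    init_estimator,
    observed_fraction,
    opw_covariance,
    opw_weight,
    opwv_covariance,
    sin_theta_loss,
    top_k_right_singular,
)

from conftest import mcar_data


@pytest.fixture
def toy():
    """Y = [[1,2],[3,4]] with the (1,2) cell hidden."""
    return ObservedData(np.array([[1.0, 0.0], [3.0, 4.0]]), np.array([[1, 0], [1, 1]]))


class TestObservedData:
    def test_rejects_nonzero_hidden_cells(self):
        with pytest.raises(ValueError, match="zero"):
            ObservedData(np.ones((2, 2)), np.array([[1, 0], [1, 1]]))

    def test_from_na_roundtrip(self):
        y = np.array([[1.0, np.nan], [3.0, 4.0]])
        data = ObservedData.from_na(y)
        assert np.array_equal(data.mask, [[1, 0], [1, 1]])
        assert np.array_equal(data.y_obs, [[1.0, 0.0], [3.0, 4.0]])


class TestObservedFraction:
    def test_full_and_partial_masks(self, toy):
        full = ObservedData(np.ones((2, 2)), np.ones((2, 2), dtype=int))
        assert observed_fraction(full) == 1.0
        assert observed_fraction(toy) == pytest.approx(3 / 4)

    def test_empty_mask_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            observed_fraction(ObservedData(np.zeros((2, 2)), np.zeros((2, 2), dtype=int)))

    def test_h1_mask_concentrates_at_nominal_rate(self):
        from pcamiss import MissingnessConfig, generate_mask

        n = d = 200
        mask = generate_mask(n, d, MissingnessConfig("H1", {}, seed=1))
        data = ObservedData(np.zeros((n, d)), mask)
        se = np.sqrt(0.05 * 0.95 / (n * d))
        assert abs(observed_fraction(data) - 0.05) < 3 * se


class TestOpwWeight:
    @pytest.mark.parametrize(
        "p_hat,diag,off",
        [(1.0, 1.0, 1.0), (0.75, 4 / 3, 16 / 9), (0.5, 2.0, 4.0)],
    )
    def test_values(self, p_hat, diag, off):
        w = opw_weight(p_hat, 3).w
        assert np.allclose(np.diag(w), diag)
        assert w[0, 1] == pytest.approx(off)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            opw_weight(0.0, 2)


class TestOpwCovariance:
    def test_hand_example(self, toy):
        expected = np.array([[20 / 3, 32 / 3], [32 / 3, 32 / 3]])
        assert np.allclose(opw_covariance(toy), expected)

    def test_full_observation_is_second_moment(self, rng):
        y = rng.standard_normal((10, 4))
        data = ObservedData(y, np.ones((10, 4), dtype=int))
        assert np.allclose(opw_covariance(data), y.T @ y / 10)

    def test_unbiased_with_known_p_weights(self, rng):
        """Monte Carlo over masks: E(G | Y) = n^-1 Y'Y with known-p weights."""
        p, n, d, reps = 0.5, 3, 3, 10_000
        y = rng.standard_normal((n, d))
        target = y.T @ y / n
        w = opw_weight(p, d).w
        masks = (rng.random((reps, n, d)) < p).astype(float)
        ym = y[None, :, :] * masks
        gs = np.einsum("rij,rik->rjk", ym, ym) / n * w[None, :, :]
        mc_mean = gs.mean(axis=0)
        mc_se = gs.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mc_mean - target) < 3 * mc_se + 1e-12)


class TestHeteroWeight:
    def test_full_mask_all_ones(self):
        assert np.allclose(hetero_weight(np.ones((5, 3))).w, 1.0)

    def test_hand_example(self, toy):
        assert np.allclose(hetero_weight(toy.mask).w, [[1.0, 2.0], [2.0, 2.0]])

    def test_never_coobserved_pair_is_zero(self):
        mask = np.array([[1, 0], [1, 0], [0, 1]])
        assert hetero_weight(mask).w[0, 1] == 0.0

    def test_concentrates_under_homogeneous_missingness(self, rng):
        n, p = 10_000, 0.3
        mask = (rng.random((n, 4)) < p).astype(int)
        w = hetero_weight(mask).w
        # co-observation count is Binomial(n, p^2) off-diagonal, (n, p) on it
        se_off = np.sqrt(n * p**2 * (1 - p**2)) * (1 / (n * p**2) ** 2) * n
        assert np.all(np.abs(w[~np.eye(4, dtype=bool)] - p**-2) < 4 * se_off)
        se_diag = np.sqrt(n * p * (1 - p)) * (1 / (n * p) ** 2) * n
        assert np.all(np.abs(np.diag(w) - 1 / p) < 4 * se_diag)


class TestHeteroCovariance:
    def test_hand_example(self, toy):
        assert np.allclose(hetero_covariance(toy), [[5.0, 12.0], [12.0, 16.0]])

    def test_agrees_with_opw_under_homogeneous_missingness(self, rng):
        n, d = 10_000, 5
        y = rng.standard_normal((n, d)) @ np.diag([3.0, 2.0, 1.0, 1.0, 1.0])
        data = mcar_data(y, 0.5, rng)
        a = opw_covariance(data)
        b = hetero_covariance(data)
        # both unbiased for the same target; entrywise gap shrinks like n^-1/2
        assert np.max(np.abs(a - b)) < 0.15

    def test_column_permutation_equivariance(self, rng, toy):
        perm = np.array([1, 0])
        permuted = ObservedData(toy.y_obs[:, perm], toy.mask[:, perm])
        for estimator in (opw_covariance, hetero_covariance):
            g = estimator(toy)
            gp = estimator(permuted)
            assert np.allclose(gp, g[np.ix_(perm, perm)])


class TestOpwvCovariance:
    def test_single_group_matches_opw(self, toy):
        groups = GroupLabels(np.zeros(2, dtype=int), 1)
        y0 = np.array([1.0, -1.0])
        g = opwv_covariance(toy, groups, y0)
        assert g[0, 0] == pytest.approx(1.0)  # empirical variance of y0
        assert np.allclose(g[1:, 1:], opw_covariance(toy))
        assert np.allclose(g[0, 1:], 0.0)

    def test_identical_groups_match_single_group(self, rng):
        y = rng.standard_normal((6, 3))
        y2 = np.vstack([y, y])
        mask = np.ones((12, 3), dtype=int)
        data = ObservedData(y2, mask)
        y0 = np.ones(12)
        one = opwv_covariance(data, GroupLabels(np.zeros(12, dtype=int), 1), y0)
        two = opwv_covariance(
            data, GroupLabels(np.repeat([0, 1], 6), 2), y0
        )
        assert np.allclose(one, two)

    def test_unbiased_for_block_covariance(self, rng):
        """Known per-group p: Monte Carlo mean of G equals Cov(y_-0)."""
        n, d, reps = 4, 3, 4000
        p_by_group = np.array([0.8, 0.4])
        labels = np.array([0, 0, 1, 1])
        sigma = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.3], [0.0, 0.3, 1.5]])
        chol = np.linalg.cholesky(sigma)
        acc = []
        for r in range(reps):
            y = rng.standard_normal((n, d)) @ chol.T
            pm = p_by_group[labels][:, None]
            mask = (rng.random((n, d)) < pm).astype(int)
            data = ObservedData.from_full(y, mask)
            try:
                g = opwv_covariance(
                    data, GroupLabels(labels, 2), np.ones(n), p_known=p_by_group
                )
            except DegenerateDataError:
                continue
            acc.append(g[1:, 1:])
        acc = np.array(acc)
        mc_mean = acc.mean(axis=0)
        mc_se = acc.std(axis=0, ddof=1) / np.sqrt(len(acc))
        assert np.all(np.abs(mc_mean - sigma) < 4 * mc_se + 1e-12)

    def test_empty_group_raises(self, toy):
        with pytest.raises(ValueError):
            GroupLabels(np.zeros(2, dtype=int), 2)


class TestInitEstimator:
    def test_diagonal(self):
        v = init_estimator(np.diag([3.0, 2.0, 1.0]), 2)
        assert np.allclose(v.basis, np.eye(3)[:, :2])

    def test_spiked_identity(self, rng):
        vec = rng.standard_normal(5)
        vec /= np.linalg.norm(vec)
        v = init_estimator(np.eye(5) + 2 * np.outer(vec, vec), 1)
        assert sin_theta_loss(v, Subspace(vec[:, None])) < 1e-10

    def test_agrees_with_right_singular_space_of_psd_root(self, rng):
        a = rng.standard_normal((6, 6))
        cov = a @ a.T
        vals, vecs = np.linalg.eigh(cov)
        root = (vecs * np.sqrt(np.maximum(vals, 0))) @ vecs.T
        assert sin_theta_loss(init_estimator(cov, 2), top_k_right_singular(root, 2)) < 1e-8

    def test_rejects_asymmetric(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            init_estimator(rng.standard_normal((4, 4)), 1)

    def test_consistency_in_spiked_model(self):
        """Qualitative consistency: n=20000, d=20, lambda1=10, p=0.5."""
        from pcamiss import SpikedModelConfig, generate_spiked

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            vec = np.full((20, 1), 20**-0.5)
            truth = Subspace(vec)
            model = SpikedModelConfig(
                n=20_000, d=20, K=1, sigma_u=np.array([[10.0]]),
                loadings=truth, noise_sd=1.0, seed=seed,
            )
            y = generate_spiked(model)
            data = mcar_data(y, 0.5, rng)
            est = init_estimator(opw_covariance(data), 1)
            if sin_theta_loss(est, truth) < 0.15:
                hits += 1
        assert hits >= 9
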