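"""Inverted encoding model: weights, optimal filters, alignment, R, cross-validation."""

import numpy as np
import pytest

from wmdecode.basis import ChannelBasis, channel_response, design_matrix
from wmdecode.delay import DelayPattern, extract_delay_patterns
from wmdecode.iem import (CURVE_GRID, align_reconstructions,
                          estimate_noise_filters, estimate_weights,
                          information_metric, invert, lobo_cv, reblock,
                          shrinkage_covariance)
from wmdecode.synth import SimConfig, generate_design, generate_bold, \
    generate_tuning_weights


class TestEstimateWeights:
    def test_identity_design_returns_patterns(self):
        rng = np.random.default_rng(0)
        B1 = rng.normal(size=(7, 9))
        W = estimate_weights(B1, np.eye(9))
        np.testing.assert_allclose(W, B1, atol=1e-12)

    def test_matches_per_voxel_normal_equations(self):
        """OLS oracle: solve the normal equations voxel by voxel."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            m, k, n = rng.integers(2, 12), rng.integers(2, 8), rng.integers(12, 30)
            B1 = rng.normal(size=(m, n))
            C1 = rng.normal(size=(k, n))
            W = estimate_weights(B1, C1)
            X = C1.T  # n x k regressors
            for v in range(m):
                beta = np.linalg.solve(X.T @ X, X.T @ B1[v])
                np.testing.assert_allclose(W[v], beta, atol=1e-10)

    def test_noiseless_recovery(self, basis):
        rng = np.random.default_rng(2)
        W_true = rng.normal(size=(10, 9))
        C1 = design_matrix(basis, rng.uniform(0, 180, size=60))
        W = estimate_weights(W_true @ C1, C1)
        np.testing.assert_allclose(W, W_true, atol=1e-8)

    def test_rank_deficient_design_warns_and_pseudo_inverts(self, caplog):
        rng = np.random.default_rng(3)
        C1 = np.vstack([np.ones((2, 10)), rng.normal(size=(2, 10))])
        B1 = rng.normal(size=(5, 10))
        with caplog.at_level("WARNING"):
            W = estimate_weights(B1, C1)
        assert "rank-deficient" in caplog.text
        assert np.all(np.isfinite(W))


class TestShrinkageCovariance:
    def test_converges_to_sample_covariance(self):
        """Large-sample check against a brute-force covariance and the
        centered analytic-shrinkage reference from scikit-learn."""
        from sklearn.covariance import ledoit_wolf

        rng = np.random.default_rng(4)
        m, n = 8, 20000
        A = rng.normal(size=(m, m))
        eps = A @ rng.normal(size=(m, n))
        sigma, lam = shrinkage_covariance(eps)
        assert lam < 0.01
        brute = sum(np.outer(eps[:, t], eps[:, t]) for t in range(n)) / (n - 1)
        np.testing.assert_allclose(sigma, brute, rtol=0.02, atol=0.02)
        sk_cov, sk_lam = ledoit_wolf(eps.T, assume_centered=True)
        np.testing.assert_allclose(sigma, sk_cov, rtol=0.05, atol=0.05)
        assert abs(lam - sk_lam) < 0.01

    def test_heavy_shrinkage_at_tiny_samples(self):
        rng = np.random.default_rng(5)
        eps = rng.normal(size=(30, 4))
        sigma, lam = shrinkage_covariance(eps)
        assert 0.1 < lam <= 1.0
        # shrunk estimate is well conditioned even with n << m
        assert np.linalg.cond(sigma) < 1e4

    def test_spherical_residuals_shrink_fully(self):
        sigma, lam = shrinkage_covariance(np.eye(3) * 2.0)
        assert np.all(np.isfinite(sigma))


class TestFilters:
    def test_identity_covariance_reduces_to_normalized_weights(self):
        rng = np.random.default_rng(6)
        W = rng.normal(size=(12, 9))
        B1 = rng.normal(size=(12, 40))
        C1 = rng.normal(size=(9, 40))
        f = estimate_noise_filters(B1, C1, W, covariance="identity")
        for i in range(9):
            np.testing.assert_allclose(f.V[:, i],
                                       W[:, i] / (W[:, i] @ W[:, i]),
                                       atol=1e-12)

    def test_unit_gain_on_own_channel(self, basis):
        rng = np.random.default_rng(7)
        for trial in range(10):
            m, n = 15, 80
            W_true = rng.normal(size=(m, 9))
            C1 = design_matrix(basis, rng.uniform(0, 180, size=n))
            B1 = W_true @ C1 + rng.normal(size=(m, n))
            W = estimate_weights(B1, C1)
            f = estimate_noise_filters(B1, C1, W)
            gains = np.einsum("vi,vi->i", f.V, W)
            np.testing.assert_allclose(gains, 1.0, atol=1e-8)
            assert np.all(f.shrinkage >= 0) and np.all(f.shrinkage <= 1)

    def test_sigma_inverse_symmetric_positive_definite(self, basis):
        rng = np.random.default_rng(8)
        W_true = rng.normal(size=(10, 9))
        C1 = design_matrix(basis, rng.uniform(0, 180, size=50))
        B1 = W_true @ C1 + rng.normal(size=(10, 50))
        f = estimate_noise_filters(B1, C1, estimate_weights(B1, C1))
        for i in range(9):
            si = f.Sigma_inv[i]
            np.testing.assert_allclose(si, si.T, atol=1e-8)
            assert np.all(np.linalg.eigvalsh(si) > 0)

    def test_zero_residual_training_falls_back(self, basis, caplog):
        rng = np.random.default_rng(9)
        W_true = rng.normal(size=(6, 9))
        C1 = design_matrix(basis, rng.uniform(0, 180, size=30))
        B1 = W_true @ C1  # noiseless: residuals are ~0
        W = estimate_weights(B1, C1)
        with caplog.at_level("WARNING"):
            f = estimate_noise_filters(B1, C1, W)
        C2 = invert(f, B1[:, :3])
        assert np.all(np.isfinite(C2))


class TestInvert:
    def test_unit_gain_reconstruction_of_own_weight_vector(self):
        rng = np.random.default_rng(10)
        W = rng.normal(size=(8, 5))
        B1 = rng.normal(size=(8, 30))
        C1 = rng.normal(size=(5, 30))
        f = estimate_noise_filters(B1, C1, W)
        C2 = invert(f, W)
        np.testing.assert_allclose(np.diag(C2), 1.0, atol=1e-8)

    def test_matches_pseudo_inverse_oracle_with_orthogonal_weights(self):
        # orthonormal weight columns + identity covariance: the filter bank
        # equals the Moore-Penrose pseudo-inverse of W
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(12, 5)))
        W = q
        f = estimate_noise_filters(rng.normal(size=(12, 30)),
                                   rng.normal(size=(5, 30)), W,
                                   covariance="identity")
        B2 = rng.normal(size=(12, 7))
        oracle = np.linalg.pinv(W) @ B2
        np.testing.assert_allclose(invert(f, B2), oracle, atol=1e-10)

    def test_zero_patterns_give_zero_responses(self):
        rng = np.random.default_rng(12)
        W = rng.normal(size=(6, 4))
        f = estimate_noise_filters(rng.normal(size=(6, 25)),
                                   rng.normal(size=(4, 25)), W)
        np.testing.assert_allclose(invert(f, np.zeros((6, 3))), 0.0)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(13)
        W = rng.normal(size=(6, 4))
        f = estimate_noise_filters(rng.normal(size=(6, 25)),
                                   rng.normal(size=(4, 25)), W)
        with pytest.raises(ValueError):
            invert(f, np.zeros((7, 3)))


class TestAlignment:
    def test_self_alignment_peaks_at_center(self, basis):
        # on-grid labels: the interpolated curve peaks exactly at 0°
        on_grid = np.array([0.0, 40.0, 100.0, 160.0])
        rec = align_reconstructions(design_matrix(basis, on_grid), on_grid, basis)
        assert np.all(np.argmax(rec.curves, axis=1) == 0)
        # off-grid labels: linear interpolation snaps the peak to the nearest
        # channel center, so it stays within half a channel spacing of 0°
        off_grid = np.array([3.0, 47.5, 90.0, 133.0, 179.0])
        rec = align_reconstructions(design_matrix(basis, off_grid), off_grid, basis)
        peaks = np.argmax(rec.curves, axis=1)
        assert np.all(np.minimum(peaks, 180 - peaks) <= 10)

    def test_rotation_equivariance(self, basis):
        theta = 30.0
        c1 = design_matrix(basis, [theta])
        c2 = design_matrix(basis, [theta + 40.0])
        rec = align_reconstructions(np.hstack([c1, c2]),
                                    [theta, theta + 40.0], basis)
        np.testing.assert_allclose(rec.curves[0], rec.curves[1], atol=1e-9)

    def test_interpolation_error_against_analytic_cosine(self, basis):
        """Linear circular interpolation of cos(2 pi theta / 180) sampled at
        the 9 channel centers stays close to the analytic curve."""
        centers = basis.centers_array
        values = np.cos(2 * np.pi * centers / 180.0)
        rec = align_reconstructions(values[:, None], [0.0], basis)
        analytic = np.cos(2 * np.pi * CURVE_GRID / 180.0)
        # 20° sampling of a full-period cosine: worst-case linear-interp
        # error is h^2 |f''| / 8 ~= 0.061
        assert np.max(np.abs(rec.curves[0] - analytic)) < 0.07

    def test_label_count_validation(self, basis):
        with pytest.raises(ValueError):
            align_reconstructions(np.zeros((9, 3)), [0.0, 10.0], basis)


class TestInformationMetric:
    def test_uniform_curve_gives_zero(self):
        assert information_metric(np.ones(180), CURVE_GRID) == pytest.approx(0.0, abs=1e-12)
        centers = np.arange(0.0, 180.0, 20.0)
        assert information_metric(np.ones(9), centers) == pytest.approx(0.0, abs=1e-12)

    def test_delta_response_at_center(self):
        centers = np.arange(0.0, 180.0, 20.0)
        resp = np.zeros(9)
        resp[0] = 1.0
        assert information_metric(resp, centers) == pytest.approx(1.0 / 9.0)

    def test_orthogonal_concentration_is_negative(self):
        centers = np.arange(0.0, 180.0, 20.0)
        resp = np.exp(-0.5 * ((centers - 90.0) / 15.0) ** 2)
        assert information_metric(resp, centers) < 0

    def test_linearity_in_responses(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=180)
        b = rng.normal(size=180)
        ra = information_metric(a, CURVE_GRID)
        rb = information_metric(b, CURVE_GRID)
        assert information_metric(3 * a - b, CURVE_GRID) == pytest.approx(3 * ra - rb)


class TestLoboCV:
    def test_partition_bookkeeping(self, small_subject, basis):
        trials, _, _, patterns = small_subject
        rec = lobo_cv(patterns, trials, basis, condition="cued")
        assert rec.curves.shape == (len(trials), 180)
        assert rec.R.shape == (len(trials),)

    def test_noiseless_identity_path_peaks_at_zero(self, basis):
        """Forward/backward consistency: noiseless data decoded with the
        identity-covariance path reconstructs every trial at its label."""
        cfg = SimConfig(n_blocks=4, n_voxels=18, noise_sd=0.0,
                        snr_encoding=0.0, jitter_range=(0.0, 0.0), seed=20)
        trials = generate_design(cfg)
        # orthogonal (one-hot) tuning: the identity-path filter bank is the
        # exact pseudo-inverse, so reconstructions carry no channel crosstalk
        w = generate_tuning_weights(cfg.n_voxels, basis, mode="one_hot")
        runs = generate_bold(trials, w, cfg)
        pat = extract_delay_patterns(runs, zscore=False)
        rec = lobo_cv(pat, trials, basis, condition="cued",
                      covariance="identity")
        peaks = np.argmax(rec.curves, axis=1)
        assert np.all(peaks == 0)
        assert rec.mean_R > 0.05

    def test_shuffle_requires_seed_and_is_reproducible(self, small_subject, basis):
        trials, _, _, patterns = small_subject
        with pytest.raises(ValueError):
            lobo_cv(patterns, trials, basis, condition="shuffled")
        r1 = lobo_cv(patterns, trials, basis, condition="shuffled", seed=5)
        r2 = lobo_cv(patterns, trials, basis, condition="shuffled", seed=5)
        np.testing.assert_allclose(r1.R, r2.R)

    def test_end_to_end_label_rotation_equivariance(self, small_subject, basis):
        """Rotating the orientation frame — all labels shifted by one channel
        spacing against the same voxel data — permutes the unaligned channel
        responses and leaves aligned reconstructions exactly invariant, even
        through the shrinkage-covariance path."""
        trials, _, _, patterns = small_subject
        delta = 40.0
        rotated = trials.copy()
        for col in ("theta_item1", "theta_item2", "theta_cued", "theta_uncued"):
            rotated[col] = (rotated[col] + delta) % 180.0
        rec = lobo_cv(patterns, trials, basis, condition="cued")
        rec_rot = lobo_cv(patterns, rotated, basis, condition="cued")
        np.testing.assert_allclose(rec.curves, rec_rot.curves, atol=1e-8)
        np.testing.assert_allclose(rec.R, rec_rot.R, atol=1e-10)

    def test_reblock_partitions_evenly(self):
        blocks = reblock(180, 18, seed=3)
        _, counts = np.unique(blocks, return_counts=True)
        assert np.all(counts == 18)
        assert np.array_equal(blocks, reblock(180, 18, seed=3))
        with pytest.raises(ValueError):
            reblock(100, 18, seed=0)
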