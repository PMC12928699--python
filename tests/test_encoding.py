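"""Inverted encoding model: basis, least squares, GLS inversion, CV."""

import numpy as np
import pytest
from scipy import optimize

from avdecode import (
    ChannelBasis,
    basis_response,
    cross_validated_reconstruct,
    design_matrix,
    estimate_noise_cov,
    fit_forward,
    invert_model,
    per_sensor_information,
    stratified_folds,
)
from avdecode.encoding import SingularDesignError


class TestBasis:
    def test_response_is_one_at_own_centre(self):
        b = ChannelBasis()
        for c in b.centres:
            resp = basis_response(b, c)
            assert resp[np.flatnonzero(b.centres == c)[0]] == pytest.approx(1.0)

    def test_response_nonnegative(self):
        b = ChannelBasis()
        locs = np.linspace(-30, 30, 201)
        assert np.all(basis_response(b, locs) >= 0)

    def test_midpoint_symmetry(self):
        b = ChannelBasis()
        resp = basis_response(b, -11.25)  # midway between -15 and -7.5
        assert resp[0] == pytest.approx(resp[1])

    def test_hand_evaluated_profile_at_edge(self):
        # cos(2 pi * 7.5/60)^5 = cos(45 deg)^5 = 0.17678; farther channels
        # are beyond the half-wave support
        resp = basis_response(ChannelBasis(), -15.0)
        np.testing.assert_allclose(resp, [1.0, 0.1768, 0.0, 0.0, 0.0], atol=5e-5)

    def test_five_by_five_design_invertible(self):
        b = ChannelBasis()
        C = design_matrix(b, b.centres)
        assert C.shape == (5, 5)
        assert np.linalg.cond(C) < 1e6


class TestDesignMatrix:
    def test_duplicated_locations_duplicate_columns(self):
        b = ChannelBasis()
        C = design_matrix(b, [0.0, 0.0, 7.5])
        np.testing.assert_array_equal(C[:, 0], C[:, 1])

    def test_missing_location_makes_design_singular(self):
        b = ChannelBasis()
        # only the two extreme locations: middle channels get no stimulation
        C = design_matrix(b, [-15.0, -15.0, 15.0, 15.0, -15.0])
        assert np.linalg.matrix_rank(C) < 5
        with pytest.raises(SingularDesignError):
            fit_forward(np.zeros((3, 5)), C)


class TestFitForward:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        b = ChannelBasis()
        W0 = rng.standard_normal((6, 5))
        locs = rng.choice(b.centres, 40)
        C = design_matrix(b, locs)
        W = fit_forward(W0 @ C, C)
        np.testing.assert_allclose(W, W0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        b = ChannelBasis()
        locs = rng.choice(b.centres, 50)
        C = design_matrix(b, locs)
        B = rng.standard_normal((4, 50))
        W = fit_forward(B, C)
        E = B - W @ C
        np.testing.assert_allclose(E @ C.T, 0.0, atol=1e-8)

    def test_matches_brute_force_minimiser(self):
        """Least-squares solution agrees with a direct numerical optimiser."""
        rng = np.random.default_rng(2)
        b = ChannelBasis()
        locs = rng.choice(b.centres, 12)
        C = design_matrix(b, locs)
        B = rng.standard_normal((3, 12))
        W = fit_forward(B, C)

        def loss(w):
            return np.sum((B - w.reshape(3, 5) @ C) ** 2)

        res = optimize.minimize(loss, np.zeros(15), method="L-BFGS-B",
                                options={"ftol": 1e-15, "gtol": 1e-12})
        np.testing.assert_allclose(W.ravel(), res.x, atol=1e-5)

    def test_linearity_in_data(self):
        rng = np.random.default_rng(3)
        b = ChannelBasis()
        locs = rng.choice(b.centres, 20)
        C = design_matrix(b, locs)
        B = rng.standard_normal((4, 20))
        np.testing.assert_allclose(fit_forward(2 * B, C), 2 * fit_forward(B, C), atol=1e-12)


class TestNoiseCov:
    def test_identity_recovered_at_large_n(self):
        rng = np.random.default_rng(4)
        E = rng.standard_normal((8, 20000))
        Sigma = estimate_noise_cov(E)
        off = Sigma[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.1
        np.testing.assert_allclose(np.diag(Sigma), 1.0, atol=0.1)

    def test_positive_definite_when_n_below_sensors(self):
        rng = np.random.default_rng(5)
        E = rng.standard_normal((64, 2))
        Sigma = estimate_noise_cov(E)
        assert np.all(np.linalg.eigvalsh(Sigma) > 0)

    def test_full_shrinkage_gives_diagonal(self):
        rng = np.random.default_rng(6)
        E = rng.standard_normal((5, 30))
        Sigma = estimate_noise_cov(E, shrinkage=1.0)
        off = Sigma[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)


class TestInvertModel:
    def test_reduces_to_pseudoinverse_under_isotropy(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((10, 5))
        D = invert_model(W, np.eye(10))
        np.testing.assert_allclose(D, np.linalg.pinv(W), atol=1e-10)

    def test_exact_inversion_of_noiseless_pattern(self):
        rng = np.random.default_rng(8)
        W = rng.standard_normal((10, 5))
        Sigma = np.diag(rng.uniform(0.5, 2.0, 10))
        D = invert_model(W, Sigma)
        np.testing.assert_allclose(D @ W, np.eye(5), atol=1e-8)
        c = rng.standard_normal(5)
        np.testing.assert_allclose(D @ (W @ c), c, atol=1e-8)

    def test_isotropic_scale_invariance(self):
        """With Sigma = s^2 I the decoder is independent of s (noise isotropy)."""
        rng = np.random.default_rng(9)
        W = rng.standard_normal((8, 5))
        D1 = invert_model(W, np.eye(8))
        D2 = invert_model(W, 25.0 * np.eye(8))
        np.testing.assert_allclose(D1, D2, atol=1e-10)

    def test_gls_beats_ols_under_anisotropic_noise(self):
        """Monte-Carlo: covariance-aware decoding has lower variance than OLS."""
        rng = np.random.default_rng(10)
        W = rng.standard_normal((12, 5))
        sd = np.concatenate([np.full(6, 0.1), np.full(6, 3.0)])
        Sigma = np.diag(sd**2)
        D_gls = invert_model(W, Sigma)
        D_ols = np.linalg.pinv(W)
        c = rng.standard_normal(5)
        noise = rng.standard_normal((10_000, 12)) * sd
        b = (W @ c)[None, :] + noise
        err_gls = ((b @ D_gls.T - c) ** 2).mean()
        err_ols = ((b @ D_ols.T - c) ** 2).mean()
        assert err_gls < err_ols

    def test_matches_gls_oracle(self):
        """Agreement with an independent generalised-least-squares estimate."""
        rng = np.random.default_rng(11)
        W = rng.standard_normal((6, 5))
        A = rng.standard_normal((6, 6))
        Sigma = A @ A.T + 6 * np.eye(6)
        b = rng.standard_normal(6)
        D = invert_model(W, Sigma)

        # GLS oracle: argmin_c (b - Wc)' Sigma^-1 (b - Wc) via a numerical optimiser
        Sinv = np.linalg.inv(Sigma)

        def loss(c):
            r = b - W @ c
            return r @ Sinv @ r

        res = optimize.minimize(loss, np.zeros(5), method="BFGS",
                                options={"gtol": 1e-12})
        np.testing.assert_allclose(D @ b, res.x, atol=1e-6)


class TestCrossValidation:
    def test_stratified_folds_balanced(self):
        labels = np.repeat([-15, -7.5, 0, 7.5, 15], 20)
        folds = stratified_folds(labels, k=10, seed=0)
        for v in np.unique(labels):
            counts = np.bincount(folds[labels == v], minlength=10)
            assert counts.max() - counts.min() <= 1

    def test_too_few_trials_per_stratum(self):
        with pytest.raises(ValueError, match="smaller k"):
            stratified_folds(np.array([0, 0, 1, 1]), k=3, seed=0)

    def test_noiseless_exact_recovery(self, noiseless_epochs):
        epochs, truth = noiseless_epochs
        sub = epochs.select((epochs.labels["condition"] == "A").to_numpy())
        locs = sub.labels["location_deg"].to_numpy(dtype=float)
        recon = cross_validated_reconstruct(sub.data, locs, sub.times, k=5, seed=0)
        peak = np.argmin(np.abs(sub.times - 0.18))
        expected = basis_response(recon.basis, locs)  # (channels, trials)
        np.testing.assert_allclose(recon.activities[:, :, peak], expected.T, atol=1e-6)

    def test_training_is_trial_order_invariant(self):
        """The fitted fold model depends on (data, label) pairs, not order."""
        from avdecode.encoding import _fit_fold

        rng = np.random.default_rng(14)
        b = ChannelBasis()
        locs = rng.choice(b.centres, 30)
        C = design_matrix(b, locs)
        B = rng.standard_normal((30, 6, 4))  # (trials, sensors, time)
        perm = rng.permutation(30)
        m1 = _fit_fold(B, C, fold=0)
        m2 = _fit_fold(B[perm], C[:, perm], fold=0)
        np.testing.assert_allclose(m1.W, m2.W, atol=1e-10)
        np.testing.assert_allclose(m1.D, m2.D, atol=1e-8)

    def test_per_sensor_information_ranks_loaded_sensors(self):
        """Zero-loading sensors score ~0 and the ranking matches the
        closed-form expected matched-filter score at high SNR."""
        from avdecode.metrics import ideal_vectors
        from scipy.stats import spearmanr

        rng = np.random.default_rng(13)
        b = ChannelBasis()
        M = rng.standard_normal((12, 5))
        M[:2] = 0.0  # sensors 0-1 carry no tuned signal
        locs = np.tile(b.centres, 40)
        times = np.arange(26) / 128.0
        kernel = np.exp(-0.5 * (times - 0.1) ** 2 / 0.03**2)
        signal = np.einsum("sc,cn,t->nst", M, basis_response(b, locs), kernel)
        data = signal + 0.1 * rng.standard_normal(signal.shape)
        scores = per_sensor_information(data, locs, times,
                                        window_s=(0.05, 0.15), k=5, seed=0)
        assert np.abs(scores[:2]).max() < 0.05
        # oracle: expected score of the trace-normalised matched filter is
        # (m' [sum_theta c(theta)(v(theta)-vbar)'] m) / ||m||^2
        Cb = basis_response(b, b.centres)
        V = ideal_vectors(b, b.centres)
        Vc = V - V.mean(axis=1, keepdims=True)
        raw = np.einsum("sc,cd,sd->s", M, Cb @ Vc.T, M)
        nrm = (M**2).sum(axis=1)
        pred = np.where(nrm > 0, raw / np.maximum(nrm, 1e-12), 0.0)
        rho, _ = spearmanr(pred, scores)
        assert rho > 0.9

    def test_duplicated_sensor_duplicates_score(self):
        rng = np.random.default_rng(15)
        b = ChannelBasis()
        locs = np.tile(b.centres, 20)
        times = np.arange(20) / 128.0
        data = rng.standard_normal((100, 3, 20))
        data[:, 2] = data[:, 0]  # sensor 2 duplicates sensor 0
        scores = per_sensor_information(data, locs, times,
                                        window_s=(0.0, 0.15), k=5, seed=0)
        assert scores[2] == pytest.approx(scores[0], abs=1e-12)
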