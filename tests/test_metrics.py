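"""Decoding accuracy (a.u.) and decoder sensitivity d'."""

import numpy as np
import pytest
from scipy.stats import norm

from avdecode import ChannelBasis, accuracy_score, decoder_dprime, location_estimate
from avdecode.metrics import ideal_vectors


BASIS = ChannelBasis()
LOCSET = BASIS.centres


def _act(vectors):
    """Stack channel vectors into a (trials, channels, 1) activity array."""
    return np.asarray(vectors, dtype=float)[:, :, None]


class TestAccuracy:
    def test_ideal_reconstruction_scores_positive(self):
        V = ideal_vectors(BASIS, LOCSET)
        for j, loc in enumerate(LOCSET):
            score = accuracy_score(_act([V[:, j]]), np.array([loc]), BASIS,
                                   location_set=LOCSET)
            expected = 1.0 - np.mean(V[:, j] @ V)
            assert score[0] == pytest.approx(expected, abs=1e-12)
            assert score[0] > 0

    def test_shuffled_labels_score_zero_on_average(self):
        rng = np.random.default_rng(0)
        V = ideal_vectors(BASIS, LOCSET)
        true = rng.choice(LOCSET, 500)
        Z = _act(V[:, np.searchsorted(LOCSET, true)].T)
        means = []
        for _ in range(1000):
            shuffled = rng.permutation(true)
            means.append(accuracy_score(Z, shuffled, BASIS, location_set=LOCSET)[0])
        means = np.array(means)
        assert abs(means.mean()) < 2 * means.std() / np.sqrt(means.size) + 1e-3

    def test_cosine_similarity_variant(self):
        from avdecode import basis_response

        rng = np.random.default_rng(7)
        # scale invariance distinguishes cosine from the projection score
        Z = np.abs(rng.standard_normal((10, 5, 2)))
        true = rng.choice(LOCSET, 10)
        s1 = accuracy_score(Z, true, BASIS, location_set=LOCSET, similarity="cosine")
        s2 = accuracy_score(3.0 * Z, true, BASIS, location_set=LOCSET,
                            similarity="cosine")
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        # an exact ideal reconstruction is a positive hit under cosine too
        z = basis_response(BASIS, 15.0)
        s = accuracy_score(_act([z]), np.array([15.0]), BASIS,
                           location_set=LOCSET, similarity="cosine")
        assert s[0] > 0
        with pytest.raises(ValueError):
            accuracy_score(Z, true, BASIS, similarity="euclid")

    def test_invariant_to_constant_channel_offset(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((20, 5, 3))
        true = rng.choice(LOCSET, 20)
        s1 = accuracy_score(Z, true, BASIS, location_set=LOCSET)
        s2 = accuracy_score(Z + 7.0, true, BASIS, location_set=LOCSET)
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestLocationEstimate:
    def test_ideal_right_vector_estimates_right(self):
        resp = BASIS.centres * 0.0
        from avdecode import basis_response

        ests = []
        for loc in LOCSET:
            z = basis_response(BASIS, loc)
            est = location_estimate(_act([z]), BASIS)[0, 0]
            ests.append(est)
        ests = np.array(ests)
        assert ests[-1] > 0 and ests[-1] == ests.max()
        assert np.all(np.diff(ests) > 0)  # monotone in true location

    def test_symmetric_profile_estimates_zero(self):
        z = np.array([0.3, 0.8, 1.0, 0.8, 0.3])
        assert location_estimate(_act([z]), BASIS)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_all_nonpositive_reads_zero(self):
        z = np.array([-1.0, -0.5, -0.2, -0.5, -1.0])
        assert location_estimate(_act([z]), BASIS)[0, 0] == 0.0


class TestDprime:
    def test_equal_rates_give_zero(self):
        est = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        loc = np.array([15.0, 15.0, -15.0, -15.0])
        assert decoder_dprime(est, loc)[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_clipped(self):
        n = 100
        est = np.concatenate([np.ones((n, 1)), -np.ones((n, 1))])
        loc = np.concatenate([np.full(n, 15.0), np.full(n, -15.0)])
        d = decoder_dprime(est, loc)[0]
        assert d == pytest.approx(2 * norm.ppf(1 - 1 / (2 * n)), abs=1e-10)
        assert d == pytest.approx(5.152, abs=1e-3)

    def test_eighty_twenty_rates(self):
        nr = 10000
        rng = np.random.default_rng(2)
        right_est = np.where(rng.random(nr) < 0.8, 1.0, -1.0)[:, None]
        left_est = np.where(rng.random(nr) < 0.2, 1.0, -1.0)[:, None]
        est = np.concatenate([right_est, left_est])
        loc = np.concatenate([np.full(nr, 7.5), np.full(nr, -7.5)])
        assert decoder_dprime(est, loc)[0] == pytest.approx(2 * norm.ppf(0.8), abs=0.06)

    def test_centre_trials_omitted(self):
        est = np.array([[1.0], [-1.0], [99.0]])
        loc = np.array([15.0, -15.0, 0.0])
        d_with = decoder_dprime(est, loc)
        d_without = decoder_dprime(est[:2], loc[:2])
        np.testing.assert_allclose(d_with, d_without)

    def test_antisymmetric_under_side_swap(self):
        rng = np.random.default_rng(3)
        est = rng.standard_normal((60, 4))
        loc = rng.choice([-15.0, 15.0], 60)
        d1 = decoder_dprime(est, loc)
        d2 = decoder_dprime(-est, -loc)
        np.testing.assert_allclose(d1, d2, atol=1e-10)
        d3 = decoder_dprime(est, -loc)
        np.testing.assert_allclose(d1, -d3, atol=1e-10)

    def test_one_sided_data_rejected(self):
        with pytest.raises(ValueError):
            decoder_dprime(np.ones((3, 1)), np.array([15.0, 15.0, 7.5]))


class TestEndToEnd:
    def test_noiseless_sign_recovery(self, noiseless_epochs):
        """Noise-free pipeline: decoded side equals presented side."""
        from avdecode import cross_validated_reconstruct

        epochs, _ = noiseless_epochs
        sub = epochs.select((epochs.labels["condition"] == "AV").to_numpy())
        locs = sub.labels["location_deg"].to_numpy(dtype=float)
        recon = cross_validated_reconstruct(sub.data, locs, sub.times, k=5, seed=0)
        peak = np.argmin(np.abs(sub.times - 0.18))
        est = location_estimate(recon)[:, peak]
        off = locs != 0
        assert np.all(np.sign(est[off]) == np.sign(locs[off]))

    def test_metrics_peak_at_information_latency(self):
        """Group-mean accuracy and d' peak at the generator's tuned latency
        (within two samples at 128 Hz)."""
        from avdecode import simulate_cohort_dprimes

        kw = dict(n_sensors=12, sample_rate_hz=128,
                  epoch_window_s=(-0.05, 0.35), noise_sigma=2.0)
        for metric in ("accuracy", "dprime"):
            d, times = simulate_cohort_dprimes(
                n_participants=6, sim_kwargs=kw, n_blocks=2, k=5, seed=33,
                metric=metric,
            )
            for cond in ("A", "V", "AV"):
                t_peak = times[np.argmax(d[cond].mean(axis=0))]
                assert abs(t_peak - 0.18) <= 2 / 128, (metric, cond)

    def test_dprime_monotone_in_tuned_gain(self):
        """Raising the tuned gain never lowers the peak decoder d'."""
        from avdecode import (SimConfig, cross_validated_reconstruct,
                              make_eeg_schedule, simulate_epochs)

        peaks = []
        for gain in (0.25, 1.0, 4.0):
            vals = []
            for rep in range(3):
                sched = make_eeg_schedule(n_participants=1, n_blocks=1,
                                          n_trials_per_block=10,
                                          n_presentations_per_trial=10,
                                          seed=50 + rep)
                sim = SimConfig(n_participants=1, n_sensors=8, sample_rate_hz=128,
                                epoch_window_s=(-0.05, 0.35), noise_sigma=3.0,
                                gain_a=gain, gain_v=gain, seed=50 + rep)
                epochs, _ = simulate_epochs(sched, sim)
                sub = epochs.select((epochs.labels["condition"] == "A").to_numpy())
                locs = sub.labels["location_deg"].to_numpy(dtype=float)
                recon = cross_validated_reconstruct(sub.data, locs, sub.times,
                                                    k=5, seed=rep)
                vals.append(decoder_dprime(location_estimate(recon), locs).max())
            peaks.append(np.mean(vals))
        assert peaks[0] <= peaks[1] <= peaks[2]
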