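"""Prototype decoder, pseudo-population resampling, nulls, generalization."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.neighbors import NearestCentroid

from popshift.decoder import (
    assemble_pseudo_population,
    build_pool,
    classify,
    cross_validated_accuracy,
    decision_values,
    decode_transfer,
    empirical_p,
    fit_prototype_decoder,
    shuffled_null,
    temporal_generalization,
)
from conftest import gaussian_pool


class TestPrototypeDecoder:
    def test_hand_evaluated_weights(self):
        dec = fit_prototype_decoder(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        np.testing.assert_array_equal(dec.w, [-1.0, 1.0])
        assert dec.b == pytest.approx(0.0)
        assert classify(dec, [0.2, 0.9])[0] == 1  # y = 0.7 -> target
        assert decision_values(dec, [0.2, 0.9])[0] == pytest.approx(0.7)

    def test_degenerate_equal_prototypes(self):
        dec = fit_prototype_decoder(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
        assert dec.degenerate

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((5, 4)), rng.random((5, 4))
        shift = rng.random(4) * 10
        d1 = fit_prototype_decoder(a, b)
        d2 = fit_prototype_decoder(a + shift, b + shift)
        np.testing.assert_allclose(d1.w, d2.w, atol=1e-12)
        # midpoint decision unchanged under the common shift
        x = rng.random((20, 4))
        np.testing.assert_array_equal(classify(d1, x), classify(d2, x + shift))

    def test_midpoint_tie_goes_to_reference(self):
        c_r, c_t = np.array([[0.0, 0.0]]), np.array([[2.0, 0.0]])
        dec = fit_prototype_decoder(c_r, c_t)
        assert classify(dec, (c_r[0] + c_t[0]) / 2)[0] == 0
        assert classify(dec, c_r[0])[0] == 0

    def test_common_gain_never_changes_classification(self):
        rng = np.random.default_rng(1)
        ref, targ = rng.random((10, 6)), rng.random((10, 6)) + 0.3
        x = rng.random((50, 6))
        base = classify(fit_prototype_decoder(ref, targ), x)
        for g in (0.1, 3.0, 250.0):
            scaled = classify(fit_prototype_decoder(g * ref, g * targ), g * x)
            np.testing.assert_array_equal(base, scaled)

    def test_exhaustive_hand_evaluation_small(self):
        # <= 8 pseudo-trials: compare against explicit nearest-centroid rule
        rng = np.random.default_rng(2)
        for _ in range(20):
            ref, targ = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
            test = rng.normal(size=(8, 5))
            dec = fit_prototype_decoder(ref, targ)
            got = classify(dec, test)
            c_r, c_t = ref.mean(0), targ.mean(0)
            oracle = [
                1 if np.sum((x - c_t) ** 2) < np.sum((x - c_r) ** 2) else 0 for x in test
            ]
            np.testing.assert_array_equal(got, oracle)

    def test_matches_sklearn_nearest_centroid(self):
        rng = np.random.default_rng(3)
        ref, targ = rng.normal(size=(20, 7)), rng.normal(size=(20, 7)) + 0.5
        test = rng.normal(size=(100, 7)) + 0.25
        dec = fit_prototype_decoder(ref, targ)
        nc = NearestCentroid()
        nc.fit(np.vstack([ref, targ]), np.r_[np.zeros(20), np.ones(20)])
        np.testing.assert_array_equal(classify(dec, test), nc.predict(test).astype(int))

    def test_dimension_mismatch_rejected(self):
        dec = fit_prototype_decoder(np.zeros((1, 3)), np.ones((1, 3)))
        with pytest.raises(ValueError, match="dimension"):
            classify(dec, np.ones((2, 4)))


class TestAssemble:
    def test_split_counts(self, cohort_pools):
        pool = cohort_pools["passive"]  # 40 trials per class per unit
        train, test = assemble_pseudo_population(pool, 0, n_train=15, seed=5)
        assert train.vectors.shape == (30, pool.n_units)
        assert test.vectors.shape == (50, pool.n_units)  # 25 + 25 remaining

    def test_seed_dependence(self, cohort_pools):
        pool = cohort_pools["passive"]
        t1, _ = assemble_pseudo_population(pool, 0, seed=1)
        t2, _ = assemble_pseudo_population(pool, 0, seed=2)
        assert not np.array_equal(t1.vectors, t2.vectors)

    def test_insufficient_trials_rejected(self):
        pool = gaussian_pool(np.random.default_rng(0), n_units=4, n_trials=15)
        with pytest.raises(ValueError, match="insufficient"):
            assemble_pseudo_population(pool, 0, n_train=15)


class TestCrossValidatedAccuracy:
    def test_strong_separation_saturates(self):
        pool = gaussian_pool(np.random.default_rng(4), separation=10.0, sigma=1.0)
        res = cross_validated_accuracy(pool, bins=[0], n_resamples=50, seed=0)
        assert res.mean[0] >= 0.99

    def test_identical_classes_at_chance(self):
        pool = gaussian_pool(np.random.default_rng(5), separation=0.0)
        res = cross_validated_accuracy(pool, bins=[0], n_resamples=100, seed=0)
        null = shuffled_null(pool, bins=[0], n_perm=30, n_cv=30, seed=1)
        lo, hi = null.ci95[:, 0]
        assert lo <= res.mean[0] <= hi

    def test_single_resample_warns(self):
        pool = gaussian_pool(np.random.default_rng(6))
        with pytest.warns(UserWarning, match="resamples"):
            res = cross_validated_accuracy(pool, bins=[0], n_resamples=1, seed=0)
        assert np.isnan(res.ci95).all()

    def test_gaussian_closed_form_small(self):
        # accuracy -> Phi(d / 2 sigma) with near-exact prototypes
        rng = np.random.default_rng(7)
        d, sigma = 2.0, 1.0
        accs = []
        for _ in range(10):
            pool = gaussian_pool(rng, n_units=25, n_trials=120, separation=d, sigma=sigma)
            res = cross_validated_accuracy(pool, bins=[0], n_train=100, n_resamples=20, seed=3)
            accs.append(res.mean[0])
        assert np.mean(accs) == pytest.approx(norm.cdf(d / (2 * sigma)), abs=0.03)


class TestShuffledNull:
    def test_null_centered_and_p_bound(self, cohort_pools):
        pool = cohort_pools["engaged"]
        null = shuffled_null(pool, windows=[(1.7, 2.0)], n_perm=25, n_cv=15, seed=9)
        se = null.null_accuracies.std(ddof=1) / np.sqrt(null.n_perm)
        assert abs(null.mean[0] - 0.5) < 3 * max(se, 1e-3)
        p, count = null.p_value(np.array([1.0]))
        assert p[0] == pytest.approx(1.0 / (null.n_perm + 1))
        assert count[0] == 0
        # separable data: observed accuracy above the null 97.5th percentile
        obs = cross_validated_accuracy(pool, windows=[(1.7, 2.0)], n_resamples=30, seed=9)
        assert obs.mean[0] > null.ci95[1, 0]

    def test_empirical_p_add_one(self):
        assert empirical_p(np.array([0.4, 0.5, 0.6]), 0.7) == pytest.approx(0.25)
        assert empirical_p(np.zeros(99), -1.0) == pytest.approx(1.0)


class TestTemporalGeneralization:
    def test_diagonal_matches_within_window_cv(self, cohort_pools):
        pool = cohort_pools["engaged"]
        win = (1.7, 2.0)
        mat = temporal_generalization(
            pool, [win], test_windows=[win], n_resamples=20, seed=13
        )
        ref = cross_validated_accuracy(pool, windows=[win], n_resamples=20, seed=13)
        assert mat[0, 0] == pytest.approx(ref.mean[0], abs=1e-12)

    def test_orthogonal_codes_do_not_generalize(self, cohort_pools):
        # planted sound (v) and silence (v2) codes are orthogonal directions
        pool = cohort_pools["engaged"]
        wins = [(1.7, 2.0), (2.5, 2.8)]
        mat = temporal_generalization(
            pool, wins, test_windows=wins, n_resamples=25, seed=14
        )
        assert mat[0, 0] > 0.9 and mat[1, 1] > 0.9
        assert mat[0, 1] < 0.7 and mat[1, 0] < 0.7

    def test_stationary_code_generalizes(self):
        rng = np.random.default_rng(15)
        direction = rng.standard_normal(20)
        pool = gaussian_pool(
            rng, n_units=20, n_trials=40, separation=6.0, n_bins=4, direction=direction
        )
        wins = [(0.0, 0.2), (0.2, 0.4)]
        mat = temporal_generalization(pool, wins, test_windows=wins, n_resamples=25, seed=16)
        assert np.all(mat > 0.95)  # off-diagonal ~ diagonal


class TestDecodeTransfer:
    def test_identical_test_distribution_matches_cv(self):
        rng = np.random.default_rng(17)
        direction = rng.standard_normal(25)
        train = gaussian_pool(rng, separation=4.0, direction=direction)
        test = gaussian_pool(rng, separation=4.0, direction=direction)
        acc = decode_transfer(train, test, bins=[0], n_resamples=30, seed=18)
        cv = cross_validated_accuracy(train, bins=[0], n_resamples=30, seed=18)
        assert acc[0] == pytest.approx(cv.mean[0], abs=0.05)

    def test_no_error_trials_rejected(self, default_cohort):
        sessions, _ = default_cohort
        with pytest.raises(ValueError):
            # passive sessions have no error trials at all
            build_pool(sessions, state="passive", outcome="error", min_trials=1)
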