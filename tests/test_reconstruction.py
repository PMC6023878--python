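"""Lagged-filter stimulus reconstruction: designs, fits, LOO error."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from popshift.data_model import BinnedTensor
from popshift.reconstruction import (
    ReconstructionParams,
    build_event_signal,
    build_lagged_design,
    fit_filter,
    loo_reconstruction_mse,
    reconstruct,
)
from popshift.synthetic import GeneratorConfig, generate_session


def _tensor(rates: np.ndarray, step: float = 0.001) -> BinnedTensor:
    n_units, n_trials, n_bins = rates.shape
    return BinnedTensor(
        rates=rates.astype(float),
        unit_ids=np.array([f"u{i}" for i in range(n_units)]),
        trial_ids=np.array([f"t{k}" for k in range(n_trials)]),
        bin_starts=np.arange(n_bins) * step,
        width=step,
        step=step,
    )


class TestLaggedDesign:
    def test_tau_zero_is_identity(self):
        r = np.arange(10.0).reshape(1, 1, 10)
        d = build_lagged_design(_tensor(r), 0, tau_steps=0)
        np.testing.assert_array_equal(d, r[:, 0, :])

    def test_shape_two_units(self):
        r = np.random.default_rng(0).random((2, 1, 8))
        d = build_lagged_design(_tensor(r), 0, tau_steps=3)
        assert d.shape == (8, 5)  # (tau+1)*N rows, T = n_bins - tau columns

    def test_index_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        r = rng.random((3, 2, 12))
        tau = 4
        d = build_lagged_design(_tensor(r), 1, tau_steps=tau)
        T = 12 - tau
        for i in range(3):
            for delta in range(tau + 1):
                for t in range(T):
                    assert d[i * (tau + 1) + delta, t] == r[i, 1, t + delta]

    def test_insufficient_length_rejected(self):
        r = np.zeros((1, 1, 5))
        with pytest.raises(ValueError, match="tau"):
            build_lagged_design(_tensor(r), 0, tau_steps=5)


class TestFitFilter:
    def test_exact_linear_system(self):
        # single unit whose rate equals the signal, tau = 0 -> g = [1]
        rng = np.random.default_rng(2)
        s = rng.random(50)
        tens = _tensor(s.reshape(1, 1, 50))
        d = build_lagged_design(tens, 0, 0)
        filt = fit_filter([d], [s], tens.unit_ids, tau_steps=0)
        assert filt.coef[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert filt.residual == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(reconstruct(filt, d), s, atol=1e-9)

    def test_white_noise_response_mse_is_signal_variance(self):
        # responses carry no signal information: held-out MSE ~ Var(S)
        rng = np.random.default_rng(3)
        n_tr, T = 30, 200
        s = rng.normal(0, 1, size=(n_tr, T))
        tens = _tensor(rng.normal(0, 1, size=(4, n_tr, T + 10)))
        designs = [build_lagged_design(tens, k, 10) for k in range(n_tr)]
        mses = []
        for k in range(3):
            tr = [d for j, d in enumerate(designs) if j != k]
            sig = [s[j] for j in range(n_tr) if j != k]
            filt = fit_filter(tr, sig, tens.unit_ids, tau_steps=10)
            err = s[k] - reconstruct(filt, designs[k])
            mses.append(np.mean(err**2))
        assert np.mean(mses) == pytest.approx(np.var(s), rel=0.2)

    def test_rank_deficient_matches_pseudoinverse(self):
        # three duplicated unit copies -> solution equals min-norm pinv fit
        rng = np.random.default_rng(4)
        base = rng.random((1, 1, 40))
        r = np.concatenate([base, base, base], axis=0)
        tens = _tensor(r)
        tau = 2
        d = build_lagged_design(tens, 0, tau)
        s = rng.random(40 - tau)
        filt = fit_filter([d], [s], tens.unit_ids, tau_steps=tau)
        oracle = s @ np.linalg.pinv(d)
        np.testing.assert_allclose(filt.flat, oracle, atol=1e-8)

    def test_zero_responses_warn_zero_filter(self):
        tens = _tensor(np.zeros((1, 1, 20)))
        d = build_lagged_design(tens, 0, 0)
        with pytest.warns(UserWarning, match="zero"):
            filt = fit_filter([d], [np.ones(20)], tens.unit_ids, tau_steps=0)
        assert not filt.coef.any()
        np.testing.assert_array_equal(reconstruct(filt, d), np.zeros(20))

    def test_training_residual_nonincreasing_in_rank(self):
        rng = np.random.default_rng(5)
        tens = _tensor(rng.random((4, 1, 60)))
        tau = 3
        d = build_lagged_design(tens, 0, tau)
        s = rng.random(60 - tau)
        resid = [
            fit_filter([d], [s], tens.unit_ids, tau, rank_cap=k).residual
            for k in (1, 2, 4, 8, 16)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(resid, resid[1:]))

    def test_reconstruct_linearity_and_shape_check(self):
        rng = np.random.default_rng(6)
        tens = _tensor(rng.random((2, 1, 30)))
        d = build_lagged_design(tens, 0, 2)
        s = rng.random(28)
        filt = fit_filter([d], [s], tens.unit_ids, 2)
        scaled = dataclasses.replace(filt, coef=2.0 * filt.coef)
        np.testing.assert_allclose(reconstruct(scaled, d), 2.0 * reconstruct(filt, d))
        with pytest.raises(ValueError, match="rows"):
            reconstruct(filt, d[:-1])


class TestEventSignal:
    def test_boxcar_kernel(self):
        events = pd.DataFrame({"trial_id": ["t0"], "time_s": [0.05]})
        t = np.arange(0, 0.2, 0.01)
        sig = build_event_signal(events, np.array(["t0", "t1"]), t, kernel_width=0.03)
        assert sig.values[0].sum() == pytest.approx(3.0)  # 3 samples of 10 ms
        assert sig.values[1].sum() == 0.0
        assert sig.values[0][5] == 1.0 and sig.values[0][8] == 0.0


class TestLooReconstruction:
    def _noise_free_session_mse(self):
        # population of delayed copies of the signal: reconstruction is exact
        rng = np.random.default_rng(7)
        T = 150
        tau = 5
        s = rng.random((6, T))
        rates = np.zeros((3, 6, T + tau))
        for i in range(3):
            rates[i, :, i : i + T] = s  # unit i sees the signal at lag i
        designs = [build_lagged_design(_tensor(rates), k, tau) for k in range(6)]
        mses = []
        for k in range(6):
            filt = fit_filter(
                [d for j, d in enumerate(designs) if j != k],
                [s[j] for j in range(6) if j != k],
                np.array(["u0", "u1", "u2"]),
                tau,
            )
            err = s[k] - reconstruct(filt, designs[k])
            mses.append(np.mean(err**2))
        return np.mean(mses), np.var(s)

    def test_noise_free_heldout_recovery(self):
        mse, var = self._noise_free_session_mse()
        assert mse < 1e-3 * var

    def test_unit_permutation_invariance(self):
        cfg = GeneratorConfig(n_units=6, n_sessions=1, n_trials=5, lick_fraction=0.0)
        sess, _ = generate_session(cfg, 11)
        params = ReconstructionParams(step=0.01, tau=0.03)
        base = loo_reconstruction_mse(sess, params)
        shuffled = dataclasses.replace(sess)
        perm = np.random.default_rng(0).permutation(len(sess.spikes))
        shuffled.spikes = sess.spikes.iloc[perm].reset_index(drop=True)
        again = loo_reconstruction_mse(shuffled, params)
        for k, v in base.mean_mse.items():
            assert again.mean_mse[k] == pytest.approx(v, rel=1e-9)

    def test_degraded_engaged_locking_raises_engaged_error(self):
        # weaker engaged click entrainment -> larger engaged LOO MSE
        params = ReconstructionParams(step=0.005, tau=0.05)
        wins = 0
        for seed in range(10):
            cfg = GeneratorConfig(
                n_units=12,
                n_sessions=1,
                n_trials=12,
                sound_gain=30.0,
                passive_class_amp=5.0,
                engaged_ref_amp=5.0,
                engaged_target_amp=5.0,
                kappa_passive=8.0,
                kappa_engaged=0.5,
                lick_fraction=0.0,
                error_fraction=0.0,
            )
            sess, _ = generate_session(cfg, 100 + seed)
            res = loo_reconstruction_mse(sess, params)
            eng = np.mean([res.mean_mse[("engaged", c)] for c in ("reference", "target")])
            pas = np.mean([res.mean_mse[("passive", c)] for c in ("reference", "target")])
            wins += eng > pas
        assert wins == 10

    def test_single_trial_cell_rejected(self):
        cfg = GeneratorConfig(n_units=4, n_sessions=1, n_trials=1, lick_fraction=0.0)
        sess, _ = generate_session(cfg, 12)
        with pytest.raises(ValueError, match="LOO"):
            loo_reconstruction_mse(sess, ReconstructionParams(step=0.01, tau=0.02))
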