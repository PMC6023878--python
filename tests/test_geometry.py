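"""Decoding-axis projections, distances, indices, latency."""

import numpy as np
import pytest

from popshift.decoder import build_pool, cross_validated_accuracy
from popshift.geometry import (
    asymmetry_index,
    class_averages,
    cross_state_projection,
    distance_from_baseline,
    enhancement_index_trace,
    latency_half_max,
    normalized_axes,
    project_on_axis,
    spontaneous_baseline,
    target_enhancement_index,
    uniform_axis,
    uniform_weight_projection,
)
from popshift.synthetic import (
    baseline_shift_config,
    evoked_change_config,
    generate_cohort,
)


def _planted(n_units=12, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n_units)
    w /= np.linalg.norm(w)
    spont = rng.random(n_units) * 4
    return rng, w, spont


class TestProjection:
    def test_subtracted_spontaneous_projects_to_zero(self):
        rng, w, spont = _planted()
        avgs = {"reference": np.tile(spont[:, None], 5)}
        trace = project_on_axis(avgs, w, spont, np.arange(5) * 0.1)
        np.testing.assert_allclose(trace.proj["reference"], 0.0, atol=1e-12)
        np.testing.assert_allclose(trace.baselines["spontaneous"], 0.0, atol=1e-12)

    def test_planted_distance_recovered(self):
        rng, w, spont = _planted()
        d = 3.7
        avgs = {"target": np.tile((spont + d * w)[:, None], 4)}
        trace = project_on_axis(avgs, w, spont, np.arange(4) * 0.1)
        dist = distance_from_baseline(trace, (0.0, 0.4))
        assert dist["target"][0] == pytest.approx(d, abs=1e-12)

    def test_orthogonal_pattern_projects_to_baseline(self):
        rng, w, spont = _planted()
        orth = rng.standard_normal(len(w))
        orth -= (orth @ w) * w  # remove the axis component
        avgs = {"reference": np.tile((spont + orth)[:, None], 3)}
        trace = project_on_axis(avgs, w, spont, np.arange(3) * 0.1)
        np.testing.assert_allclose(trace.proj["reference"], 0.0, atol=1e-9)

    def test_projection_is_linear(self):
        rng, w, spont = _planted()
        a = rng.random((len(w), 6))
        b = rng.random((len(w), 6))
        t = np.arange(6) * 0.1
        pa = project_on_axis({"x": a}, w, spont, t).proj["x"]
        pb = project_on_axis({"x": b}, w, spont, t).proj["x"]
        pm = project_on_axis({"x": (a + b) / 2}, w, spont, t).proj["x"]
        np.testing.assert_allclose(pm, (pa + pb) / 2, atol=1e-10)

    def test_window_mean_matches_hand_average(self):
        rng, w, spont = _planted()
        a = rng.random((len(w), 10))
        t = np.arange(10) * 0.1
        trace = project_on_axis({"x": a}, w, spont, t)
        d = distance_from_baseline(trace, (0.2, 0.5))
        hand = abs(np.mean(trace.proj["x"][0, 2:5]))
        assert d["x"][0] == pytest.approx(hand, abs=1e-12)


class TestIndices:
    def test_asymmetry_values(self):
        assert asymmetry_index(2.0, 0.5) == pytest.approx(1.5)
        assert asymmetry_index(1.0, 1.0) == 0.0
        assert asymmetry_index(0.5, 2.0) == -asymmetry_index(2.0, 0.5)

    def test_target_enhancement_values(self):
        assert target_enhancement_index(1, 1, 1, 1) == 0.0
        assert target_enhancement_index(3, 1, 0.5, 1) == pytest.approx(2.5)

    def test_symmetric_gain_algebra(self):
        # pure gain g on both classes: index = (g - 1) * (d_T - d_R)
        d_t, d_r, g = 2.4, 0.9, 1.7
        got = target_enhancement_index(g * d_t, d_t, g * d_r, d_r)
        assert got == pytest.approx((g - 1) * (d_t - d_r), abs=1e-12)


class TestCrossState:
    def test_identical_states_all_cases_equal(self):
        rng, w, spont = _planted()
        avgs = {"reference": rng.random((len(w), 6)), "target": rng.random((len(w), 6))}
        by_state = {"passive": avgs, "engaged": avgs}
        bases = {"passive": spont, "engaged": spont}
        out = cross_state_projection(w, by_state, bases, np.arange(6) * 0.1, (0.0, 0.6))
        vals = [v[0] for v in out.values()]
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)
        assert vals[1] == pytest.approx(vals[2], abs=1e-12)

    def test_missing_state_rejected(self):
        rng, w, spont = _planted()
        with pytest.raises(ValueError, match="missing state"):
            cross_state_projection(w, {"passive": {}}, {"passive": spont}, np.arange(2), (0, 1))

    def _mechanism_cases(self, cfg, seed):
        sessions, _ = generate_cohort(cfg, seed)
        pools = {st: build_pool(sessions, state=st) for st in ("passive", "engaged")}
        avgs = {st: class_averages(p) for st, p in pools.items()}
        bases = {st: spontaneous_baseline(p) for st, p in pools.items()}
        dec = cross_validated_accuracy(
            pools["engaged"], windows=[(1.7, 2.0)], n_resamples=40, seed=7
        )
        times = pools["engaged"].bin_starts + 0.05
        out = cross_state_projection(dec.weights[0], avgs, bases, times, (1.7, 2.0))
        return {k: float(np.mean(v)) for k, v in out.items()}

    def test_baseline_shift_mechanism_recovered(self):
        c = self._mechanism_cases(
            baseline_shift_config(n_units=20, n_sessions=2, n_trials=30), 31
        )
        c1 = c["passive_evoked_vs_engaged_spont"]
        c2 = c["engaged_evoked_vs_passive_spont"]
        c3 = c["engaged_evoked_vs_engaged_spont"]
        assert c1 == pytest.approx(c3, abs=0.25 * abs(c3))
        assert c3 - c2 > 0.5 * abs(c3)  # case ii clearly differs

    def test_evoked_change_mechanism_recovered(self):
        c = self._mechanism_cases(
            evoked_change_config(n_units=20, n_sessions=2, n_trials=30), 32
        )
        c1 = c["passive_evoked_vs_engaged_spont"]
        c3 = c["engaged_evoked_vs_engaged_spont"]
        assert abs(c1 - c3) > 0.5 * abs(c3)


class TestUniformWeight:
    def test_zero_sum_asymmetry_invisible_to_population_average(self, default_cohort, cohort_pools):
        # planted class directions are orthogonal to the all-ones vector
        pools = cohort_pools
        avgs = {st: class_averages(p) for st, p in pools.items()}
        bases = {st: spontaneous_baseline(p) for st, p in pools.items()}
        uni = uniform_weight_projection(avgs, bases)
        dec = cross_validated_accuracy(
            pools["engaged"], windows=[(1.7, 2.0)], n_resamples=40, seed=3
        )
        decoder_tei = enhancement_index_trace(avgs, bases, dec.weights[0])
        sound = pools["engaged"].window_bins((1.7, 2.0))
        assert abs(uni[:, sound].mean()) < 0.2 * decoder_tei[:, sound].mean()
        assert decoder_tei[:, sound].mean() > 5.0

    def test_global_target_gain_seen_by_both_readouts(self):
        from popshift.synthetic import GeneratorConfig, generate_cohort
        from popshift.decoder import build_pool

        cfg = GeneratorConfig(
            n_units=20, n_sessions=2, n_trials=30, target_common_gain=10.0,
            lick_fraction=0.0,
        )
        sessions, _ = generate_cohort(cfg, 33)
        pools = {st: build_pool(sessions, state=st) for st in ("passive", "engaged")}
        avgs = {st: class_averages(p) for st, p in pools.items()}
        bases = {st: spontaneous_baseline(p) for st, p in pools.items()}
        uni = uniform_weight_projection(avgs, bases)
        dec = cross_validated_accuracy(
            pools["engaged"], windows=[(1.7, 2.0)], n_resamples=40, seed=4
        )
        decoder_tei = enhancement_index_trace(avgs, bases, dec.weights[0])
        sound = pools["engaged"].window_bins((1.7, 2.0))
        assert uni[:, sound].mean() > 1.0
        assert decoder_tei[:, sound].mean() > 1.0

    def test_uniform_axis_equals_explicit_projection(self):
        rng, _, spont = _planted()
        n = len(spont)
        avgs = {"x": rng.random((n, 4))}
        t = np.arange(4) * 0.1
        a = project_on_axis(avgs, uniform_axis(n), spont, t).proj["x"]
        b = project_on_axis(avgs, np.ones((1, n)), spont, t).proj["x"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestLatency:
    def test_step_crosses_at_step_time(self):
        t = np.arange(0, 3.2, 0.1) + 0.05  # bin centers
        y = np.where(t > 1.79, 2.0, 0.0)  # continuous step at 1.8 s
        res = latency_half_max(t, y, response_window=(1.65, 3.2), onset=1.65)
        assert res.defined
        assert res.latency == pytest.approx(1.8 - 1.65, abs=1e-9)

    def test_linear_ramp_half_time(self):
        t = np.arange(0.0, 1.0, 0.01) + 0.005
        y = 2.0 * t  # ramp 0 -> 2 over [0, 1] from zero baseline
        res = latency_half_max(
            t, y, response_window=(0.0, 1.0), baseline_window=(0.0, 0.01),
            onset=0.0, smooth_bins=1,
        )
        # baseline is the first sample (~0), half-max ~1.0, crossing ~0.5 s
        assert res.latency == pytest.approx(0.5, abs=0.02)

    def test_flat_trace_undefined(self):
        t = np.arange(0, 3.2, 0.1)
        res = latency_half_max(t, np.ones_like(t), response_window=(1.65, 3.2))
        assert not res.defined
        assert np.isnan(res.latency)


def test_normalized_axes_zero_safe():
    w = np.array([[3.0, 4.0], [0.0, 0.0]])
    out = normalized_axes(w)
    np.testing.assert_allclose(out[0], [0.6, 0.8])
    np.testing.assert_allclose(out[1], 0.0)
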