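"""Identification and removal of lick-responsive units.

Motor (licking) activity can masquerade as stimulus information, so units
whose activity lets lick events be decoded are excluded before the
population analyses.  The procedure:

1. reconstruct the lick-event signal separately for each unit with the
   lagged-filter method (single-unit designs);
2. sample each unit's reconstruction at lick times and at an equal number
   of random non-lick times (kept a margin away from any lick), forming
   lick / non-lick population vectors;
3. classify lick vs non-lick vectors with the prototype decoder under
   cross-validation;
4. calibrate chance with randomized data obtained by reconstructing one
   session's lick signal from a *different* session's activity (with a
   single session, a circular trial-shift fallback is used and logged);
5. iteratively remove the unit with the highest current decoder weight and
   re-evaluate, until the empirical p rises above 0.4 — the remaining
   units then carry no more lick information than randomized data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import SessionData, bin_spikes
from .decoder import empirical_p, fit_prototype_decoder
from .reconstruction import build_event_signal, build_lagged_design, fit_filter, reconstruct

__all__ = [
    "LickControlParams",
    "LickFeatureSet",
    "LickDecodability",
    "LickRemovalResult",
    "lick_feature_extraction",
    "lick_decodability",
    "iterative_unit_removal",
]


@dataclass(frozen=True)
class LickControlParams:
    """Reconstruction and testing settings for the lick control."""

    width: float = 0.010
    step: float = 0.005
    tau: float = 0.100
    rank_cap: int = 70
    sv_floor: float = 1e-10
    kernel_width: float = 0.010
    exclusion_margin: float = 0.100  # non-lick samples stay this far from licks
    n_cv: int = 20  # cross-validations per removal step
    n_cv_final: int = 50  # full evaluation at termination
    n_null: int = 20  # randomized-pairing replicates
    p_threshold: float = 0.4

    @property
    def tau_steps(self) -> int:
        return int(round(self.tau / self.step))


@dataclass
class LickFeatureSet:
    """Per-unit reconstruction values at lick and matched non-lick times."""

    lick_values: np.ndarray  # (n_events, n_units)
    nonlick_values: np.ndarray  # (n_events, n_units)
    unit_ids: np.ndarray
    session_id: str
    seed: int | None = None

    def drop_units(self, drop: set) -> "LickFeatureSet":
        keep = np.array([u not in drop for u in self.unit_ids])
        return LickFeatureSet(
            lick_values=self.lick_values[:, keep],
            nonlick_values=self.nonlick_values[:, keep],
            unit_ids=self.unit_ids[keep],
            session_id=self.session_id,
            seed=self.seed,
        )


@dataclass
class LickDecodability:
    accuracy: float
    null_accuracies: np.ndarray
    p: float
    raw_count: int
    unit_weights: dict  # unit_id -> mean |normalized weight|


@dataclass
class LickRemovalResult:
    removed_unit_ids: list
    p_trajectory: list[float]
    accuracy_trajectory: list[float]
    retained_unit_ids: list
    termination_step: int
    final_p: float = np.nan


# ---------------------------------------------------------------------------
# per-unit lick reconstruction
# ---------------------------------------------------------------------------

@dataclass
class _SessionTraces:
    """Per-trial, per-unit lick reconstructions on the signal time grid."""

    traces: np.ndarray  # (n_trials, n_samples, n_units)
    t_sig: np.ndarray
    licks_by_trial: dict
    trial_ids: np.ndarray
    unit_ids: np.ndarray
    session_id: str


def _session_traces(
    lick_session: SessionData,
    activity_session: SessionData,
    params: LickControlParams,
    circular_shift: int = 0,
) -> _SessionTraces:
    """Reconstruct `lick_session`'s lick signal from `activity_session`'s units.

    Trial pairing is positional over engaged trials; ``circular_shift``
    rotates the activity trials (single-session randomization fallback).
    """
    if len(lick_session.licks) == 0:
        raise ValueError(f"session {lick_session.session_id} has no lick events")
    lick_trials = lick_session.select_trials(state="engaged")
    act_trials = activity_session.select_trials(state="engaged")
    n = min(len(lick_trials), len(act_trials))
    lick_trials, act_trials = lick_trials[:n], act_trials[:n]
    if circular_shift:
        act_trials = np.roll(act_trials, -circular_shift)
    binned = bin_spikes(activity_session, width=params.width, step=params.step, trial_ids=act_trials)
    tau = params.tau_steps
    t_sig = binned.bin_starts[: binned.n_bins - tau]
    sig = build_event_signal(
        lick_session.licks[lick_session.licks["trial_id"].isin(lick_trials)],
        lick_trials,
        t_sig,
        params.kernel_width,
    )
    n_units = binned.n_units
    traces = np.zeros((n, t_sig.size, n_units))
    for i in range(n_units):
        designs = [
            build_lagged_design(binned.select_units([binned.unit_ids[i]]), k, tau)
            for k in range(n)
        ]
        filt = fit_filter(
            designs,
            list(sig.values),
            unit_ids=binned.unit_ids[i : i + 1],
            tau_steps=tau,
            rank_cap=params.rank_cap,
            sv_floor=params.sv_floor,
        )
        for k in range(n):
            traces[k, :, i] = reconstruct(filt, designs[k])
    licks_by_trial = {
        k: g["time_s"].to_numpy()
        for k, g in lick_session.licks.groupby("trial_id")
        if k in set(lick_trials)
    }
    return _SessionTraces(
        traces=traces,
        t_sig=t_sig,
        licks_by_trial=licks_by_trial,
        trial_ids=lick_trials,
        unit_ids=binned.unit_ids,
        session_id=lick_session.session_id,
    )


def _sample_features(
    tr: _SessionTraces, margin: float, rng: np.random.Generator, seed: int | None = None
) -> LickFeatureSet:
    """Sample reconstruction values at lick and matched non-lick times."""
    t_max = tr.t_sig[-1]
    lick_rows, non_rows = [], []
    for k, tid in enumerate(tr.trial_ids):
        lt = tr.licks_by_trial.get(tid)
        if lt is None:
            continue
        lt = lt[lt < t_max]
        if lt.size == 0:
            continue
        idx = np.searchsorted(tr.t_sig, lt, side="right") - 1
        lick_rows.append(tr.traces[k, idx, :])
        # matched count of non-lick times, >= margin from any lick
        need = lt.size
        got = []
        for _ in range(200):
            cand = rng.uniform(0.0, t_max, size=4 * need)
            ok = np.min(np.abs(cand[:, None] - lt[None, :]), axis=1) >= margin
            got.extend(cand[ok].tolist())
            if len(got) >= need:
                break
        if len(got) < need:
            continue  # trial nearly saturated with licks; skip its samples
        cand = np.asarray(got[:need])
        idx = np.searchsorted(tr.t_sig, cand, side="right") - 1
        non_rows.append(tr.traces[k, idx, :])
    if not lick_rows:
        raise ValueError(f"session {tr.session_id}: no usable lick events")
    lick_vals = np.vstack(lick_rows)
    non_vals = np.vstack(non_rows)
    n = min(len(lick_vals), len(non_vals))
    return LickFeatureSet(
        lick_values=lick_vals[:n],
        nonlick_values=non_vals[:n],
        unit_ids=tr.unit_ids,
        session_id=tr.session_id,
        seed=seed,
    )


def lick_feature_extraction(
    session: SessionData,
    params: LickControlParams = LickControlParams(),
    seed: int | None = None,
    activity_session: SessionData | None = None,
    circular_shift: int = 0,
) -> LickFeatureSet:
    """Per-unit lick-reconstruction features for one session.

    With ``activity_session`` (or a nonzero ``circular_shift``) the lick
    signal is reconstructed from mismatched activity — the randomized
    control.
    """
    rng = np.random.default_rng(seed)
    tr = _session_traces(session, activity_session or session, params, circular_shift)
    return _sample_features(tr, params.exclusion_margin, rng, seed)


# ---------------------------------------------------------------------------
# decodability
# ---------------------------------------------------------------------------

def _cv_accuracy(features: list[LickFeatureSet], n_cv: int, rng: np.random.Generator):
    """Mean CV accuracy of lick vs non-lick classification, pooled weights.

    Half of the events train the prototype decoder, the rest are tested;
    one decoder per session, accuracy averaged over sessions and CVs.
    """
    accs = []
    weight_sums = {}
    for fs in features:
        n = len(fs.lick_values)
        if n < 2:
            raise ValueError("need at least 2 lick events per session")
        n_train = max(1, n // 2)
        sess_acc = np.zeros(n_cv)
        w_acc = np.zeros(fs.lick_values.shape[1])
        for r in range(n_cv):
            pl = rng.permutation(n)
            pn = rng.permutation(n)
            dec = fit_prototype_decoder(
                fs.nonlick_values[pn[:n_train]], fs.lick_values[pl[:n_train]]
            )
            y_l = fs.lick_values[pl[n_train:]] @ dec.w + dec.b
            y_n = fs.nonlick_values[pn[n_train:]] @ dec.w + dec.b
            sess_acc[r] = 0.5 * (np.mean(y_l > 0) + np.mean(y_n <= 0))
            nrm = np.linalg.norm(dec.w)
            w_acc += np.abs(dec.w) / (nrm if nrm else 1.0)
        accs.append(sess_acc.mean())
        for u, wv in zip(fs.unit_ids, w_acc / n_cv):
            weight_sums[u] = float(wv)
    return float(np.mean(accs)), weight_sums


def lick_decodability(
    features: list[LickFeatureSet],
    null_features: list[list[LickFeatureSet]],
    n_cv: int = 20,
    seed: int | None = None,
) -> LickDecodability:
    """Observed lick decodability against the randomized-pairing control.

    p = (1 + #{null >= observed}) / (1 + n_null) — add-one corrected, so it
    can never reach 0; the raw exceedance count is reported alongside.
    """
    if not null_features:
        raise ValueError("need at least one randomized control replicate")
    rng = np.random.default_rng(seed)
    acc, weights = _cv_accuracy(features, n_cv, rng)
    null = np.array([_cv_accuracy(nf, n_cv, rng)[0] for nf in null_features])
    p = empirical_p(null, acc)
    return LickDecodability(
        accuracy=acc,
        null_accuracies=null,
        p=p,
        raw_count=int(np.sum(null >= acc)),
        unit_weights=weights,
    )


# ---------------------------------------------------------------------------
# iterative removal
# ---------------------------------------------------------------------------

def iterative_unit_removal(
    sessions: list[SessionData],
    params: LickControlParams = LickControlParams(),
    seed: int | None = None,
) -> LickRemovalResult:
    """Remove highest-weight units until lick decodability is at chance.

    One unit per step (the largest current |decoder weight|, recomputed at
    every step); the loop stops when the empirical p exceeds
    ``params.p_threshold`` (default 0.4), after which a final evaluation at
    ``n_cv_final`` is reported.  Aborts rather than emptying the population.
    """
    ss = np.random.SeedSequence(0 if seed is None else seed)
    rng = np.random.default_rng(ss)
    n_sessions = len(sessions)
    if n_sessions < 2:
        warnings.warn(
            "single session: randomized control falls back to circular trial shifts",
            stacklevel=2,
        )
    # reconstruction traces: observed pairing + mismatched pairings
    obs = [_session_traces(s, s, params) for s in sessions]
    mism: list[list[_SessionTraces]] = []
    if n_sessions >= 2:
        for rot in range(1, n_sessions):
            mism.append(
                [_session_traces(sessions[i], sessions[(i + rot) % n_sessions], params) for i in range(n_sessions)]
            )
    else:
        for shift in range(1, 4):
            mism.append([_session_traces(sessions[0], sessions[0], params, circular_shift=shift)])

    def draw_features(drop: set):
        feats = [
            _sample_features(t, params.exclusion_margin, rng).drop_units(drop) for t in obs
        ]
        nulls = []
        for r in range(params.n_null):
            group = mism[r % len(mism)]
            nulls.append(
                [_sample_features(t, params.exclusion_margin, rng).drop_units(drop) for t in group]
            )
        return feats, nulls

    removed: list = []
    p_traj: list[float] = []
    acc_traj: list[float] = []
    drop: set = set()
    n_units_total = sum(len(t.unit_ids) for t in obs)
    step = 0
    while True:
        feats, nulls = draw_features(drop)
        res = lick_decodability(feats, nulls, n_cv=params.n_cv, seed=int(rng.integers(2**31)))
        p_traj.append(res.p)
        acc_traj.append(res.accuracy)
        if res.p > params.p_threshold:
            break
        if n_units_total - len(removed) <= 1:
            raise RuntimeError(
                "lick-unit removal would empty the population before reaching chance"
            )
        worst = max(res.unit_weights, key=lambda u: res.unit_weights[u])
        removed.append(worst)
        drop.add(worst)
        step += 1
    # final evaluation at full n_cv
    feats, nulls = draw_features(drop)
    final = lick_decodability(feats, nulls, n_cv=params.n_cv_final, seed=int(rng.integers(2**31)))
    retained = [u for t in obs for u in t.unit_ids if u not in drop]
    return LickRemovalResult(
        removed_unit_ids=removed,
        p_trajectory=p_traj,
        accuracy_trajectory=acc_traj,
        retained_unit_ids=retained,
        termination_step=step,
        final_p=final.p,
    )
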