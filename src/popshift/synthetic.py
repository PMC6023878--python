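"""Synthetic Go/No-Go session generator with planted, recoverable structure.

The generator emulates the features of passive/engaged A1 recordings that
the downstream analyses are designed to detect, with inhomogeneous Poisson
spiking at 1 ms resolution:

* per-unit log-normal baseline rates, shifted in the engaged state by
  ``delta`` along a non-negative unit-norm state direction ``u`` (so task
  engagement raises spontaneous rates on average);
* a neutral TORC response shared by both classes and states;
* click-train responses modulated by a von Mises-shaped periodic kernel at
  the trial's click rate with concentration ``kappa`` (engaged < passive,
  i.e. weaker phase locking during behavior);
* class-specific evoked patterns: symmetric ``+/- s*v`` about a common gain
  in the passive state; in the engaged state the reference pattern lies
  along ``u`` (hence near the shifted baseline as seen by the decoder) and
  the target carries a large amplitude along ``v``;
* a persistent post-stimulus (silence-epoch) pattern along ``v2`` on target
  trials, much larger when engaged, reduced to the passive amplitude on
  error trials;
* a planted subset of lick-locked units driven by a causal kernel around
  each lick event, with avoidance-style lick behavior (lick throughout
  reference trials, stop shortly after target onset on correct trials,
  keep licking on error trials).

Class/state directions ``v`` and ``v2`` are drawn orthogonal to the
all-ones vector (zero population-mean patterns), so planted asymmetries are
invisible to a uniform-weight readout; ``u`` has non-negative entries.
All randomness flows from a master seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .data_model import EpochTemplate, SessionData

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_session",
    "generate_cohort",
    "make_lick_times",
    "baseline_shift_config",
    "evoked_change_config",
]

_SUBSTREAMS = {"directions": 0, "baselines": 1, "trial_order": 2, "spikes": 3, "licks": 4}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    Rates are in spikes/s; amplitudes are pattern norms in spikes/s along
    unit-norm directions.  ``n_units`` is per session.
    """

    n_units: int = 30
    n_sessions: int = 2
    n_trials: int = 40  # per state per class per session
    template: EpochTemplate = field(default_factory=EpochTemplate)
    reference_rates_hz: tuple[float, ...] = (6.0, 7.0, 8.0, 15.0)
    target_rates_hz: tuple[float, ...] = (24.0, 28.0, 32.0, 36.0)
    # baselines
    baseline_log_mean: float = float(np.log(4.0))
    baseline_log_sd: float = 0.4
    delta: float = 2.0  # engaged spontaneous shift magnitude along u
    # evoked structure
    torc_gain: float = 3.0
    sound_gain: float = 5.0  # common per-unit gain during the click train
    passive_class_amp: float = 20.0  # +/- along v in the passive state
    engaged_ref_amp: float = 3.0  # along u in the engaged state
    engaged_target_amp: float = 40.0  # along v in the engaged state
    target_common_gain: float = 0.0  # extra uniform gain, engaged targets only
    silence_amp_passive: float = 8.0  # target-trial persistent code along v2
    silence_amp_engaged: float = 25.0
    # phase locking
    kappa_passive: float = 5.0
    kappa_engaged: float = 2.0
    # lick units and behavior
    lick_fraction: float = 0.1
    lick_amp: float = 15.0
    lick_kernel_width: float = 0.1
    lick_rate_hz: float = 7.0
    lick_mode: str = "avoidance"  # or "appetitive"
    lick_stop_latency: float = 0.35
    lick_start_latency: float = 0.35
    error_fraction: float = 0.2  # fraction of engaged target trials
    # mechanism planting switches
    engaged_evoked_same_as_passive: bool = False
    shift_toward_reference: bool = False  # u = -v ("baseline-shift" planting)
    evoked_absolute: bool = False  # absolute click-epoch patterns state-invariant
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_sessions < 1 or self.n_trials < 1:
            raise ValueError("n_units, n_sessions and n_trials must be >= 1")
        if not (0.0 <= self.lick_fraction <= 1.0 and 0.0 <= self.error_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.lick_mode not in ("avoidance", "appetitive"):
            raise ValueError(f"unknown lick mode {self.lick_mode!r}")


def baseline_shift_config(**overrides) -> GeneratorConfig:
    """Config planting the baseline-shift mechanism.

    Evoked patterns are state-invariant; only the spontaneous pattern moves,
    along the decoding axis toward the reference-evoked pattern.
    """
    kw = dict(
        engaged_evoked_same_as_passive=True,
        shift_toward_reference=True,
        evoked_absolute=True,
        delta=8.0,
        lick_fraction=0.0,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def evoked_change_config(**overrides) -> GeneratorConfig:
    """Config planting the evoked-change mechanism (spontaneous state-invariant)."""
    kw = dict(delta=0.0, lick_fraction=0.0)
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass
class GroundTruth:
    """Planted parameters, derivable deterministically from (config, seed)."""

    u: np.ndarray
    v: np.ndarray
    v2: np.ndarray
    delta: float
    kappa: dict[str, float]
    lick_unit_ids: list[str]
    unit_ids: list[str]
    baselines: dict[str, np.ndarray]  # per state, per unit
    expected_vs: dict[str, np.ndarray]  # per state, reference-class, per unit
    planted_distances: dict[str, dict[str, float]]  # state -> class -> d along ideal sound axis
    silence_amps: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# direction and baseline draws
# ---------------------------------------------------------------------------

def _draw_directions(rng: np.random.Generator, n: int, toward_reference: bool):
    """Unit-norm u (non-negative entries), v, v2 (zero-sum, orthonormal)."""
    raw = rng.standard_normal((2, n))
    raw -= raw.mean(axis=1, keepdims=True)  # orthogonal to the ones vector
    q, _ = np.linalg.qr(raw.T)
    v, v2 = q[:, 0], q[:, 1]
    if toward_reference:
        u = -v
    else:
        u = np.abs(rng.standard_normal(n))
        u /= np.linalg.norm(u)
    return u, v, v2


def _class_patterns(cfg: GeneratorConfig, u, v, state: str) -> dict[str, np.ndarray]:
    """Evoked click-train pattern (on top of common sound gain) per class."""
    n = len(v)
    common = np.full(n, cfg.sound_gain)
    if state == "passive" or cfg.engaged_evoked_same_as_passive:
        ref = common - cfg.passive_class_amp * v
        targ = common + cfg.passive_class_amp * v
    else:
        ref = common + cfg.engaged_ref_amp * u
        targ = common + cfg.engaged_target_amp * v + cfg.target_common_gain
    return {"reference": ref, "target": targ}


def _expected_vs(cfg: GeneratorConfig, baseline, pattern, kappa) -> np.ndarray:
    """Diluted von Mises resultant: locked A with r=I1/I0, unlocked B uniform."""
    locked = np.clip(pattern, 0.0, None)
    r_vm = i1e(kappa) / i0e(kappa)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = locked * r_vm / (locked + np.clip(baseline, 0.0, None))
    return np.nan_to_num(out)


# ---------------------------------------------------------------------------
# lick behavior
# ---------------------------------------------------------------------------

def make_lick_times(
    trials: pd.DataFrame,
    template: EpochTemplate,
    mode: str = "avoidance",
    lick_rate_hz: float = 7.0,
    stop_latency: float = 0.35,
    start_latency: float = 0.35,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Poisson lick events per engaged trial under a behavior model.

    avoidance: lick throughout reference trials; on correct target trials
    cease ``stop_latency`` after target (click-train) onset; keep licking on
    error trials.  appetitive: the reverse (no licks on reference; start
    ``start_latency`` after target onset on correct trials).
    Passive trials never contain licks.
    """
    if mode not in ("avoidance", "appetitive"):
        raise ValueError(f"unknown lick mode {mode!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    span = template.trial_span
    onset = template.click_train[0]
    rows_t, rows_time = [], []
    for _, tr in trials.iterrows():
        if tr["state"] != "engaged":
            continue
        if mode == "avoidance":
            if tr["stimulus"] == "reference" or tr["outcome"] == "error":
                interval = (0.0, span)
            else:
                interval = (0.0, onset + stop_latency)
        else:  # appetitive
            if tr["stimulus"] == "target" and tr["outcome"] == "correct":
                interval = (onset + start_latency, span)
            else:
                continue
        a, b = interval
        n = rng.poisson(lick_rate_hz * (b - a))
        if n:
            t = np.sort(rng.uniform(a, b, size=n))
            rows_t.extend([tr["trial_id"]] * n)
            rows_time.extend(t.tolist())
    return pd.DataFrame({"trial_id": rows_t, "time_s": np.asarray(rows_time, dtype=float)})


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _vm_kernel(times: np.ndarray, onset: float, rate_hz: float, kappa: float) -> np.ndarray:
    """Mean-one periodic von Mises kernel at the click rate.

    exp(kappa*(cos - 1)) / i0e(kappa) is the overflow-safe form of
    exp(kappa*cos) / I0(kappa).
    """
    if kappa == 0:
        return np.ones_like(times)
    phase = 2.0 * np.pi * (times - onset) * rate_hz
    return np.exp(kappa * (np.cos(phase) - 1.0)) / i0e(kappa)


def _make_trials(cfg: GeneratorConfig, sid: str, rng: np.random.Generator) -> pd.DataFrame:
    ref_rate = float(rng.choice(cfg.reference_rates_hz))
    targ_rate = float(rng.choice(cfg.target_rates_hz))
    rows = []
    n_err = int(round(cfg.error_fraction * cfg.n_trials))
    for state in ("passive", "engaged"):
        for stim, rate in [("reference", ref_rate), ("target", targ_rate)]:
            outcomes = np.array(["correct"] * cfg.n_trials, dtype=object)
            if state == "engaged" and stim == "target" and n_err:
                err_idx = rng.choice(cfg.n_trials, size=n_err, replace=False)
                outcomes[err_idx] = "error"
            for j in range(cfg.n_trials):
                rows.append((f"{sid}_{state}_{stim}_{j:03d}", state, stim, outcomes[j], rate))
    return pd.DataFrame(rows, columns=["trial_id", "state", "stimulus", "outcome", "click_rate_hz"])


def _click_times(template: EpochTemplate, rate_hz: float) -> np.ndarray:
    a, b = template.click_train
    n = int(np.floor((b - a) * rate_hz - 1e-9)) + 1
    t = a + np.arange(n) / rate_hz
    return t[t < b - 1e-12]


def _generate_one_session(
    cfg: GeneratorConfig,
    sid: str,
    baselines: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    v2: np.ndarray,
    lick_mask: np.ndarray,
    seeds,
) -> SessionData:
    tpl = cfg.template
    n_steps = int(round(tpl.trial_span / cfg.dt))
    times = (np.arange(n_steps) + 0.5) * cfg.dt
    rng_trials = np.random.default_rng(seeds["trial_order"])
    rng_spikes = np.random.default_rng(seeds["spikes"])
    rng_licks = np.random.default_rng(seeds["licks"])

    trials = _make_trials(cfg, sid, rng_trials)
    licks = make_lick_times(
        trials,
        tpl,
        mode=cfg.lick_mode,
        lick_rate_hz=cfg.lick_rate_hz,
        stop_latency=cfg.lick_stop_latency,
        start_latency=cfg.lick_start_latency,
        rng=rng_licks,
    )
    licks_by_trial = {k: g["time_s"].to_numpy() for k, g in licks.groupby("trial_id")}

    # epoch masks on the time grid
    torc_mask = (times >= tpl.epoch("torc")[0]) & (times < tpl.epoch("torc")[1])
    click_a, click_b = tpl.click_train
    click_mask = (times >= click_a) & (times < click_b)
    sil_mask = (times >= tpl.epoch("post_silence")[0]) & (times < tpl.epoch("post_silence")[1])

    kappa = {"passive": cfg.kappa_passive, "engaged": cfg.kappa_engaged}
    clicks_rows_t, clicks_rows_time = [], []
    sp_unit, sp_trial, sp_time = [], [], []
    unit_ids = np.array([f"{sid}_u{i:03d}" for i in range(cfg.n_units)])

    # base rate profiles per (state, stimulus, outcome-group, click rate)
    base_cache: dict[tuple, np.ndarray] = {}

    def base_profile(state, stim, outcome, rate_hz):
        key = (state, stim, outcome, rate_hz)
        if key not in base_cache:
            lam = np.repeat(
                (baselines + (cfg.delta * u if state == "engaged" else 0.0))[:, None],
                n_steps,
                axis=1,
            )
            lam[:, torc_mask] += cfg.torc_gain
            pattern = _class_patterns(cfg, u, v, state)[stim]
            kern = _vm_kernel(times[click_mask], click_a, rate_hz, kappa[state])
            lam[:, click_mask] += pattern[:, None] * kern[None, :]
            if cfg.evoked_absolute and state == "engaged":
                # absolute stimulus-driven pattern is state-invariant: the
                # baseline shift is not carried into the click-train epoch
                lam[:, click_mask] -= (cfg.delta * u)[:, None]
            if stim == "target":
                if state == "engaged":
                    amp = cfg.silence_amp_engaged if outcome == "correct" else cfg.silence_amp_passive
                else:
                    amp = cfg.silence_amp_passive
                lam[:, sil_mask] += amp * v2[:, None]
            base_cache[key] = np.clip(lam, 0.0, None)
        return base_cache[key]

    for _, tr in trials.iterrows():
        rate_hz = tr["click_rate_hz"]
        ct = _click_times(tpl, rate_hz)
        clicks_rows_t.extend([tr["trial_id"]] * len(ct))
        clicks_rows_time.extend(ct.tolist())
        lam = base_profile(tr["state"], tr["stimulus"], tr["outcome"], rate_hz)
        lt = licks_by_trial.get(tr["trial_id"])
        if lt is not None and lick_mask.any() and cfg.lick_amp > 0:
            lam = lam.copy()
            bump = np.zeros(n_steps)
            for t0 in lt:
                a = int(np.floor(t0 / cfg.dt))
                b = min(int(np.ceil((t0 + cfg.lick_kernel_width) / cfg.dt)), n_steps)
                bump[a:b] += cfg.lick_amp
            lam[lick_mask] = np.clip(lam[lick_mask] + bump[None, :], 0.0, None)
        counts = rng_spikes.poisson(lam * cfg.dt)
        ui, si = np.nonzero(counts)
        c = counts[ui, si]
        ui = np.repeat(ui, c)
        si = np.repeat(si, c)
        t = (si + rng_spikes.random(len(si))) * cfg.dt
        order = np.lexsort((t, ui))
        sp_unit.extend(unit_ids[ui[order]].tolist())
        sp_trial.extend([tr["trial_id"]] * len(ui))
        sp_time.extend(t[order].tolist())

    session = SessionData(
        session_id=sid,
        units=pd.DataFrame({"unit_id": unit_ids, "session_id": sid}),
        trials=trials,
        spikes=pd.DataFrame(
            {"unit_id": sp_unit, "trial_id": sp_trial, "time_s": np.asarray(sp_time)}
        ),
        clicks=pd.DataFrame(
            {"trial_id": clicks_rows_t, "time_s": np.asarray(clicks_rows_time, dtype=float)}
        ),
        licks=licks,
        template=tpl,
    )
    return session


def _planted_distances(cfg: GeneratorConfig, u, v) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for state in ("passive", "engaged"):
        pats = _class_patterns(cfg, u, v, state)
        w = pats["target"] - pats["reference"]
        nrm = np.linalg.norm(w)
        if nrm == 0:
            out[state] = {"reference": 0.0, "target": 0.0}
            continue
        w = w / nrm
        out[state] = {c: float(abs(pats[c] @ w)) for c in ("reference", "target")}
    return out


def generate_cohort(
    config: GeneratorConfig, seed: int
) -> tuple[list[SessionData], GroundTruth]:
    """Generate ``n_sessions`` sessions with disjoint unit ids plus pooled truth."""
    ss = np.random.SeedSequence(seed)
    n_children = len(_SUBSTREAMS) + 3 * config.n_sessions
    children = ss.spawn(n_children)
    rng_dir = np.random.default_rng(children[_SUBSTREAMS["directions"]])
    rng_base = np.random.default_rng(children[_SUBSTREAMS["baselines"]])

    n_total = config.n_units * config.n_sessions
    u, v, v2 = _draw_directions(rng_dir, n_total, config.shift_toward_reference)
    baselines = np.exp(
        config.baseline_log_mean + config.baseline_log_sd * rng_base.standard_normal(n_total)
    )
    n_lick = int(round(config.lick_fraction * n_total))
    lick_idx = rng_dir.choice(n_total, size=n_lick, replace=False) if n_lick else np.array([], int)
    lick_mask_all = np.zeros(n_total, dtype=bool)
    lick_mask_all[lick_idx] = True

    sessions = []
    all_unit_ids: list[str] = []
    for s in range(config.n_sessions):
        sid = f"s{s}"
        sl = slice(s * config.n_units, (s + 1) * config.n_units)
        seeds = {
            name: children[len(_SUBSTREAMS) + 3 * s + j]
            for j, name in enumerate(("trial_order", "spikes", "licks"))
        }
        sess = _generate_one_session(
            config, sid, baselines[sl], u[sl], v[sl], v2[sl], lick_mask_all[sl], seeds
        )
        sessions.append(sess)
        all_unit_ids.extend(sess.units["unit_id"].tolist())

    unit_ids = np.asarray(all_unit_ids)
    eng_base = baselines + config.delta * u
    pats = {st: _class_patterns(config, u, v, st) for st in ("passive", "engaged")}
    truth = GroundTruth(
        u=u,
        v=v,
        v2=v2,
        delta=config.delta,
        kappa={"passive": config.kappa_passive, "engaged": config.kappa_engaged},
        lick_unit_ids=unit_ids[lick_mask_all].tolist(),
        unit_ids=unit_ids.tolist(),
        baselines={"passive": baselines, "engaged": eng_base},
        expected_vs={
            "passive": _expected_vs(config, baselines, pats["passive"]["reference"], config.kappa_passive),
            "engaged": _expected_vs(config, eng_base, pats["engaged"]["reference"], config.kappa_engaged),
        },
        planted_distances=_planted_distances(config, u, v),
        silence_amps={
            "passive": config.silence_amp_passive,
            "engaged": config.silence_amp_engaged,
        },
    )
    return sessions, truth


def generate_session(config: GeneratorConfig, seed: int) -> tuple[SessionData, GroundTruth]:
    """Generate a single session (``n_sessions`` forced to 1)."""
    cfg = dataclasses.replace(config, n_sessions=1)
    sessions, truth = generate_cohort(cfg, seed)
    return sessions[0], truth
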