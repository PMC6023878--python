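"""Optimal-prior linear reconstruction of event signals from population rates.

A continuous event signal S(t) (clicks, or licks for the motor control) is
modelled as a linear function of lagged population activity,

    S(t) = sum_i sum_{d=0..tau} g_i(d) r_i(t + d),

fit by least squares over training trials,

    G_hat = S (sum_k R_k^T) (sum_k R_k R_k^T)^{-1},

where R_k stacks the lagged responses of every unit on trial k.  The
autocorrelation inverse is computed through an SVD truncated at a component
cap (default 70) to suppress noisy components; singular values below a
relative floor are also dropped, which makes the truncated inverse the
pseudo-inverse on rank-deficient inputs.  Reconstruction quality is
measured with leave-one-trial-out mean-squared error, one filter per
(state, stimulus) cell as in the source analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .data_model import BinnedTensor, SessionData, bin_spikes, epoch_mean_rate
from .metrics import modulation_index

__all__ = [
    "ReconstructionParams",
    "StimulusSignal",
    "LaggedFilter",
    "ReconstructionResult",
    "build_event_signal",
    "build_lagged_design",
    "fit_filter",
    "reconstruct",
    "loo_reconstruction_mse",
]

DEFAULT_RANK_CAP = 70


@dataclass(frozen=True)
class ReconstructionParams:
    """Binning, lag span and regularization settings.

    Defaults follow the source analysis: responses binned at 10 ms with a
    1 ms step, SVD component cap 70, units with spontaneous rate above
    2 spikes/s retained.  ``tau`` (s) is the lag span; the event kernel is
    a 10 ms boxcar (S = 1 for ``kernel_width`` after each event).
    """

    width: float = 0.010
    step: float = 0.001
    tau: float = 0.100
    rank_cap: int = DEFAULT_RANK_CAP
    sv_floor: float = 1e-10
    rate_floor: float = 2.0
    kernel_width: float = 0.010
    target: str = "clicks"  # or "licks"

    @property
    def tau_steps(self) -> int:
        return int(round(self.tau / self.step))


@dataclass
class StimulusSignal:
    """Per-trial sampled event signal aligned to a BinnedTensor time axis."""

    values: np.ndarray  # (n_trials, n_samples)
    trial_ids: np.ndarray
    sample_times: np.ndarray


@dataclass
class LaggedFilter:
    """Per-unit reconstruction coefficients g_i(d), d = 0..tau_steps."""

    coef: np.ndarray  # (n_units, tau_steps + 1)
    unit_ids: np.ndarray
    tau_steps: int
    rank_cap: int
    retained_rank: int = 0
    residual: float = np.nan

    @property
    def flat(self) -> np.ndarray:
        return self.coef.reshape(-1)


@dataclass
class ReconstructionResult:
    """Held-out reconstructions and their mean-squared errors."""

    per_trial: pd.DataFrame  # trial_id, state, stimulus, mse
    mean_mse: dict[tuple[str, str], float]
    reconstructions: dict = field(default_factory=dict)  # trial_id -> array
    signals: StimulusSignal | None = None

    def state_mi(self, stimulus: str) -> float:
        """MI(engaged error, passive error) for one stimulus class."""
        res = modulation_index(
            self.mean_mse[("engaged", stimulus)], self.mean_mse[("passive", stimulus)]
        )
        return res.mi


def build_event_signal(
    events: pd.DataFrame,
    trial_ids: np.ndarray,
    sample_times: np.ndarray,
    kernel_width: float = 0.010,
) -> StimulusSignal:
    """Boxcar event signal: S(t) = 1 for ``kernel_width`` s after each event."""
    by_trial = {k: g["time_s"].to_numpy() for k, g in events.groupby("trial_id")}
    vals = np.zeros((len(trial_ids), len(sample_times)))
    for k, tid in enumerate(trial_ids):
        for t0 in by_trial.get(tid, ()):  # few events per trial
            vals[k][(sample_times >= t0 - 1e-12) & (sample_times < t0 + kernel_width - 1e-12)] = 1.0
    return StimulusSignal(values=vals, trial_ids=np.asarray(trial_ids), sample_times=sample_times)


def build_lagged_design(binned: BinnedTensor, trial: int | str, tau_steps: int) -> np.ndarray:
    """Lagged design matrix R_k of shape ((tau+1)*N, T), T = n_bins - tau.

    Row (i, d), column t holds r_i(t + d); rows are unit-major blocks
    [R_1; R_2; ...], each block spanning lags 0..tau in order.
    """
    if isinstance(trial, (int, np.integer)):
        idx = int(trial)
    else:
        idx = int(np.flatnonzero(binned.trial_ids == trial)[0])
    r = binned.rates[:, idx, :]
    if r.shape[1] <= tau_steps:
        raise ValueError(
            f"trial has {r.shape[1]} samples; need more than tau_steps={tau_steps}"
        )
    win = sliding_window_view(r, tau_steps + 1, axis=1)  # (N, T, tau+1)
    return win.transpose(0, 2, 1).reshape(r.shape[0] * (tau_steps + 1), -1)


def _truncated_inverse(a: np.ndarray, rank_cap: int, sv_floor: float):
    u, s, vt = np.linalg.svd(a, hermitian=True)
    keep = s > sv_floor * (s[0] if s.size else 1.0)
    k = min(int(keep.sum()), max(rank_cap, 1))
    inv = (vt[:k].T / s[:k]) @ u[:, :k].T
    return inv, k


def fit_filter(
    designs: list[np.ndarray],
    signals: list[np.ndarray],
    unit_ids: np.ndarray,
    tau_steps: int,
    rank_cap: int = DEFAULT_RANK_CAP,
    sv_floor: float = 1e-10,
) -> LaggedFilter:
    """Least-squares lagged filter over training trials with SVD truncation."""
    if not designs:
        raise ValueError("need at least one training trial")
    d = designs[0].shape[0]
    a = np.zeros((d, d))
    b = np.zeros(d)
    for r, s in zip(designs, signals):
        a += r @ r.T
        b += np.asarray(s).ravel() @ r.T
    if not np.any(a):
        warnings.warn("all-zero responses; returning zero filter", stacklevel=2)
        coef = np.zeros((len(unit_ids), tau_steps + 1))
        return LaggedFilter(coef, np.asarray(unit_ids), tau_steps, rank_cap, 0, np.nan)
    inv, k = _truncated_inverse(a, rank_cap, sv_floor)
    g = b @ inv
    resid = 0.0
    n = 0
    for r, s in zip(designs, signals):
        e = np.asarray(s).ravel() - g @ r
        resid += float(e @ e)
        n += e.size
    return LaggedFilter(
        coef=g.reshape(len(unit_ids), tau_steps + 1),
        unit_ids=np.asarray(unit_ids),
        tau_steps=tau_steps,
        rank_cap=rank_cap,
        retained_rank=k,
        residual=resid / max(n, 1),
    )


def reconstruct(filt: LaggedFilter, design: np.ndarray) -> np.ndarray:
    """S_hat = G_hat R for one trial's lagged design."""
    flat = filt.flat
    if design.shape[0] != flat.size:
        raise ValueError(
            f"design has {design.shape[0]} rows, filter expects {flat.size}"
        )
    return flat @ design


def _spont_rate_filter(session: SessionData, binned: BinnedTensor, floor: float) -> np.ndarray:
    """Units whose pre-stimulus spontaneous rate exceeds `floor` in any state."""
    keep = np.zeros(binned.n_units, dtype=bool)
    win = session.template.epoch("pre_silence")
    for state in ("passive", "engaged"):
        tids = session.select_trials(state=state)
        if tids.size == 0:
            continue
        sub = binned.select_trials(tids)
        keep |= epoch_mean_rate(sub, win).mean(axis=1) > floor
    return keep


def loo_reconstruction_mse(
    session: SessionData,
    params: ReconstructionParams = ReconstructionParams(),
    states: tuple[str, ...] = ("passive", "engaged"),
    stimuli: tuple[str, ...] = ("reference", "target"),
) -> ReconstructionResult:
    """Leave-one-trial-out reconstruction error per (state, stimulus) cell.

    One filter is fitted per cell per session; each trial is left out in
    turn, reconstructed with the filter fitted on the remaining trials, and
    scored by mean-squared error against the event signal.
    """
    events = session.clicks if params.target == "clicks" else session.licks
    binned = bin_spikes(session, width=params.width, step=params.step)
    keep = _spont_rate_filter(session, binned, params.rate_floor)
    if not keep.any():
        raise ValueError("no unit passes the spontaneous-rate floor")
    binned = binned.select_units(binned.unit_ids[keep])
    tau = params.tau_steps
    t_sig = binned.bin_starts[: binned.n_bins - tau]

    rows = []
    recons: dict = {}
    mean_mse: dict[tuple[str, str], float] = {}
    for state in states:
        for stim in stimuli:
            tids = session.select_trials(state=state, stimulus=stim)
            if len(tids) < 2:
                raise ValueError(
                    f"cell ({state}, {stim}) has {len(tids)} trial(s); need >= 2 for LOO"
                )
            sig = build_event_signal(
                events[events["trial_id"].isin(tids)], tids, t_sig, params.kernel_width
            )
            designs = [build_lagged_design(binned, tid, tau) for tid in tids]
            # accumulate total sums once, subtract the held-out trial
            d = designs[0].shape[0]
            a_k = [r @ r.T for r in designs]
            b_k = [sig.values[j] @ r.T for j, r in enumerate(designs)]
            a_tot = np.sum(a_k, axis=0)
            b_tot = np.sum(b_k, axis=0)
            mses = []
            for j, tid in enumerate(tids):
                a = a_tot - a_k[j]
                b = b_tot - b_k[j]
                if not np.any(a):
                    warnings.warn("all-zero responses in training set", stacklevel=2)
                    g = np.zeros(d)
                else:
                    inv, _ = _truncated_inverse(a, params.rank_cap, params.sv_floor)
                    g = b @ inv
                s_hat = g @ designs[j]
                err = sig.values[j] - s_hat
                mse = float(np.mean(err**2))
                mses.append(mse)
                recons[tid] = s_hat
                rows.append((tid, state, stim, mse))
            mean_mse[(state, stim)] = float(np.mean(mses))
    return ReconstructionResult(
        per_trial=pd.DataFrame(rows, columns=["trial_id", "state", "stimulus", "mse"]),
        mean_mse=mean_mse,
        reconstructions=recons,
    )
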