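"""Projection of population activity onto decoding axes.

Trial-averaged population vectors are projected onto the unit-normalized
decoding vectors stored from cross-validation, giving a single
information-bearing dimension per axis.  With per-unit spontaneous
activity subtracted before projection, the projected spontaneous point is
0 by construction, so deviations from 0 show activity moving away from
baseline along the decoding axis.  Distances of class projections from a
baseline quantify each stimulus' contribution to decoding:

    asymmetry index            d(Targ_X) - d(Ref_X)
    target enhancement index   (d(Targ_eng) - d(Targ_pass))
                             - (d(Ref_eng)  - d(Ref_pass))

The cross-state projection fixes one (engaged) axis and attributes the
engaged asymmetry to a spontaneous-baseline shift vs a change in evoked
patterns by swapping which state supplies the evoked activity and which
supplies the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import CLASSES, DecodingResult, PopulationPool

__all__ = [
    "ProjectionTrace",
    "LatencyResult",
    "class_averages",
    "spontaneous_baseline",
    "normalized_axes",
    "uniform_axis",
    "project_on_axis",
    "distance_from_baseline",
    "asymmetry_index",
    "target_enhancement_index",
    "enhancement_index_trace",
    "cross_state_projection",
    "uniform_weight_projection",
    "latency_half_max",
]


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def class_averages(pool: PopulationPool) -> dict[str, np.ndarray]:
    """Trial-averaged population activity per class: (n_units, n_bins)."""
    return {
        c: np.concatenate([m.mean(axis=1) for m in mats], axis=0)
        for c, mats in pool.class_rates.items()
    }


def spontaneous_baseline(
    pool: PopulationPool, window: tuple[float, float] = (0.0, 0.4)
) -> np.ndarray:
    """Per-unit mean rate over the pre-stimulus silence, all trials pooled."""
    idx = pool.window_bins(window)
    parts = []
    n_sessions = len(pool.class_rates[CLASSES[0]])
    for s in range(n_sessions):
        both = np.concatenate([pool.class_rates[c][s] for c in CLASSES], axis=1)
        parts.append(both[:, :, idx].mean(axis=(1, 2)))
    return np.concatenate(parts)


def normalized_axes(weights: np.ndarray) -> np.ndarray:
    """Unit-normalize decoding vectors (rows); zero vectors stay zero."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    nrm = np.linalg.norm(w, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return w / nrm


def uniform_axis(n_units: int) -> np.ndarray:
    """The normalized all-ones readout (population-average control)."""
    return np.full((1, n_units), 1.0 / np.sqrt(n_units))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectionTrace:
    """Projections of class-averaged activity on a set of decoding axes.

    ``proj[c]`` has shape (n_axes, n_bins); ``baselines[name]`` holds the
    projected spontaneous point per axis.  In ``subtract_spontaneous`` mode
    the subtracted state's baseline projects to exactly 0.
    """

    times: np.ndarray
    proj: dict[str, np.ndarray]
    baselines: dict[str, np.ndarray]
    mode: str
    axis_provenance: dict | None = None

    def mean(self, cls: str) -> np.ndarray:
        return self.proj[cls].mean(axis=0)

    def std(self, cls: str) -> np.ndarray:
        return self.proj[cls].std(axis=0, ddof=0)


def project_on_axis(
    averages: dict[str, np.ndarray],
    weights: np.ndarray | DecodingResult,
    baseline: np.ndarray | dict[str, np.ndarray],
    times: np.ndarray,
    mode: str = "subtract_spontaneous",
    subtract_with: str | None = None,
    axis_provenance: dict | None = None,
) -> ProjectionTrace:
    """Project trial-averaged activity on unit-normalized decoding axes.

    ``averages`` maps class -> (n_units, n_bins); ``baseline`` is one
    per-unit spontaneous vector or a dict of named baselines (e.g. both
    states).  In ``subtract_spontaneous`` mode the (single or
    ``subtract_with``-named) baseline is removed from every unit before
    projection; in ``raw_with_baselines`` mode activity is projected as is
    and every named baseline is projected alongside.
    """
    if mode not in ("subtract_spontaneous", "raw_with_baselines"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(weights, DecodingResult):
        if weights.weights.shape[0] != 1:
            raise ValueError("pass a single-feature DecodingResult or a weight array")
        weights = weights.weights[0]
    axes = normalized_axes(weights)
    bases = baseline if isinstance(baseline, dict) else {"spontaneous": baseline}
    n_units = axes.shape[1]
    for c, a in averages.items():
        if a.shape[0] != n_units:
            raise ValueError(f"class {c!r} has {a.shape[0]} units, axes have {n_units}")
    if mode == "subtract_spontaneous":
        key = subtract_with or next(iter(bases))
        offset = bases[key]
        proj = {c: axes @ (a - offset[:, None]) for c, a in averages.items()}
        proj_bases = {k: axes @ (b - offset) for k, b in bases.items()}
    else:
        proj = {c: axes @ a for c, a in averages.items()}
        proj_bases = {k: axes @ b for k, b in bases.items()}
    return ProjectionTrace(
        times=np.asarray(times),
        proj=proj,
        baselines=proj_bases,
        mode=mode,
        axis_provenance=axis_provenance,
    )


def distance_from_baseline(
    trace: ProjectionTrace,
    window: tuple[float, float],
    baseline: str | None = None,
) -> dict[str, np.ndarray]:
    """|mean projection over `window` - projected baseline| per class, per axis."""
    idx = np.flatnonzero(
        (trace.times >= window[0] - 1e-12) & (trace.times < window[1] - 1e-12)
    )
    if idx.size == 0:
        raise ValueError(f"window {window} contains no samples")
    if baseline is None:
        base = 0.0 if trace.mode == "subtract_spontaneous" else next(iter(trace.baselines.values()))
    else:
        base = trace.baselines[baseline]
    return {c: np.abs(p[:, idx].mean(axis=1) - base) for c, p in trace.proj.items()}


def asymmetry_index(d_target, d_reference):
    """d(Targ) - d(Ref): positive when the target dominates the axis."""
    return np.asarray(d_target) - np.asarray(d_reference)


def target_enhancement_index(d_t_eng, d_t_pass, d_r_eng, d_r_pass):
    """(d(Targ_eng) - d(Targ_pass)) - (d(Ref_eng) - d(Ref_pass))."""
    return (np.asarray(d_t_eng) - np.asarray(d_t_pass)) - (
        np.asarray(d_r_eng) - np.asarray(d_r_pass)
    )


def enhancement_index_trace(
    averages_by_state: dict[str, dict[str, np.ndarray]],
    baselines_by_state: dict[str, np.ndarray],
    weights: np.ndarray,
) -> np.ndarray:
    """Per-bin target enhancement index, shape (n_axes, n_bins).

    Distances are taken from each state's own spontaneous baseline after
    projection on the shared axes.
    """
    axes = normalized_axes(weights)
    d = {}
    for state in ("passive", "engaged"):
        base = axes @ baselines_by_state[state]
        for c in CLASSES:
            p = axes @ averages_by_state[state][c]
            d[(state, c)] = np.abs(p - base[:, None])
    return target_enhancement_index(
        d[("engaged", "target")], d[("passive", "target")],
        d[("engaged", "reference")], d[("passive", "reference")],
    )


def cross_state_projection(
    axes_weights: np.ndarray,
    averages_by_state: dict[str, dict[str, np.ndarray]],
    baselines_by_state: dict[str, np.ndarray],
    times: np.ndarray,
    window: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Asymmetry for the three evoked-state x baseline-state cases.

    With a fixed (engaged) decoding axis: (i) passive evoked activity
    against the engaged spontaneous baseline, (ii) engaged evoked against
    passive spontaneous, (iii) engaged evoked against engaged spontaneous.
    Under a pure baseline-shift mechanism (state-invariant evoked patterns)
    case i equals case iii while case ii differs; under a pure
    evoked-change mechanism case i differs from case iii.
    Returns per-case per-axis asymmetry arrays.
    """
    for state in ("passive", "engaged"):
        if state not in averages_by_state or state not in baselines_by_state:
            raise ValueError(f"missing state {state!r}")
    cases = {
        "passive_evoked_vs_engaged_spont": ("passive", "engaged"),
        "engaged_evoked_vs_passive_spont": ("engaged", "passive"),
        "engaged_evoked_vs_engaged_spont": ("engaged", "engaged"),
    }
    out = {}
    for name, (evoked_state, base_state) in cases.items():
        trace = project_on_axis(
            averages_by_state[evoked_state],
            axes_weights,
            {k: v for k, v in baselines_by_state.items()},
            times,
            mode="raw_with_baselines",
        )
        d = distance_from_baseline(trace, window, baseline=base_state)
        out[name] = asymmetry_index(d["target"], d["reference"])
    return out


def uniform_weight_projection(
    averages_by_state: dict[str, dict[str, np.ndarray]],
    baselines_by_state: dict[str, np.ndarray],
) -> np.ndarray:
    """Target enhancement index trace with equal weight for every unit."""
    n_units = next(iter(averages_by_state["passive"].values())).shape[0]
    return enhancement_index_trace(
        averages_by_state, baselines_by_state, uniform_axis(n_units)
    )


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatencyResult:
    latency: float  # seconds relative to `onset`
    defined: bool
    half_level: float = np.nan


def _boxcar(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kern = np.ones(width)
    num = np.convolve(values, kern, mode="same")
    den = np.convolve(np.ones_like(values), kern, mode="same")
    return num / den


def latency_half_max(
    times: np.ndarray,
    values: np.ndarray,
    response_window: tuple[float, float],
    baseline_window: tuple[float, float] = (0.0, 0.4),
    onset: float = 1.65,
    smooth_bins: int = 3,
) -> LatencyResult:
    """First time the trace reaches halfway from baseline to its peak.

    The trace is boxcar-smoothed, the baseline is its mean over
    ``baseline_window``, the peak its maximum over ``response_window``, and
    the crossing is linearly interpolated between samples.  The result is
    relative to ``onset`` (click-train start by default).  A flat trace
    yields an undefined-flagged result rather than a number.
    """
    t = np.asarray(times, dtype=float)
    y = _boxcar(np.asarray(values, dtype=float), smooth_bins)
    bidx = np.flatnonzero((t >= baseline_window[0] - 1e-12) & (t < baseline_window[1] - 1e-12))
    ridx = np.flatnonzero((t >= response_window[0] - 1e-12) & (t < response_window[1] - 1e-12))
    if bidx.size == 0 or ridx.size == 0:
        raise ValueError("baseline or response window contains no samples")
    base = y[bidx].mean()
    peak = y[ridx].max()
    if not peak > base:
        return LatencyResult(latency=np.nan, defined=False)
    half = base + 0.5 * (peak - base)
    # search from the start of the response window
    start = ridx[0]
    for j in range(start, ridx[-1] + 1):
        if y[j] >= half:
            if j == 0 or y[j - 1] >= half:
                cross = t[j]
            else:
                f = (half - y[j - 1]) / (y[j] - y[j - 1])
                cross = t[j - 1] + f * (t[j] - t[j - 1])
            return LatencyResult(latency=float(cross - onset), defined=True, half_level=float(half))
    return LatencyResult(latency=np.nan, defined=False, half_level=float(half))
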