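"""Core data types for trial-structured spike data.

The trial timeline of the click-rate discrimination task is a fixed sequence
of epochs: a pre-stimulus silence, a broadband noise burst (TORC) carrying no
behavioral meaning, a periodic click train whose rate defines the stimulus
class (reference vs target), and a post-stimulus silence that contains the
behavioral response window.  All event times are expressed in seconds
relative to trial onset.

Spike, click and lick events live in a :class:`SessionData` container
(pandas DataFrames with documented columns); analyses operate on
:class:`BinnedTensor`, a units x trials x time-bins firing-rate array.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochTemplate",
    "SessionData",
    "BinnedTensor",
    "PseudoPopulationSample",
    "SchemaError",
    "read_session",
    "write_session",
    "bin_spikes",
    "epoch_mean_rate",
]

STATES = ("passive", "engaged")
STIMULI = ("reference", "target")
OUTCOMES = ("correct", "error")

_SPIKE_COLS = ["unit_id", "trial_id", "time_s"]
_TRIAL_COLS = ["trial_id", "state", "stimulus", "outcome", "click_rate_hz"]
_EVENT_COLS = ["trial_id", "time_s"]


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass(frozen=True)
class EpochTemplate:
    """Ordered, contiguous trial epochs plus named analysis windows.

    Defaults follow the click-rate task: 0.4 s silence, 1.25 s TORC,
    0.75 s click train, 0.8 s post-stimulus silence (the final 0.4 s of
    which is the no-go response window).  Analysis windows are the
    sound (1.7-2.0 s) and silence (2.5-2.8 s) decoding windows and the
    equal-duration early/late sound periods used for temporal
    generalization.
    """

    epochs: tuple[tuple[str, float, float], ...] = (
        ("pre_silence", 0.0, 0.4),
        ("torc", 0.4, 1.65),
        ("click_train", 1.65, 2.4),
        ("post_silence", 2.4, 3.2),
    )
    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sound_window": (1.7, 2.0),
            "silence_window": (2.5, 2.8),
            "early_sound": (1.7, 1.9),
            "late_sound": (2.2, 2.4),
            "response_window": (2.8, 3.2),
        }
    )

    def __post_init__(self) -> None:
        allowed = {"pre_silence", "torc", "click_train", "post_silence", "response_window"}
        prev_end = None
        for label, start, end in self.epochs:
            if label not in allowed:
                raise ValueError(f"unknown epoch label {label!r}")
            if not end > start:
                raise ValueError(f"epoch {label!r} is empty or reversed")
            if prev_end is not None and not np.isclose(start, prev_end):
                raise ValueError(f"epoch {label!r} not contiguous with previous epoch")
            prev_end = end
        span = self.trial_span
        for name, (a, b) in self.windows.items():
            if not (0.0 <= a < b <= span + 1e-12):
                raise ValueError(f"window {name!r}=({a},{b}) outside trial span [0,{span}]")

    @property
    def trial_span(self) -> float:
        return self.epochs[-1][2]

    def epoch(self, label: str) -> tuple[float, float]:
        for lab, a, b in self.epochs:
            if lab == label:
                return (a, b)
        raise KeyError(label)

    @property
    def click_train(self) -> tuple[float, float]:
        return self.epoch("click_train")

    def to_dict(self) -> dict:
        return {
            "epochs": [[lab, a, b] for lab, a, b in self.epochs],
            "windows": {k: list(v) for k, v in self.windows.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EpochTemplate":
        return cls(
            epochs=tuple((str(l), float(a), float(b)) for l, a, b in d["epochs"]),
            windows={str(k): (float(v[0]), float(v[1])) for k, v in d["windows"].items()},
        )


@dataclass
class SessionData:
    """One recording session: unit/trial registries and event tables.

    Attributes
    ----------
    session_id : str
    units : DataFrame with columns ``unit_id``, ``session_id``.
    trials : DataFrame with columns ``trial_id``, ``state``, ``stimulus``,
        ``outcome``, ``click_rate_hz``.
    spikes, clicks, licks : event DataFrames (``unit_id`` only in spikes),
        times in seconds from trial onset.
    template : EpochTemplate describing the trial timeline.
    """

    session_id: str
    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    clicks: pd.DataFrame
    licks: pd.DataFrame
    template: EpochTemplate = field(default_factory=EpochTemplate)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for df, cols, name in [
            (self.spikes, _SPIKE_COLS, "spikes"),
            (self.trials, _TRIAL_COLS, "trials"),
            (self.clicks, _EVENT_COLS, "clicks"),
            (self.licks, _EVENT_COLS, "licks"),
        ]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s) {missing}")
        span = self.template.trial_span
        trial_ids = set(self.trials["trial_id"])
        unit_ids = set(self.units["unit_id"])
        for name, df in [("spikes", self.spikes), ("clicks", self.clicks), ("licks", self.licks)]:
            t = df["time_s"].to_numpy(dtype=float)
            bad = np.flatnonzero((t < 0) | (t >= span))
            if bad.size:
                raise SchemaError(
                    f"{name} row {int(bad[0])}: time {t[bad[0]]:g} s outside [0, {span:g})"
                )
            unknown = ~df["trial_id"].isin(trial_ids).to_numpy()
            if unknown.any():
                row = int(np.flatnonzero(unknown)[0])
                raise SchemaError(f"{name} row {row}: unknown trial_id {df['trial_id'].iloc[row]!r}")
        unknown_u = ~self.spikes["unit_id"].isin(unit_ids).to_numpy()
        if unknown_u.any():
            row = int(np.flatnonzero(unknown_u)[0])
            raise SchemaError(f"spikes row {row}: unknown unit_id {self.spikes['unit_id'].iloc[row]!r}")
        for col, allowed in [("state", STATES), ("stimulus", STIMULI), ("outcome", OUTCOMES)]:
            bad = ~self.trials[col].isin(allowed).to_numpy()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise SchemaError(
                    f"trials row {row}: {col}={self.trials[col].iloc[row]!r} not in {allowed}"
                )
        a, b = self.template.click_train
        ct = self.clicks["time_s"].to_numpy(dtype=float)
        bad = np.flatnonzero((ct < a) | (ct >= b))
        if bad.size:
            raise SchemaError(
                f"clicks row {int(bad[0])}: time {ct[bad[0]]:g} s outside click_train [{a:g}, {b:g})"
            )

    # -- convenience -----------------------------------------------------
    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    def select_trials(
        self,
        state: str | None = None,
        stimulus: str | None = None,
        outcome: str | None = None,
    ) -> np.ndarray:
        """Trial ids matching the given labels (None = no constraint)."""
        m = np.ones(len(self.trials), dtype=bool)
        if state is not None:
            m &= (self.trials["state"] == state).to_numpy()
        if stimulus is not None:
            m &= (self.trials["stimulus"] == stimulus).to_numpy()
        if outcome is not None:
            m &= (self.trials["outcome"] == outcome).to_numpy()
        return self.trials.loc[m, "trial_id"].to_numpy()

    def subset_units(self, keep: Sequence) -> "SessionData":
        """A copy restricted to the given unit ids."""
        keep = set(keep)
        return SessionData(
            session_id=self.session_id,
            units=self.units[self.units["unit_id"].isin(keep)].reset_index(drop=True),
            trials=self.trials.copy(),
            spikes=self.spikes[self.spikes["unit_id"].isin(keep)].reset_index(drop=True),
            clicks=self.clicks.copy(),
            licks=self.licks.copy(),
            template=self.template,
        )

    def equals(self, other: "SessionData", atol: float = 1e-9) -> bool:
        """Equality up to `atol` on event times (for round-trip checks)."""
        if self.session_id != other.session_id:
            return False
        if not self.trials.reset_index(drop=True).equals(other.trials.reset_index(drop=True)):
            return False
        for a, b in [(self.spikes, other.spikes), (self.clicks, other.clicks), (self.licks, other.licks)]:
            if len(a) != len(b):
                return False
            for col in a.columns:
                if col == "time_s":
                    if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float), atol=atol):
                        return False
                else:
                    if not (a[col].to_numpy() == b[col].to_numpy()).all():
                        return False
        return True


@dataclass
class BinnedTensor:
    """units x trials x bins firing-rate array (spikes/s).

    Bins are half-open ``[start, start+width)`` labelled by their start
    time; a spike exactly on a boundary is counted in the later bin.
    ``step`` may be smaller than ``width`` (overlapping bins).
    """

    rates: np.ndarray  # (n_units, n_trials, n_bins)
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    bin_starts: np.ndarray
    width: float
    step: float
    session_id: str = ""

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def window_bins(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of bins whose *start* lies in [window[0], window[1])."""
        a, b = window
        return np.flatnonzero((self.bin_starts >= a - 1e-12) & (self.bin_starts < b - 1e-12))

    def select_trials(self, trial_ids: Sequence) -> "BinnedTensor":
        idx = _index_of(self.trial_ids, np.asarray(trial_ids))
        return dataclasses.replace(
            self, rates=self.rates[:, idx, :], trial_ids=self.trial_ids[idx]
        )

    def select_units(self, unit_ids: Sequence) -> "BinnedTensor":
        idx = _index_of(self.unit_ids, np.asarray(unit_ids))
        return dataclasses.replace(
            self, rates=self.rates[idx, :, :], unit_ids=self.unit_ids[idx]
        )


@dataclass
class PseudoPopulationSample:
    """Pseudo-trial population vectors with balanced class labels.

    Each unit's trials are drawn independently, so noise correlations
    between simultaneously recorded units are destroyed by construction.
    """

    vectors: np.ndarray  # (n_pseudo_trials, n_units)
    labels: np.ndarray  # (n_pseudo_trials,) values in {0 reference, 1 target}
    seed: int | None = None
    source_trials: np.ndarray | None = None  # (n_pseudo_trials, n_units)

    def __post_init__(self) -> None:
        n0 = int(np.sum(self.labels == 0))
        n1 = int(np.sum(self.labels == 1))
        if n0 != n1:
            raise ValueError(f"class counts unbalanced: {n0} reference vs {n1} target")


def _index_of(haystack: np.ndarray, needles: np.ndarray) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(haystack.tolist())}
    try:
        return np.array([lookup[v] for v in needles.tolist()], dtype=int)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"id {e.args[0]!r} not present") from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_session(session: SessionData, outdir: str | Path) -> dict[str, Path]:
    """Write the four CSV tables (UTF-8, comma-separated, header row)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("spikes", session.spikes),
        ("trials", session.trials),
        ("clicks", session.clicks),
        ("licks", session.licks),
        ("units", session.units),
    ]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    return paths


def read_session(
    paths: Mapping[str, str | Path] | str | Path,
    template: EpochTemplate | None = None,
    session_id: str = "session0",
) -> SessionData:
    """Read and validate a session from CSV tables.

    ``paths`` is either a directory containing spikes/trials/clicks/licks.csv
    or a mapping from those names to file paths.  Rows violating the schema
    (missing column, out-of-range time, unknown label) are rejected with the
    offending row number.
    """
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        paths = {n: d / f"{n}.csv" for n in ("spikes", "trials", "clicks", "licks", "units")}
    frames = {}
    for name in ("spikes", "trials", "clicks", "licks"):
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(p)
        frames[name] = pd.read_csv(p)
    frames["trials"]["click_rate_hz"] = frames["trials"]["click_rate_hz"].astype(float)
    units_path = Path(paths["units"]) if "units" in paths else None
    if units_path is not None and units_path.exists():
        units = pd.read_csv(units_path)
    else:  # fall back to units observed in the spike table
        units = pd.DataFrame(
            {
                "unit_id": np.sort(frames["spikes"]["unit_id"].unique()),
                "session_id": session_id,
            }
        )
    return SessionData(
        session_id=session_id,
        units=units,
        trials=frames["trials"],
        spikes=frames["spikes"],
        clicks=frames["clicks"],
        licks=frames["licks"],
        template=template or EpochTemplate(),
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_count(span: float, width: float, step: float) -> int:
    return int(np.floor((span - width) / step + 1e-9)) + 1


def bin_spikes(
    session: SessionData,
    width: float,
    step: float | None = None,
    trial_ids: Sequence | None = None,
    unit_ids: Sequence | None = None,
) -> BinnedTensor:
    """Bin spike events into a units x trials x bins rate tensor.

    ``rates[i, k, t]`` is the spike count of unit *i* on trial *k* inside
    the half-open bin ``[start_t, start_t + width)`` divided by ``width``.
    ``step < width`` produces overlapping bins.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    step = width if step is None else step
    if step <= 0:
        raise ValueError("step must be > 0")
    span = session.template.trial_span
    if width > span:
        raise ValueError(f"width {width} exceeds trial span {span}")
    units = np.asarray(unit_ids if unit_ids is not None else session.unit_ids)
    trials = np.asarray(trial_ids if trial_ids is not None else session.trials["trial_id"].to_numpy())
    n_bins = bin_count(span, width, step)
    starts = np.arange(n_bins) * step
    uidx = {v: i for i, v in enumerate(units.tolist())}
    tidx = {v: i for i, v in enumerate(trials.tolist())}
    sp = session.spikes
    keep = sp["unit_id"].isin(uidx).to_numpy() & sp["trial_id"].isin(tidx).to_numpy()
    ui = np.fromiter((uidx[v] for v in sp.loc[keep, "unit_id"]), dtype=int, count=int(keep.sum()))
    ti = np.fromiter((tidx[v] for v in sp.loc[keep, "trial_id"]), dtype=int, count=int(keep.sum()))
    t = sp.loc[keep, "time_s"].to_numpy(dtype=float)

    counts = np.zeros((len(units), len(trials), n_bins), dtype=float)
    if step == width:
        # non-overlapping: each spike falls in exactly one bin
        b = np.floor(t / width + 1e-9).astype(int)
        ok = b < n_bins
        np.add.at(counts, (ui[ok], ti[ok], b[ok]), 1.0)
    else:
        # overlapping bins: spike at t lies in bin b iff b*step <= t < b*step+width;
        # the +1e-9 nudge enforces the half-open convention on exact boundaries
        lo = np.ceil((t - width) / step + 1e-9).astype(int)
        hi = np.floor(t / step + 1e-9).astype(int)
        for s_ui, s_ti, s_lo, s_hi in zip(ui, ti, np.maximum(lo, 0), np.minimum(hi, n_bins - 1)):
            if s_hi >= s_lo:
                counts[s_ui, s_ti, s_lo : s_hi + 1] += 1.0
    return BinnedTensor(
        rates=counts / width,
        unit_ids=units,
        trial_ids=trials,
        bin_starts=starts,
        width=width,
        step=step,
        session_id=session.session_id,
    )


def epoch_mean_rate(
    binned: BinnedTensor,
    window: tuple[float, float],
    baseline_correct: bool = False,
    baseline_window: tuple[float, float] = (0.0, 0.4),
) -> np.ndarray:
    """Per-unit per-trial mean rate over bins whose start lies in `window`.

    With ``baseline_correct`` the unit's mean rate over ``baseline_window``
    (default: the pre-stimulus silence) is subtracted per trial.
    """
    idx = binned.window_bins(window)
    if idx.size == 0:
        raise ValueError(f"window {window} contains no bins")
    out = binned.rates[:, :, idx].mean(axis=2)
    if baseline_correct:
        bidx = binned.window_bins(baseline_window)
        if bidx.size == 0:
            raise ValueError(f"baseline window {baseline_window} contains no bins")
        out = out - binned.rates[:, :, bidx].mean(axis=2)
    return out
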