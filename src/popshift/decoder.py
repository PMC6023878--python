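"""Prototype-based linear classification of reference vs target trials.

The classifier mimics a downstream readout neuron: at each time bin the
decoding vector is the difference of class-mean pseudo-population vectors,

    w_t = c_T,t - c_R,t,      b_t = -((c_R,t + c_T,t) . w_t) / 2,

and a population vector x is called a target iff y(x) = w_t . x + b_t > 0
(ties go to reference).  Pseudo-population vectors are assembled by drawing
each unit's trials independently across sessions, which destroys noise
correlations by construction.  Cross-validation redraws balanced train
(default 15 per class) and test sets, 400 times by default, so p values
estimated from the resampling distribution are bounded below by 1/400.
Chance level is calibrated by shuffling trial labels (default 100
permutations x 100 cross-validations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import BinnedTensor, PseudoPopulationSample, SessionData, bin_spikes

__all__ = [
    "LinearDecoder",
    "DecodingResult",
    "NullDistribution",
    "PopulationPool",
    "build_pool",
    "fit_prototype_decoder",
    "classify",
    "decision_values",
    "assemble_pseudo_population",
    "cross_validated_accuracy",
    "shuffled_null",
    "temporal_generalization",
    "decode_transfer",
    "empirical_p",
]

CLASSES = ("reference", "target")
DEFAULT_N_TRAIN = 15
DEFAULT_N_RESAMPLES = 400
DEFAULT_N_PERM = 100
DEFAULT_N_CV = 100


# ---------------------------------------------------------------------------
# decoder primitives
# ---------------------------------------------------------------------------

@dataclass
class LinearDecoder:
    """Per-bin decoding vector and bias with training provenance."""

    w: np.ndarray
    b: float
    unit_ids: np.ndarray | None = None
    training_window: tuple[float, float] | None = None
    training_state: str | None = None
    seed: int | None = None
    degenerate: bool = False


def fit_prototype_decoder(
    train_reference: np.ndarray, train_target: np.ndarray, **provenance
) -> LinearDecoder:
    """Decoder from class-mean prototypes of the training pseudo-trials."""
    ref = np.atleast_2d(np.asarray(train_reference, dtype=float))
    targ = np.atleast_2d(np.asarray(train_target, dtype=float))
    if ref.shape[0] < 1 or targ.shape[0] < 1:
        raise ValueError("need at least one training pseudo-trial per class")
    c_r = ref.mean(axis=0)
    c_t = targ.mean(axis=0)
    w = c_t - c_r
    b = -float((c_r + c_t) @ w) / 2.0
    return LinearDecoder(w=w, b=b, degenerate=bool(not np.any(w)), **provenance)


def decision_values(decoder: LinearDecoder, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != decoder.w.size:
        raise ValueError(f"dimension mismatch: x has {x.shape[1]}, decoder {decoder.w.size}")
    return x @ decoder.w + decoder.b


def classify(decoder: LinearDecoder, x: np.ndarray) -> np.ndarray:
    """1 = target where y(x) > 0; 0 = reference otherwise (tie -> reference)."""
    return (decision_values(decoder, x) > 0).astype(int)


# ---------------------------------------------------------------------------
# pooled pseudo-population data
# ---------------------------------------------------------------------------

@dataclass
class PopulationPool:
    """Per-class, per-session trial-rate tensors for one behavioral state."""

    class_rates: dict[str, list[np.ndarray]]  # class -> [(n_units_s, n_trials_s, n_bins)]
    unit_ids: np.ndarray
    bin_starts: np.ndarray
    width: float
    step: float
    state: str | None = None
    _feature_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_units(self) -> int:
        return int(self.unit_ids.size)

    @property
    def n_bins(self) -> int:
        return int(self.bin_starts.size)

    def window_bins(self, window: tuple[float, float]) -> np.ndarray:
        a, b = window
        idx = np.flatnonzero((self.bin_starts >= a - 1e-12) & (self.bin_starts < b - 1e-12))
        if idx.size == 0:
            raise ValueError(f"window {window} contains no bins")
        return idx

    def min_trials(self, cls: str) -> int:
        return min(m.shape[1] for m in self.class_rates[cls])

    def feature_matrices(self, feature: tuple[int, ...]) -> dict[str, list[np.ndarray]]:
        """Per-class (n_units_s, n_trials_s) rates averaged over `feature` bins."""
        key = tuple(int(i) for i in feature)
        if key not in self._feature_cache:
            idx = np.asarray(key, dtype=int)
            self._feature_cache[key] = {
                c: [m[:, :, idx].mean(axis=2) for m in mats]
                for c, mats in self.class_rates.items()
            }
        return self._feature_cache[key]


def build_pool(
    sessions: Sequence[SessionData],
    state: str,
    width: float = 0.1,
    step: float | None = None,
    outcome: str | Mapping[str, str] | None = None,
    unit_subset: Sequence | None = None,
    min_trials: int = 2,
) -> PopulationPool:
    """Bin each session and pool per-class trial tensors across sessions.

    ``outcome`` may be a single label or a per-class mapping (e.g. target
    trials restricted to errors for the correct-to-error transfer test).
    Sessions lacking ``min_trials`` trials for some class are dropped with
    a warning rather than failing the run.
    """
    per_class: dict[str, list[np.ndarray]] = {c: [] for c in CLASSES}
    unit_ids: list = []
    keep_set = set(unit_subset) if unit_subset is not None else None
    for sess in sessions:
        units = [u for u in sess.unit_ids if keep_set is None or u in keep_set]
        if not units:
            continue
        trial_sets = {}
        for c in CLASSES:
            oc = outcome[c] if isinstance(outcome, Mapping) else outcome
            trial_sets[c] = sess.select_trials(state=state, stimulus=c, outcome=oc)
        if any(len(t) < min_trials for t in trial_sets.values()):
            warnings.warn(
                f"session {sess.session_id}: fewer than {min_trials} trials in some class; "
                "units dropped from the pseudo-population",
                stacklevel=2,
            )
            continue
        binned = bin_spikes(sess, width=width, step=step, unit_ids=units)
        for c in CLASSES:
            per_class[c].append(binned.select_trials(trial_sets[c]).rates)
        unit_ids.extend(units)
        bin_starts = binned.bin_starts
    if not unit_ids:
        raise ValueError("no usable sessions/units for the pool")
    return PopulationPool(
        class_rates=per_class,
        unit_ids=np.asarray(unit_ids),
        bin_starts=bin_starts,
        width=width,
        step=step if step is not None else width,
        state=state,
    )


def as_features(
    pool: PopulationPool,
    bins: Sequence[int] | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
) -> list[tuple[int, ...]]:
    """Normalize a bin list or window list to per-feature bin-index tuples."""
    if (bins is None) == (windows is None):
        raise ValueError("specify exactly one of bins or windows")
    if bins is not None:
        return [(int(b),) for b in bins]
    return [tuple(int(i) for i in pool.window_bins(w)) for w in windows]


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _draw_split(pool: PopulationPool, rng: np.random.Generator) -> dict[str, list[np.ndarray]]:
    """Independent per-unit trial permutations for each class and session."""
    out = {}
    for c, mats in pool.class_rates.items():
        out[c] = [np.argsort(rng.random((m.shape[0], m.shape[1])), axis=1) for m in mats]
    return out


def _gather(
    feats: dict[str, list[np.ndarray]],
    split: dict[str, list[np.ndarray]],
    cls: str,
    cols: slice,
) -> np.ndarray:
    """Pseudo-trial vectors (n_pseudo, n_units) from permuted trial columns."""
    parts = []
    for f, idx in zip(feats[cls], split[cls]):
        take = idx[:, cols]
        parts.append(np.take_along_axis(f, take, axis=1))
    return np.vstack(parts).T


def _max_test(pool: PopulationPool, n_train: int) -> int:
    return min(pool.min_trials(c) for c in CLASSES) - n_train


def assemble_pseudo_population(
    pool: PopulationPool,
    feature: tuple[int, ...] | int,
    n_train: int = DEFAULT_N_TRAIN,
    seed: int | np.random.Generator | None = None,
    n_test: int | None = None,
) -> tuple[PseudoPopulationSample, PseudoPopulationSample]:
    """Balanced (train, test) pseudo-population samples for one feature.

    Every unit contributes ``n_train`` independently drawn trials per class
    to the training set; the test set is balanced from the remaining trials
    (all of them by default).
    """
    if isinstance(feature, (int, np.integer)):
        feature = (int(feature),)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_test = _max_test(pool, n_train)
    if max_test < 1:
        raise ValueError(
            f"insufficient trials: need at least {n_train + 1} per class per unit"
        )
    n_test = max_test if n_test is None else min(n_test, max_test)
    feats = pool.feature_matrices(feature)
    split = _draw_split(pool, rng)
    tr = [_gather(feats, split, c, slice(0, n_train)) for c in CLASSES]
    te = [_gather(feats, split, c, slice(n_train, n_train + n_test)) for c in CLASSES]
    mk = lambda parts: PseudoPopulationSample(
        vectors=np.vstack(parts),
        labels=np.concatenate([np.zeros(len(parts[0]), int), np.ones(len(parts[1]), int)]),
    )
    return mk(tr), mk(te)


# ---------------------------------------------------------------------------
# cross-validated decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Per-feature accuracy distribution over resamples, decoders retained."""

    features: list[tuple[int, ...]]
    feature_times: np.ndarray  # mean bin-start time of each feature
    accuracies: np.ndarray  # (n_features, n_resamples)
    weights: np.ndarray  # (n_features, n_resamples, n_units)
    biases: np.ndarray  # (n_features, n_resamples)
    unit_ids: np.ndarray
    n_train: int
    seed: int | None

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def std(self) -> np.ndarray:
        return self.accuracies.std(axis=1, ddof=0)

    @property
    def ci95(self) -> np.ndarray:
        if self.accuracies.shape[1] < 2:
            return np.full((2, self.accuracies.shape[0]), np.nan)
        return np.percentile(self.accuracies, [2.5, 97.5], axis=1)


def _feature_rng(seed: int | None, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=0 if seed is None else seed, spawn_key=(index,)))


def _cv_accuracy_one_feature(
    pool: PopulationPool,
    feature: tuple[int, ...],
    rng: np.random.Generator,
    n_train: int,
    n_resamples: int,
    n_test: int,
    test_features: Sequence[tuple[int, ...]] | None = None,
    test_pool: PopulationPool | None = None,
):
    """Accuracies and decoders for one training feature.

    When ``test_features`` is given, each resample's decoder (trained on
    ``feature``) is also tested on every test feature (temporal
    generalization); when ``test_pool`` is given, test vectors come from it
    instead of held-out trials (correct-to-error transfer).
    """
    feats = pool.feature_matrices(feature)
    tfs = list(test_features) if test_features is not None else [feature]
    acc = np.zeros((len(tfs), n_resamples))
    w_store = np.zeros((n_resamples, pool.n_units))
    b_store = np.zeros(n_resamples)
    for r in range(n_resamples):
        split = _draw_split(pool, rng)
        c_r = _gather(feats, split, "reference", slice(0, n_train)).mean(axis=0)
        c_t = _gather(feats, split, "target", slice(0, n_train)).mean(axis=0)
        w = c_t - c_r
        b = -float((c_r + c_t) @ w) / 2.0
        w_store[r] = w
        b_store[r] = b
        for fi, tf in enumerate(tfs):
            if test_pool is not None:
                t_feats = test_pool.feature_matrices(tf)
                t_split = _draw_split(test_pool, rng)
                nt = min(test_pool.min_trials(c) for c in CLASSES)
                ref = _gather(t_feats, t_split, "reference", slice(0, nt))
                targ = _gather(t_feats, t_split, "target", slice(0, nt))
            else:
                t_feats = pool.feature_matrices(tf)
                ref = _gather(t_feats, split, "reference", slice(n_train, n_train + n_test))
                targ = _gather(t_feats, split, "target", slice(n_train, n_train + n_test))
            y_ref = ref @ w + b
            y_targ = targ @ w + b
            acc[fi, r] = 0.5 * (np.mean(y_ref <= 0) + np.mean(y_targ > 0))
    return acc, w_store, b_store


def cross_validated_accuracy(
    pool: PopulationPool,
    bins: Sequence[int] | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
    n_train: int = DEFAULT_N_TRAIN,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
    n_test: int | None = None,
    features: list[tuple[int, ...]] | None = None,
) -> DecodingResult:
    """Balanced cross-validated accuracy per feature over resamples.

    Both training and test sets are redrawn on every resample.  With a
    single resample only the mean is meaningful (a warning is issued).
    """
    if features is None:
        features = as_features(pool, bins=bins, windows=windows)
    if n_resamples < 2:
        warnings.warn("n_resamples < 2: no spread/CI available", stacklevel=2)
    max_test = _max_test(pool, n_train)
    if max_test < 1:
        raise ValueError(f"insufficient trials: need at least {n_train + 1} per class per unit")
    n_test = max_test if n_test is None else min(n_test, max_test)
    accs, ws, bs = [], [], []
    for fi, feature in enumerate(features):
        rng = _feature_rng(seed, fi)
        a, w, b = _cv_accuracy_one_feature(pool, feature, rng, n_train, n_resamples, n_test)
        accs.append(a[0])
        ws.append(w)
        bs.append(b)
    return DecodingResult(
        features=features,
        feature_times=np.array([pool.bin_starts[list(f)].mean() for f in features]),
        accuracies=np.asarray(accs),
        weights=np.asarray(ws),
        biases=np.asarray(bs),
        unit_ids=pool.unit_ids,
        n_train=n_train,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Label-shuffled accuracy distribution per feature."""

    features: list[tuple[int, ...]]
    null_accuracies: np.ndarray  # (n_features, n_perm)
    n_perm: int
    n_cv: int

    @property
    def mean(self) -> np.ndarray:
        return self.null_accuracies.mean(axis=1)

    @property
    def ci95(self) -> np.ndarray:
        return np.percentile(self.null_accuracies, [2.5, 97.5], axis=1)

    def p_value(self, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Add-one-corrected empirical p plus the raw exceedance count."""
        obs = np.asarray(observed, dtype=float).reshape(-1, 1)
        count = (self.null_accuracies >= obs).sum(axis=1)
        return (1.0 + count) / (1.0 + self.n_perm), count


def empirical_p(null: np.ndarray, observed: float) -> float:
    """(1 + #{null >= observed}) / (1 + n) — never below 1/(n+1)."""
    null = np.asarray(null, dtype=float)
    return float((1 + int(np.sum(null >= observed))) / (1 + null.size))


def _shuffle_pool_labels(pool: PopulationPool, rng: np.random.Generator) -> PopulationPool:
    """Permute class labels of trials within each session (all units alike)."""
    new: dict[str, list[np.ndarray]] = {c: [] for c in CLASSES}
    n_sessions = len(pool.class_rates[CLASSES[0]])
    for s in range(n_sessions):
        ref = pool.class_rates["reference"][s]
        targ = pool.class_rates["target"][s]
        both = np.concatenate([ref, targ], axis=1)
        perm = rng.permutation(both.shape[1])
        new["reference"].append(both[:, perm[: ref.shape[1]], :])
        new["target"].append(both[:, perm[ref.shape[1] :], :])
    return PopulationPool(
        class_rates=new,
        unit_ids=pool.unit_ids,
        bin_starts=pool.bin_starts,
        width=pool.width,
        step=pool.step,
        state=pool.state,
    )


def shuffled_null(
    pool: PopulationPool,
    bins: Sequence[int] | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    n_cv: int = DEFAULT_N_CV,
    n_train: int = DEFAULT_N_TRAIN,
    seed: int | None = None,
) -> NullDistribution:
    """Chance-level accuracy from label-shuffled surrogate datasets."""
    features = as_features(pool, bins=bins, windows=windows)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=0 if seed is None else seed, spawn_key=(999,)))
    null = np.zeros((len(features), n_perm))
    for p in range(n_perm):
        shuffled = _shuffle_pool_labels(pool, rng)
        res = cross_validated_accuracy(
            shuffled,
            features=features,
            n_train=n_train,
            n_resamples=n_cv,
            seed=int(rng.integers(2**31)),
        )
        null[:, p] = res.mean
    return NullDistribution(features=features, null_accuracies=null, n_perm=n_perm, n_cv=n_cv)


# ---------------------------------------------------------------------------
# temporal generalization and transfer
# ---------------------------------------------------------------------------

def temporal_generalization(
    pool: PopulationPool,
    train_windows: Sequence[tuple[float, float]],
    test_bins: Sequence[int] | None = None,
    test_windows: Sequence[tuple[float, float]] | None = None,
    n_train: int = DEFAULT_N_TRAIN,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
) -> np.ndarray:
    """Mean accuracy matrix: train windows x test features.

    A cell whose test feature equals its training window reproduces the
    within-window cross-validated accuracy (identical resamples).
    """
    test_features = as_features(pool, bins=test_bins, windows=test_windows)
    max_test = _max_test(pool, n_train)
    if max_test < 1:
        raise ValueError(f"insufficient trials: need at least {n_train + 1} per class per unit")
    out = np.zeros((len(train_windows), len(test_features)))
    for wi, win in enumerate(train_windows):
        feature = tuple(int(i) for i in pool.window_bins(win))
        rng = _feature_rng(seed, wi)
        acc, _, _ = _cv_accuracy_one_feature(
            pool, feature, rng, n_train, n_resamples, max_test, test_features=test_features
        )
        out[wi] = acc.mean(axis=1)
    return out


def decode_transfer(
    train_pool: PopulationPool,
    test_pool: PopulationPool,
    bins: Sequence[int] | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
    n_train: int = DEFAULT_N_TRAIN,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
) -> np.ndarray:
    """Mean accuracy of decoders trained on `train_pool` applied to `test_pool`.

    Used for the correct-to-error transfer: train on engaged correct trials
    and test on pseudo-populations built from error trials.
    """
    features = as_features(train_pool, bins=bins, windows=windows)
    if min(test_pool.min_trials(c) for c in CLASSES) < 1:
        raise ValueError("test pool has no trials in some class")
    max_test = _max_test(train_pool, n_train)
    if max_test < 1:
        raise ValueError(f"insufficient trials: need at least {n_train + 1} per class per unit")
    out = np.zeros(len(features))
    for fi, feature in enumerate(features):
        rng = _feature_rng(seed, fi)
        acc, _, _ = _cv_accuracy_one_feature(
            train_pool,
            feature,
            rng,
            n_train,
            n_resamples,
            max_test,
            test_features=[feature],
            test_pool=test_pool,
        )
        out[fi] = acc.mean()
    return out
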