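# Methods

## Trial model and data containers

A trial spans 3.2 s: pre-stimulus silence [0, 0.4), a neutral broadband
noise (TORC) [0.4, 1.65), a periodic click train [1.65, 2.4) whose rate
defines the stimulus class, and post-stimulus silence [2.4, 3.2) whose
final 0.4 s is the behavioral response window. Analysis windows are the
sound window [1.7, 2.0), the silence window [2.5, 2.8), and equal-duration
early/late sound windows [1.7, 1.9) and [2.2, 2.4) for temporal
generalization. All events are seconds from trial onset.

Spikes are binned into rate tensors (spikes/s, counts divided by the bin
width). Bins are half-open `[start, start+width)` and labelled by their
start; a spike exactly on a boundary goes to the later bin — a pure
tie-break chosen for determinism. Decoding uses 100 ms non-overlapping
bins; reconstruction uses 10 ms bins at a 1 ms step (overlapping bins are
supported generally). Whether decoding bins should overlap was an open
choice; non-overlapping bins were adopted as the default because the
per-bin decoders are estimated and reported independently.

## Single-unit metrics

Vector strength is the resultant length of spike phases relative to the
click period, `r = |Σ_j e^{iθ_j}|/n` with
`θ_j = 2π((t_j − onset) mod P)/P`; 1 means fully locked, 0 unlocked.
Significance is Rayleigh's statistic `p = exp(−n r²)` at the p < 0.001
criterion. VS is computed over the whole click-train epoch, separately per
state and stimulus class, and only for units firing above 1 spike/s there;
a unit with no spikes yields an undefined-flagged result, never r = 0.

The modulation index `MI = (X₁−X₂)/(X₁+X₂)` is used with the fixed
argument order (engaged, passive) throughout, so MI > 0 always reads
"larger when engaged". The behavioral discrimination ratio is
`DR = HR·(1−FA)`.

## Stimulus reconstruction

A linear mapping from lagged population rates to a continuous event
signal, `S(t) = Σ_i Σ_{δ=0..τ} g_i(δ) r_i(t+δ)`, is fitted by least
squares over training trials: `Ĝ = S (Σ_k R_kᵀ)(Σ_k R_k R_kᵀ)⁻¹`, where
R_k stacks each unit's lag rows. The autocorrelation inverse goes through
an SVD truncated at 70 components (per fitted filter); singular values
below 1e-10 of the largest are also dropped, making the fit the minimum
norm (pseudo-inverse) solution on rank-deficient designs. Units must
exceed a 2 spikes/s spontaneous rate to enter. One filter is fitted per
(state, stimulus) cell per session and every trial is left out in turn;
error is the held-out mean-squared error.

Choices the method leaves open, fixed here: the lag span τ defaults to
100 ms (covers click-response latencies; configurable); the event signal
is a 10 ms boxcar after each click or lick (matches the response bin
width); there is no intercept, so signals are reconstructed about zero.

## Population decoding

Pseudo-population vectors pool units across sessions by drawing each
unit's trials independently, which destroys noise correlations by
construction. Per time bin, the prototype decoder is
`w_t = c_{T,t} − c_{R,t}` and `b_t = −((c_{R,t}+c_{T,t})·w_t)/2`; a vector
is a target iff `y = w·x + b > 0`, with the measure-zero tie y = 0 sent to
reference for determinism. Training draws 15 trials per class per unit;
the test set is all remaining trials, balanced. Both sets are redrawn on
each of 400 resamples, so resampling-based p values are floored at
1/400 = 0.0025. Chance is calibrated by shuffling trial labels within
session (100 permutations x 100 cross-validations); empirical p values
use the add-one form (1 + #{null ≥ obs})/(1 + n), reported alongside the
raw exceedance count, because a pure count can produce p = 0.

Temporal generalization trains on a window-averaged feature and tests on
every other bin with the same resamples, so the diagonal reproduces the
within-window accuracy exactly. Correct-to-error transfer applies
correct-trained decoders to pseudo-populations built from error target
trials paired with correct reference trials (false-alarm reference errors
are not modelled).

## Projection geometry

Decoding axes are unit-normalized before projection so distances are
comparable across windows and states (the method itself fixes no scale).
The spontaneous baseline is each unit's mean rate over the pre-stimulus
silence, per state; with baseline subtraction the projected spontaneous
point is 0 by construction. Distances are window means of the projected
trace (window-mean rather than endpoint bins), spreads are the std over
the stored cross-validation decoders, and the indices are
`asymmetry = d(Targ) − d(Ref)` and
`TEI = (d(Targ_eng)−d(Targ_pass)) − (d(Ref_eng)−d(Ref_pass))`.
The cross-state analysis fixes the engaged axis and compares three cases
(passive evoked vs engaged baseline; engaged evoked vs passive baseline;
engaged evoked vs engaged baseline): a pure baseline-shift mechanism makes
case i equal case iii, a pure evoked-change mechanism separates them.
Latency to half-max is measured on the trial-averaged projected trace
after 3-bin boxcar smoothing (width configurable), with linear
interpolation between bin centers, relative to click-train onset; a flat
trace returns an undefined flag.

## Lick control

Each unit's lick signal reconstruction (single-unit lagged filters) is
sampled at lick times and at an equal number of random non-lick times kept
at least 100 ms from any lick (both counts matched per trial; the margin
and matching are package choices, the method states neither). A prototype
decoder classifies lick vs non-lick population vectors under
cross-validation; the null reconstructs one session's licks from another
session's activity (with a single session, a circular trial-shift fallback
is used and logged). Units are removed one per step — the largest current
|decoder weight|, recomputed each step, with per-unit accuracy ranking
available as an option — until p > 0.4, using a reduced number of
cross-validations per step and a fuller evaluation at termination. The
procedure always halts: once no informative units remain the empirical p
fluctuates around uniform and crosses the threshold.

## Synthetic sessions

The generator emulates the study conditions so each analysis has a planted
truth to recover. Spiking is inhomogeneous Poisson at 1 ms resolution with
rate `λ_i(t) = max(0, b_i^state + evoked_i(t) + lick_i(t))`; rectification
at zero (rather than an exponential link) keeps planted means
interpretable. Defaults, per session: 30 units (2 sessions), 40 trials per
state per class, log-normal baselines (median 4 spikes/s, σ_log 0.4),
reference/target click rates drawn per session from {6,7,8,15} /
{24,28,32,36} Hz.

Planted structure, all amplitudes in spikes/s along unit-norm population
directions:

- engaged baseline shift Δ = 2 along a non-negative direction u (folded
  normal, normalized), so engagement raises spontaneous rates on average;
- a 3 spikes/s TORC response common to classes and states;
- click-train responses: common gain 5 plus class patterns — passive
  ±20·v (symmetric about baseline); engaged reference 3·u (aligned with
  the baseline-shift direction, hence near-invisible to the decoder) and
  target 40·v. The patterns are modulated by a mean-one von Mises kernel
  at the trial's click rate with concentration κ = 5 passive, 2 engaged
  (weaker engaged locking), chosen so single-bin decoding saturates in
  the sound window while phase locking and reconstruction degrade when
  engaged;
- a persistent silence-epoch pattern 25·v₂ (engaged) vs 8·v₂ (passive) on
  target trials, set to the passive amplitude on error trials (20% of
  engaged target trials), so error-trial silence decoding collapses
  toward the passive level while the sound response is intact;
- 10% lick units driven by a 15 spikes/s, 100 ms causal kernel after each
  lick; avoidance-mode behavior licks at 7 Hz through reference trials,
  stops 0.35 s after target onset on correct trials, and keeps licking on
  errors (an appetitive mode reverses the contingency).

v and v₂ are drawn orthonormal and zero-sum (orthogonal to the all-ones
vector), so planted asymmetries are invisible to a uniform-weight readout
— this realizes the population-average control cleanly and is the
package's own design choice. Mechanism-planting presets:
`baseline_shift_config` makes evoked patterns state-invariant in absolute
terms and shifts the engaged baseline along −v (toward the reference
pattern, Δ = 8); `evoked_change_config` sets Δ = 0 and keeps the
asymmetric engaged evoked geometry. All randomness flows from a master
seed through named substreams (directions, baselines, trial order, spikes,
licks), so one component can be varied holding the others fixed.

What the generator does **not** emulate: refractoriness and ISI structure,
adaptation, noise correlations within a session beyond shared epoch
structure, TORC acoustics, multi-animal variability, laminar structure.
Passing tests therefore show that the pipeline recovers planted population
geometry from Poisson spikes at realistic rates — not that real cortical
data satisfies the planted model.

## Problem sizes and numerical choices

Tests and the analysis drivers run the pipeline at two-session cohorts of
50–60 units with 40 trials per state per class — the recorded-session
scale of the study design — with explicit resample counts (20–100) below
the 400-default, and reconstruction on coarser lag grids (5–10 ms step,
50–100 ms span) than the 1 ms library default; these sizes are package
choices that keep the planted effects comfortably detectable. Degenerate
inputs are handled by flags rather than silent numbers: zero-spike VS,
zero-denominator MI, equal prototypes, flat latency traces. Sessions with
too few trials for a balanced split are dropped from the pseudo-population
with a warning rather than failing a run.

## Known limitations

- The prototype decoder is the study's readout model; no regularized or
  max-margin alternatives are provided.
- Lick/no-lick sampling can retain stimulus-locked information (lick
  timing is behaviorally yoked to the stimulus class), so the lick-removal
  p trajectory is a noisy criterion at small null-replicate counts; the
  mismatched-session null shares the trial structure to absorb most of
  this.
- GPFA-style trajectory visualization and LFP/laminar analyses are out of
  scope.
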