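# Methods

This note documents the models, estimators and numerical choices behind
`sdchoice`, and what the synthetic-session generator does and does not
emulate.

## Task and session model

A session is a trial table, per-neuron spike-time lists and per-channel LFP
traces at 1 kHz.  Trials follow the state-dependent choice task: 600 ms
central fixation, a 600 ms state cue (2 cue pictures per state), a 100 ms
hold, then one (forced, 20%) or two (free, 80%) choice options drawn from 4
juice-drop value levels (2 pictures each); the state determines which value
scheme applies.  The session clock is in seconds, per-trial event times are
millisecond offsets from trial start, and every analysis window is half-open
`[start, end)`.  Units with a mean session rate below 1 Hz are excluded from
analysis.

Pseudorandomization is implemented as counterbalanced shuffling: states, cue
sets and the free/forced split (stratified by state) are balanced then
shuffled, and forced-trial values are balanced within state.  This mirrors
standard task programming and guarantees `n_trials/40` forced trials in every
state × value cell, so condition-balanced resampling (20 trials/condition)
is always possible at the default 800 trials.  The inter-trial interval
(700 ms default) is a free parameter; nothing downstream depends on it
beyond session length.

Choices on free trials follow a softmax on the state-conditional value
difference (inverse temperature 2.5, giving ~96% accuracy, in the range of
well-trained subjects).  Decision times are a base (300 ms) plus planted
linear terms in |Δvalue| (−15 ms/drop), state (−7 ms/code unit) and best
side (0), plus lognormal noise (median 50 ms, σ=0.45) — positive and
right-skewed, as reaction-time residuals are.

## Spike generation

Spikes are sampled by thinning a dominating homogeneous Poisson process —
exact for inhomogeneous intensities.  The intensity is an epoch-gated rate,

    rate(t) = rectify( baseline + state_beta[gate]·state
                        + value_beta[state]·coded_value  [choice gate only] )

with value coded −2,−1,1,2 and state −1/+1, and a 50 ms response latency on
the gates.  A warning is raised if rectification removes more than 10% of
the nominal rate mass.

Phase locking multiplies the intensity by a von Mises factor
`exp(κ·cos(φ(t) − μ))` of the concurrent band-limited LFP phase on the
neuron's own channel, active from the state cue onward (the state is unknown
during fixation).  The factor is normalised by its empirical cross-trial
mean **per state and per 20 ms peri-cue bin**, not merely by `I₀(κ)`:
evoked theta is phase-aligned across trials, so a plain von Mises gain would
systematically raise the firing rate wherever alignment is high and thereby
convert a planted phase code into a rate code — exactly the confound the
analyses are meant to separate.  With the time-resolved normalisation the
peri-event rate profile is preserved and the planted effect is a phase code
only.

## LFP generation

Each channel is the sum of

1. **1/f background noise** (power ∝ 1/f), RMS 5 by default;
2. **event-evoked theta bursts** with envelope `amp·(t/rise)·exp(1 − t/rise)`
   and trial-consistent initial phase (an onset-jitter parameter, default 0,
   degrades cross-trial alignment for power studies).  The default fixation
   burst (amp 8, rise 120 ms) lasts 500 ms, ending before the state cue: at
   5 Hz, a tail reaching into the cue window is phase-coherent with the
   unlagged cue burst but not with the lagged copy in the other area, which
   measurably biases the area latency comparison;
3. a **shared theta component** — cue-evoked burst (amp 12, rise 150 ms,
   5 Hz) plus weak tonic 4–8 Hz noise (RMS 1.5; primate theta is evoked by
   salient events, with little tonic component) — injected into HPC channels
   directly and into OFC channels 40 ms later.  This single component
   produces cross-trial phase alignment at the cue, interareal theta
   coherence, a positive HPC→OFC GPDC, and an HPC lead in theta-peak
   latency, all from one planted mechanism.

Per probe, the first channel carries the full shared weight (1.0) and the
second 0.6, marking a planted "best" channel for the channel-selection rule.

What the generator does **not** emulate: biophysical membrane dynamics,
spike waveforms/sorting artefacts, eye movements, volume conduction,
cross-frequency coupling, and nonstationarities other than the planted
structure.  Passing recovery tests therefore demonstrates estimator
correctness under the planted model, not robustness to every pathology of
real recordings.

## Analysis choices

**Epochs.** Fixation = [0, 600) ms from fixation onset; state = [100, 500) ms
from cue onset; choice = [100, 500) ms from option onset.

**Sliding ANOVA.** Rates in 100 ms windows stepped by 25 ms, aligned
separately to cue and option onsets (variable response times preclude one
continuous alignment); two-way state × cue ANOVA with interaction; effect
sums of squares are drop-one-term (type III with the −1/+1 coding); partial
ω² as in the README.  Raw ω² is retained; clipping at 0 is for display.
Prevalence is compared across areas per window with an uncorrected 2×2 χ²
(no continuity correction); sliding-window p-values are pointwise at 0.05
with no multiple-comparison correction (a deliberate mirroring of common
practice; a cluster-permutation option would be the principled extension).

**Epoch regressions.** The trial-number nuisance regressor uses the recorded
trial number (z-scored), so fits are invariant to table row order.  Value
regressors use the chosen option's value on free trials and the offered
value on forced trials.

**Geometry.** PCA is fit on the 8 condition means (conditions as
observations, neurons as features, column-mean centred).  Rates are *not*
z-scored per neuron by default: scaling every neuron to unit
condition-variance inflates untuned neurons' sampling noise until it can
bury the value plane (measured: a planted 30° angle recovered as ~72° with
z-scoring, ~31° without); the toggle remains for sensitivity analysis.
Dimensionality is decided by Horn-style parallel analysis: beyond PC1, a
component is retained only while its variance exceeds the 95th percentile of
the top eigenvalue of condition-mean noise simulated from the
within-condition SEMs.  This matters because PCA concentrates the
between-state slope-difference noise into the leading residual PC; with a
fixed k≥2 rule that pure-noise dimension manufactures a ~7° angle floor at a
planted 0°, while a plain 95%-cumulative-variance rule instead drops a
genuine second value direction at small planted angles.

The value axis is the first principal direction of a state's 4 value points
(oriented so projected value increases; a chord definition is available).
The rigid rotation is a Givens rotation in the plane spanned by the two
axes — the unique minimal rotation carrying one axis onto the other,
identity on the orthogonal complement — applied to state B's points after
centring each state's 4 points on its own centroid (a pure rotation cannot
absorb the between-state mean offset).  The angle is found by a 1° grid plus
bounded refinement to 0.1° over ±180°, and verified in tests against the
closed-form in-plane Procrustes solution `atan2(c2, c1)`.  All angles are
folded into [0°, 90°] (axis-orientation ambiguity); zero rotation is always
in the search set, so the post-rotation RMSE never exceeds the pre-rotation
RMSE.

**Decoding.** Per bootstrap, 20 trials per value × state are drawn without
replacement (160 trials), standardised and reduced by PCA retaining 95%
variance *fit across all 160 trials* — the procedure as practised, which
leaks marginal feature statistics into the test fold; a leakage-free
per-fold variant (`pca_on_train=True`) exists and is off by default.  One
linear max-margin multiclass decoder per state (one-vs-one, C=1,
`sklearn.svm.SVC`) under stratified leave-one-out; within- and cross-state
accuracies use identically sized 4-trial test sets.  Neuron dropping
re-bootstraps both the neuron subset and trials at each population size.

**LFP phase.**  4th-order Butterworth bandpass applied forward–backward
(zero phase), 500 ms reflection padding, Hilbert transform.  Bands: theta
4–8, alpha 9–12, beta 13–30, gamma 30–60 Hz.  Theta-peak latency: the
envelope is z-scored over the session per channel, smoothed with a 50 ms
centred boxcar (a quarter theta cycle — an envelope cannot peak at
millisecond scale, and unsmoothed sample-level ripples register as spurious
early peaks), and the first strict local maximum with z > 0 after cue onset
is taken; sample 0 counts as a peak when it exceeds sample 1; trials with no
qualifying peak are excluded with a count.

**Connectivity.** Multitaper coherograms use 3 Slepian tapers
(time–bandwidth 2), 1 s windows, 90% overlap; event-aligned spectra average
over trials × tapers (which is what gives coherence its degrees of freedom),
and the theta time course is z-scored per pair across the session.  Channel
selection takes, per probe, the highest peak theta cross-trial alignment
among channels hosting at least one unit, then forms all HPC × OFC pairs.
GPDC uses a bivariate autoregressive model fit by ensemble least squares
over per-trial 600 ms segments beginning 300 ms after cue onset (per-trial
means removed, channels standardised); order by minimum BIC up to 15
(600 ms of 1 kHz data supports modest orders only); unstable fits retry at
lower order.  Net directionality = GPDC(HPC→OFC) − GPDC(OFC→HPC) per
frequency, summarised at 5 Hz and band-averaged.  The time-domain Granger
confirmation uses nested-model variance-ratio F tests at the same order.

**Bootstrap CIs.** All bootstrap-percentile intervals are the 5th/95th percentiles of
1,000 (scaled where noted) draws of 80% of the data.  Draws are made *with*
replacement: with an 80% subsample drawn without replacement the resample
spread is only ~half the sampling SD (variance ratio n/m − 1 = 0.25), and
the percentile interval grossly undercovers — measured ~80% coverage of zero
for the null net-GPDC, worsening with trial count.  Note these percentiles
form a 90% interval even where convention labels them 95% CIs.

**Spike phase.** Rayleigh `Z = nR²` with the standard small-sample p-value
approximation; significance p < 0.01.  The preferred state is the sign of
the state beta from a regression of z-scored epoch rates on state and cue
set (the asymmetric −1/2 cue dummy codes as practised; a symmetric option
exists); the epoch is chosen automatically as the larger-|beta| of the state
and choice epochs, since some populations express their state code only at
choice time.  The expected both-state-modulated proportion is the
independence product `p̂_A·p̂_B` (a literal union `p̂_A + p̂_B − p̂_A·p̂_B` is
the either-state probability and is reported alongside for transparency),
tested against the observed count with a two-sided binomial test.  Neurons
firing more in their preferred state have more spikes and hence more
Rayleigh power; an optional spike-count-matched subsampling variant
equalises n across states, with the unmatched version the default.

## Default study population

The default session (800 trials; 40 neurons + one sub-1 Hz unit per area;
2 probes × 2 channels per area) plants the dual-area dissociation: 40% of
HPC neurons carry ±4 Hz state tuning in the state epoch, 40% of OFC neurons
carry it in the choice epoch; both groups are theta phase-locked during the
state cue with κ=2 in their preferred state and κ=0.2 otherwise.  Half of
each area's neurons carry value tuning (RMS 2.5 Hz per coded unit on 5–14 Hz
baselines): the HPC's state-B coding direction is the state-A direction
rotated 30° in neuron space (a largely state-general code), while the OFC's
value-coding halves are disjoint across states (an orthogonal code).  These
are the conditions under which the recovery studies and the acceptance
script run; bootstrap counts are scaled to 200 (from 1,000) to keep the full
run within a few CPU-minutes, and recovery means are taken over 3
independent session replicates per condition because a single session's
realized effect carries shared finite-trial noise across all its bootstraps.

## Known limitations

- The Granger F statistics on sessions with a strong deterministic evoked
  component are inflated in both directions (the burst is predictable from
  either channel's past); the *difference* and the GPDC remain directional.
- Parallel-analysis dimensionality assumes approximately Gaussian
  condition-mean noise with independent entries; strongly correlated noise
  across neurons would require a shuffle-based null instead.
- The DT model is linear with additive lognormal noise; no sequential
  sampling (drift-diffusion) structure is modelled.
- Rate rectification makes planted linear tuning slightly convex for
  low-baseline neurons; recovery tests tolerate this as part of the planted
  conditions.
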