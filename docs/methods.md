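# Methods

This note documents the models and procedures implemented in `photoplast`,
the defaults they use, and what the synthetic-data validation does and
does not establish.

## Closed-loop BCI transform

The control law is the piecewise-linear voltage map with gain 7.9 steps/s
per volt, ceiling 3.3 V, 685 µm steps, 7 mm start distance, 6 mm reward
distance, 10 s timeout, and 20 Hz frames. Thresholds are F_L = median and
F_U = maximum of a spontaneous-period trace; F_U = F_L is flagged
degenerate rather than silently mapped. The median of an even-length
trace is the mean of the central pair.

Port motion integrates the *expected* displacement step_size × f_step × Δt
each frame. This keeps the loop deterministic and reproducible; a
stochastic mode drawing Poisson(f_step Δt) step counts is available behind
a flag for studying stepping noise. Trial sequencing after a hit requires
the CN below F_L for 200 ms, then a 2 s delay, then a 300 ms port return;
after a miss the port resets logically and the next trial starts after
the return time. An optional fixed control lag (default 0) stands in for
online motion-correction delay; the real delay is variable, but its
distribution is not modelled. Event times are frame-aligned; a trailing
unfinished trial is dropped.

## Task epochs and tuning

Epoch windows are half-open `(start, end]` over frame timestamps:
pretrial (−2, −1] s before trial start (only on trials following a hit,
because trial initiation differs after misses), early trial (start,
reward − 1 s], late trial (reward − 1 s, reward], reward (reward,
reward + 3 s]. Early/late/reward exist only on hit trials, and a hit
shorter than 1 s has no early entry: restricting all within-trial epochs
to hit trials keeps them mutually consistent, since "late" is defined
relative to reward. Analyses use the first 40 trials.

The 4-dim tuning vector is the trial-mean of each epoch entry; the Δ
components are OLS slopes of the entry on trial index over available
trials (absent with fewer than two trials). Adding a constant to every
trial shifts the base components and leaves the slopes unchanged, which
the tests assert.

The CN-sparsity bootstrap draws one non-CN neuron per session (optionally
restricted to candidate-CN neurons), takes the median across sessions,
and repeats `n_draws` times; the one-sided p is the fraction of null
medians at or above the CN median. The CN is excluded from the pool so
that a CN strictly above the population attains percentile 1. The seed is
a required argument. Candidate-CN screening ranks neurons by activity
modulation (fraction of time above their own s.d.) and trial-start tuning
(in-trial mean minus pretrial mean), and keeps the 5% nearest the
reference CN in Euclidean rank space — rank space because the two
statistics have incommensurate units.

The epoch-weighted population average normalises by Σ|wᵢ| so the output
keeps trace units under sign-mixed weights.

## Photostimulation responses and causal connectivity

Windows: 200 ms before onset, read as `[-200, 0)` ms, and 300 ms after
offset, read as `(0, 300]` ms after the 100 ms stimulation (which is
laser-contaminated and excluded) — 4 and 6 frames at 20 Hz. With the
0.6 s inter-stimulus interval the after-window of one event and the
before-window of the next share exactly one frame; this is a property of
the stated window conventions, not a bug, and it slightly inflates
baselines when responses persist.

The baseline b is the repeat-averaged before-window mean per
(neuron, group), computed over retained repeats only; b ≤ 0 (possible on
synthetic data) invalidates the entry rather than flipping response
signs. A neuron that was a target of the immediately preceding event is
excluded from the current one. The repeat s.d. uses the sample (n−1)
estimator; PS responses require ≥10 repeats. Distances are 2-D within the
imaging plane; cross-day neuron identity is assumed given. Target
(< 20 µm) and non-target (30–100 µm) masks on session pairs require the
criterion on both days.

## Regression of connectivity on tuning

Regressor columns are Yᵢ·X_g with Y over {1} ∪ tuning components of the
non-target neuron and X over {1} ∪ components of the targets, where
X_g = Σ_{j∈targets} X_j W̃_j,g for component X and X_g = 1 for the
constant; the (1,1) combination is the intercept and is dropped, giving
24 (4-dim) or 80 (8-dim) candidates. The total target response W̃_g (or
ΔW̃_g) is the control column. For single-neuron in-silico groups the
weighting is disabled (direct drive is uniform) and the components are
configurable, which the model-side fits use.

The final columns are z-scored before the lasso (the components are not
individually standardised before forming products); coefficients are
reported in standardised units with a raw-scale back-transform available.
The penalty grid is 50 log-spaced values on [10⁻⁴λ_max, λ_max], where
λ_max zeroes all slopes; the penalty minimises mean out-of-fold squared
error over 10 folds, and out-of-fold predictions cover every row exactly
once. Fold assignment can be grouped (e.g. by session) to avoid leakage.
Wald inference is performed on an OLS refit of the lasso-selected columns
plus the control — lasso coefficients have no valid standard errors — and
reported one-sided for positive slopes. A per-column scan (control plus
one regressor at a time) probes raw associations.

## RNN models

Vanilla rate dynamics h ← h + (Δt/τ)(−h + φ(a⊙(W_rec h + W_inp x)) + n)
with φ = tanh, Δt = 0.01 s, τ = 0.1 s, per-step noise 0.01·N(0,1),
n = 100 hidden and d = 10 input units. Weights are initialised
scale/√fan-in · N(0,1) with scales 0.5 (recurrent) and 0.1 (input): the
recurrent scale keeps the spectral radius near 0.5 so photostimulation
responses are not dominated by long-lived modes, and the input scale is
kept below it, which is required for the positive correlation–
connectivity relationship.

Trials are two 1 s periods (pretrial, late) with distinct constant input
drives drawn once per model; hidden state resets to 0 each trial. The CN
is chosen after a 10-trial stabilisation period without updates: among
neurons above the median in both pretrial and late mean activity, the one
with the smallest |pretrial − late| difference (ties to the lowest
index); the target γ̂ is the 95th percentile of CN activity over
stabilisation. Training is BPTT, one trial per update, on the late-period
MSE of the readout w_bci·h against γ̂, with gradients w.r.t. the hidden
state routed through the misaligned feedback vector
w_back = w_bci + w̃, w̃ ~ 0.25·N(0,1) off the CN and exactly 0 at the CN
(so w_back·w_bci = 1 exactly). Gradients are hand-derived and verified
against finite differences. The plasticity locus gates which arrays
receive updates (input, recurrent, both with first-trial-matched
learning-rate scaling, excitability gains, or the upstream RNN's
recurrent weights); everything outside the locus is bit-identical after
training. Runs whose smoothed loss (first vs last 5 trials) does not
decrease are flagged rejected, and rejection fractions are reported.

Learning rates are scanned on a 9-point log grid over [10⁻³, 10]. A rate
is eligible if its median loss decreases and its median completion trial
(first trial with CN late activity ≥ 90% of γ̂) is ≤ 30; the largest
eligible rate is selected by default. At very small rates the scan-median
completion is unreliable — CN activity can drift past the threshold
before any learning — so preferring large stable rates is the robust
choice; a `target_completion` option instead selects the eligible rate
closest to a desired behavioural pace.

In-silico photostimulation clamps one neuron to h_pert = 1.0 (activity
units comparable to tanh saturation; configurable) after each update step
for 1 s, with the preceding 1 s average as baseline and noise active, 5
repeats, all groups batched. Correlations come from the 10-trial
stabilisation periods before and after training. The discrimination
analysis pools off-diagonal (C, W̃) and (ΔC, ΔW̃) pairs over seeds into
positive Wald tests; no control column is needed because direct drive is
identical across single-neuron groups.

## Preparatory circuit model

Rectified-linear dynamics h ← h + (Δt/τ)(−h + W_rec φ(h) + W_inp x),
φ(x) = max(x, 0), deterministic. Populations: 10 pretrial neurons with
recurrent self-excitation (summed weight 0.8, giving slow preparatory
decay), 10 TRIAL neurons (input-driven during the trial period, plus
summed 0.5 drive from the pretrial population), five 4-neuron modules,
and one reward neuron that receives trial-population input and does not
project back. The pretrial population additionally projects weakly
(summed 0.1) to the whole downstream circuit — the widespread
preparatory excitation the feedback variant relies on — which leaves
module pretrial activity near zero before learning. The CN is the second
neuron of the first module with a weak trial-population input (summed
0.3) that keeps its late activity below the movement threshold of 0.6.

Learning edits weights directly (nothing is trained online). Manipulation
1 adds summed 0.6 from the pretrial population onto one neuron per module
(the Δpretrial neurons). The broadcast variant additionally adds 0.15
from each Δpretrial neuron onto every downstream neuron; the feedback
variant instead adds 0.09 from each Δpretrial neuron onto each pretrial
neuron, incorporating them into the preparatory loop (the loop gain is
then slightly supercritical, producing transient growth within the 2 s
trial rather than a fixed point). Baseline weights and increments are not
dictated by data; they were calibrated once so the pre-learning CN sits
just below and the post-learning CN just above the threshold in both
variants, and the tests assert exactly that crossing plus an exact
weight-diff audit of each edit. The in-model Δconnectivity regression
uses components (pre, late, Δpre, Δlate) from the simulated trial before
and after learning; the broadcast variant yields positive lasso
coefficients on pretrial→Δpretrial and Δpretrial→All, and the feedback
variant reproduces the Δpretrial→All pattern as a single-regressor
effect, consistent with it arising indirectly through the preparatory
population.

## Synthetic ground truth

Weights follow a Gaussian centre–surround distance kernel (σ_exc = 25 µm,
σ_inh = 80 µm, amplitude 0.3) constrained to cross zero at the 60 µm
excitation radius, plus N(0, 0.05²) heterogeneity and two planted motifs
with gain 0.05: like-to-like coupling proportional to rew_i·rew_j and
broad excitation proportional to the sender's pretrial amplitude.
Neurons are assigned epochs (pre/early/late/reward/untuned with
probabilities 0.15/0.2/0.15/0.2/0.3) and amplitudes |N(0.6, 0.2²)|,
tiling the trial.

Sessions: the CN trace is produced frame-by-frame through the trial state
machine with a per-trial gain schedule (default linearly rising
0.05 → 1), and the authoritative events are then re-derived by running
the actual closed loop over that trace. Other neurons receive
epoch-aligned drives on the realized events, one-step propagation through
the true weights (gain 0.3), a causal exponential calcium filter
(τ = 1 s, GCaMP6s-like), and Gaussian frame noise (0.05). The reward
drive lasts 1.2 s — shorter than the 3 s analysis window — because with
~3 s inter-trial intervals a longer consumption drive leaks into the next
trial's pretrial window and destroys planted pretrial tuning; similarly
the preparatory drive spans (−2.5, −0.3) s so the (−2, −1) s window
samples its plateau. Raw fluorescence is F0·(1 + ΔF/F) with F0 ~
U(80, 120), and ΔF/F is re-derived from the session median, matching the
analysis convention.

Photostimulation blocks stimulate groups sequentially every 0.6 s:
targets get a direct 0.5 ΔF/F response (±10%), everyone else gets the
one-step sum of true weights from the targets plus N(0, 0.1²) repeat
noise; a paired-day mode applies a specified true ΔW. The default noise
level leaves estimated W correlated ≈ 0.95 with the true summed weights
at 20 repeats — deliberately favourable so that pipeline failures
indicate bugs, not noise.

**What passing tests show, and what they do not.** The generator shares
the analysis' own assumptions (linear one-step propagation, Gaussian
repeat noise, drives aligned exactly to events). Recovery on this ground
truth validates the estimators' book-keeping, masks, normalisations and
regression algebra; it does not establish robustness to real-data
features it omits: neuropil contamination, motion, off-plane
photostimulation, nonlinear calcium indicators, non-Gaussian and
correlated noise, or cross-day registration errors.

## Experiment drivers and problem sizes

`pipeline.run_full_synthetic` chains circuit → sessions → tuning →
paired photostimulation → W/ΔW → lasso fits and emits a JSON report that
is byte-identical across runs at a fixed seed; per-stage seeds derive
from the global seed by crc32 of the stage name. The default study size
is 300 neurons, 3 sessions × 30 trials, 100 groups × 20 repeats. The test
suite and the acceptance script use 120–250 neurons, 50–80 groups and
12–15 repeats, sizes at which every planted effect is still recovered
with wide margin while a full run stays in the tens of seconds on one
CPU. The group-size experiment fixes the stimulation-event budget
(groups × repeats) and scores ridge reconstruction of the full true
weight matrix, with never-probed pairs scored at the zero prior: scoring
only probed pairs would reward single-site groups for probing few pairs
accurately and invert the effect.

## Known limitations

* The trial state machine models port return and inter-trial timing as
  fixed dead times; partial mid-trial port returns are not modelled.
* Tuning regression treats binned-scatter presentation as display-only;
  no binning is implemented.
* The upstream-RNN and loop (cortico-subcortical) variants implement the
  stated dynamics and training paths but have no spatial embedding, so
  distance-based masks do not apply to them.
* The preparatory model is a demonstration of sufficiency, not a fit: its
  weights are chosen by hand, and only the qualitative coefficient
  pattern is meaningful.
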