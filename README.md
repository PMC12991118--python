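# photoplast

Analysis and modelling toolkit for single-neuron brain–computer-interface
(BCI) learning experiments with an all-optical readout: two-photon calcium
imaging of a ~1 mm field of view at 20 Hz, closed-loop neurofeedback from
one *conditioned neuron* (CN), and holographic two-photon photostimulation
to measure causal connectivity before and after learning.

It is written for systems neuroscientists who want to run this entire
analysis chain — and the accompanying network models — on their own
sessions or on synthetic ground truth:

1. **Closed-loop BCI** (`photoplast.bci`). The CN's raw fluorescence is
   mapped onto a control voltage between two thresholds (the median
   F_L and maximum F_U of a preceding spontaneous period) and the voltage
   sets the reward-port stepping frequency,

   f_step = 7.9 × V_m,   V_m = 0 for h ≤ F_L,
   V_m = V_max (h − F_L)/(F_U − F_L) for F_L < h ≤ F_U, V_max above,

   with 685 µm steps, a 6 mm travel to reward, and a 10 s timeout. A trial
   state machine converts a CN trace into hit/miss events.

2. **Task-epoch tuning** (`photoplast.tuning`). Per-trial mean ΔF/F in
   four epochs — pretrial (−2,−1) s before trial start, early trial, late
   trial (final 1 s before reward), reward (0–3 s after reward) — gives a
   4-dimensional tuning vector (Preᵢ, Earlyᵢ, Lateᵢ, Rewᵢ) per neuron, and
   OLS slopes over trials give the learning components (ΔPreᵢ, …). A
   bootstrap over random draws of one neuron per session quantifies how
   extreme the CN's change is.

3. **Causal connectivity** (`photoplast.connectivity`). Each
   photostimulation of a 10-site group yields a repeat response
   (after-window mean − before-window mean)/baseline; the PS response
   W̃ᵢ,g is the repeat mean divided by the repeat s.d., and its across-day
   change uses error propagation. Responses of *non-target* neurons
   (30–100 µm from the nearest site) are the causal connectivity Wᵢ,g and
   ΔWᵢ,g.

4. **Tuning regression** (`photoplast.regression`). W and ΔW are fit by
   cross-validated lasso on regressors Aᵢ,g = Yᵢ·X_g, where Yᵢ ranges over
   the non-target tuning components and X_g over PS-response-weighted
   group tuning (24 candidates for 4-dim tuning, 80 for 8-dim), with the
   total target response W̃_g as a control and one-sided Wald tests on an
   OLS refit.

5. **RNN plasticity-locus models** (`photoplast.rnn`). A rate RNN
   (n = 100, τ = 0.1 s, dt = 0.01 s) trained by BPTT with feedback
   misalignment raises CN activity to a self-calibrated target; plasticity
   can be restricted to input weights ("upstream" hypothesis), recurrent
   weights ("local" hypothesis), both, excitability, or an upstream RNN.
   In-silico photostimulation (activity clamps) shows that correlations
   predict connectivity in both models, but *changes* in correlation
   predict *changes* in connectivity only under local recurrent
   plasticity — the experimentally testable discriminator.

6. **Preparatory circuit model** (`photoplast.prep`). A hand-wired
   rectified-linear network (pretrial population → trial population →
   modules + reward neuron) in which strengthening pretrial→Δpretrial and
   Δpretrial→all connections (or, alternatively, a Δpretrial→pretrial
   feedback loop) pushes the CN across the movement threshold.

7. **Synthetic ground truth** (`photoplast.synth`) generates circuits with
   distance-dependent weights (excitatory within ~60 µm), epoch-tuned
   sessions driven through the real closed loop, and photostimulation
   blocks propagated through the true weight matrix — so every stage of
   the pipeline can be validated against known truth.

## Worked example

```python
import numpy as np
from photoplast import synth, tuning, connectivity as co, regression

circuit = synth.sample_circuit(synth.CircuitConfig(n_neurons=300), seed=0)
session = synth.simulate_session(circuit, seed=0)

table = tuning.epoch_activity(session)
tv = tuning.tuning_and_delta(table, session.n_neurons)

groups = synth.sample_groups(circuit.positions, n_groups=100, group_size=10, seed=1)
raw, groups = synth.simulate_photostim_block(circuit, groups, repeats=20, seed=2)
masks = co.classify_neurons(circuit.positions, groups)
ps = co.ps_response(co.repeat_response(raw, 20.0, groups, masks))
mats = co.connectivity_matrices(ps, masks)

C = regression.pairwise_correlations(session.dff)
a_rho = regression.correlation_regressor(C, ps, masks)
tab = regression.build_tuning_regressors(
    tv, ps, masks, mode="base4",
    response=mats.W, control=mats.group_total, correlation_column=a_rho,
)
slope, p = regression.wald_positive_test(
    tab["y"], tab["A_rho"], controls=tab["control"].to_numpy()
)
```

This prints, with the seeds above:

```
trials: 30  hit rate: 0.67
CN late-trial slope: 0.0139 dF/F per trial (percentile 1.00 of population)
causal connectivity: 2506 (neuron, group) pairs; corr with ground-truth summed weights r = 0.97
correlation regressor (control-adjusted positive Wald): slope 0.005, p = 4.21e-04
lasso MLR: held-out r = 0.20; Y:rew|X:rew = 1.933, Y:1|X:pre = 0.855
```

Reading the numbers: the simulated mouse's hit rate rises within the
session and the CN's late-trial slope sits at the top of the population
(the conditioned change is sparse); estimated causal connectivity tracks
the ground-truth summed weights from targets (r = 0.97); BCI-session
correlations predict non-target photostimulation responses even after the
total target response is regressed out; and the lasso recovers the two
planted connectivity motifs (like-to-like coupling between reward-tuned
neurons, broad excitation from pretrial-tuned neurons) with positive
coefficients.

The same flows are scriptable from the shell:

```bash
photoplast synth --preset session --seed 0 --out out/
photoplast tuning --session out/session.h5 --out out/tuning.csv --seed 1
photoplast rnn --locus recurrent --seeds 10 --out out/rnn.json
photoplast prep-model --variant broadcast
photoplast experiment --seed 0 --out out/report.json
```

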