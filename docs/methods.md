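# Methods

This note documents the models behind `mbflex`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that matter for reproducing results.

## Synthetic Kenyon-cell populations (`mbflex.synth.gen_kc_dataset`)

Each cell responds to an odor with probability `responder_fraction`
(default 0.1 — sparse coding at the level reported for mushroom-body odor
representations). The similar odor pair (A, A′) shares a fraction
`overlap_AAprime` (default 0.85) of A's responders; the dissimilar odor B
shares `overlap_B` (default 0.05). Responder amplitudes are gamma(shape 2,
scale 0.5) draws, giving positive, right-skewed ΔF/F amplitudes with mean 1.

The pooled per-cell Pearson correlation between A and A′ amplitudes is the
quantity figure-level analyses report, so the generator targets it directly
(`amplitude_corr_target`, default 0.74): A′ amplitudes on shared responders
are a convex mix of the A amplitude and an independent draw, and the mixing
coefficient is set by bisection on the noise-free latent table before any
trial noise is drawn. With sparse codes the correlation is bounded above by
the responder-overlap structure (expected maximum ≈0.83 at the defaults);
if a requested target is unreachable for a particular seed the generator
uses the closest attainable value and warns. Single-seed realizations stay
within ±0.1 of the target at n ≥ 200 cells; heavy amplitude outliers on
unshared responders occasionally push a seed toward the lower edge of that
band, which pooling across flies averages out.

Traces are first-order relaxations toward a per-epoch target amplitude
(rise τ = 0.3 s, decay τ = 1.0 s; plotted response shapes are never
parameterized by the experiments this emulates, so the simplest kinetics
that are linear in amplitude were chosen — linearity makes window-mean
amplitudes scale exactly with planted factors). Trial noise is additive
i.i.d. Gaussian per frame (`trial_noise_sd`, default 0.1 ΔF/F), the simplest
model sufficient for recovery testing. Raw fluorescence is reconstructed as
`background + F0·(1 + ΔF/F)` with per-cell F0 ~ U(80, 120) and background 10
(arbitrary units), so the full background-subtraction → ΔF/F chain is
exercised and exactly invertible in the noise-free case.

Transition trials: the second-pulse amplitude vector equals that odor's
single-pulse amplitudes plus `order_effect_eps` times a fixed, order-specific
Gaussian perturbation on the union of the two odors' responders (clipped at
zero). The perturbation is constant across trials, so order is decodable
exactly when `order_effect_eps` dominates trial noise. The default 0.5 sits
well above that threshold at the default noise 0.1 — a pilot sweep of the
construction confirmed separability from ≈0.2 upward — while keeping the
transition response "coarsely similar" to the single pulse. With
`order_effect_eps = 0`, a transition carries no information beyond its
second odor's identity; note the two transition orders are still separable
by that identity, and what disappears is the possibility of satisfying the
order-discrimination targets jointly with the pulse targets (see the
transfer-protocol tests).

Defaults follow the emulated acquisition: 8 trials per stimulus, 10 Hz
frames, 5 s pulses, zero-gap transitions, 10 s baseline.

## Synthetic MBON recordings (`gen_mbon_dataset`)

A single ROI with equal pre-pairing amplitude (default 2.0 ΔF/F) for all
three odors. Post-pairing, isolated pulses of A and A′ scale by
`depression_factor_A` / `depression_factor_Aprime` (defaults 0.3 — strong
learning-induced depression), B is unchanged, and A′ *when it directly
follows A* scales by `transition_recovery` (default 1.0 — full recovery,
the order-asymmetric effect). A second when preceded by A′ stays depressed.
Because trace dynamics are linear in amplitude, the measured post/pre
window-mean ratio for an isolated pulse equals the planted factor exactly in
the noise-free case; second-pulse windows additionally contain a small
(<2 % at the defaults) carryover term from the decaying first pulse, inside
the stated ±0.05 recovery tolerance.

## Synapse counts and connectome initialization

Per-KC synapse counts are lognormal (σ = 1) rounded to integers ≥ 1, with
the mean targeted at 8.8 — the connectome-scale average for one MBON
(2959 synapses across 336 α′/β′ KCs). Only the scale is biological; the
lognormal family is a choice (counts are heavy-tailed and positive).
Decoder initialization resamples these counts normalized to their maximum,
uniformly with replacement, giving initial weights in (0, 1].

## Arena trajectories (`gen_arena_trajectories`)

Flies are independent Gaussian random walks (`step_sd` mm/frame, default 1.0
at 30 Hz ≈ 30 mm/s — brisk walking) inside a reflecting disk (radius 50 mm).
During odor epochs an outward radial drift `upwind_drift` (mm/s) is added —
odor flows inward from the arena rim, so upwind is outward. During choice
epochs proposed steps are Metropolis-filtered with quadrant weight
`quadrant_bias` for paired-odor quadrants, so the stationary occupancy ratio
between paired and unpaired quadrants equals the bias and the stationary PI
is (w−1)/(w+1). Initial positions are area-uniform over a disk
(`init_radius`, default the full arena — the stationary law of the reflected
walk) or exactly on that radius (`init_mode="ring"`).

What this does *not* emulate: persistent heading and run/turn statistics of
real fly locomotion, inter-fly interactions, odor plume structure, or
boundary-following behavior. Passing recovery tests therefore demonstrates
the correctness of the metrics and estimators, not fidelity to real
trajectories.

Quadrants are the half-open angular sectors [90q, 90(q+1)) about the center;
a fly exactly on a boundary belongs to the counter-clockwise-adjacent sector
(deterministic, measure-zero). The PI summary is the mean over frames in
[T_end − 30 s, T_end); the baseline is the mean over the whole pre-odor
epoch. Flies with missing frames are dropped from a metric rather than
interpolated.

## Decoder numerics

No intercept: the model is h = σ(Xθ) with θ of length n (an MBON-like
readout has no bias unit). Probabilities are clipped to [1e-12, 1−1e-12]
inside the cost only. The optimizer is full-batch gradient descent
(learning rate 0.1, max 10 000 iterations, cost tolerance 1e-8) with
backtracking: a step that would raise the cost halves the step size, and the
step size recovers by ×1.5 after accepted steps, so the accepted-cost
sequence is non-increasing and the whole procedure is deterministic. A zero
cost change is treated as a clipped-probability plateau, not convergence;
convergence requires a positive change below tolerance or a vanishing
gradient. LOOCV holds out every trial exactly once and trains on all
remaining trials of all classes; folds whose training set loses a class are
skipped with a warning. Per-odor accuracy is the hit rate (h ≥ 0.5, ties
positive) on held-out target-odor trials; a balanced mode that also scores
held-out negatives is available. λ = 1 is the odor-decoding default and the
transfer protocols use λ = 0 with all-ones initialization, matching the two
regimes the analyses require; both initialization schemes are exposed
because the emulated workflows describe both.

## Statistics

Holm correction is the step-down procedure with a running maximum for
monotonicity, applied within explicit comparison families (figure-panel
granularity). Signed-rank and rank-sum tests delegate to scipy with exact
small-sample nulls (n ≤ 8 per group, no ties) and continuity-corrected
normal approximations otherwise; identical paired samples return p = 1 with
a warning rather than an error, since "no signal" is the informative answer.
SEM is sample SD/√n.

## Recovery-experiment design choices

*Planted-bias recovery* uses the generalization design with paired controls:
the control run reuses the trained run's seed (common random numbers), so
pre-odor baselines cancel exactly and the score's variance drops about
seven-fold; 12 runs of 15 flies then recover the planted stationary PI
within ±0.1. Independent controls (the default in `run_choice_experiment`)
mimic the real assay, where control cohorts are different flies.

*Planted-drift recovery* subtracts matched drift-off runs from drift-on runs
(same initial law, disjoint seeds) because a reflected random walk away from
stationarity gains radius diffusively (≈ step_sd²/2r per frame) even with no
drift; cohorts start on a 20 mm ring with step_sd 0.3 so the wall rarely
censors the 10 s drift window. The estimator recovers a planted 1.0 mm/s
within a few percent.

*Permutation-null check for LOOCV* is run at 2 odors × 4 trials, the largest
size at which all C(8,4) = 70 label assignments can be enumerated through
the full pipeline to give an exact chance level; the fold-structure oracle
runs at the full 8 trials × 3 odors.

## Problem sizes

Default study conditions: 500 cells × 8 trials/stimulus for KC analyses
pooled over 3 synthetic flies; 8 synthetic flies × 2 trials/stimulus for
MBON analyses; 12 arena runs × 15 flies for behavior. The test suite and
acceptance script complete in a few minutes on one CPU at these sizes.

## Known limitations

* Generator realism is deliberately minimal (see above); effect sizes are
  planted, not fitted to data.
* Gradient descent on separable λ = 0 problems stops at `max_iter` with
  weights still growing; held-out probabilities are saturated long before,
  so protocol outputs are insensitive to the cutoff.
* The per-cell correlation calibration targets the noise-free latent table;
  measured correlations add (small) trial-noise attenuation.
* PI mixing toward the stationary bias value takes ~1–2 min of simulated
  time at the default step size; shorter choice tests under-shoot the
  stationary PI.
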