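# Methods

This note documents the models, algorithms and design choices behind
`popconf`, in the order the pipeline runs them.

## The decision model

Choices and reaction times are modeled as a race between two
anti-correlated accumulators, x_L and x_R, integrating momentary evidence
for leftward-minus-rightward motion and its complement. Per step of
Δt = 5 ms:

    x_L ← max(x_L + κΔt(C + C0) + u(t) + η_L√Δt,  B_reflect)
    x_R ← max(x_R − κΔt(C + C0) + u(t) + η_R√Δt,  B_reflect)

with (η_L, η_R) bivariate standard normal with correlation ρ = −0.7, C the
signed motion coherence (leftward positive), C0 a bias in coherence units,
and u(t) a step urgency equal to 0 before the onset delay d and aΔt per
step afterwards. The lower reflecting bound B_reflect is the non-negative
firing-rate analogue: an accumulator may touch it but not cross. The first
accumulator to reach the upper bound B fixes choice and decision time; RT
adds a Normal(μ_nd, σ_nd) non-decision time truncated at zero (truncation
is logged when it affects more than 1% of samples). Trials that fail to
terminate within 10 s are censored and excluded with a logged count.

The noise term is scaled by √Δt so the diffusion has unit variance per
unit time and κ keeps its usual signal-to-noise interpretation; with that
convention the ρ = −1, B_reflect → −∞ limit collapses to a single
diffusion between ±B whose accuracy has the closed form
1/(1 + exp(−2κCB)), which the test suite checks by simulation.

Free parameters Θ = {κ, B, a, d, C0, μ_nd, σ_nd}; ρ, Δt and B_reflect are
fixed constants. B_reflect defaults to −0.5 (below zero, above −B).

### Simulation-based likelihood

The likelihood of single-trial (coherence, choice, RT) data is estimated
by forward simulation: for each coherence, `n_sim_factor` times as many
trials as observed are simulated; decision times per (coherence, choice)
cell are smoothed with an Epanechnikov kernel (bandwidth by Silverman's
rule on the simulated sample, floored at Δt — the source of this analysis
chain does not state a bandwidth) on a 1 ms grid over [0, 5] s, and
convolved with the non-decision-time density. Densities are floored at
1e-10 and an observed RT outside the grid contributes the floor. The
simulation seed is a fixed function of the likelihood seed and the
condition index, so the objective is deterministic in (Θ, seed) — common
random numbers, without which derivative-free optimizers cannot certify
convergence.

### Fitting

`fit_race` maximizes the objective with Powell's bounded derivative-free
method (the reference analysis used BADS; any bounded derivative-free
optimizer serves). The objective's κ–B ridge is shallow relative to the
simulation noise, so `fit_race_refined` runs two stages: a coarse search
(300 evaluations, 5× simulation factor) followed by a polish from the
stage-1 optimum (200 evaluations, 20× factor). At 6,000 trials this
recovers κ and μ_nd within ~15% relative error and C0 within ±0.01 across
the seeds examined, in about two minutes on one core.

## Population decoders

All decoders are L2-lightly-regularized logistic regressions
(ridge 1e-6, just enough to tame perfect separation) on standardized
spike counts in the presaccadic window — the 100 ms epoch ending 50 ms
before saccade initiation. Standardization is computed once on the
decoder's trial set before cross-validation; per-fold standardization is
a config option but z-score leakage is second order. Cross-validation
uses 10 seeded random folds of near-equal size; every trial's probability
is out of sample. The stored coding direction is the all-trials fit.

Targets: *accuracy* (correct vs. error, per choice category), *choice*
(left vs. right, all trials), and *RT class* (faster vs. slower than the
within-set median, contralateral choices). AUC follows the Mann–Whitney
convention with ties counted 0.5 and is checked in the tests against
brute-force pair counting and against scikit-learn. Bootstrap standard
errors and one-sided decoder comparisons resample trials (all-pairs
exceedance across two independent bootstrap samples); session-level
comparisons use a one-tailed paired t test on logit-transformed AUCs,
with AUC = 1 clamped to 1 − 1e-6.

## Clustering of per-neuron regressions

Each Tin neuron's standardized presaccadic count is regressed (OLS) on
signed coherence, RT, choice and an offset, correct trials only; the
choice regressor is coded 0/1 (left = 1). K-means (k = 3, 50 seeded
greedy-k-means++ restarts) clusters the (β_coherence, β_RT, β_choice)
triples unscaled — the counts are already standardized and the
coefficients share units. Labels are renumbered by ascending cluster-mean
coherence coefficient, which makes the output deterministic. Split-half
stability re-runs the regression and clustering on odd- and even-indexed
trials (1-based within session) and matches labels across halves by the
best of the 3! permutations; the chance level of that statistic is
computed by brute-force label shuffling at the observed cluster sizes.

## Confidence signatures

The accuracy decoder's out-of-sample probability-correct is the per-trial
confidence signal. For binary high/low reports the signal is thresholded
at the quantile that makes 61% of choices high-confidence, matching the
human study this analysis parallels; ties break by strict inequality.
Signature tables summarize confidence by motion strength and accuracy
(cells under 4 trials masked), and by RT (trials sorted by RT, boxcar of
300 trials, truncated shrinking windows at the edges so the curve spans
the full RT range). `signature_checks` condenses the six canonical
orderings into signed differences and Spearman correlations, with
matched-RT variants computed inside RT quintile bins.

## Pulse dynamics

Spikes are counted in 100 ms windows advanced in 20 ms steps from −60 to
+800 ms around pulse onset, using only pulse trials with RT ≥ window
start + 150 ms. Counts are standardized within each (signed coherence,
window) cell — sign retained because the base motion differs — and the
left-minus-right pulse-direction difference, averaged within cluster and
baseline-subtracted over t ∈ [0, 0.2] s, gives the cluster curve D_K(t).
The decay model assumes Normal(μ, σ) onset latency and exponential
dissipation at rate α:

    f(t) = d · exp(μα + σ²α²/2 − αt) · Φ(t | μ + σ²α, σ),

the closed-form solution of df/dt = −αf + d·N(t | μ, σ) (verified by
numerical differentiation in the tests). Least squares over the curve
points, multi-started on an α grid spanning [−2, 200] — generous at the
top because near-instant dissipation fits α in the hundreds, flagged when
it lands on the bound. Cluster comparisons resample neurons with
replacement and refit.

## Latency estimation

Per neuron: direction AUC on counts in [0.100, 0.400) s (correct trials,
RT > 450 ms strictly, |coherence| > 10%) gates eligibility at AUC > 0.55.
The CUSUM of per-bin (25 ms) preferred-minus-null mean-count differences
is fit with a continuous dogleg — a free flat level joined to a line at
breakpoint t1 ∈ [0, 0.5] s — by exhaustive grid search at bin resolution
plus bounded golden-section refinement; t1 is the latency. Continuity at
the breakpoint is imposed because a jump makes t1 unidentifiable under
noise; a series whose dogleg explains essentially nothing beyond a flat
line is flagged undefined. Population latencies bootstrap sessions,
average the AUC(t) curves, and dogleg-fit each sample; the divergence
order of two signals is the proportion of samples in which one breakpoint
exceeds the other.

## Cross-correlations

Group-mean counts in 25 ms motion-onset-aligned bins (valid until 50 ms
before the saccade) are z-scored within (bin, signed coherence, session)
and concatenated across sessions. Pearson correlations at all bin pairs
(tx, ty) in [0.2, 0.8] s form the heatmap (cells with fewer than 5 common
valid trials masked, masked cells excluded unweighted from ROI means).
The asymmetry statistic is mean ρ over ROI1 (tx > ty) minus ROI2; its
null distribution permutes the trial order of the second series only
(200 shuffles), one-sided by default since the hypothesis is directional.
The Min-neuron variant correlates a cluster's residuals against the
difference of left- and right-preferring Min group residuals.

## The synthetic-data generator

The generator is the package's test bed: it produces sessions with the
statistical structure every downstream stage assumes, plus the planted
truth needed for recovery tests.

*Behavior* comes from the race model. The default parameters
(κ = 14, B = 0.6, a = 1.0 after d = 0.2 s, C0 = 0, μ_nd = 0.35 s,
σ_nd = 0.06 s, B_reflect = −0.3) put mean RT near 0.6 s, accuracy near
0.85, and — because the bound is low relative to the diffusion noise —
make errors at strong motion early and fast, the empirically observed
error chronometric and a prerequisite for the error-trial confidence
signatures.

*Neurons* are inhomogeneous Poisson processes. Each neuron's rate ramps
linearly from a common 20 Hz baseline at motion onset to a trial-specific
presaccadic target

    baseline + b_coh · e + b_rt · RT + b_choice · 1[left],

floored at zero (the firing-rate analogue of the reflecting bound; a
configuration driving more than 1% of neuron-trials negative is
rejected). Coefficients are drawn per neuron around three planted cluster
means, by default (−4, 14, 3), (0, 0, 4), (6, −14, 3) Hz with 1.5 Hz
spread — an evidence-negative/time-positive cluster, a stereotyped
cluster, and an evidence-positive/time-negative cluster, ordered by
ascending coherence coefficient to match the downstream label rule.

The evidence regressor `e` is, by default, the race model's *terminal
momentary evidence*: an exponential moving average (time constant 0.1 s)
of the leftward-minus-rightward per-step input at decision termination,
expressed in coherence units (E[e] = C + C0; with noise disabled it
equals C + C0 exactly). This matters. A population that encodes the
stimulus coherence veridically lets a 150-neuron decoder read the signed
stimulus almost perfectly, and an accuracy decoder then *correctly*
predicts low accuracy for strong-motion errors — inverting the
empirically observed rise of confidence with motion strength on error
trials. Terminal evidence instead carries the selection bias intrinsic to
a race: an error at strong opposing motion can only have terminated
because recent evidence looked choice-congruent, so the encoded evidence
on errors is nearly independent of the true coherence while the fast
error RTs push decoded confidence up with |C|. A veridical-stimulus mode
remains available (`encode_terminal_evidence=False`), as does additive
trial-level drift variability (`evidence_noise_sd`).

*Shared noise* is a boxcar-smoothed (50 ms) unit-variance Gaussian latent
per trial, scaled to 2 Hz and added to every neuron's rate with a
cluster-specific lag (cluster k delayed by (k−1) × 50 ms), producing the
asymmetric cross-cluster correlations the lagged analysis measures.

*Pulses* occur on half the trials, onset drawn from an exponential
truncated to [0.1, 0.8] s (time constant 0.4 s), direction random. They
perturb rates additively with the same latency-convolved exponential
shape the pulse analysis fits — planted dissipation rates (0.3, 3, 30)/s
across clusters, onset latency 0.3 s so the fast cluster's transient
clears the analysis' [0, 0.2] s baseline interval, and amplitudes
(2, 4, 10) Hz chosen so the three clusters' peak standardized effects are
comparable. Pulses do not feed back on behavior.

*Spike synthesis* discretizes each trial into 5 ms bins from −0.2 s to
RT + 0.2 s, draws Poisson counts from the floored rate, and places spike
times uniformly within bins. Coherence 0 trials record a Bernoulli(1/2)
rewarded direction (the ±0 distinction of the task cannot live in a float
column).

*Prior-task sessions* contain a single Tin neuron. Per block the
probability that the rewarded direction is leftward equals the block
prior (0.2, 0.5 or 0.8); the race bias C0 shifts by 0.2 × (prior − 0.5)
(the subject exploits the base rate) and the neuron's presaccadic target
gains 16 × (prior − 0.5) Hz. Both gains are defaults chosen to make the
planted effect clearly resolvable by a one-neuron decoder at a few
thousand trials per session.

### Study configurations

Three named configurations package the conditions under which specific
analyses have adequate power: `cluster_study_config` (cluster separation
large relative to regression noise — the regime where split-half
assignments are fully stable), `pulse_study_config` (a slower race so
late pulse-aligned windows keep surviving trials, higher baseline rate,
stronger pulse amplitudes), and `xcorr_study_config` (the same long-RT
conditions with a stronger, 100 ms-lag shared latent). The default
configuration is used for the decoding and signature analyses; its
decoder AUC for accuracy lands near 0.6 — the low end of the range such
decoders reach on real recordings — because raising it further would
require more behaviorally separable errors than the fast-error regime
allows.

### What the generator does not emulate

Real sessions differ in ways that bound what green tests imply: neuron
counts and firing statistics vary across sessions (no Fano-factor
matching); pulses influence real behavior; real coherence coding need not
be linear; non-stationarities (drift, adaptation) are absent; and the
single-session generator has no cross-session heterogeneity, so pooled
statistics here are cleaner than pooled statistics on real data. Passing
tests demonstrate that the estimators recover what was planted under the
model's assumptions, not that the assumptions hold in tissue.

## Problem sizes and runtime

Analyses run at the sizes a single core handles comfortably: 4,000-trial,
150-neuron sessions for decoding and signatures; 6,000 trials for race
recovery; 2,000-trial, 45-neuron sessions for pulse and correlation
analyses; bootstrap sizes 200–500 where the reference procedure uses
5,000 (defaults expose the larger values). The full test suite runs in
roughly ten minutes; `scripts/acceptance.py` in about six.

## Known limitations

* The race likelihood is simulation-based; very small σ_nd (< 2 ms) makes
  the RT density spiky relative to the 1 ms grid.
* κ and B trade off along a shallow likelihood ridge; recovery of κ to a
  few percent needs either more trials or a longer polish stage.
* The dogleg latency is biased late when the post-break trend is convex
  (as for CUSUM of a ramp rather than a step); planted-step recovery is
  unbiased within one bin.
* `bootstrap_alpha_compare` refits per resample with multi-start least
  squares; pathological resamples that fail to fit are dropped and
  counted, which can bias the proportion when failures correlate with α.
* With k > 3 clusters the label-ordering rule (ascending mean coherence
  coefficient) remains deterministic but no longer maps onto the
  three-part evidence/stereotyped/time taxonomy.
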