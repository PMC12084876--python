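# popconf

Decoding decision confidence from heterogeneous parietal population
activity.

## The problem

When a decision is formed by a race between two bounded evidence
accumulators, the winning accumulator ends every trial at its bound — so
its *average* firing rate carries no information about whether the choice
was right. Yet confidence (the decision-maker's estimate of being
correct) covaries lawfully with evidence strength, reaction time and
accuracy. `popconf` implements the analysis chain that resolves this
tension for populations of parietal (LIP) neurons recorded during the
reaction-time random-dot-motion task: individual neurons deviate
systematically from the stereotyped average — some track momentary
evidence, some elapsed decision time — and a linear readout of that
heterogeneity predicts choice accuracy on single trials.

The package is aimed at systems/computational neuroscientists who want to
run this chain on their own trial/spike tables or on its built-in
synthetic sessions with planted ground truth.

## What it implements

* **Race model** (`popconf.race`) — two anti-correlated accumulators
  (ρ = −0.7) with drift ±κΔt(C + C0), a step urgency signal u(t) = aΔt
  after delay d, a reflecting lower bound B_reflect, and an absorbing
  upper bound B; RT = decision time + Normal(μ_nd, σ_nd) non-decision
  time. Parameters Θ = {κ, B, a, d, C0, μ_nd, σ_nd} are fit to
  single-trial (coherence, choice, RT) data by maximum likelihood, where
  the RT densities come from Epanechnikov-kernel-smoothed simulations
  convolved with the non-decision density, optimized by bounded Powell
  search with common random numbers.
* **Decoders** (`popconf.decode`) — 10-fold cross-validated logistic
  decoders of accuracy (logit p(correct) = β_conf·S̃ + β0), choice and RT
  class from standardized presaccadic spike counts; Mann–Whitney AUC;
  bootstrap and paired-t inference; coding directions, cosine similarity,
  projections, time-resolved AUC.
* **Clustering** (`popconf.cluster`) — per-neuron OLS of presaccadic
  counts on (coherence, RT, choice), k-means on the coefficient triples
  with labels ordered by the coherence coefficient, split-half stability,
  cluster-restricted decoding, control-task separation tests.
* **Signatures** (`popconf.signatures`) — the decoder's out-of-sample
  p(correct) as a confidence signal; 61%-quantile thresholding; the six
  behavioral signatures of confidence versus motion strength, accuracy
  and RT; the biased-prior single-neuron analysis.
* **Pulse dynamics** (`popconf.pulse`) — pulse-triggered standardized
  response differences, cluster curves, and the latency-convolved
  exponential-dissipation fit f(t) = d·exp(μα + σ²α²/2 − αt)·Φ(t|μ+σ²α, σ)
  with neuron-bootstrap comparisons of the dissipation rate α.
* **Latency** (`popconf.latency`) — CUSUM of direction-selective count
  differences with a dogleg (flat-then-line) breakpoint fit per neuron,
  and bootstrap population latencies from time-resolved AUC curves.
* **Cross-correlations** (`popconf.xcorr`) — lagged trial-by-trial
  Pearson correlations between standardized residuals of neuron groups,
  with a directional ROI permutation test for temporal asymmetry.
* **Synthetic sessions** (`popconf.synth`) — a generator that couples the
  race model's behavior to inhomogeneous-Poisson populations with planted
  three-cluster coefficient structure, lag-shifted shared noise,
  pulse transients, and full planted-truth output. See
  `docs/methods.md` for the generative model and its deliberate
  departures from a veridical stimulus code.

Session data lives in plain CSV directories (`trials.csv`, `spikes.csv`,
`neurons.csv`) wrapped by `SessionBundle`; spike times are motion-onset
relative, windows half-open, saccade alignment computed as t − RT.

## Worked example

```python
from popconf.synth import PopulationGenConfig, generate_session
from popconf.signatures import decode_confidence, signature_checks
from popconf.decode import auc

cfg = PopulationGenConfig(n_trials=4000, n_neurons_per_cluster=(50, 50, 50), seed=1)
bundle, truth = generate_session(cfg)

trials, conf = decode_confidence(bundle, seed=0)   # oos p(correct), left choices
print(round(auc(conf, trials["correct"].astype(int)).auc, 3))
for k, v in signature_checks(conf, trials).items():
    print(f"{k:38s} {v:+.3f}")
```

Output:

```
0.638
d_correct_minus_error                  +0.085
rho_coherence_correct                  +0.219
rho_coherence_error                    +0.053
rho_rt                                 -0.433
d_correct_minus_error_matched_rt       +0.049
rho_coherence_matched_rt               +0.040
```

The decoder separates correct from error trials (AUC 0.64) even though
every trial ends with the winning accumulator at its bound. The six
statistics are the behavioral hallmarks of confidence: higher on correct
trials, increasing with motion strength on both corrects and errors,
decreasing with RT, and — at matched RT — still higher on corrects and
still increasing with motion strength.

A thin CLI wraps the same stages for shell use:

```bash
popconf --seed 3 simulate --config gen.yaml --out session/
popconf --seed 3 decode --session session/ --target accuracy --out results/
popconf --seed 3 cluster --session session/ --out results/
```

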