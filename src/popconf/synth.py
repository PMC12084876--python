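"""Synthetic session generator with planted ground truth.

Sessions emulate simultaneous parietal population recordings in the
reaction-time random-dot-motion task:

* choices and RTs are drawn from the race model (:mod:`popconf.race`);
* each Tin neuron is an inhomogeneous Poisson process whose firing rate
  ramps linearly from a common baseline at motion onset to a
  trial-specific presaccadic target
  ``baseline + b_coh*C + b_rt*RT + b_choice*1[left]``, with per-neuron
  coefficients drawn around planted cluster means (three clusters);
* a temporally smoothed Gaussian latent, shared across neurons within a
  trial and lag-shifted per cluster, produces asymmetric cross-cluster
  noise correlations;
* on ~half the trials a brief motion pulse adds a signed, cluster-specific
  transient to the rate, with Normal-latency onset and exponential
  dissipation (the same functional form the pulse analysis fits);
* rates are floored at zero (the firing-rate analogue of the race
  model's reflecting bound), keeping counts integer Poisson draws.

Everything is reproducible from the config seed, and the planted
coefficients, cluster labels, race parameters and dissipation rates are
returned for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from popconf.data import DEFAULT_COHERENCE_SET, SessionBundle
from popconf.pulse import decay_f
from popconf.race import RaceParams, simulate_trials

logger = logging.getLogger(__name__)

BIN = 0.005          # rate discretization for spike generation, s
PRE = 0.2            # spikes generated from -PRE s before motion onset
POST = 0.2           # ... to POST s after the saccade


def default_race_params() -> RaceParams:
    """Race parameters producing realistic chronometric/psychometric data.

    The bound is low relative to the diffusion noise so that errors at
    strong motion are early, noise-driven, and therefore fast — the
    empirically observed error-RT pattern.
    """
    return RaceParams(
        kappa=14.0, B=0.6, a=1.0, d_urg=0.2, C0=0.0,
        mu_nd=0.35, sigma_nd=0.06, B_reflect=-0.3,
    )


@dataclass
class PopulationGenConfig:
    """Conditions of a generated session.

    Cluster order is by ascending ``b_coh`` so that planted labels match
    the downstream label-ordering rule. Coefficients are on the rate
    scale (Hz per unit regressor); ``pulse_effect`` entries are
    (amplitude Hz, onset latency s, dissipation rate 1/s) per cluster.
    """

    n_trials: int = 4000
    coherence_set: tuple = DEFAULT_COHERENCE_SET
    race: RaceParams = field(default_factory=default_race_params)
    n_neurons_per_cluster: tuple = (50, 50, 50)
    baseline_rate: float = 20.0
    coef_means: tuple = ((-4.0, 14.0, 3.0), (0.0, 0.0, 4.0), (6.0, -14.0, 3.0))
    coef_sd: float = 1.5
    evidence_noise_sd: float = 0.0
    encode_terminal_evidence: bool = True
    evidence_tau: float = 0.1
    # amplitudes scaled so the three clusters' peak standardized effects are
    # comparable despite very different dissipation rates; onset latency sits
    # past the 0-0.2 s baseline interval of the pulse analysis
    pulse_effect: tuple = ((2.0, 0.3, 0.3), (4.0, 0.3, 3.0), (10.0, 0.3, 30.0))
    pulse_fraction: float = 0.5
    shared_noise_sd: float = 2.0
    shared_noise_lag: float = 0.05
    shared_noise_weights: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 100:
            raise ValueError("n_trials must be >= 100 (10 x number of CV folds)")


@dataclass
class PlantedTruth:
    """Ground truth of a generated session, aligned with neuron ids."""

    coefficients: pd.DataFrame   # neuron_id, cluster, b_coh, b_rt, b_choice
    race: RaceParams
    pulse_alpha: dict            # cluster -> dissipation rate
    shared_noise_lag: float

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "coefficients": self.coefficients.to_dict(orient="list"),
            "race": self.race.to_dict(),
            "pulse_alpha": {str(k): v for k, v in self.pulse_alpha.items()},
            "shared_noise_lag": self.shared_noise_lag,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _simulate_behavior(cfg: PopulationGenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial coherence, choice, rt from the race model.

    Each trial's drift uses the *perceived* coherence ``C + eps`` with
    trial-level evidence noise eps ~ Normal(0, evidence_noise_sd); the
    same perceived value later drives the neurons' rate targets, so
    behavior and neural activity share the evidence fluctuation.
    Censored trials (no bound crossing) are re-simulated.
    """
    coh_levels = np.asarray(cfg.coherence_set, dtype=float)
    coh = rng.choice(coh_levels, size=cfg.n_trials)
    eps = (
        rng.normal(0.0, cfg.evidence_noise_sd, size=cfg.n_trials)
        if cfg.evidence_noise_sd > 0 else np.zeros(cfg.n_trials)
    )
    cols = ["choice", "decision_time", "rt", "censored", "evidence"]
    sims = simulate_trials(
        cfg.race, coh + eps, 1, seed=rng, full_output=True, track_evidence=True,
        evidence_tau=cfg.evidence_tau,
    )
    for _ in range(20):
        bad = sims["censored"].to_numpy()
        if not bad.any():
            break
        redo = simulate_trials(
            cfg.race, coh[bad] + eps[bad], 1, seed=rng,
            full_output=True, track_evidence=True, evidence_tau=cfg.evidence_tau,
        )
        sims.loc[bad, cols] = redo[cols].to_numpy()
    if sims["censored"].any():
        raise RuntimeError("censored trials persisted after re-simulation")
    seen = (
        sims["evidence"].to_numpy() if cfg.encode_terminal_evidence else coh + eps
    )
    out = pd.DataFrame(
        {
            "trial_id": np.arange(cfg.n_trials),
            "coherence": coh,
            "coherence_seen": seen,
            "choice": sims["choice"].to_numpy(),
            "rt": sims["rt"].to_numpy(),
        }
    )
    correct = np.where(
        out["coherence"] > 0, out["choice"] == "left",
        np.where(out["coherence"] < 0, out["choice"] == "right",
                 rng.random(len(out)) < 0.5),
    )
    out["correct"] = correct.astype(bool)
    return out


def _pulse_schedule(
    n: int, fraction: float, rng: np.random.Generator,
    t_min: float = 0.1, t_max: float = 0.8, tau: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Pulse onsets (NaN where absent) from a truncated exponential."""
    has = rng.random(n) < fraction
    u = rng.random(n)
    # inverse-CDF of an exponential truncated to [t_min, t_max]
    cdf_span = 1 - np.exp(-(t_max - t_min) / tau)
    onset = t_min - tau * np.log(1 - u * cdf_span)
    onset = np.where(has, onset, np.nan)
    direction = np.where(rng.random(n) < 0.5, "left", "right")
    return onset, np.where(has, direction, None)


def _draw_neurons(cfg: PopulationGenConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    nid = 0
    for k, (n_k, means) in enumerate(zip(cfg.n_neurons_per_cluster, cfg.coef_means), 1):
        coefs = rng.normal(loc=means, scale=cfg.coef_sd, size=(n_k, 3))
        for b_coh, b_rt, b_choice in coefs:
            rows.append(
                {"neuron_id": nid, "cluster": k,
                 "b_coh": b_coh, "b_rt": b_rt, "b_choice": b_choice}
            )
            nid += 1
    return pd.DataFrame(rows)


def _shared_latent(
    n_trials: int, n_bins: int, rng: np.random.Generator, smooth_bins: int = 10
) -> np.ndarray:
    """Unit-variance smooth Gaussian latent per (trial, bin)."""
    z = rng.standard_normal((n_trials, n_bins + smooth_bins))
    kern = np.ones(smooth_bins) / smooth_bins
    sm = np.apply_along_axis(lambda r: np.convolve(r, kern, mode="valid"), 1, z)
    sm = sm[:, :n_bins]
    return sm / np.sqrt((kern ** 2).sum())


def generate_session(cfg: PopulationGenConfig) -> tuple[SessionBundle, PlantedTruth]:
    """Generate one synthetic session and its planted ground truth."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_beh, rng_neu, rng_spk = (np.random.default_rng(s) for s in ss.spawn(3))

    trials = _simulate_behavior(cfg, rng_beh)
    coh_seen = trials.pop("coherence_seen").to_numpy()
    onset, direction = _pulse_schedule(len(trials), cfg.pulse_fraction, rng_beh)
    trials["pulse_onset"] = onset
    trials["pulse_direction"] = direction
    trials["prior_block"] = np.nan
    trials["session_id"] = "synth"

    neurons_truth = _draw_neurons(cfg, rng_neu)
    rts = trials["rt"].to_numpy()
    coh = coh_seen  # neurons encode the perceived evidence
    left = (trials["choice"] == "left").to_numpy().astype(float)

    # presaccadic target rate per (neuron, trial)
    B = neurons_truth[["b_coh", "b_rt", "b_choice"]].to_numpy()
    targets = cfg.baseline_rate + B @ np.vstack([coh, rts, left])   # (n_neurons, n_trials)
    frac_neg = float((targets < 0).mean())
    if frac_neg > 0.01:
        raise ValueError(
            f"configuration yields negative mean rates on {frac_neg:.1%} of neuron-trials"
        )

    t_hi = float(rts.max()) + POST
    grid = np.arange(-PRE, t_hi, BIN)
    n_bins = grid.size
    tt = grid[None, :]
    # linear ramp from baseline at motion onset to the target at the saccade
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp = np.clip(tt / rts[:, None], 0.0, 1.0)
    valid = tt < (rts[:, None] + POST)

    lag_bins = int(round(cfg.shared_noise_lag / BIN))
    if cfg.shared_noise_sd > 0:
        z = _shared_latent(len(trials), n_bins + 2 * lag_bins, rng_spk)
    per_cluster_noise = {}
    per_cluster_pulse = {}
    has_pulse = trials["pulse_onset"].notna().to_numpy()
    sign = np.where(trials["pulse_direction"].to_numpy() == "left", 1.0, -1.0)
    for k, (amp, lat, alpha) in enumerate(cfg.pulse_effect, 1):
        if cfg.shared_noise_sd > 0:
            # cluster k's rate at bin b tracks the latent at b - shift,
            # so earlier clusters lead later ones
            shift = (k - 1) * lag_bins
            per_cluster_noise[k] = (
                cfg.shared_noise_sd * cfg.shared_noise_weights[k - 1]
                * np.roll(z[:, :n_bins], shift, axis=1)
            )
            if shift:
                per_cluster_noise[k][:, :shift] = 0.0
        else:
            per_cluster_noise[k] = 0.0
        pulse = np.zeros((len(trials), n_bins))
        if has_pulse.any() and amp != 0:
            rel = tt - trials["pulse_onset"].to_numpy()[:, None]
            rows = has_pulse
            pulse[rows] = sign[rows, None] * decay_f(rel[rows], amp, lat, 0.05, alpha)
        per_cluster_pulse[k] = pulse

    nid_col, tid_col, st_col = [], [], []
    trial_ids = trials["trial_id"].to_numpy()
    for _, nr in neurons_truth.iterrows():
        k = int(nr["cluster"])
        rate = (
            cfg.baseline_rate
            + (targets[int(nr["neuron_id"])][:, None] - cfg.baseline_rate) * ramp
            + per_cluster_noise[k]
            + per_cluster_pulse[k]
        )
        lam = np.clip(rate, 0.0, None) * BIN * valid
        counts = rng_spk.poisson(lam)
        ti, bi = np.nonzero(counts)
        reps = counts[ti, bi]
        times = np.repeat(grid[bi], reps) + rng_spk.random(int(reps.sum())) * BIN
        nid_col.append(np.full(times.size, int(nr["neuron_id"]), dtype=np.int32))
        tid_col.append(np.repeat(trial_ids[ti], reps).astype(np.int32))
        st_col.append(times.astype(np.float64))

    spikes = pd.DataFrame(
        {
            "neuron_id": np.concatenate(nid_col),
            "trial_id": np.concatenate(tid_col),
            "spike_time": np.concatenate(st_col),
        }
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": neurons_truth["neuron_id"].astype(int),
            "session_id": "synth",
            "neuron_class": "Tin",
            "cluster": np.nan,
        }
    )
    bundle = SessionBundle(trials, spikes, neurons, coherence_set=cfg.coherence_set)
    truth = PlantedTruth(
        coefficients=neurons_truth,
        race=cfg.race,
        pulse_alpha={k + 1: cfg.pulse_effect[k][2] for k in range(3)},
        shared_noise_lag=cfg.shared_noise_lag,
    )
    return bundle, truth


def pulse_study_config(seed: int = 7, n_trials: int = 2000) -> PopulationGenConfig:
    """Session conditions for the pulse-dynamics analyses.

    A slower-terminating race (higher bound, weak urgency) lengthens RTs
    so that late pulse-aligned windows retain enough surviving trials,
    and the baseline rate is raised to keep rates non-negative over the
    longer ramps.
    """
    race = RaceParams(
        kappa=14.0, B=0.9, a=0.5, d_urg=0.3, C0=0.0,
        mu_nd=0.35, sigma_nd=0.06, B_reflect=-0.3,
    )
    return PopulationGenConfig(
        n_trials=n_trials, n_neurons_per_cluster=(15, 15, 15), seed=seed,
        race=race, baseline_rate=32.0,
        pulse_effect=((5.0, 0.3, 0.3), (8.0, 0.3, 3.0), (20.0, 0.3, 30.0)),
    )


def xcorr_study_config(seed: int = 9, n_trials: int = 2000) -> PopulationGenConfig:
    """Session conditions for the lagged cross-correlation analyses.

    Long-RT race conditions (many valid bins per trial) with a stronger,
    longer-lag shared latent so that the cluster-pair asymmetries are
    detectable at a few thousand trials.
    """
    cfg = pulse_study_config(seed=seed, n_trials=n_trials)
    return replace(cfg, shared_noise_sd=4.0, shared_noise_lag=0.1)


def cluster_study_config(seed: int = 7, n_trials: int = 3000) -> PopulationGenConfig:
    """Session conditions for cluster-recovery analyses.

    Cluster separation is large relative to both the within-cluster
    coefficient spread and the regression estimation noise, the regime in
    which split-half cluster assignments should be fully stable.
    """
    return PopulationGenConfig(
        n_trials=n_trials, n_neurons_per_cluster=(12, 12, 12), seed=seed,
        coef_means=((-8.0, 20.0, 3.0), (0.0, 0.0, 4.0), (8.0, -20.0, 3.0)),
        coef_sd=0.5, shared_noise_sd=1.0, baseline_rate=25.0,
    )


def generate_prior_session(
    cfg: PopulationGenConfig,
    priors: tuple = (0.5, 0.2, 0.8),
    block_sizes: tuple = (400, 400, 400),
    prior_rate_gain: float = 16.0,
    prior_c0_gain: float = 0.2,
    seed: int | None = None,
) -> SessionBundle:
    """Single-neuron session from the biased-prior task.

    Per block, the probability that the rewarded (and hence prevalent)
    motion direction is leftward equals the block prior; the race model's
    bias C0 shifts with the prior (the subject exploits the base rate),
    and the neuron's presaccadic rate carries a prior-dependent offset
    ``prior_rate_gain * (prior - 0.5)``.
    """
    for p in priors:
        if p not in (0.2, 0.5, 0.8):
            raise ValueError(f"prior {p} outside {{0.2, 0.5, 0.8}}")
    if any(b <= 0 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mags = np.unique(np.abs(np.asarray(cfg.coherence_set)))

    rows = []
    tid = 0
    for prior, size in zip(priors, block_sizes):
        race = RaceParams(
            **{**cfg.race.to_dict(), "C0": cfg.race.C0 + prior_c0_gain * (prior - 0.5)}
        )
        mag = rng.choice(mags, size=size)
        sgn = np.where(rng.random(size) < prior, 1.0, -1.0)
        coh = mag * sgn
        for cv in np.unique(coh):
            n = int((coh == cv).sum())
            sims = simulate_trials(race, [cv], int(n * 1.1) + 20, seed=rng).iloc[:n]
            for _, r in sims.iterrows():
                if cv == 0:
                    # reward direction at 0% coherence follows the block prior
                    rewarded_left = rng.random() < prior
                    correct = (r["choice"] == "left") == rewarded_left
                else:
                    correct = r["choice"] == ("left" if cv > 0 else "right")
                rows.append(
                    {
                        "trial_id": tid, "coherence": cv, "choice": r["choice"],
                        "correct": bool(correct), "rt": r["rt"],
                        "pulse_onset": np.nan, "pulse_direction": None,
                        "prior_block": prior, "session_id": f"prior_{seed}",
                    }
                )
                tid += 1
    trials = pd.DataFrame(rows).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    trials = trials.reset_index(drop=True)
    trials["trial_id"] = np.arange(len(trials))

    # single Tin neuron with evidence- and time-sensitive presaccadic rate
    b_coh, b_rt, b_choice = cfg.coef_means[2]
    coh = trials["coherence"].to_numpy()
    rts = trials["rt"].to_numpy()
    left = (trials["choice"] == "left").to_numpy().astype(float)
    prior_off = prior_rate_gain * (trials["prior_block"].to_numpy() - 0.5)
    targets = cfg.baseline_rate + b_coh * coh + b_rt * rts + b_choice * left + prior_off

    t_hi = float(rts.max()) + POST
    grid = np.arange(-PRE, t_hi, BIN)
    tt = grid[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp = np.clip(tt / rts[:, None], 0.0, 1.0)
    valid = tt < (rts[:, None] + POST)
    rate = cfg.baseline_rate + (targets[:, None] - cfg.baseline_rate) * ramp
    lam = np.clip(rate, 0.0, None) * BIN * valid
    counts = rng.poisson(lam)
    ti, bi = np.nonzero(counts)
    reps = counts[ti, bi]
    times = np.repeat(grid[bi], reps) + rng.random(int(reps.sum())) * BIN
    spikes = pd.DataFrame(
        {
            "neuron_id": np.zeros(times.size, dtype=np.int32),
            "trial_id": np.repeat(trials["trial_id"].to_numpy()[ti], reps),
            "spike_time": times,
        }
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": [0], "session_id": trials["session_id"].iloc[0],
            "neuron_class": "Tin", "cluster": [np.nan],
        }
    )
    return SessionBundle(trials, spikes, neurons, coherence_set=cfg.coherence_set)
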