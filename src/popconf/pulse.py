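"""Transient influence of brief motion pulses on Tin activity.

For each neuron, spikes are counted in 100 ms windows advanced in 20 ms
steps relative to pulse onset; counts are standardized within each
(signed coherence, window) cell, and the mean difference between
leftward- and rightward-pulse trials gives the pulse-triggered response
delta per neuron and time. Cluster averages, baseline-subtracted over
the pre-effect interval [0, 0.2] s, are fit with a decay model: the
pulse's influence arrives with Normal(mu, sigma) latency and dissipates
exponentially at rate alpha, i.e.

    df/dt = -alpha * f(t) + d * N(t | mu, sigma)

whose closed form is

    f(t) = d * exp(mu*alpha + sigma^2 alpha^2 / 2 - alpha*t)
             * Phi(t | m, sigma),        m = mu + sigma^2 * alpha.

Dissipation rates are compared across clusters by resampling neurons
with replacement and refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from popconf.data import SessionBundle
from popconf.cluster import ClusterAssignment

logger = logging.getLogger(__name__)

ALPHA_BOUNDS = (-2.0, 200.0)


@dataclass
class PulseResponseCurve:
    """Pulse-triggered response difference over window-start times."""

    t: np.ndarray            # window-start times, s
    delta: np.ndarray        # per-neuron (n_neurons, n_t) or cluster (n_t,)
    neuron_ids: np.ndarray | None = None
    n_trials: np.ndarray | None = None
    baseline: float | None = None
    D: np.ndarray | None = None   # baseline-subtracted cluster curve


@dataclass
class PulseDecayFit:
    d: float
    mu: float
    sigma: float
    alpha: float
    sse: float
    converged: bool = True

    @property
    def m(self) -> float:
        return self.mu + self.sigma ** 2 * self.alpha


def decay_f(t, d: float, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Latency-convolved exponential-dissipation response function."""
    t = np.asarray(t, dtype=float)
    m = mu + sigma ** 2 * alpha
    arg = mu * alpha + 0.5 * (sigma * alpha) ** 2 - alpha * t \
        + stats.norm.logcdf(t, loc=m, scale=sigma)
    return d * np.exp(np.clip(arg, -700.0, 700.0))


def pulse_delta_response(
    bundle: SessionBundle,
    window_len: float = 0.100,
    step: float = 0.020,
    t_range: tuple = (-0.060, 0.800),
    rt_margin: float = 0.150,
    neuron_ids=None,
    min_per_cell: int = 2,
) -> PulseResponseCurve:
    """Left-minus-right pulse response delta per neuron and window.

    Only pulse trials whose RT exceeds ``t + rt_margin`` enter the
    average at window start ``t``. Standardization is within each
    (signed coherence, window) cell; cells with fewer than
    ``min_per_cell`` trials are dropped from that window's mean.
    """
    trials = bundle.trials
    pulse = trials[trials["pulse_onset"].notna()].copy()
    if len(pulse) == 0:
        raise ValueError("bundle has no pulse trials")
    neuron_ids = bundle.tin_ids if neuron_ids is None else np.asarray(neuron_ids)
    ts = np.round(np.arange(t_range[0], t_range[1] + step / 2, step), 9)

    sp = bundle.spikes[bundle.spikes["neuron_id"].isin(neuron_ids)]
    sp = sp[sp["trial_id"].isin(pulse["trial_id"])]
    info = pulse.set_index("trial_id")
    onset = info["pulse_onset"]
    # re-reference spikes to pulse onset once
    rel = sp["spike_time"].to_numpy() - onset.loc[sp["trial_id"]].to_numpy()

    trial_ids = pulse["trial_id"].to_numpy()
    coh = info["coherence"].loc[trial_ids].to_numpy()
    rts = info["rt"].loc[trial_ids].to_numpy()
    is_left = (info["pulse_direction"].loc[trial_ids] == "left").to_numpy()

    ti = pd.Categorical(sp["trial_id"], categories=trial_ids).codes
    ni = pd.Categorical(sp["neuron_id"], categories=neuron_ids).codes

    n_nr, n_t = len(neuron_ids), len(ts)
    delta = np.full((n_nr, n_t), np.nan)
    n_used = np.zeros(n_t, dtype=int)
    for it, t0 in enumerate(ts):
        ok_trial = rts >= t0 + rt_margin
        if ok_trial.sum() < 2 * min_per_cell:
            continue
        in_win = (rel >= t0) & (rel < t0 + window_len)
        counts = np.zeros((len(trial_ids), n_nr))
        np.add.at(counts, (ti[in_win], ni[in_win]), 1.0)
        counts = counts[ok_trial]
        c_coh = coh[ok_trial]
        c_left = is_left[ok_trial]
        z = np.full_like(counts, np.nan)
        for cv in np.unique(c_coh):
            rows = c_coh == cv
            if rows.sum() < min_per_cell:
                continue
            mu = counts[rows].mean(axis=0)
            sd = counts[rows].std(axis=0)
            sd = np.where(sd == 0, np.nan, sd)
            z[rows] = (counts[rows] - mu) / sd
        if np.isnan(z).all():
            continue
        with np.errstate(invalid="ignore"):
            mean_l = np.nanmean(np.where(c_left[:, None], z, np.nan), axis=0)
            mean_r = np.nanmean(np.where(~c_left[:, None], z, np.nan), axis=0)
        delta[:, it] = mean_l - mean_r
        n_used[it] = int(ok_trial.sum())
    return PulseResponseCurve(t=ts, delta=delta, neuron_ids=neuron_ids, n_trials=n_used)


def cluster_pulse_curve(
    curves: PulseResponseCurve,
    assignment: ClusterAssignment,
    K: int,
    baseline_range: tuple = (0.0, 0.2),
) -> PulseResponseCurve:
    """Unweighted cluster mean of per-neuron deltas, baseline-subtracted."""
    members = assignment.members(K)
    members = members[np.isin(members, curves.neuron_ids)]
    if members.size == 0:
        raise ValueError(f"cluster {K} empty")
    rows = np.isin(curves.neuron_ids, members)
    return _aggregate_curve(curves.t, curves.delta[rows], baseline_range, curves.n_trials)


def _aggregate_curve(
    ts: np.ndarray,
    per_neuron: np.ndarray,
    baseline_range: tuple = (0.0, 0.2),
    n_trials=None,
) -> PulseResponseCurve:
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_neuron, axis=0)
    in_base = (ts >= baseline_range[0]) & (ts <= baseline_range[1])
    baseline = float(np.nanmean(mean[in_base]))
    return PulseResponseCurve(
        t=ts, delta=mean, baseline=baseline, D=mean - baseline, n_trials=n_trials
    )


def fit_decay(
    curve: PulseResponseCurve,
    alpha_starts: tuple = (-1.0, 0.0, 1.0, 3.0, 10.0, 30.0, 100.0),
) -> PulseDecayFit:
    """Least-squares fit of {d, mu, sigma, alpha} to a cluster curve.

    Multi-start over a coarse alpha grid spanning both signs; parameters
    at the alpha bound are flagged via the logger.
    """
    t = curve.t
    D = curve.D if curve.D is not None else curve.delta
    ok = np.isfinite(D)
    if ok.sum() < 10:
        raise ValueError("need at least 10 valid curve points")
    tt, yy = t[ok], D[ok]

    lob = np.array([-np.inf, 0.0, 0.01, ALPHA_BOUNDS[0]])
    upb = np.array([np.inf, 0.6, 0.3, ALPHA_BOUNDS[1]])
    scale0 = yy[np.argmax(np.abs(yy))]
    if scale0 == 0:
        scale0 = 1e-3

    best = None
    for a0 in alpha_starts:
        x0 = np.clip(np.array([scale0, 0.2, 0.05, a0]), lob, upb)
        try:
            res = optimize.least_squares(
                lambda x: decay_f(tt, *x) - yy,
                x0, bounds=(lob, upb), max_nfev=400,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("decay fit failed from every start")
    d, mu, sigma, alpha = best.x
    if abs(alpha - ALPHA_BOUNDS[1]) < 1e-6 or abs(alpha - ALPHA_BOUNDS[0]) < 1e-6:
        logger.info("fit_decay: alpha at search bound (%g)", alpha)
    return PulseDecayFit(
        d=float(d), mu=float(mu), sigma=float(sigma), alpha=float(alpha),
        sse=float(2 * best.cost), converged=bool(best.success),
    )


def bootstrap_alpha_compare(
    curves: PulseResponseCurve,
    assignment: ClusterAssignment,
    K_a: int,
    K_b: int,
    n_boot: int = 5000,
    seed: int = 0,
    baseline_range: tuple = (0.0, 0.2),
) -> float:
    """Proportion of neuron-resampled fits with alpha_a > alpha_b."""
    rng = np.random.default_rng(seed)
    rows = {}
    for K in (K_a, K_b):
        members = assignment.members(K)
        members = members[np.isin(members, curves.neuron_ids)]
        if members.size < 3:
            raise ValueError(f"cluster {K} has fewer than 3 neurons")
        rows[K] = np.flatnonzero(np.isin(curves.neuron_ids, members))
    wins = 0
    used = 0
    for _ in range(n_boot):
        alphas = {}
        try:
            for K in (K_a, K_b):
                pick = rng.choice(rows[K], size=rows[K].size, replace=True)
                agg = _aggregate_curve(curves.t, curves.delta[pick], baseline_range)
                alphas[K] = fit_decay(agg).alpha
        except (ValueError, RuntimeError):
            continue
        used += 1
        if alphas[K_a] > alphas[K_b]:
            wins += 1
    if used < n_boot:
        logger.info("bootstrap_alpha_compare: %d/%d fits failed", n_boot - used, n_boot)
    if used == 0:
        raise RuntimeError("all bootstrap fits failed")
    return wins / used
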