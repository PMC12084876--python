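"""Two-accumulator race model with urgency and a reflecting lower bound.

Two anti-correlated drift-diffusion processes, x_L and x_R, accumulate
evidence for left-minus-right and right-minus-left motion. Per time step
of length ``dt``::

    x_L += kappa * dt * (C + C0) + u(t) + eta_L * sqrt(dt)
    x_R += -kappa * dt * (C + C0) + u(t) + eta_R * sqrt(dt)

where (eta_L, eta_R) is a bivariate standard normal pair with correlation
``rho`` (fixed at -0.7), C is the signed motion coherence (leftward
positive), C0 a bias, and u(t) a step urgency signal equal to 0 for
t < d and ``a * dt`` afterwards. Neither process may fall below the
reflecting bound ``B_reflect`` (the non-negative-firing-rate analogue);
the first to reach the upper bound ``B`` fixes choice and decision time.
RT adds a Normal(mu_nd, sigma_nd) non-decision time truncated at 0.

Parameters are fit to single-trial (coherence, choice, rt) data by
simulation-based maximum likelihood: decision-time densities per
(coherence, choice) cell are estimated by Epanechnikov-kernel smoothing
of simulated decision times and convolved with the non-decision-time
density. The objective uses common random numbers (a fixed simulation
seed per evaluation) so it is deterministic given (params, seed), and is
maximized with a bounded derivative-free optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-10
MAX_DECISION_TIME = 10.0


@dataclass
class RaceParams:
    """Race-model parameters.

    Free parameters (fit to data): kappa, B, a, d_urg, C0, mu_nd,
    sigma_nd. Fixed constants: rho (noise correlation, -0.7), dt (step,
    5 ms), B_reflect (lower reflecting bound).
    """

    kappa: float          # signal-to-noise scale
    B: float              # upper (terminating) bound
    a: float              # urgency rise rate, units of evidence / s
    d_urg: float          # urgency onset delay, s
    C0: float             # bias in coherence units
    mu_nd: float          # mean non-decision time, s
    sigma_nd: float       # SD of non-decision time, s
    rho: float = -0.7
    dt: float = 0.005
    B_reflect: float = -0.5

    def __post_init__(self) -> None:
        if not self.B > self.B_reflect:
            raise ValueError("B must exceed B_reflect")
        if self.sigma_nd <= 0 or self.dt <= 0:
            raise ValueError("sigma_nd and dt must be positive")
        if not -1.0 <= self.rho <= 0.0:
            raise ValueError("rho must lie in [-1, 0]")

    def free_vector(self) -> np.ndarray:
        return np.array(
            [self.kappa, self.B, self.a, self.d_urg, self.C0, self.mu_nd, self.sigma_nd]
        )

    def with_free_vector(self, v: Sequence[float]) -> "RaceParams":
        return replace(
            self,
            kappa=float(v[0]), B=float(v[1]), a=float(v[2]), d_urg=float(v[3]),
            C0=float(v[4]), mu_nd=float(v[5]), sigma_nd=float(v[6]),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_trials(
    params: RaceParams,
    coherences: Sequence[float],
    n_per_coh: int = 1,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
    max_t: float = MAX_DECISION_TIME,
    track_min: bool = False,
    full_output: bool = False,
    track_evidence: bool = False,
    evidence_tau: float = 0.1,
) -> pd.DataFrame:
    """Simulate race trials; one row per non-censored trial.

    Returns a DataFrame with columns ``coherence, choice, decision_time,
    rt`` (and ``min_x`` when ``track_min``). Trials that fail to
    terminate within ``max_t`` are censored: excluded with a logged
    count, or, with ``full_output=True``, kept in input order with a
    ``censored`` flag and NaN times. ``noise=False`` is a test hook that
    disables diffusion noise.

    With ``track_evidence=True`` an ``evidence`` column holds the
    leftward momentary evidence at decision termination: an exponential
    moving average (time constant ``evidence_tau``) of the
    left-minus-right per-step input, expressed in coherence units. With
    noise disabled it equals ``C + C0`` exactly; with noise it is a
    selection-biased estimate — trials that terminate leftward did so
    because recent evidence favored left.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coh = np.repeat(np.asarray(coherences, dtype=float), n_per_coh)
    n = coh.size
    dt = params.dt
    sqdt = np.sqrt(dt)
    drift = params.kappa * dt * (coh + params.C0)

    xL = np.zeros(n)
    xR = np.zeros(n)
    active = np.ones(n, dtype=bool)
    dec_step = np.full(n, -1, dtype=np.int64)
    won_left = np.zeros(n, dtype=bool)
    min_x = np.zeros(n)
    ema = 2.0 * drift.copy()   # start at the expected per-step input
    beta = dt / evidence_tau

    # Cholesky factor for correlation rho between the two noise streams.
    c = np.sqrt(1.0 - params.rho ** 2)
    n_steps = int(np.ceil(max_t / dt))
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        t = step * dt
        u = params.a * dt if t >= params.d_urg else 0.0
        if noise:
            z = rng.standard_normal((idx.size, 2))
            eL = z[:, 0]
            eR = params.rho * z[:, 0] + c * z[:, 1]
        else:
            eL = eR = 0.0
        xL[idx] = np.maximum(
            xL[idx] + drift[idx] + u + eL * sqdt, params.B_reflect
        )
        xR[idx] = np.maximum(
            xR[idx] - drift[idx] + u + eR * sqdt, params.B_reflect
        )
        if track_min:
            min_x[idx] = np.minimum(min_x[idx], np.minimum(xL[idx], xR[idx]))
        if track_evidence:
            # leftward-minus-rightward per-step input (urgency cancels)
            inc = 2.0 * drift[idx] + (eL - eR) * sqdt if noise else 2.0 * drift[idx]
            ema[idx] = (1.0 - beta) * ema[idx] + beta * inc
        hitL = xL[idx] >= params.B
        hitR = xR[idx] >= params.B
        done = hitL | hitR
        if done.any():
            d_idx = idx[done]
            dec_step[d_idx] = step
            # ties (both cross in the same step) go to the larger value
            won_left[d_idx] = xL[d_idx] >= xR[d_idx]
            active[d_idx] = False

    censored = int(active.sum())
    if censored:
        logger.info("simulate_trials: %d trials censored at %.1f s", censored, max_t)
    keep = np.ones(n, dtype=bool) if full_output else ~active
    dec_time = np.where(dec_step[keep] > 0, dec_step[keep] * dt, np.nan)
    nd = rng.normal(params.mu_nd, params.sigma_nd, size=int(keep.sum()))
    n_trunc = int((nd < 0).sum())
    if n_trunc > 0.01 * max(nd.size, 1):
        logger.info("non-decision truncation affected %d samples", n_trunc)
    nd = np.maximum(nd, 0.0)
    out = pd.DataFrame(
        {
            "coherence": coh[keep],
            "choice": np.where(won_left[keep], "left", "right"),
            "decision_time": dec_time,
            "rt": dec_time + nd,
        }
    )
    if track_min:
        out["min_x"] = min_x[keep]
    if track_evidence:
        out["evidence"] = ema[keep] / (2.0 * params.kappa * dt)
    if full_output:
        out["censored"] = active[keep]
    return out


@dataclass
class ConditionPdf:
    """Smoothed RT density for one (coherence, choice) cell."""

    grid: np.ndarray       # RT grid, s
    density: np.ndarray    # per-second density values (floored)
    p_choice: float        # probability mass of this choice at this coherence
    coherence: float = np.nan
    choice: str = ""

    def density_at(self, rt: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        d = np.interp(rt, self.grid, self.density, left=DENSITY_FLOOR, right=DENSITY_FLOOR)
        return np.maximum(d, DENSITY_FLOOR)


def _silverman_bandwidth(x: np.ndarray, floor: float) -> float:
    n = x.size
    if n < 2:
        return floor
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        return floor
    return max(0.9 * scale * n ** (-0.2), floor)


def _smooth_decision_times(
    dts: np.ndarray,
    params: RaceParams,
    grid_step: float,
    t_max: float,
    bandwidth: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Epanechnikov-KDE of decision times convolved with the ND density."""
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    if dts.size == 0:
        return grid, np.full(grid.size, DENSITY_FLOOR)
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(dts, params.dt)
    # Histogram on the fine grid, then discrete convolution with the
    # Epanechnikov kernel and the non-decision-time normal density.
    nbins = grid.size
    hist, _ = np.histogram(dts, bins=np.append(grid, grid[-1] + grid_step))
    dens = hist / (dts.size * grid_step)
    m = int(np.ceil(h / grid_step))
    uu = np.arange(-m, m + 1) * grid_step / h
    kern = 0.75 * np.maximum(1 - uu ** 2, 0.0) / h
    kern = kern / (kern.sum() * grid_step)
    dens = np.convolve(dens, kern * grid_step, mode="same")
    # convolve with Normal(mu_nd, sigma_nd); kernel support mu +- 6 sigma
    lo = params.mu_nd - 6 * params.sigma_nd
    hi = params.mu_nd + 6 * params.sigma_nd
    kt = np.arange(np.floor(lo / grid_step), np.ceil(hi / grid_step) + 1) * grid_step
    gk = stats.norm.pdf(kt, params.mu_nd, params.sigma_nd)
    gk = gk / gk.sum()
    full = np.convolve(dens, gk, mode="full")
    # time of full[i] = grid[0] + (i + k0) * grid_step where k0 = kt[0]/grid_step
    offset = int(round(kt[0] / grid_step))
    out = np.full(nbins, 0.0)
    src = np.arange(full.size) + offset
    ok = (src >= 0) & (src < nbins)
    np.add.at(out, src[ok], full[ok])
    return grid, np.maximum(out, DENSITY_FLOOR)


def condition_pdf(
    params: RaceParams,
    coherence: float,
    choice: str,
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
    grid_step: float = 0.001,
    t_max: float = 5.0,
    bandwidth: float | None = None,
) -> ConditionPdf:
    """Kernel-smoothed RT density and choice probability for one cell."""
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    sims = simulate_trials(params, [coherence], n_sim, seed=seed)
    return _pdf_from_sims(sims, params, coherence, choice, grid_step, t_max, bandwidth)


def _pdf_from_sims(
    sims: pd.DataFrame,
    params: RaceParams,
    coherence: float,
    choice: str,
    grid_step: float = 0.001,
    t_max: float = 5.0,
    bandwidth: float | None = None,
) -> ConditionPdf:
    sel = sims["choice"] == choice
    p_choice = float(sel.mean()) if len(sims) else 0.0
    dts = sims.loc[sel, "decision_time"].to_numpy()
    grid, dens = _smooth_decision_times(dts, params, grid_step, t_max, bandwidth)
    return ConditionPdf(grid, dens, p_choice, coherence=coherence, choice=choice)


def loglik(
    params: RaceParams,
    trials: pd.DataFrame,
    n_sim_factor: int = 10,
    seed: int = 0,
    grid_step: float = 0.001,
    t_max: float = 5.0,
) -> float:
    """Log-likelihood of (coherence, choice, rt) data under the race model.

    For each coherence, ``n_sim_factor`` times as many trials as observed
    are simulated with a seed derived only from ``seed`` and the
    condition, so repeated evaluations at the same parameters return the
    same value (common random numbers).
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    total = 0.0
    for ci, (coh, sub) in enumerate(sorted(trials.groupby("coherence"))):
        n_sim = max(int(n_sim_factor) * len(sub), 1000)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), ci]))
        sims = simulate_trials(params, [coh], n_sim, seed=rng)
        for choice in ("left", "right"):
            obs = sub.loc[sub["choice"] == choice, "rt"].to_numpy()
            if obs.size == 0:
                continue
            pdf = _pdf_from_sims(sims, params, coh, choice, grid_step, t_max)
            pc = max(pdf.p_choice, DENSITY_FLOOR)
            total += float(np.log(pc * pdf.density_at(obs)).sum())
    if not np.isfinite(total):
        return -np.inf
    return total


DEFAULT_BOUNDS = {
    "kappa": (1.0, 40.0),
    "B": (0.3, 4.0),
    "a": (0.0, 10.0),
    "d_urg": (0.0, 1.0),
    "C0": (-0.3, 0.3),
    "mu_nd": (0.1, 0.8),
    "sigma_nd": (0.01, 0.3),
}


def fit_race(
    trials: pd.DataFrame,
    init: RaceParams,
    bounds: dict | None = None,
    seed: int = 0,
    n_sim_factor: int = 10,
    maxfev: int = 500,
) -> tuple[RaceParams, float, bool]:
    """Maximum-likelihood race-model fit by bounded derivative-free search.

    Powell's method over the 7 free parameters with common random numbers
    across objective evaluations. Returns (best params, log-likelihood,
    converged flag); on non-convergence the best-so-far point is returned
    with the flag False and a logged warning.
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    names = ["kappa", "B", "a", "d_urg", "C0", "mu_nd", "sigma_nd"]
    lob = np.array([bounds[k][0] for k in names])
    upb = np.array([bounds[k][1] for k in names])
    x0 = np.clip(init.free_vector(), lob, upb)

    best = {"x": x0, "f": np.inf}

    def objective(x: np.ndarray) -> float:
        p = init.with_free_vector(np.clip(x, lob, upb))
        f = -loglik(p, trials, n_sim_factor=n_sim_factor, seed=seed)
        if f < best["f"]:
            best["f"], best["x"] = f, np.array(x)
        return f

    res = optimize.minimize(
        objective,
        x0,
        method="Powell",
        bounds=list(zip(lob, upb)),
        options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-3},
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("fit_race: optimizer did not converge (%s)", res.message)
    x = np.clip(best["x"], lob, upb)
    return init.with_free_vector(x), -best["f"], converged


def fit_race_refined(
    trials: pd.DataFrame,
    init: RaceParams,
    bounds: dict | None = None,
    seed: int = 0,
) -> tuple[RaceParams, float, bool]:
    """Two-stage race fit: coarse search, then a low-noise polish.

    The first stage explores with a cheap simulation budget; the second
    restarts Powell from the stage-1 optimum with four times the
    per-condition simulation sample, sharpening the kappa/B ridge that a
    noisy objective leaves poorly resolved.
    """
    stage1, _, _ = fit_race(
        trials, init, bounds=bounds, seed=seed, n_sim_factor=5, maxfev=300
    )
    return fit_race(
        trials, stage1, bounds=bounds, seed=seed, n_sim_factor=20, maxfev=200
    )
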