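"""Direction-selectivity latencies via CUSUM and dogleg fits.

Per neuron: spike-count differences between preferred- and null-direction
trials are accumulated over 25 ms bins (CUSUM); a "dogleg" function — a
flat segment from t=0 that transitions to a line at a breakpoint t1 — is
fit by least squares, and t1 estimates the selectivity latency.
Eligibility requires a direction AUC above 0.55 on counts in
[0.100, 0.400) s, computed on correct trials with RT > 0.45 s and
|coherence| > 10%.

At the population level, session AUC(t) curves are bootstrap-resampled,
averaged, and dogleg-fit, yielding a latency distribution; the
divergence-order comparison between two signals is the proportion of
bootstrap samples in which one diverges later than the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from popconf.data import SessionBundle, extract_counts
from popconf.decode import auc

logger = logging.getLogger(__name__)


@dataclass
class CusumSeries:
    neuron_id: int
    bin_edges: np.ndarray
    cumulative_diff: np.ndarray
    selectivity_auc: float
    preferred: str = "left"


@dataclass
class DoglegFit:
    t1: float             # breakpoint = latency, s
    slope: float
    flat_level: float
    sse: float
    defined: bool = True  # False when no post-break trend exists


def _dogleg_sse(t: np.ndarray, y: np.ndarray, t1: float) -> tuple[float, float, float]:
    """Least-squares flat level and slope for a fixed breakpoint."""
    X = np.column_stack([np.ones_like(t), np.maximum(t - t1, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), float(beta[0]), float(beta[1])


def fit_dogleg(t: np.ndarray, y: np.ndarray, t1_range: tuple = (0.0, 0.5)) -> DoglegFit:
    """Continuous dogleg fit: exhaustive grid at sample resolution then
    golden-section refinement of the breakpoint."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = max(t1_range[0], t.min())
    hi = min(t1_range[1], t.max())
    grid = t[(t >= lo) & (t <= hi)]
    if grid.size == 0:
        grid = np.array([lo])
    sses = np.array([_dogleg_sse(t, y, g)[0] for g in grid])
    i = int(np.argmin(sses))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda x: _dogleg_sse(t, y, x)[0], bounds=(a, b), method="bounded"
        )
        t1 = float(res.x)
    else:
        t1 = float(grid[i])
    sse, level, slope = _dogleg_sse(t, y, t1)
    # no trend: the dogleg explains essentially nothing beyond a flat line
    flat_sse = float(np.sum((y - y.mean()) ** 2))
    defined = flat_sse > 0 and (flat_sse - sse) > 1e-3 * flat_sse
    return DoglegFit(t1=t1, slope=slope, flat_level=level, sse=sse, defined=defined)


def selectivity_filter(
    bundle: SessionBundle,
    window: tuple = (0.100, 0.400),
    rt_min: float = 0.450,
    coh_min: float = 0.10,
    auc_threshold: float = 0.55,
    neuron_ids=None,
) -> dict:
    """Neurons whose direction AUC exceeds the threshold.

    Returns {neuron_id: (auc, preferred_direction)} for eligible neurons;
    the trial filter keeps correct trials with RT strictly greater than
    ``rt_min`` and |coherence| strictly greater than ``coh_min``.
    """
    t = bundle.trials
    use = t[(t["correct"]) & (t["rt"] > rt_min) & (t["coherence"].abs() > coh_min)]
    if len(use) == 0:
        logger.info("selectivity_filter: no eligible trials")
        return {}
    neuron_ids = bundle.tin_ids if neuron_ids is None else np.asarray(neuron_ids)
    cm = extract_counts(
        bundle, window, alignment="motion_onset",
        neuron_filter=neuron_ids, trial_filter=use["trial_id"],
    )
    left = (
        use.set_index("trial_id").loc[cm.trial_ids, "coherence"].to_numpy() > 0
    )
    out = {}
    for j, nid in enumerate(cm.neuron_ids):
        a = auc(cm.values[:, j], left).auc
        if max(a, 1 - a) > auc_threshold:
            out[int(nid)] = (a, "left" if a >= 0.5 else "right")
    return out


def cusum_latency(
    bundle: SessionBundle,
    neuron_id: int,
    preferred: str = "left",
    bin_width: float = 0.025,
    t_range: tuple = (0.0, 0.5),
    rt_min: float = 0.450,
    coh_min: float = 0.10,
) -> tuple[CusumSeries, DoglegFit]:
    """CUSUM of preferred-minus-null per-bin mean counts plus dogleg fit.

    Latency is the fitted breakpoint t1, constrained to ``t_range``. A
    flat cumulative sum (no post-break trend) yields ``defined=False``.
    """
    t = bundle.trials
    use = t[(t["correct"]) & (t["rt"] > rt_min) & (t["coherence"].abs() > coh_min)]
    pref_left = preferred == "left"
    pref_ids = use.loc[(use["coherence"] > 0) == pref_left, "trial_id"].to_numpy()
    null_ids = use.loc[(use["coherence"] > 0) != pref_left, "trial_id"].to_numpy()
    edges = np.arange(t_range[0], t_range[1] + bin_width / 2, bin_width)
    sp = bundle.spikes
    sp = sp[sp["neuron_id"] == neuron_id]

    def _mean_counts(ids: np.ndarray) -> np.ndarray:
        sub = sp[sp["trial_id"].isin(ids)]
        st = sub["spike_time"].to_numpy()
        # half-open bins: histogram edges match [edge_i, edge_{i+1})
        hist, _ = np.histogram(st[(st >= edges[0]) & (st < edges[-1])], bins=edges)
        return hist / max(len(ids), 1)

    diffs = _mean_counts(pref_ids) - _mean_counts(null_ids)
    cusum = np.cumsum(diffs)
    series = CusumSeries(
        neuron_id=int(neuron_id),
        bin_edges=edges,
        cumulative_diff=cusum,
        selectivity_auc=np.nan,
        preferred=preferred,
    )
    fit = fit_dogleg(edges[1:], cusum, t1_range=t_range)
    return series, fit


def population_latency(
    auc_series_by_session: np.ndarray,
    times: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    t1_range: tuple | None = None,
) -> tuple[float, np.ndarray]:
    """Bootstrap latency of a population AUC(t) signal.

    ``auc_series_by_session`` is (n_sessions, n_times). Sessions are
    resampled with replacement, curves averaged, and a dogleg fit per
    sample; returns (mean latency, per-sample latencies). Undefined fits
    are dropped with a logged count.
    """
    S = np.asarray(auc_series_by_session, dtype=float)
    times = np.asarray(times, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("need at least 2 sessions")
    if t1_range is None:
        t1_range = (float(times.min()), float(times.max()))
    rng = np.random.default_rng(seed)
    lat = []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, S.shape[0], S.shape[0])
        curve = np.nanmean(S[pick], axis=0)
        ok = np.isfinite(curve)
        fit = fit_dogleg(times[ok], curve[ok], t1_range=t1_range)
        if fit.defined:
            lat.append(fit.t1)
        else:
            dropped += 1
    if dropped:
        logger.info("population_latency: %d undefined dogleg fits dropped", dropped)
    lat = np.asarray(lat)
    if lat.size == 0:
        raise RuntimeError("all dogleg fits undefined")
    return float(lat.mean()), lat


def latency_order_p(lat_a: np.ndarray, lat_b: np.ndarray) -> float:
    """Proportion of bootstrap pairs in which signal A diverges later than B."""
    n = min(len(lat_a), len(lat_b))
    return float(np.mean(np.asarray(lat_a[:n]) > np.asarray(lat_b[:n])))
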