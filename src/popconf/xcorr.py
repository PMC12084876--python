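"""Lagged trial-by-trial correlations between neuron-group residuals.

Group-mean spike counts in 25 ms bins (motion-onset aligned, valid up to
50 ms before the saccade) are z-scored within each (bin, signed
coherence, session) cell, removing stimulus- and time-locked structure.
The Pearson correlation between two groups' residuals at all time-bin
pairs (tx, ty) forms a heatmap; temporal asymmetry — correlations above
vs. below the diagonal — is tested by permuting trial order of one
group (the trial-shuffle null preserves each bin's marginal
distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popconf.data import SessionBundle

logger = logging.getLogger(__name__)


@dataclass
class ResidualSeries:
    """Per (trial, bin) standardized residual of group-mean counts."""

    values: np.ndarray     # trials x bins, NaN where invalid
    bin_starts: np.ndarray
    trial_ids: np.ndarray


@dataclass
class CorrHeatmap:
    rho: np.ndarray        # (n_tx, n_ty), NaN where masked
    n: np.ndarray
    tx: np.ndarray
    ty: np.ndarray


def _group_counts(
    bundle: SessionBundle, neuron_ids: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Mean count per (trial, bin) over a neuron group."""
    trial_ids = np.sort(bundle.trials["trial_id"].to_numpy())
    sp = bundle.spikes[bundle.spikes["neuron_id"].isin(neuron_ids)]
    ti = pd.Categorical(sp["trial_id"], categories=trial_ids).codes
    st = sp["spike_time"].to_numpy()
    bi = np.floor((st - edges[0]) / (edges[1] - edges[0])).astype(int)
    ok = (bi >= 0) & (bi < edges.size - 1)
    counts = np.zeros((trial_ids.size, edges.size - 1))
    np.add.at(counts, (ti[ok], bi[ok]), 1.0)
    return counts / max(len(neuron_ids), 1)


def binned_residuals(
    bundle: SessionBundle,
    group,
    bin_width: float = 0.025,
    t_max: float = 1.0,
    rt_margin: float = 0.050,
    min_per_cell: int = 5,
) -> ResidualSeries:
    """Standardized residual group-mean counts per (trial, bin).

    ``group`` is either an iterable of neuron ids, or a pair
    ``(pos_ids, neg_ids)`` whose residuals are differenced (the signed
    combination used for opposed motion-preference groups). Bins ending
    after ``rt - rt_margin`` are invalid (NaN); (bin, coherence) cells
    with fewer than ``min_per_cell`` valid trials are masked.
    """
    edges = np.arange(0.0, t_max + bin_width / 2, bin_width)
    starts = edges[:-1]
    if isinstance(group, tuple) and len(group) == 2 and not np.isscalar(group[0]):
        pos = _residualize(bundle, np.asarray(group[0]), edges, rt_margin, min_per_cell)
        neg = _residualize(bundle, np.asarray(group[1]), edges, rt_margin, min_per_cell)
        vals = pos - neg
    else:
        vals = _residualize(bundle, np.asarray(list(group)), edges, rt_margin, min_per_cell)
    trial_ids = np.sort(bundle.trials["trial_id"].to_numpy())
    return ResidualSeries(values=vals, bin_starts=starts, trial_ids=trial_ids)


def _residualize(
    bundle: SessionBundle,
    neuron_ids: np.ndarray,
    edges: np.ndarray,
    rt_margin: float,
    min_per_cell: int,
) -> np.ndarray:
    if neuron_ids.size == 0:
        raise ValueError("empty neuron group")
    counts = _group_counts(bundle, neuron_ids, edges)
    trial_ids = np.sort(bundle.trials["trial_id"].to_numpy())
    info = bundle.trials.set_index("trial_id").loc[trial_ids]
    rts = info["rt"].to_numpy()
    coh = info["coherence"].to_numpy()
    valid = edges[None, 1:] <= (rts[:, None] - rt_margin)
    z = np.full_like(counts, np.nan)
    for cv in np.unique(coh):
        rows = coh == cv
        for b in range(counts.shape[1]):
            cell = rows & valid[:, b]
            if cell.sum() < min_per_cell:
                continue
            x = counts[cell, b]
            sd = x.std()
            if sd == 0:
                continue
            z[cell, b] = (x - x.mean()) / sd
    return z


def combine_sessions(series: list[ResidualSeries]) -> ResidualSeries:
    """Concatenate per-session residuals along trials (common bin grid)."""
    base = series[0].bin_starts
    for s in series[1:]:
        if not np.allclose(s.bin_starts, base):
            raise ValueError("sessions use different bin grids")
    vals = np.vstack([s.values for s in series])
    ids = np.concatenate(
        [s.trial_ids + 1_000_000 * i for i, s in enumerate(series)]
    )
    return ResidualSeries(values=vals, bin_starts=base, trial_ids=ids)


def _masked_corr(X: np.ndarray, Y: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r over jointly valid trials, via mask algebra."""
    Mx = np.isfinite(X).astype(float)
    My = np.isfinite(Y).astype(float)
    A = np.where(Mx > 0, X, 0.0)
    B = np.where(My > 0, Y, 0.0)
    n = Mx.T @ My
    Sx = A.T @ My
    Sy = Mx.T @ B
    Sxx = (A * A).T @ My
    Syy = Mx.T @ (B * B)
    Sxy = A.T @ B
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * Sxy - Sx * Sy
        den = np.sqrt((n * Sxx - Sx ** 2) * (n * Syy - Sy ** 2))
        rho = num / den
    rho[n < min_n] = np.nan
    return rho, n


def corr_heatmap(
    x: ResidualSeries,
    y: ResidualSeries,
    t_range: tuple = (0.2, 0.8),
    min_n: int = 5,
) -> CorrHeatmap:
    """Pearson correlation between two residual series at all bin pairs."""
    if x.values.shape[0] != y.values.shape[0]:
        raise ValueError("series must share a common trial index")
    selx = (x.bin_starts >= t_range[0]) & (x.bin_starts < t_range[1])
    sely = (y.bin_starts >= t_range[0]) & (y.bin_starts < t_range[1])
    X = x.values[:, selx]
    Y = y.values[:, sely]
    rho, n = _masked_corr(X, Y, min_n)
    return CorrHeatmap(rho=rho, n=n, tx=x.bin_starts[selx], ty=y.bin_starts[sely])


def _roi_delta(hm_rho: np.ndarray, tx: np.ndarray, ty: np.ndarray) -> float:
    TX = tx[:, None]
    TY = ty[None, :]
    roi1 = TX > TY
    roi2 = TY > TX
    m1 = np.nanmean(hm_rho[roi1]) if np.isfinite(hm_rho[roi1]).any() else np.nan
    m2 = np.nanmean(hm_rho[roi2]) if np.isfinite(hm_rho[roi2]).any() else np.nan
    return float(m1 - m2)


def lead_follow_asymmetry(
    leader: ResidualSeries,
    follower: ResidualSeries,
    **kwargs,
) -> tuple[float, float]:
    """ROI test oriented so delta > 0 when ``leader`` precedes ``follower``.

    Correlations between the follower at tx and the leader at ty
    concentrate at tx > ty (ROI1) when the leader's fluctuations appear
    in the follower after a lag.
    """
    return roi_permutation_test(follower, leader, **kwargs)


def roi_permutation_test(
    x: ResidualSeries,
    y: ResidualSeries,
    n_shuffle: int = 200,
    seed: int = 0,
    t_range: tuple = (0.2, 0.8),
    min_n: int = 5,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Temporal-asymmetry test: mean rho(ROI1: tx>ty) - mean rho(ROI2).

    The null distribution permutes the trial order of ``y`` only. Returns
    (observed delta, permutation p). ``alternative`` is "greater"
    (directional: correlations larger where x follows y) or "two-sided".
    """
    if n_shuffle < 50:
        logger.warning("roi_permutation_test: n_shuffle=%d is small", n_shuffle)
    selx = (x.bin_starts >= t_range[0]) & (x.bin_starts < t_range[1])
    sely = (y.bin_starts >= t_range[0]) & (y.bin_starts < t_range[1])
    X = x.values[:, selx]
    Y = y.values[:, sely]
    tx = x.bin_starts[selx]
    ty = y.bin_starts[sely]
    rho, _ = _masked_corr(X, Y, min_n)
    delta = _roi_delta(rho, tx, ty)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for s in range(n_shuffle):
        perm = rng.permutation(Y.shape[0])
        rho_s, _ = _masked_corr(X, Y[perm], min_n)
        null[s] = _roi_delta(rho_s, tx, ty)
    if alternative == "greater":
        p = (1 + np.sum(null >= delta)) / (n_shuffle + 1)
    elif alternative == "two-sided":
        p = (1 + np.sum(np.abs(null) >= abs(delta))) / (n_shuffle + 1)
    else:
        raise ValueError(f"unknown alternative: {alternative}")
    return delta, float(p)
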