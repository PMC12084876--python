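"""Behavioral signatures of confidence derived from decoder output.

The accuracy decoder's out-of-sample probability-correct serves as a
per-trial confidence signal. To parallel human experiments in which
choices carry a binary high/low confidence report, the continuous signal
is thresholded at the quantile that reproduces a target fraction of
high-confidence choices (61% in the matched human study). Signature
tables then summarize confidence against motion strength, accuracy, and
RT; a single-neuron variant handles sessions from the biased-prior task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popconf.data import PRESACCADIC_WINDOW, SessionBundle, extract_counts
from popconf.decode import fit_logistic_cv

logger = logging.getLogger(__name__)


@dataclass
class ConfidenceSeries:
    """Continuous confidence with an optional binary high/low report."""

    conf: np.ndarray
    high: np.ndarray | None = None
    threshold: float | None = None


def threshold_confidence(conf, target_high: float) -> ConfidenceSeries:
    """Flag the top ``target_high`` fraction of trials as high confidence.

    The criterion is the (1 - target_high) quantile of the continuous
    signal; a trial is high-confidence iff strictly above it. The
    achieved fraction matches the target within 1/n for non-degenerate
    inputs.
    """
    conf = np.asarray(conf, dtype=float)
    if not 0.0 <= target_high <= 1.0:
        raise ValueError("target_high must lie in [0, 1]")
    if np.ptp(conf) == 0:
        raise ValueError("confidence series is degenerate (all equal)")
    if target_high >= 1.0:
        crit = -np.inf
    else:
        crit = float(np.quantile(conf, 1.0 - target_high))
    return ConfidenceSeries(conf=conf, high=conf > crit, threshold=crit)


def signature_by_coherence(
    series: ConfidenceSeries | np.ndarray,
    trials: pd.DataFrame,
    min_n: int = 4,
    use_binary: bool = True,
) -> pd.DataFrame:
    """Mean confidence (or fraction high) per (|C|, correct/error).

    Cells with fewer than ``min_n`` trials are masked (NaN). ``trials``
    must be row-aligned with the confidence series.
    """
    vals = _values(series, use_binary)
    df = pd.DataFrame(
        {
            "acoh": np.abs(trials["coherence"].to_numpy()),
            "correct": trials["correct"].to_numpy(),
            "conf": vals,
        }
    )
    out = (
        df.groupby(["acoh", "correct"])["conf"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    out.loc[out["n"] < min_n, "mean"] = np.nan
    return out


def _values(series, use_binary: bool) -> np.ndarray:
    if isinstance(series, ConfidenceSeries):
        if use_binary and series.high is not None:
            return series.high.astype(float)
        return series.conf
    return np.asarray(series, dtype=float)


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    """Centered running mean with truncated (shrinking) edge windows."""
    return pd.Series(x).rolling(n, min_periods=1, center=True).mean().to_numpy()


def signature_by_rt(
    series: ConfidenceSeries | np.ndarray,
    trials: pd.DataFrame,
    boxcar_n: int = 300,
    split: str = "correct_error",
    use_binary: bool = True,
) -> dict:
    """Confidence vs. RT curves, boxcar-smoothed over RT-sorted trials.

    ``split`` is ``"correct_error"`` (one curve per accuracy outcome) or
    ``"per_coherence"`` (correct trials only, one curve per |C|). Each
    curve is a DataFrame with smoothed ``rt`` and ``conf`` columns. A
    split cell smaller than the boxcar uses the largest odd window that
    fits (logged).
    """
    vals = _values(series, use_binary)
    rt = trials["rt"].to_numpy()
    if split == "correct_error":
        cells = {bool(c): trials["correct"].to_numpy() == c for c in (True, False)}
    elif split == "per_coherence":
        acoh = np.abs(trials["coherence"].to_numpy())
        corr = trials["correct"].to_numpy()
        cells = {c: (acoh == c) & corr for c in np.unique(acoh)}
    else:
        raise ValueError(f"unknown split: {split}")
    curves = {}
    for key, mask in cells.items():
        if mask.sum() == 0:
            continue
        n = boxcar_n
        if mask.sum() < boxcar_n:
            n = max(int(mask.sum()) // 2 * 2 - 1, 1)
            logger.info("signature_by_rt: cell %r uses window %d", key, n)
        order = np.argsort(rt[mask], kind="stable")
        curves[key] = pd.DataFrame(
            {
                "rt": _boxcar(rt[mask][order], n),
                "conf": _boxcar(vals[mask][order], n),
            }
        )
    return curves


def decode_confidence(
    bundle: SessionBundle,
    choice_side: str = "left",
    window: tuple = PRESACCADIC_WINDOW,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Out-of-sample probability correct for one choice category.

    Runs the accuracy decoder (cross-validated logistic regression on
    standardized presaccadic Tin counts) on trials with the given choice.
    Returns (aligned trial table, confidence per trial).
    """
    use = bundle.trials[bundle.trials["choice"] == choice_side]
    cm = extract_counts(
        bundle, window, alignment="saccade",
        neuron_filter=bundle.tin_ids, trial_filter=use["trial_id"],
        standardize=True,
    )
    t = use.set_index("trial_id").loc[cm.trial_ids].reset_index()
    labels = t["correct"].to_numpy().astype(int)
    fit = fit_logistic_cv(cm.values, labels, folds=folds, seed=seed)
    return t, fit.oos_prob


def signature_checks(
    conf: np.ndarray,
    trials: pd.DataFrame,
    n_rt_bins: int = 5,
) -> dict:
    """The six confidence-signature statistics.

    Signs expected of a confidence signal: (1) higher on corrects than
    errors; (2) increasing in |C| on corrects; (3) increasing in |C| on
    errors; (4) decreasing in RT; (5) higher on corrects at matched RT;
    (6) increasing in |C| at matched RT (correct trials). (2), (3), (4)
    and (6) are Spearman rank correlations; (1) and (5) are signed mean
    differences; matching uses RT quantile bins.
    """
    from scipy.stats import spearmanr

    conf = np.asarray(conf, dtype=float)
    corr = trials["correct"].to_numpy().astype(bool)
    acoh = np.abs(trials["coherence"].to_numpy())
    rt = trials["rt"].to_numpy()

    out = {
        "d_correct_minus_error": float(conf[corr].mean() - conf[~corr].mean()),
        "rho_coherence_correct": float(spearmanr(acoh[corr], conf[corr]).statistic),
        "rho_coherence_error": float(spearmanr(acoh[~corr], conf[~corr]).statistic),
        "rho_rt": float(spearmanr(rt, conf).statistic),
    }
    edges = np.quantile(rt, np.linspace(0, 1, n_rt_bins + 1))
    bins = np.clip(np.searchsorted(edges, rt, side="right") - 1, 0, n_rt_bins - 1)
    diffs, weights, rhos = [], [], []
    for b in range(n_rt_bins):
        m = bins == b
        if corr[m].any() and (~corr[m]).any():
            diffs.append(conf[m & corr].mean() - conf[m & ~corr].mean())
            weights.append(m.sum())
        mc = m & corr
        if mc.sum() > 2 and np.unique(acoh[mc]).size > 1:
            rhos.append(spearmanr(acoh[mc], conf[mc]).statistic)
    out["d_correct_minus_error_matched_rt"] = float(
        np.average(diffs, weights=weights)
    )
    out["rho_coherence_matched_rt"] = float(np.mean(rhos))
    return out


def prior_block_analysis(
    sessions: list[SessionBundle],
    window: tuple = PRESACCADIC_WINDOW,
    contralateral: str = "left",
    folds: int = 10,
    seed: int = 0,
    min_n: int = 4,
) -> pd.DataFrame:
    """Decoded p(correct) by prior block, |C|, and accuracy outcome.

    Each session contributes a single-neuron (or small-population)
    accuracy decoder fit with cross-validation on contralateral-choice
    trials; out-of-sample probabilities are pooled across sessions and
    averaged per (prior, |C|, correct/error) cell. Cells below ``min_n``
    trials are masked.
    """
    rows = []
    for si, bundle in enumerate(sessions):
        use = bundle.trials[bundle.trials["choice"] == contralateral]
        cm = extract_counts(
            bundle, window, alignment="saccade",
            neuron_filter=bundle.tin_ids, trial_filter=use["trial_id"],
            standardize=True,
        )
        t = use.set_index("trial_id").loc[cm.trial_ids]
        labels = t["correct"].to_numpy().astype(int)
        fit = fit_logistic_cv(cm.values, labels, folds=folds, seed=seed + si)
        rows.append(
            pd.DataFrame(
                {
                    "prior": t["prior_block"].to_numpy(),
                    "acoh": np.abs(t["coherence"].to_numpy()),
                    "correct": t["correct"].to_numpy(),
                    "p_correct": fit.oos_prob,
                }
            )
        )
    pooled = pd.concat(rows, ignore_index=True)
    out = (
        pooled.groupby(["prior", "acoh", "correct"])["p_correct"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    out.loc[out["n"] < min_n, "mean"] = np.nan
    return out
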