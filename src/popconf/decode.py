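"""Cross-validated logistic population decoders and ROC/AUC inference.

Decoders are plain L2-lightly-regularized logistic regressions on
standardized presaccadic spike counts. Three targets are supported:

* ``accuracy`` — correct vs. error, fit per choice category, yielding an
  out-of-sample probability-correct per trial (the putative confidence
  signal);
* ``choice`` — left vs. right, fit on all trials;
* ``rt_class`` — fast vs. slow relative to the within-set median RT.

AUC follows the Mann-Whitney convention (ties count 0.5). Bootstrap
resampling (trial level) provides standard errors and one-sided
comparisons between decoders; session-level comparisons use a paired
t test on logit-transformed AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from popconf.data import CountMatrix, EmptySelectionError, extract_counts

logger = logging.getLogger(__name__)


@dataclass
class DecoderFit:
    """Result of a cross-validated logistic decoder."""

    weights: np.ndarray        # coding direction, one weight per feature
    bias: float
    target: str
    oos_prob: np.ndarray       # out-of-sample P(label=1), one per trial
    fold_assignment: np.ndarray
    trained_on: str = ""


@dataclass
class RocResult:
    auc: float
    se: float | None
    n_pos: int
    n_neg: int


@dataclass
class CodingDirection:
    weights: np.ndarray
    target: str
    derived_from: str = "all_trials"
    bias: float = 0.0


def _as_array(features) -> np.ndarray:
    if isinstance(features, CountMatrix):
        return np.asarray(features.values, dtype=float)
    return np.asarray(features, dtype=float)


def _logistic(l2: float) -> LogisticRegression:
    # sklearn's C is the inverse regularization strength
    return LogisticRegression(C=1.0 / l2, solver="lbfgs", max_iter=2000)


def _fold_split(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random partition into near-equal folds."""
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = f
    return assignment


def fit_logistic_cv(
    features,
    labels,
    folds: int = 10,
    seed: int = 0,
    l2: float = 1e-6,
    target: str = "accuracy",
) -> DecoderFit:
    """Logistic decoder with k-fold cross-validated probabilities.

    Every trial receives an out-of-sample probability (its fold is held
    out of training). The stored ``weights``/``bias`` come from a final
    fit on all trials (a single coding direction per dataset). If a
    training split misses a class the folds are re-drawn once before
    raising.
    """
    X = _as_array(features)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    rng = np.random.default_rng(seed)

    for attempt in range(2):
        assignment = _fold_split(y.size, folds, rng)
        ok = all(
            np.unique(y[assignment != f]).size == 2 for f in range(folds)
        )
        if ok:
            break
    else:
        raise ValueError("a training fold contains a single class")

    oos = np.empty(y.size)
    for f in range(folds):
        test = assignment == f
        clf = _logistic(l2).fit(X[~test], y[~test])
        oos[test] = clf.predict_proba(X[test])[:, 1]
    final = _logistic(l2).fit(X, y)
    return DecoderFit(
        weights=final.coef_.ravel().copy(),
        bias=float(final.intercept_[0]),
        target=target,
        oos_prob=oos,
        fold_assignment=assignment,
    )


def rt_class_labels(rt: np.ndarray) -> np.ndarray:
    """1 = fast (rt below the within-set median), 0 = slow."""
    rt = np.asarray(rt, dtype=float)
    return (rt < np.median(rt)).astype(int)


def auc(scores, labels) -> RocResult:
    """Mann-Whitney AUC: P(random positive outscores random negative)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return RocResult(auc=float(u / (n_pos * n_neg)), se=None, n_pos=n_pos, n_neg=n_neg)


def _boot_aucs(
    s: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = s.size
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            out[b] = np.nan
            continue
        out[b] = auc(s[idx], yb).auc
    return out


def bootstrap_auc_se(scores, labels, n_boot: int = 5000, seed: int = 0) -> RocResult:
    """AUC with a trial-resampling bootstrap standard error."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    base = auc(s, y)
    rng = np.random.default_rng(seed)
    boots = _boot_aucs(s, y, n_boot, rng)
    return RocResult(base.auc, float(np.nanstd(boots)), base.n_pos, base.n_neg)


def bootstrap_compare(
    scores_a, labels_a, scores_b, labels_b,
    n_boot: int = 5000, seed: int = 0,
) -> tuple[float, float, float]:
    """Bootstrap SEs for two AUCs and P(AUC_a <= AUC_b) over resamples.

    The two datasets are resampled independently and all pairwise
    bootstrap comparisons are scored, matching the all-pairs convention.
    """
    if n_boot < 100:
        logger.warning("bootstrap_compare: n_boot=%d is small", n_boot)
    rng = np.random.default_rng(seed)
    ba = _boot_aucs(np.asarray(scores_a, float), np.asarray(labels_a).astype(bool), n_boot, rng)
    bb = _boot_aucs(np.asarray(scores_b, float), np.asarray(labels_b).astype(bool), n_boot, rng)
    ba = ba[~np.isnan(ba)]
    bb = bb[~np.isnan(bb)]
    # all-pairs exceedance computed by sorting rather than the full outer product
    order = np.sort(bb)
    p = float(np.searchsorted(order, ba, side="right").sum() / (ba.size * bb.size))
    return float(np.std(ba)), float(np.std(bb)), 1.0 - p


def logit(p: np.ndarray, clamp: float = 1e-6) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), clamp, 1 - clamp)
    return np.log(p / (1 - p))


def session_auc_test(per_session_aucs_a, per_session_aucs_b) -> float:
    """One-tailed paired t test on logit AUCs (H1: a > b)."""
    a = np.asarray(per_session_aucs_a, dtype=float)
    b = np.asarray(per_session_aucs_b, dtype=float)
    if a.size != b.size:
        raise ValueError("sessions must be paired")
    if a.size < 3:
        raise ValueError("need at least 3 sessions")
    if ((a >= 1) | (b >= 1)).any():
        logger.info("session_auc_test: AUC at 1.0 clamped to 1-1e-6 for logit")
    if np.allclose(a, b):
        return 0.5
    res = stats.ttest_rel(logit(a), logit(b), alternative="greater")
    return float(res.pvalue)


def coding_direction(features, labels, target: str, l2: float = 1e-6) -> CodingDirection:
    """Single all-trials weight vector (no cross-validation)."""
    X = _as_array(features)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")
    clf = _logistic(l2).fit(X, y)
    return CodingDirection(
        weights=clf.coef_.ravel().copy(),
        target=target,
        derived_from="all_trials",
        bias=float(clf.intercept_[0]),
    )


def cosine_similarity(cd1, cd2) -> float:
    w1 = cd1.weights if isinstance(cd1, CodingDirection) else np.asarray(cd1, float)
    w2 = cd2.weights if isinstance(cd2, CodingDirection) else np.asarray(cd2, float)
    if w1.size != w2.size:
        raise ValueError("coding directions must have equal length")
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm coding direction")
    return float(w1 @ w2 / (n1 * n2))


def project(features, cd) -> np.ndarray:
    """Dot product of each trial's population vector with a coding direction."""
    X = _as_array(features)
    w = cd.weights if isinstance(cd, CodingDirection) else np.asarray(cd, float)
    if X.shape[1] != w.size:
        raise ValueError("dimension mismatch between features and coding direction")
    return X @ w


def time_resolved_auc(
    bundle,
    cd,
    labels_by_trial: dict,
    t_range: tuple = (-0.1, 0.8),
    window: float = 0.1,
    step: float = 0.025,
    alignment: str = "motion_onset",
    neuron_ids=None,
    min_per_class: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """AUC(t) of coding-direction projections in sliding count windows.

    ``labels_by_trial`` maps trial_id -> binary label; trials absent from
    the map are skipped. Windows with fewer than ``min_per_class`` trials
    in either class return NaN.

    Returns (window start times, AUC series).
    """
    neuron_ids = bundle.tin_ids if neuron_ids is None else np.asarray(neuron_ids)
    trial_ids = np.array(sorted(labels_by_trial))
    labels = np.array([labels_by_trial[t] for t in trial_ids]).astype(bool)
    starts = np.arange(t_range[0], t_range[1] - window + 1e-9, step)
    out = np.full(starts.size, np.nan)
    rt_map = bundle.trials.set_index("trial_id")["rt"]
    rts = rt_map.loc[trial_ids].to_numpy()
    for i, s in enumerate(starts):
        cm = extract_counts(
            bundle, (s, s + window), alignment=alignment,
            neuron_filter=neuron_ids, trial_filter=trial_ids,
        )
        # only trials still deliberating: window must end before the saccade
        valid = rts[np.searchsorted(trial_ids, cm.trial_ids)] >= s + window
        y = labels[np.searchsorted(trial_ids, cm.trial_ids)][valid]
        if y.sum() < min_per_class or (~y).sum() < min_per_class:
            continue
        proj = project(cm.standardize().values[valid], cd)
        out[i] = auc(proj, y).auc
    return starts, out
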