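"""Per-neuron regression and k-means clustering of Tin response structure.

Each Tin neuron's standardized presaccadic spike count is regressed on
signed motion coherence, RT, choice, and an offset (correct trials
only). K-means applied to the (coherence, RT, choice) coefficient triple
splits the population into clusters whose labels are ordered by
ascending mean coherence coefficient. A separate coherence-only
regression on correct contralateral trials yields ``beta_coh``, the
per-neuron coherence sensitivity whose near-zero population mean
explains why the averaged activity appears stereotyped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from popconf.data import PRESACCADIC_WINDOW, SessionBundle, extract_counts
from popconf.decode import DecoderFit, RocResult, auc, fit_logistic_cv

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Neuron -> cluster map with centroids in coefficient space."""

    labels: dict            # neuron_id -> label in {1..k}
    centroids: np.ndarray   # k x 3, rows ordered by label
    inertia: float
    k: int = 3

    def members(self, label: int) -> np.ndarray:
        return np.array([nid for nid, lab in self.labels.items() if lab == label])


def neuron_regression(
    bundle: SessionBundle,
    correct_only: bool = True,
    window: tuple = PRESACCADIC_WINDOW,
    choice_coding: tuple = (0.0, 1.0),
    min_trials: int = 30,
    contralateral: str = "left",
) -> pd.DataFrame:
    """OLS of standardized presaccadic counts on (C, RT, choice, 1) per neuron.

    Returns a DataFrame indexed by neuron_id with columns beta0..beta3
    (offset, coherence, RT, choice) and ``beta_coh`` from the
    coherence-only model fit on correct contralateral-choice trials.
    ``choice_coding`` maps (non-left, left) choices to regressor values.
    """
    trials = bundle.trials
    sel = trials["correct"] if correct_only else pd.Series(True, index=trials.index)
    use = trials[sel]
    if len(use) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, have {len(use)}")
    tin = bundle.tin_ids
    cm = extract_counts(
        bundle, window, alignment="saccade",
        neuron_filter=tin, trial_filter=use["trial_id"], standardize=True,
    )
    t = use.set_index("trial_id").loc[cm.trial_ids]
    C = t["coherence"].to_numpy()
    rt = t["rt"].to_numpy()
    ch = np.where(t["choice"] == "left", choice_coding[1], choice_coding[0])
    X = np.column_stack([np.ones_like(C), C, rt, ch])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant regressor?)")

    contra = t["choice"] == contralateral
    rows = []
    for j, nid in enumerate(cm.neuron_ids):
        y = cm.values[:, j]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        yc = y[contra.to_numpy()]
        Cc = C[contra.to_numpy()]
        if np.unique(Cc).size < 2:
            raise ValueError(f"neuron {nid}: single coherence in contralateral set")
        Xc = np.column_stack([np.ones_like(Cc), Cc])
        bcoh, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        rows.append(
            {
                "neuron_id": nid, "beta0": beta[0], "beta1": beta[1],
                "beta2": beta[2], "beta3": beta[3], "beta_coh": bcoh[1],
            }
        )
    return pd.DataFrame(rows).set_index("neuron_id")


def cluster_neurons(
    regs: pd.DataFrame,
    k: int = 3,
    n_restarts: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """Best-of-restarts k-means on (beta1, beta2, beta3); labels ordered by beta1."""
    pts = regs[["beta1", "beta2", "beta3"]].to_numpy()
    if len(pts) < k:
        raise ValueError(f"need at least k={k} neurons")
    if np.unique(pts, axis=0).shape[0] < k:
        raise ValueError("fewer than k distinct coefficient points (degenerate)")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(pts)
    raw = km.labels_
    order = np.argsort([pts[raw == c, 0].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = {int(nid): int(relabel[raw[i]]) for i, nid in enumerate(regs.index)}
    centroids = km.cluster_centers_[order]
    return ClusterAssignment(labels, centroids, float(km.inertia_), k=k)


def _best_agreement(labels_a: np.ndarray, labels_b: np.ndarray, k: int) -> float:
    """Max fraction of identical assignments over label permutations."""
    best = 0.0
    for perm in itertools.permutations(range(1, k + 1)):
        mapped = np.array([perm[l - 1] for l in labels_a])
        best = max(best, float(np.mean(mapped == labels_b)))
    return best


def split_half_stability(
    bundle: SessionBundle,
    k: int = 3,
    seed: int = 0,
    **regression_kwargs,
) -> float:
    """Cluster agreement between odd- and even-trial halves.

    Trials are split by their 1-based position in the session (odd =
    first). Cluster labels from the two halves are matched by the
    permutation maximizing agreement; the consistent fraction is
    returned.
    """
    order = bundle.trials["trial_id"].to_numpy()
    odd = order[::2]
    even = order[1::2]
    halves = []
    for ids in (odd, even):
        sub = bundle.subset_trials(ids)
        regs = neuron_regression(sub, **regression_kwargs)
        asn = cluster_neurons(regs, k=k, seed=seed)
        halves.append(np.array([asn.labels[int(n)] for n in regs.index]))
    return _best_agreement(halves[0], halves[1], k)


def split_half_chance(
    n_per_cluster: np.ndarray, n_rep: int = 2000, k: int = 3, seed: int = 0
) -> float:
    """Chance level of permutation-matched agreement for random labels.

    Brute-force: draw two independent random labelings with the given
    cluster sizes and score them with the same matching rule.
    """
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(1, k + 1), n_per_cluster)
    vals = np.empty(n_rep)
    for r in range(n_rep):
        a = rng.permutation(base)
        b = rng.permutation(base)
        vals[r] = _best_agreement(a, b, k)
    return float(vals.mean())


def cluster_decode(
    bundle: SessionBundle,
    assignment: ClusterAssignment,
    mode: str = "per_cluster",
    target: str = "accuracy",
    window: tuple = PRESACCADIC_WINDOW,
    choice_side: str = "left",
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Decode accuracy (or choice) from cluster-restricted features.

    Modes
    -----
    ``per_cluster``
        One decoder per cluster using that cluster's neurons.
    ``mean_of_clusters_13``
        Two features: the mean standardized count of cluster-1 neurons
        and of cluster-k neurons (the two extreme clusters).
    ``grand_mean``
        A single feature, the mean standardized count of all Tin neurons.
    ``per_neuron``
        One single-feature decoder per neuron.

    Returns a dict mapping mode key -> RocResult of out-of-sample scores.
    """
    trials = bundle.trials
    if target == "accuracy":
        use = trials[trials["choice"] == choice_side]
        labels = use["correct"].to_numpy().astype(int)
    elif target == "choice":
        use = trials
        labels = (use["choice"] == "left").to_numpy().astype(int)
    else:
        raise ValueError(f"unsupported target: {target}")
    tin = bundle.tin_ids
    cm = extract_counts(
        bundle, window, alignment="saccade",
        neuron_filter=tin, trial_filter=use["trial_id"], standardize=True,
    )
    lab = use.set_index("trial_id").loc[cm.trial_ids]
    labels = (
        lab["correct"].to_numpy().astype(int)
        if target == "accuracy"
        else (lab["choice"] == "left").to_numpy().astype(int)
    )

    def _roc(X) -> RocResult:
        fit = fit_logistic_cv(X, labels, folds=folds, seed=seed, target=target)
        return auc(fit.oos_prob, labels)

    out: dict = {}
    if mode == "per_cluster":
        for c in range(1, assignment.k + 1):
            members = assignment.members(c)
            members = members[np.isin(members, cm.neuron_ids)]
            if members.size == 0:
                logger.info("cluster %d empty in session; skipped", c)
                continue
            cols = np.isin(cm.neuron_ids, members)
            out[c] = _roc(cm.values[:, cols])
    elif mode == "mean_of_clusters_13":
        feats = []
        for c in (1, assignment.k):
            members = assignment.members(c)
            cols = np.isin(cm.neuron_ids, members)
            if not cols.any():
                raise ValueError(f"cluster {c} empty")
            feats.append(cm.values[:, cols].mean(axis=1))
        out["mean_13"] = _roc(np.column_stack(feats))
    elif mode == "grand_mean":
        out["grand_mean"] = _roc(cm.values.mean(axis=1, keepdims=True))
    elif mode == "per_neuron":
        for j, nid in enumerate(cm.neuron_ids):
            out[int(nid)] = _roc(cm.values[:, [j]])
    else:
        raise ValueError(f"unknown mode: {mode}")
    return out


def control_task_cluster_test(
    diff_by_neuron: pd.Series,
    assignment: ClusterAssignment,
) -> tuple[pd.Series, dict]:
    """Cluster separation test on a per-neuron condition-difference statistic.

    ``diff_by_neuron`` holds, per neuron, the mean standardized count
    difference between two control-task conditions (e.g., left vs. right
    memory saccades). Returns the per-cluster mean statistic and
    Wilcoxon rank-sum p values for every cluster pair; pairs with a
    cluster of fewer than 3 neurons report NaN.
    """
    means = {}
    groups = {}
    for c in range(1, assignment.k + 1):
        members = assignment.members(c)
        vals = diff_by_neuron.loc[[m for m in members if m in diff_by_neuron.index]]
        groups[c] = vals.to_numpy()
        means[c] = float(vals.mean()) if len(vals) else np.nan
    pvals = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(groups[a]) < 3 or len(groups[b]) < 3:
            pvals[(a, b)] = np.nan
            continue
        pvals[(a, b)] = float(stats.ranksums(groups[a], groups[b]).pvalue)
    return pd.Series(means, name="mean_diff"), pvals
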