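import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from popconf.decode import (
    auc,
    bootstrap_compare,
    coding_direction,
    cosine_similarity,
    fit_logistic_cv,
    project,
    rt_class_labels,
    session_auc_test,
    time_resolved_auc,
)


def brute_force_auc(scores, labels):
    """All-pairs counting oracle: ties weighted 0.5."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 200)
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_roc_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        assert auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        scores=st.lists(
            st.integers(min_value=-5, max_value=5), min_size=4, max_size=60
        ),
        data=st.data(),
    )
    def test_property_matches_oracle_and_rank_invariance(self, scores, data):
        """For any tied/untied score list: AUC equals pair counting and is
        invariant under the strictly monotone map x -> exp(x)."""
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        labels = np.asarray(labels)
        if labels.all() or not labels.any():
            return
        s = np.asarray(scores, dtype=float)
        a = auc(s, labels).auc
        assert a == pytest.approx(brute_force_auc(s, labels), abs=1e-12)
        assert auc(np.exp(s), labels).auc == pytest.approx(a, abs=1e-12)

    def test_enumerated_example(self):
        # positives {2,3}, negatives {1,2}: wins 3, tie 1 of 4 pairs
        assert auc([2, 3, 1, 2], [1, 1, 0, 0]).auc == pytest.approx(0.875)

    def test_all_tied_scores_give_half(self):
        assert auc([1.0] * 10, [1] * 4 + [0] * 6).auc == 0.5

    def test_perfect_separation_gives_one(self):
        assert auc([5, 6, 1, 2], [1, 1, 0, 0]).auc == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=500)
        y = rng.random(500) < 0.5
        assert auc(np.exp(s), y).auc == pytest.approx(auc(s, y).auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])


class TestLogisticCv:
    def test_pure_noise_features_are_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 8))
        y = (rng.random(2000) < 0.5).astype(int)
        fit = fit_logistic_cv(X, y, seed=0)
        assert abs(auc(fit.oos_prob, y).auc - 0.5) < 0.03

    def test_label_as_feature_is_near_perfect(self):
        rng = np.random.default_rng(4)
        y = (rng.random(500) < 0.5).astype(int)
        X = np.column_stack([y.astype(float), rng.normal(size=500)])
        fit = fit_logistic_cv(X, y, seed=0)
        assert auc(fit.oos_prob, y).auc > 0.99

    def test_matches_analytic_gaussian_discriminant(self):
        # one feature, classes N(0,1) vs N(d',1): AUC = Phi(d'/sqrt(2))
        rng = np.random.default_rng(5)
        n = 4000
        y = (rng.random(n) < 0.5).astype(int)
        x = rng.normal(size=n) + y * 1.0
        fit = fit_logistic_cv(x[:, None], y, seed=0)
        assert auc(fit.oos_prob, y).auc == pytest.approx(
            norm.cdf(1 / np.sqrt(2)), abs=0.02
        )

    def test_every_trial_scored_out_of_sample_once(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.5).astype(int)
        fit = fit_logistic_cv(X, y, folds=10, seed=0)
        assert np.bincount(fit.fold_assignment).sum() == 200
        assert ((fit.oos_prob > 0) & (fit.oos_prob < 1)).all()

    def test_rt_class_split_at_median(self):
        rt = np.array([0.3, 0.4, 0.5, 0.6, 0.9])
        np.testing.assert_array_equal(rt_class_labels(rt), [1, 1, 0, 0, 0])


class TestBootstrapInference:
    def test_identical_datasets_give_even_odds(self):
        rng = np.random.default_rng(7)
        y = rng.random(600) < 0.5
        s = rng.normal(size=600) + y
        _, _, p = bootstrap_compare(s, y, s, y, n_boot=400, seed=0)
        assert abs(p - 0.5) < 0.06

    def test_planted_auc_gap_detected(self):
        rng = np.random.default_rng(8)
        n = 800
        ya = rng.random(n) < 0.5
        sa = rng.normal(size=n) + ya * 0.95   # AUC ~ 0.75
        yb = rng.random(n) < 0.5
        sb = rng.normal(size=n) + yb * 0.18   # AUC ~ 0.55
        _, _, p = bootstrap_compare(sa, ya, sb, yb, n_boot=600, seed=0)
        assert p < 0.01

    def test_se_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(9)
        ses = {}
        for n in (400, 1600):
            y = rng.random(n) < 0.5
            s = rng.normal(size=n) + y * 0.5
            se, _, _ = bootstrap_compare(s, y, s, y, n_boot=500, seed=1)
            ses[n] = se
        assert ses[400] / ses[1600] == pytest.approx(2.0, rel=0.3)

    def test_paired_session_test(self):
        a = np.full(8, 0.7)
        assert session_auc_test(a, a) == 0.5
        rng = np.random.default_rng(10)
        b = a - 0.1 + rng.normal(0, 0.005, 8)
        assert session_auc_test(a, b) < 0.01
        # boundary AUC of 1.0 is clamped, not fatal
        assert np.isfinite(session_auc_test(np.append(a[:7], 1.0), b))
        with pytest.raises(ValueError):
            session_auc_test([0.6, 0.7], [0.5, 0.6])


class TestCodingDirections:
    def test_cosine_similarity_hand_examples(self):
        assert cosine_similarity([1, 1, 0], [1, 1, 0]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(
            1 / np.sqrt(2)
        )
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_projection_on_unit_vector_reads_one_feature(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 4))
        np.testing.assert_allclose(project(X, [0, 0, 1, 0]), X[:, 2])
        with pytest.raises(ValueError):
            project(X, [1, 0])

    def test_coding_direction_recovers_planted_axis(self):
        rng = np.random.default_rng(12)
        n = 3000
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(n, 5))
        X[:, 1] += y * 1.5
        cd = coding_direction(X, y, target="choice")
        assert np.argmax(np.abs(cd.weights)) == 1
        # projections onto the planted axis separate the classes
        assert auc(project(X, cd), y).auc > 0.8


class TestTimeResolved:
    def test_no_signal_before_motion_onset(self, small_session):
        bundle, _ = small_session
        trials = bundle.trials
        labels = dict(zip(trials["trial_id"], (trials["choice"] == "left").astype(int)))
        from popconf.data import PRESACCADIC_WINDOW, extract_counts
        cm = extract_counts(
            bundle, PRESACCADIC_WINDOW, alignment="saccade",
            neuron_filter=bundle.tin_ids, standardize=True,
        )
        y = np.array([labels[t] for t in cm.trial_ids])
        cd = coding_direction(cm.values, y, target="choice")
        ts, series = time_resolved_auc(
            bundle, cd, labels, t_range=(-0.3, 0.6), window=0.1, step=0.1
        )
        pre = series[ts <= -0.1]
        post = series[(ts >= 0.3)]
        assert np.nanmean(np.abs(pre - 0.5)) < 0.05
        assert np.nanmean(post) > np.nanmean(pre) + 0.05

    def test_series_invariant_to_additive_count_shift(self):
        # projections onto a direction shift by a constant; AUC is rank-based
        rng = np.random.default_rng(13)
        s = rng.normal(size=400)
        y = rng.random(400) < 0.5
        assert auc(s + 7.0, y).auc == auc(s, y).auc
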