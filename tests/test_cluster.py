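import numpy as np
import pandas as pd
import pytest

from popconf.cluster import (
    ClusterAssignment,
    cluster_decode,
    cluster_neurons,
    control_task_cluster_test,
    neuron_regression,
    split_half_chance,
    split_half_stability,
)


def blob_regs(rng, centers, n_per=20, sd=0.1):
    rows = []
    nid = 0
    for c in centers:
        for _ in range(n_per):
            b1, b2, b3 = rng.normal(c, sd)
            rows.append({"neuron_id": nid, "beta1": b1, "beta2": b2, "beta3": b3})
            nid += 1
    return pd.DataFrame(rows).set_index("neuron_id")


class TestKmeans:
    def test_well_separated_blobs_recovered_and_ordered(self):
        rng = np.random.default_rng(0)
        centers = [(-2.0, 1.0, 0.0), (0.5, -1.0, 0.3), (3.0, 0.0, -0.2)]
        regs = blob_regs(rng, centers)
        asn = cluster_neurons(regs, seed=0)
        labels = np.array([asn.labels[n] for n in regs.index])
        expected = np.repeat([1, 2, 3], 20)
        np.testing.assert_array_equal(labels, expected)
        # centroid beta1 means ascend with the label
        assert asn.centroids[0, 0] < asn.centroids[1, 0] < asn.centroids[2, 0]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        regs = blob_regs(rng, [(-2, 0, 0), (0, 2, 0), (2, -2, 0)])
        asn = cluster_neurons(regs, seed=0)
        perm = regs.sample(frac=1.0, random_state=3)
        asn_p = cluster_neurons(perm, seed=0)
        assert asn.labels == asn_p.labels

    def test_identical_points_degenerate(self):
        regs = pd.DataFrame(
            {"beta1": 1.0, "beta2": 0.0, "beta3": 0.0},
            index=pd.Index(range(10), name="neuron_id"),
        )
        with pytest.raises(ValueError, match="degenerate|distinct"):
            cluster_neurons(regs)

    def test_fewer_neurons_than_clusters(self):
        regs = blob_regs(np.random.default_rng(2), [(0, 0, 0)], n_per=2)
        with pytest.raises(ValueError):
            cluster_neurons(regs, k=3)


class TestNeuronRegression:
    def test_recovers_planted_coefficient_structure(self, small_session):
        bundle, truth = small_session
        regs = neuron_regression(bundle)
        planted = truth.coefficients.set_index("neuron_id").loc[regs.index]
        # standardized-count coefficients are proportional to the planted
        # rate-scale coefficients; rank agreement is the recovery check.
        # beta1 is attenuated because neurons encode the perceived (noisy)
        # evidence while the regression uses the nominal coherence.
        for est, true, r_min in (
            ("beta1", "b_coh", 0.6),
            ("beta2", "b_rt", 0.8),
            ("beta3", "b_choice", 0.6),
        ):
            r = np.corrcoef(regs[est], planted[true])[0, 1]
            assert r > r_min, f"{est} vs {true}: r={r:.2f}"

    def test_cluster_labels_recovered_end_to_end(self, small_session):
        # realistic (noisy) conditions: most neurons land in their planted
        # cluster, with a few boundary misassignments; exact recovery under
        # strong separation is covered by the cluster-study conditions
        bundle, truth = small_session
        regs = neuron_regression(bundle)
        asn = cluster_neurons(regs, seed=0)
        planted = truth.coefficients.set_index("neuron_id")["cluster"]
        got = np.array([asn.labels[n] for n in regs.index])
        assert (got == planted.loc[regs.index].to_numpy()).mean() >= 0.85

    def test_single_coherence_design_rejected(self, small_session):
        bundle, _ = small_session
        one_coh = bundle.trials.loc[
            (bundle.trials["coherence"] == 0.128) & bundle.trials["correct"],
            "trial_id",
        ]
        sub = bundle.subset_trials(one_coh)
        with pytest.raises(ValueError):
            neuron_regression(sub)


class TestSplitHalf:
    def test_planted_separation_fully_stable(self):
        from popconf.synth import cluster_study_config, generate_session

        bundle, _ = generate_session(cluster_study_config(seed=7))
        assert split_half_stability(bundle, seed=0) == 1.0

    def test_null_coefficients_at_permutation_chance(self):
        from popconf.synth import PopulationGenConfig, generate_session

        cfg = PopulationGenConfig(
            n_trials=1200, n_neurons_per_cluster=(12, 12, 12), seed=21,
            coef_means=((0.0, 0.0, 4.0),) * 3, coef_sd=0.3,
            shared_noise_sd=0.0,
        )
        bundle, _ = generate_session(cfg)
        frac = split_half_stability(bundle, seed=0)
        chance = split_half_chance(np.array([12, 12, 12]), n_rep=500, seed=0)
        assert abs(frac - chance) < 0.2

    def test_chance_level_exceeds_one_third(self):
        # permutation matching inflates chance above the naive 1/k
        chance = split_half_chance(np.array([20, 20, 20]), n_rep=500, seed=1)
        assert 1 / 3 < chance < 0.75


class TestClusterDecode:
    def test_informative_clusters_beat_null_cluster(self, small_session):
        bundle, _ = small_session
        asn = cluster_neurons(neuron_regression(bundle), seed=0)
        per = cluster_decode(bundle, asn, mode="per_cluster", seed=0)
        # planted: clusters 1 and 3 carry coherence/RT coding, cluster 2 none
        assert per[1].auc > per[2].auc
        assert per[3].auc > per[2].auc

    def test_two_cluster_means_match_full_population(self, small_session):
        bundle, _ = small_session
        asn = cluster_neurons(neuron_regression(bundle), seed=0)
        pair = cluster_decode(bundle, asn, mode="mean_of_clusters_13", seed=0)
        full = cluster_decode(
            bundle,
            ClusterAssignment(
                labels={int(n): 1 for n in bundle.tin_ids},
                centroids=np.zeros((1, 3)), inertia=0.0, k=1,
            ),
            mode="per_cluster", seed=0,
        )
        assert pair["mean_13"].auc > full[1].auc - 0.05

    def test_grand_mean_collapses_heterogeneous_code(self, small_session):
        bundle, _ = small_session
        asn = cluster_neurons(neuron_regression(bundle), seed=0)
        gm = cluster_decode(bundle, asn, mode="grand_mean", seed=0)
        full = cluster_decode(bundle, asn, mode="mean_of_clusters_13", seed=0)
        # averaging across all neurons cancels the opposed cluster codes
        assert gm["grand_mean"].auc < full["mean_13"].auc

    def test_single_cluster_equals_population_decode(self, small_session):
        bundle, _ = small_session
        one = ClusterAssignment(
            labels={int(n): 1 for n in bundle.tin_ids},
            centroids=np.zeros((1, 3)), inertia=0.0, k=1,
        )
        a = cluster_decode(bundle, one, mode="per_cluster", seed=0)[1]
        from popconf.data import PRESACCADIC_WINDOW, extract_counts
        from popconf.decode import auc as auc_fn, fit_logistic_cv

        use = bundle.trials[bundle.trials["choice"] == "left"]
        cm = extract_counts(
            bundle, PRESACCADIC_WINDOW, alignment="saccade",
            neuron_filter=bundle.tin_ids, trial_filter=use["trial_id"],
            standardize=True,
        )
        y = use.set_index("trial_id").loc[cm.trial_ids, "correct"].astype(int).to_numpy()
        fit = fit_logistic_cv(cm.values, y, seed=0)
        assert a.auc == pytest.approx(auc_fn(fit.oos_prob, y).auc, abs=1e-12)


class TestControlTasks:
    @staticmethod
    def _assignment(n_per=30):
        labels = {}
        nid = 0
        for c in (1, 2, 3):
            for _ in range(n_per):
                labels[nid] = c
                nid += 1
        return ClusterAssignment(labels, np.zeros((3, 3)), 0.0, k=3)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        asn = self._assignment()
        diffs = pd.Series(rng.normal(size=90), index=range(90))
        diffs.loc[0:29] += 1.0   # cluster 1 shifted by +1 SD
        means, pvals = control_task_cluster_test(diffs, asn)
        assert pvals[(1, 2)] < 0.01 and pvals[(1, 3)] < 0.01
        assert pvals[(2, 3)] > 0.01

    def test_sign_flip_leaves_pvalues_unchanged(self):
        rng = np.random.default_rng(4)
        asn = self._assignment()
        diffs = pd.Series(rng.normal(size=90), index=range(90))
        _, p1 = control_task_cluster_test(diffs, asn)
        _, p2 = control_task_cluster_test(-diffs, asn)
        for k in p1:
            assert p1[k] == pytest.approx(p2[k])

    def test_tiny_cluster_reports_undefined(self):
        labels = {0: 1, 1: 1, 2: 2, 3: 2, 4: 2, 5: 3, 6: 3, 7: 3}
        asn = ClusterAssignment(labels, np.zeros((3, 3)), 0.0, k=3)
        diffs = pd.Series(np.arange(8.0), index=range(8))
        _, pvals = control_task_cluster_test(diffs, asn)
        assert np.isnan(pvals[(1, 2)])
        assert np.isfinite(pvals[(2, 3)])
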