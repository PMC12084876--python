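import numpy as np
import pytest
from scipy.stats import norm, spearmanr

from popconf.cluster import ClusterAssignment
from popconf.pulse import (
    PulseResponseCurve,
    bootstrap_alpha_compare,
    cluster_pulse_curve,
    decay_f,
    fit_decay,
    pulse_delta_response,
)

TS = np.round(np.arange(-0.06, 0.801, 0.02), 9)


class TestDecayFunction:
    def test_zero_dissipation_reduces_to_scaled_cumulative_gaussian(self):
        t = np.linspace(-0.2, 1.0, 500)
        f = decay_f(t, d=1.3, mu=0.2, sigma=0.05, alpha=0.0)
        ref = 1.3 * norm.cdf(t, loc=0.2, scale=0.05)
        assert np.max(np.abs(f - ref)) < 1e-10

    @pytest.mark.parametrize("alpha", [-2.0, 0.0, 3.0, 30.0, 100.0])
    def test_solves_the_dissipation_ode(self, alpha):
        # df/dt = -alpha f + d N(t|mu, sigma), checked by central differences
        d, mu, sigma = 0.8, 0.2, 0.05
        h = 1e-6
        t = np.linspace(0.05, 0.6, 200)
        fp = (decay_f(t + h, d, mu, sigma, alpha) - decay_f(t - h, d, mu, sigma, alpha)) / (2 * h)
        rhs = -alpha * decay_f(t, d, mu, sigma, alpha) + d * norm.pdf(t, mu, sigma)
        assert np.max(np.abs(fp - rhs)) < 1e-5

    def test_parameter_recovery_from_noisy_curve(self):
        rng = np.random.default_rng(0)
        true = dict(d=1.0, mu=0.2, sigma=0.05, alpha=3.0)
        D = decay_f(TS, **true) + rng.normal(0, 0.02, TS.size)
        fit = fit_decay(PulseResponseCurve(t=TS, delta=D, D=D))
        assert abs(fit.alpha - true["alpha"]) < 0.5

    def test_fitted_alpha_tracks_planted_persistence_ladder(self):
        rng = np.random.default_rng(1)
        planted = [0.3, 1.0, 3.0, 10.0, 30.0]
        fitted = []
        for a in planted:
            D = decay_f(TS, 1.0, 0.2, 0.05, a) + rng.normal(0, 0.01, TS.size)
            fitted.append(fit_decay(PulseResponseCurve(t=TS, delta=D, D=D)).alpha)
        assert spearmanr(planted, fitted).statistic == pytest.approx(1.0, abs=1e-9)


def _neuron_curves(rng, alphas, n_per=40, noise=0.05):
    """Per-neuron pulse curves drawn around cluster decay shapes."""
    deltas, labels = [], {}
    nid = 0
    for k, a in enumerate(alphas, 1):
        base = decay_f(TS, 1.0, 0.2, 0.05, a)
        for _ in range(n_per):
            deltas.append(base + rng.normal(0, noise, TS.size))
            labels[nid] = k
            nid += 1
    curves = PulseResponseCurve(
        t=TS, delta=np.array(deltas), neuron_ids=np.arange(nid)
    )
    asn = ClusterAssignment(labels, np.zeros((len(alphas), 3)), 0.0, k=len(alphas))
    return curves, asn


class TestClusterCurves:
    def test_single_neuron_cluster_is_its_own_baseline_subtracted_curve(self):
        rng = np.random.default_rng(2)
        curves, asn = _neuron_curves(rng, [3.0], n_per=1)
        c = cluster_pulse_curve(curves, asn, 1)
        base = np.nanmean(curves.delta[0][(TS >= 0) & (TS <= 0.2)])
        np.testing.assert_allclose(c.D, curves.delta[0] - base)

    def test_baseline_interval_mean_is_zero_by_construction(self):
        rng = np.random.default_rng(3)
        curves, asn = _neuron_curves(rng, [3.0, 0.5])
        for K in (1, 2):
            c = cluster_pulse_curve(curves, asn, K)
            assert abs(np.nanmean(c.D[(TS >= 0) & (TS <= 0.2)])) < 1e-12

    def test_duplicated_neuron_does_not_change_mean(self):
        rng = np.random.default_rng(4)
        curves, asn = _neuron_curves(rng, [3.0], n_per=1)
        dup = PulseResponseCurve(
            t=TS, delta=np.vstack([curves.delta, curves.delta]),
            neuron_ids=np.array([0, 1]),
        )
        asn2 = ClusterAssignment({0: 1, 1: 1}, np.zeros((1, 3)), 0.0, k=1)
        c1 = cluster_pulse_curve(curves, asn, 1)
        c2 = cluster_pulse_curve(dup, asn2, 1)
        np.testing.assert_allclose(c1.D, c2.D)


class TestBootstrapCompare:
    def test_planted_dissipation_ordering_detected(self):
        rng = np.random.default_rng(5)
        curves, asn = _neuron_curves(rng, [10.0, 0.5], n_per=40)
        prop = bootstrap_alpha_compare(curves, asn, 1, 2, n_boot=200, seed=0)
        assert prop > 0.95

    def test_swapping_clusters_mirrors_the_proportion(self):
        rng = np.random.default_rng(6)
        curves, asn = _neuron_curves(rng, [5.0, 1.0], n_per=20)
        p_ab = bootstrap_alpha_compare(curves, asn, 1, 2, n_boot=100, seed=3)
        p_ba = bootstrap_alpha_compare(curves, asn, 2, 1, n_boot=100, seed=3)
        assert p_ab + p_ba == pytest.approx(1.0, abs=0.15)

    def test_identical_clusters_are_exchangeable(self):
        # any one realization reflects its sampled neurons; exchangeability
        # shows up in the average over independent populations
        rng = np.random.default_rng(7)
        props = []
        for _ in range(6):
            curves, asn = _neuron_curves(rng, [3.0, 3.0], n_per=30)
            props.append(
                bootstrap_alpha_compare(curves, asn, 1, 2, n_boot=60, seed=1)
            )
        assert 0.25 < np.mean(props) < 0.75


class TestDeltaResponse:
    def test_antisymmetric_under_pulse_label_swap(self, small_session):
        bundle, _ = small_session
        curves = pulse_delta_response(bundle, neuron_ids=bundle.tin_ids[:6])
        flipped = bundle.trials.copy()
        swap = {"left": "right", "right": "left"}
        flipped["pulse_direction"] = flipped["pulse_direction"].map(
            lambda v: swap.get(v, v)
        )
        import dataclasses
        b2 = dataclasses.replace(bundle, trials=flipped)
        curves2 = pulse_delta_response(b2, neuron_ids=bundle.tin_ids[:6])
        np.testing.assert_allclose(curves.delta, -curves2.delta, atol=1e-12)

    def test_no_pulse_trials_rejected(self, small_session):
        bundle, _ = small_session
        import dataclasses
        t = bundle.trials.copy()
        t["pulse_onset"] = np.nan
        with pytest.raises(ValueError):
            pulse_delta_response(dataclasses.replace(bundle, trials=t))

    def test_planted_cluster_persistence_ordering_in_generator(self):
        from popconf.synth import generate_session, pulse_study_config

        bundle, truth = generate_session(pulse_study_config(seed=8))
        curves = pulse_delta_response(bundle, t_range=(-0.06, 0.7))
        labels = truth.coefficients.set_index("neuron_id")["cluster"]
        asn = ClusterAssignment(
            labels.to_dict(), np.zeros((3, 3)), 0.0, k=3
        )
        alphas = {}
        for K in (1, 2, 3):
            alphas[K] = fit_decay(cluster_pulse_curve(curves, asn, K)).alpha
        # generator plants increasing dissipation rates across clusters
        assert alphas[1] < alphas[2] < alphas[3]
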