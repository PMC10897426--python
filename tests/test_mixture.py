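"""Gaussian-mixture EM, BIC component selection, percentile gating, and
model-based subpopulation probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from mmpsim import (
    EmptyGateWarning,
    FlowSample,
    MixtureFit,
    MixtureSpec,
    ValidationError,
    fit_mixture,
    gate_percentiles,
    generate_flow_sample,
    select_components,
    subpopulation_probability,
)


def _two_component_sample(n=5000, seed=123):
    spec = MixtureSpec(weights=(0.5, 0.5), means=(10.0, 20.0), sds=(1.0, 2.0))
    return generate_flow_sample(spec, n, seed)


class TestFitMixture:
    def test_k1_is_the_closed_form_mle(self, bimodal_sample):
        fit = fit_mixture(bimodal_sample, 1, seed=0)
        x = bimodal_sample.intensities
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-8)
        assert fit.sds[0] == pytest.approx(x.std(), abs=1e-8)  # ML divisor N
        assert fit.weights[0] == 1.0
        assert fit.converged

    def test_two_component_recovery(self):
        sample = _two_component_sample()
        fit = fit_mixture(sample, 2, seed=1)
        assert fit.converged
        np.testing.assert_allclose(fit.means, [10.0, 20.0], atol=0.2)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.03)

    def test_agrees_with_independent_em_implementation(self):
        """Cross-check against scikit-learn's GaussianMixture on the same
        sample: both routes must land on the same two components."""
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        sample = _two_component_sample()
        fit = fit_mixture(sample, 2, seed=1)
        gm = sklearn_mixture.GaussianMixture(
            n_components=2, n_init=3, random_state=0, tol=1e-6
        ).fit(sample.intensities[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(fit.means, gm.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(fit.weights, gm.weights_[order], atol=0.01)
        np.testing.assert_allclose(
            fit.sds, np.sqrt(gm.covariances_.ravel()[order]), atol=0.05
        )

    def test_constant_sample_hits_the_sd_floor_and_converges(self):
        sample = FlowSample("const", np.full(40, 7.0))
        fit = fit_mixture(sample, 2, seed=0)
        assert fit.converged
        assert np.all(fit.sds == 1e-12)
        assert np.isfinite(fit.log_likelihood)

    def test_log_likelihood_trace_is_monotone(self):
        fit = fit_mixture(_two_component_sample(n=2000), 3, seed=4)
        trace = np.asarray(fit.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_too_few_events_raises(self):
        sample = FlowSample("tiny", np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="2k"):
            fit_mixture(sample, 2, seed=0)

    def test_scale_equivariance(self):
        sample = _two_component_sample(n=2000)
        scaled = FlowSample("scaled", sample.intensities * 3.0)
        fit = fit_mixture(sample, 2, seed=2)
        fit3 = fit_mixture(scaled, 2, seed=2)
        np.testing.assert_allclose(fit3.means, 3.0 * fit.means, rtol=1e-6)
        np.testing.assert_allclose(fit3.sds, 3.0 * fit.sds, rtol=1e-6)
        np.testing.assert_allclose(fit3.weights, fit.weights, atol=1e-6)


class TestSelectComponents:
    def test_unimodal_sample_selects_one_component(self):
        spec = MixtureSpec(weights=(1.0,), means=(10.0,), sds=(1.0,))
        sample = generate_flow_sample(spec, 5000, seed=11)
        best = select_components(sample, 3, seed=0)
        # direct BIC oracle: the k = 1 fit must beat the k = 2 fit
        f1 = fit_mixture(sample, 1, seed=0)
        f2 = fit_mixture(sample, 2, seed=0)
        assert f1.bic <= f2.bic
        assert best.k == 1

    def test_bimodal_fixture_selects_two_components(self, bimodal_sample):
        best = select_components(bimodal_sample, 4, seed=0)
        f1 = fit_mixture(bimodal_sample, 1, seed=0)
        f2 = fit_mixture(bimodal_sample, 2, seed=0)
        assert f2.bic < f1.bic
        assert best.k == 2

    def test_kmax_one_returns_the_single_component_fit(self, bimodal_sample):
        assert select_components(bimodal_sample, 1, seed=0).k == 1

    def test_bic_formula(self, bimodal_sample):
        fit = fit_mixture(bimodal_sample, 2, seed=0)
        n = bimodal_sample.n_events
        expected = -2.0 * fit.log_likelihood + (3 * 2 - 1) * np.log(n)
        assert fit.bic == pytest.approx(expected)


class TestGatePercentiles:
    def test_exact_ranks_on_one_to_hundred(self):
        sample = FlowSample("ranks", np.arange(1.0, 101.0))
        gate = gate_percentiles(sample, 0.05, 0.05)
        assert sorted(sample.intensities[gate.low_indices]) == [1, 2, 3, 4, 5]
        assert gate.low_threshold == 5.0
        assert sorted(sample.intensities[gate.high_indices]) == [96, 97, 98, 99, 100]
        assert gate.high_threshold == 96.0

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(2, 5000), frac=st.floats(0.01, 0.5))
    def test_gate_size_is_floor_of_fraction_times_n(self, n, frac):
        rng = np.random.default_rng(n)
        sample = FlowSample("s", rng.uniform(1.0, 100.0, n))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyGateWarning)
            gate = gate_percentiles(sample, frac, frac)
        assert gate.low_indices.size == int(np.floor(frac * n))
        assert gate.high_indices.size == int(np.floor(frac * n))
        assert set(gate.low_indices) & set(gate.high_indices) == set() or frac > 0.5

    def test_empty_gate_warns(self):
        sample = FlowSample("ten", np.arange(1.0, 11.0))
        with pytest.warns(EmptyGateWarning):
            gate = gate_percentiles(sample, 0.05, 0.5)
        assert gate.low_indices.size == 0
        assert gate.high_indices.size == 5

    def test_stable_tie_break(self):
        sample = FlowSample("ties", np.array([2.0, 1.0, 1.0, 1.0, 5.0, 6.0]))
        gate = gate_percentiles(sample, 0.4, 0.2)
        # two lowest slots: the earliest events with intensity 1
        assert gate.low_indices.tolist() == [1, 2]

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_bounds(self, frac, bimodal_sample):
        with pytest.raises(ValidationError):
            gate_percentiles(bimodal_sample, frac, 0.05)


class TestSubpopulationProbability:
    def _fit(self, weights, means, sds):
        return MixtureFit(
            k=len(weights), weights=np.asarray(weights, float),
            means=np.asarray(means, float), sds=np.asarray(sds, float),
            log_likelihood=0.0, bic=0.0, n_iter=1, converged=True,
        )

    def test_single_standard_normal_symmetry(self):
        fit = self._fit([1.0], [0.0], [1.0])
        assert subpopulation_probability(fit, 0.0, "below") == pytest.approx(0.5)

    def test_symmetric_two_component_mixture(self):
        fit = self._fit([0.5, 0.5], [-10.0, 10.0], [1.0, 1.0])
        assert subpopulation_probability(fit, 0.0, "below") == pytest.approx(0.5)
        assert subpopulation_probability(fit, 0.0, "above") == pytest.approx(0.5)

    def test_matches_numerical_integration_of_the_density(self, bimodal_sample):
        fit = fit_mixture(bimodal_sample, 2, seed=0)
        threshold = float(np.quantile(bimodal_sample.intensities, 0.05))
        p = subpopulation_probability(fit, threshold, "below")
        oracle, err = quad(fit.pdf, -np.inf, threshold)
        assert abs(p - oracle) < max(1e-6, 10 * err)

    def test_label_permutation_invariance(self):
        fit = self._fit([0.3, 0.7], [2.0, 8.0], [0.5, 1.5])
        permuted = self._fit([0.7, 0.3], [8.0, 2.0], [1.5, 0.5])
        x = np.linspace(0, 12, 50)
        np.testing.assert_allclose(fit.pdf(x), permuted.pdf(x))
        for thr in (1.0, 5.0, 9.0):
            assert subpopulation_probability(fit, thr) == pytest.approx(
                subpopulation_probability(permuted, thr)
            )

    def test_requires_converged_fit_and_finite_threshold(self):
        fit = self._fit([1.0], [0.0], [1.0])
        with pytest.raises(ValidationError):
            subpopulation_probability(fit, np.inf)
        bad = MixtureFit(k=1, weights=np.array([1.0]), means=np.array([0.0]),
                         sds=np.array([1.0]), log_likelihood=0.0, bic=0.0,
                         n_iter=1, converged=False)
        with pytest.raises(ValidationError):
            subpopulation_probability(bad, 0.0)

    def test_gate_probability_consistency(self, bimodal_sample):
        """For a tight fit, the mixture tail mass below the empirical 5%
        threshold approaches the gate fraction."""
        fit = fit_mixture(bimodal_sample, 2, seed=0)
        gate = gate_percentiles(bimodal_sample, 0.05, 0.05)
        p = subpopulation_probability(fit, gate.low_threshold, "below")
        assert abs(p - 0.05) < 0.01
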