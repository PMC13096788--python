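"""Tests of the MLE/LSE/WLS estimation machinery."""

import numpy as np
import pytest

from nowwdist import (
    DomainError,
    NOWWParams,
    fit_lse,
    fit_mle,
    fit_neutrosophic,
    fit_wls,
    heart_pulse_data,
    loglik,
    noww_cdf,
    noww_logpdf,
    noww_quantile,
    noww_rvs,
    plotting_weights,
    synthetic_intervals,
)
from nowwdist.neutro import Interval, IntervalSample

TRUTH = NOWWParams(0.9, 1.2, 1.6, 1.4)


@pytest.fixture(scope="module")
def synth2000():
    return noww_rvs(2000, TRUTH, seed=1)


class TestLoglik:
    def test_single_observation(self, p_mid):
        x = 0.8
        assert loglik(p_mid, [x]) == pytest.approx(float(noww_logpdf(x, p_mid)), rel=1e-14)

    def test_permutation_invariance(self, p_mid, rng):
        data = rng.uniform(0.1, 2.0, size=30)
        assert loglik(p_mid, data) == pytest.approx(
            loglik(p_mid, rng.permutation(data)), rel=1e-12
        )

    def test_sums_logpdf(self, p_mid, rng):
        data = rng.uniform(0.1, 2.0, size=50)
        assert loglik(p_mid, data) == pytest.approx(
            float(np.sum(noww_logpdf(data, p_mid))), rel=1e-14
        )

    def test_variant_difference_formula(self, p_mid, rng):
        # exact minus uncorrected = sum log((1-e^-u) e^u + u) - log(1-e^-u)
        data = rng.uniform(0.1, 2.0, size=40)
        u = p_mid.alpha * data**p_mid.beta
        em = -np.expm1(-u)
        expected = float(np.sum(np.log(em * np.exp(u) + u) - np.log(em)))
        diff = loglik(p_mid, data, "exact") - loglik(p_mid, data, "uncorrected")
        assert diff == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_data_rejected(self, p_mid):
        with pytest.raises(DomainError):
            loglik(p_mid, [1.0, -0.5])

    def test_unknown_variant(self, p_mid):
        with pytest.raises(DomainError):
            loglik(p_mid, [1.0], variant="printed")


class TestPlottingWeights:
    def test_n3_exact(self):
        w = plotting_weights(3).weights
        assert np.allclose(w, [80 / 3, 20.0, 80 / 3])

    def test_symmetry(self):
        w = plotting_weights(10).weights
        assert np.allclose(w, w[::-1])

    def test_positive_large_n(self):
        assert np.all(plotting_weights(10_000).weights > 0)

    def test_invalid_n(self):
        with pytest.raises(DomainError):
            plotting_weights(0)


class TestFitMle:
    def test_determinism(self, synth2000):
        data = synth2000[:200]
        a = fit_mle(data, seed=7)
        b = fit_mle(data, seed=7)
        assert a.params.as_tuple() == b.params.as_tuple()
        assert a.objective == b.objective

    def test_optimality_beats_truth(self, synth2000):
        r = fit_mle(synth2000, seed=7)
        assert r.objective >= loglik(TRUTH, synth2000)
        assert r.converged

    def test_functional_recovery(self, synth2000):
        # the fitted law matches the truth closely even though individual
        # parameters ride a flat likelihood ridge and are weakly identified
        r = fit_mle(synth2000, seed=7)
        xs = np.linspace(1e-3, noww_quantile(0.999, TRUTH), 300)
        assert np.max(np.abs(noww_cdf(xs, r.params) - noww_cdf(xs, TRUTH))) < 0.05

    def test_explicit_starts_used(self, synth2000):
        r = fit_mle(synth2000[:100], starts=[TRUTH], seed=0)
        assert r.n_starts_used == 1
        assert r.objective >= loglik(TRUTH, synth2000[:100])

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            fit_mle([0.5, 0.8, 1.1], starts=[TRUTH], seed=0)


class TestFitLsWls:
    def test_objective_nonnegative(self, synth2000):
        data = synth2000[:300]
        assert fit_lse(data, seed=7).objective >= 0.0
        assert fit_wls(data, seed=7).objective >= 0.0

    def test_functional_recovery(self, synth2000):
        xs = np.linspace(1e-3, noww_quantile(0.999, TRUTH), 300)
        Ft = noww_cdf(xs, TRUTH)
        for fitter in (fit_lse, fit_wls):
            r = fitter(synth2000, seed=7)
            assert np.max(np.abs(noww_cdf(xs, r.params) - Ft)) < 0.05

    def test_wls_with_unit_weights_is_lse(self, synth2000):
        data = synth2000[:300]
        a = fit_lse(data, seed=7)
        b = fit_wls(data, seed=7, weights=np.ones(300))
        assert a.params.as_tuple() == pytest.approx(b.params.as_tuple(), rel=1e-9)
        assert a.objective == pytest.approx(b.objective, rel=1e-9)

    def test_methods_agree_functionally(self, synth2000):
        # the three estimators agree on the law within sampling noise
        xs = np.linspace(0.2, noww_quantile(0.99, TRUTH), 100)
        curves = []
        for fitter in (fit_mle, fit_lse, fit_wls):
            r = fitter(synth2000, seed=7)
            curves.append(noww_cdf(xs, r.params))
        for c in curves[1:]:
            assert np.max(np.abs(c - curves[0])) < 0.03


class TestFitNeutrosophic:
    def test_zero_width_sample_degenerates(self, synth2000):
        data = synth2000[:80]
        s = IntervalSample.from_arrays(data, data)
        r = fit_neutrosophic(s, method="mle", seed=3)
        assert r.lower_fit.params.as_tuple() == r.upper_fit.params.as_tuple()
        assert r.interval_params.lambda_.is_degenerate()

    def test_two_stream_functional_recovery(self):
        s = synthetic_intervals(TRUTH, width_mean=0.4, width_shape=2.0, n=800, seed=5)
        r = fit_neutrosophic(s, method="mle", seed=3)
        xs = np.linspace(1e-3, noww_quantile(0.999, TRUTH), 200)
        # the lower-endpoint fit recovers the generating law of the lower stream
        d = np.max(np.abs(noww_cdf(xs, r.lower_fit.params) - noww_cdf(xs, TRUTH)))
        assert d < 0.06
        # assembled intervals contain both point estimates
        for iv, a, b in zip(
            (r.interval_params.lambda_, r.interval_params.delta,
             r.interval_params.alpha, r.interval_params.beta),
            r.lower_fit.params.as_tuple(),
            r.upper_fit.params.as_tuple(),
        ):
            assert iv.lo <= min(a, b) + 1e-12 and iv.hi >= max(a, b) - 1e-12

    def test_heart_loglik_ordering(self):
        # upper-endpoint sample has the larger (worse) -logL, as its spread
        # sits further from the fitted law; this ordering matches the
        # published interval bracketing for this dataset
        h = heart_pulse_data()
        r = fit_neutrosophic(h, method="mle", seed=1)
        assert -r.lower_fit.objective < -r.upper_fit.objective

    def test_unknown_method(self):
        with pytest.raises(DomainError):
            fit_neutrosophic(heart_pulse_data(), method="map", seed=0)
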