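"""Tests of the classical NOWW distribution functions."""

import math

import numpy as np
import pytest
from scipy import integrate

from nowwdist import (
    ComputationError,
    DomainError,
    NOWWParams,
    cf,
    incomplete_moment,
    mgf,
    moment_ratios,
    noww_cdf,
    noww_hazard,
    noww_logpdf,
    noww_pdf,
    noww_quantile,
    noww_rvs,
    noww_sf,
    raw_moment,
    renyi_entropy,
)
from nowwdist.core import quantile_lambertw

from conftest import random_params


class TestParams:
    def test_valid_construction(self):
        p = NOWWParams(1.0, 2.0, 0.5, 1.5)
        assert p.as_tuple() == (1.0, 2.0, 0.5, 1.5)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_rejects_nonpositive_nonfinite(self, bad):
        with pytest.raises(DomainError):
            NOWWParams(bad, 1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            NOWWParams(1.0, 1.0, 1.0, bad)

    def test_from_sequence_length(self):
        with pytest.raises(DomainError):
            NOWWParams.from_sequence([1.0, 2.0, 3.0])


class TestCdf:
    def test_zero_at_origin(self, p_mid):
        assert noww_cdf(0.0, p_mid) == 0.0

    def test_monotone_and_limits(self, p_mid, rng):
        x = np.sort(rng.uniform(0.01, 5.0, size=200))
        F = noww_cdf(x, p_mid)
        assert np.all(np.diff(F) >= 0)
        assert np.all((F >= 0) & (F <= 1))
        assert noww_cdf(50.0, p_mid) > 1 - 1e-12

    def test_table_inverse_value(self):
        # F at the printed Set-1 lower quantile for c = 0.1 recovers 0.1
        p = NOWWParams(1.1, 1.6, 1.8, 1.5)
        assert abs(noww_cdf(0.45228, p) - 0.1) < 1e-4

    def test_negative_x_rejected(self, p_mid):
        with pytest.raises(DomainError):
            noww_cdf(-0.5, p_mid)


class TestPdf:
    def test_normalization_random_params(self, rng):
        for p in random_params(rng, 20):
            hi = 10.0 * noww_quantile(0.999, p)
            val, _ = integrate.quad(lambda x: noww_pdf(x, p), 0.0, hi,
                                    limit=200, points=[noww_quantile(0.5, p)])
            assert abs(val - 1.0) < 1e-6

    def test_matches_cdf_derivative(self, rng):
        for p in random_params(rng, 20):
            x = noww_quantile(rng.uniform(0.05, 0.95), p)
            h = 1e-6 * x
            fd = (noww_cdf(x + h, p) - noww_cdf(x - h, p)) / (2 * h)
            assert abs(noww_pdf(x, p) - fd) < 1e-5 * max(1.0, fd)

    def test_delta_one_exponent_degeneracy(self, rng):
        # with delta = 1 the G**(delta-1) factor is identically 1, so the
        # density reduces to lambda * G'(x) * exp(-lambda * G): both exponent
        # sign conventions for that factor coincide
        for _ in range(10):
            lam, alpha, beta = rng.uniform(0.3, 3.0, size=3)
            p = NOWWParams(lam, 1.0, alpha, beta)
            x = float(rng.uniform(0.05, 2.0))
            u = alpha * x**beta
            g = u * -math.expm1(-u)
            gp = alpha * beta * x ** (beta - 1) * (-math.expm1(-u) + u * math.exp(-u))
            direct = lam * gp * math.exp(-lam * g)
            assert noww_pdf(x, p) == pytest.approx(direct, rel=1e-12)

    def test_nonnegative(self, p_mid, rng):
        x = rng.uniform(0.001, 10.0, size=100)
        assert np.all(noww_pdf(x, p_mid) >= 0)


class TestLogPdf:
    def test_identity_with_pdf(self, p_mid, rng):
        x = rng.uniform(0.05, 3.0, size=50)
        assert np.allclose(np.exp(noww_logpdf(x, p_mid)), noww_pdf(x, p_mid), rtol=1e-12)

    def test_finite_where_direct_underflows(self):
        # large u regime: direct density underflows to 0 but the log stays finite
        p = NOWWParams(2.0, 2.5, 2.0, 2.5)
        x = 20.0
        assert noww_pdf(x, p) == 0.0
        lp = noww_logpdf(x, p)
        assert np.isfinite(lp) and lp < -700

    def test_nonpositive_x_is_minus_inf(self, p_mid):
        assert noww_logpdf(0.0, p_mid) == -np.inf
        assert noww_logpdf(-1.0, p_mid) == -np.inf


class TestSfHazard:
    def test_sf_at_zero(self, p_mid):
        assert noww_sf(0.0, p_mid) == 1.0

    def test_sf_complement(self, p_mid, rng):
        x = rng.uniform(0.01, 5.0, size=50)
        assert np.allclose(noww_sf(x, p_mid) + noww_cdf(x, p_mid), 1.0, atol=1e-12)

    def test_hazard_identity(self, p_mid, rng):
        x = rng.uniform(0.05, 2.0, size=50)
        assert np.allclose(
            noww_hazard(x, p_mid) * noww_sf(x, p_mid), noww_pdf(x, p_mid), rtol=1e-10
        )

    def test_hazard_is_log_sf_derivative(self, p_mid):
        for x in [0.3, 0.7, 1.1]:
            h = 1e-6 * x
            fd = -(np.log(noww_sf(x + h, p_mid)) - np.log(noww_sf(x - h, p_mid))) / (2 * h)
            assert noww_hazard(x, p_mid) == pytest.approx(fd, rel=1e-5)


class TestQuantile:
    def test_table_set1_lower(self):
        p = NOWWParams(1.1, 1.6, 1.8, 1.5)
        assert abs(noww_quantile(0.1, p) - 0.45228) < 5e-5

    def test_table_set3_upper_vector(self):
        # the all-upper Set-3 vector produces the LOWER printed endpoint at c=0.5
        p = NOWWParams(2.3, 2.6, 2.4, 2.9)
        assert abs(noww_quantile(0.5, p) - 0.73899) < 5e-5

    def test_roundtrip(self, rng):
        for p in random_params(rng, 25):
            for c in rng.uniform(0.001, 0.999, size=4):
                x = noww_quantile(float(c), p)
                assert abs(noww_cdf(x, p) - c) < 1e-8

    def test_small_c_limit(self, p_mid):
        qs = [noww_quantile(c, p_mid) for c in (1e-3, 1e-6, 1e-9, 1e-12)]
        assert all(a > b for a, b in zip(qs, qs[1:]))
        assert qs[-1] < 0.01

    @pytest.mark.parametrize("c", [0.0, 1.0, -0.1, 1.3])
    def test_domain(self, c, p_mid):
        with pytest.raises(DomainError):
            noww_quantile(c, p_mid)

    def test_lambertw_tail_cross_check(self, rng):
        # the Lambert-type evaluator is a tail approximation: it agrees with
        # the root-finding quantile in the upper tail where u is large
        for p in random_params(rng, 10, lo=0.8, hi=2.0):
            errs = []
            for c in (0.999, 0.9999, 0.99999):
                a = noww_quantile(c, p)
                b = quantile_lambertw(c, p)
                errs.append(abs(b - a) / a)
            assert errs[0] < 2e-2
            # the approximation sharpens as the tail deepens
            assert errs[-1] < errs[0] and errs[-1] < 5e-3


class TestRvs:
    def test_determinism(self, p_mid):
        a = noww_rvs(100, p_mid, seed=42)
        b = noww_rvs(100, p_mid, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, noww_rvs(100, p_mid, seed=43))

    def test_support(self, p_mid):
        assert np.all(noww_rvs(1000, p_mid, seed=7) > 0)

    def test_ks_against_cdf(self, p_mid):
        n = 10_000
        x = np.sort(noww_rvs(n, p_mid, seed=11))
        z = noww_cdf(x, p_mid)
        i = np.arange(1, n + 1)
        d = max(np.max(i / n - z), np.max(z - (i - 1) / n))
        assert d < 1.63 / math.sqrt(n)


class TestMoments:
    def test_r0_is_one(self, p_mid):
        assert raw_moment(0, p_mid) == pytest.approx(1.0, abs=1e-8)

    def test_mean_against_sampling(self, p_mid):
        n = 100_000
        draws = noww_rvs(n, p_mid, seed=5)
        mu = raw_moment(1, p_mid)
        se = np.std(draws, ddof=1) / math.sqrt(n)
        assert abs(np.mean(draws) - mu) < 3 * se

    def test_variance_identity(self, p_mid):
        mr = moment_ratios(p_mid)
        mu1, mu2 = raw_moment(1, p_mid), raw_moment(2, p_mid)
        assert mr.variance == pytest.approx(mu2 - mu1**2, rel=1e-9)
        assert mr.variance >= 0

    def test_raw_ratio_definitions(self, p_mid):
        mr = moment_ratios(p_mid)
        mu2, mu3, mu4 = (raw_moment(r, p_mid) for r in (2, 3, 4))
        assert mr.skewness_raw == pytest.approx(mu3 / mu2**1.5, rel=1e-9)
        assert mr.kurtosis_raw == pytest.approx(mu4 / mu2**2 - 3, rel=1e-9)

    def test_central_skewness_against_sampling(self, p_mid):
        draws = noww_rvs(200_000, p_mid, seed=9)
        mr = moment_ratios(p_mid)
        d = draws - np.mean(draws)
        sk = np.mean(d**3) / np.mean(d**2) ** 1.5
        assert abs(sk - mr.skewness_central) < 0.05

    def test_invalid_order(self, p_mid):
        with pytest.raises(DomainError):
            raw_moment(-1, p_mid)


class TestIncompleteMoment:
    def test_small_y_vanishes(self, p_mid):
        assert incomplete_moment(1, 1e-6, p_mid) < 1e-8

    def test_converges_to_raw_moment(self, p_mid):
        y = 10.0 * noww_quantile(0.999, p_mid)
        assert incomplete_moment(2, y, p_mid) == pytest.approx(
            raw_moment(2, p_mid), rel=1e-4
        )

    def test_monotone_in_y(self, p_mid):
        ys = [0.3, 0.6, 1.0, 2.0]
        vals = [incomplete_moment(1, y, p_mid) for y in ys]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_dual_integrator(self, p_mid, rng):
        # independent fixed-order Gauss-Legendre vs adaptive quadrature
        for _ in range(5):
            r = int(rng.integers(1, 4))
            y = float(rng.uniform(0.3, 1.5))
            nodes, weights = np.polynomial.legendre.leggauss(400)
            xg = 0.5 * y * (nodes + 1.0)
            gl = 0.5 * y * np.sum(weights * xg**r * noww_pdf(xg, p_mid))
            assert incomplete_moment(r, y, p_mid) == pytest.approx(gl, rel=1e-6, abs=1e-9)


class TestMgfCf:
    def test_at_zero(self, p_mid):
        assert mgf(0.0, p_mid) == pytest.approx(1.0, abs=1e-8)
        assert cf(0.0, p_mid) == pytest.approx(1.0 + 0j, abs=1e-8)

    def test_mgf_derivative_is_mean(self, p_mid):
        h = 1e-4
        fd = (mgf(h, p_mid) - mgf(-h, p_mid)) / (2 * h)
        assert fd == pytest.approx(raw_moment(1, p_mid), rel=1e-4)

    def test_cf_bounded(self, p_mid):
        for t in [-5.0, -1.0, 0.5, 2.0, 10.0]:
            assert abs(cf(t, p_mid)) <= 1.0 + 1e-9

    def test_mgf_divergence_detected(self):
        # beta * delta < 1: stretched-exponential tail lighter than e^{tx}
        p = NOWWParams(1.0, 0.5, 1.0, 1.0)
        with pytest.raises(ComputationError):
            mgf(1.0, p)


class TestRenyi:
    def test_theta2_dual_integrator(self, p_mid):
        hi = 10.0 * noww_quantile(0.999, p_mid)
        nodes, weights = np.polynomial.legendre.leggauss(800)
        xg = 0.5 * hi * (nodes + 1.0)
        val = 0.5 * hi * np.sum(weights * noww_pdf(xg, p_mid) ** 2)
        assert renyi_entropy(2.0, p_mid) == pytest.approx(-math.log(val), rel=1e-6)

    def test_theta_limit_brackets_shannon(self, p_mid):
        hi = 10.0 * noww_quantile(0.999, p_mid)

        def sh_int(x):
            f = noww_pdf(x, p_mid)
            return -f * math.log(f) if f > 0 else 0.0

        shannon, _ = integrate.quad(sh_int, 0, hi, limit=200)
        lo_v = renyi_entropy(1.001, p_mid)
        hi_v = renyi_entropy(0.999, p_mid)
        assert lo_v <= shannon <= hi_v

    def test_monotone_nonincreasing_in_theta(self, p_mid):
        thetas = [0.5, 0.8, 1.5, 2.0, 3.0]
        vals = [renyi_entropy(t, p_mid) for t in thetas]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.5])
    def test_invalid_theta(self, theta, p_mid):
        with pytest.raises(DomainError):
            renyi_entropy(theta, p_mid)
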