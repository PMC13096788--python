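"""Series representations of the NOWW distribution functions.

Verification-grade code: every closed-form quantity in :mod:`nowwdist.core`
has a truncated-series twin here, built from two expansions.  Writing
``u = alpha * x**beta`` and ``G(u) = u * (1 - e^{-u})``:

* the exponential factor is expanded term by term,
  ``exp(-mu * G**delta) = sum_i (-mu)^i / i! * G**(i*delta)``;
* real powers ``G**s = u**(2s) * [(1 - e^{-u})/u]**s`` are expanded as a
  power series in ``u`` via the J.C.P. Miller recurrence for real powers of
  a power series (the base series ``(1 - e^{-u})/u`` has unit leading
  coefficient, so the recurrence applies directly).

The base series has radius of convergence ``2*pi`` (the nearest complex
zeros of ``1 - e^{-u}`` sit at ``u = +-2*pi*i``), so the expansion is only
trusted for ``u`` comfortably below that; every value carries a convergence
flag and flagged values must not be used in equivalence assertions.

Nothing in the estimation or goodness-of-fit code depends on this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import integrate, special

from .core import ComputationError, DomainError, NOWWParams, noww_pdf, noww_quantile

__all__ = [
    "SeriesConfig",
    "SeriesValue",
    "series_power",
    "cdf_series",
    "cdf_power_series",
    "pdf_series",
    "renyi_series",
]

_U_RADIUS = 2.0 * math.pi  # convergence radius of the base series in u


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation order and tail tolerance for all series evaluations."""

    K: int = 30
    tail_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if int(self.K) != self.K or self.K < 1:
            raise DomainError("truncation order K must be a positive integer")
        if not self.tail_tolerance > 0:
            raise DomainError("tail_tolerance must be positive")


class SeriesValue(NamedTuple):
    value: float
    converged: bool


def series_power(base_coeffs, exponent: float, K: int) -> np.ndarray:
    """First ``K + 1`` coefficients of ``(sum_w a_w z^w)**exponent``.

    Miller recurrence: with ``c_0 = a_0**m``,

        c_n = (n * a_0)^{-1} * sum_{k=1}^{n} (k * (m + 1) - n) * a_k * c_{n-k}.
    """
    a = np.asarray(base_coeffs, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise DomainError("base_coeffs must be a non-empty 1-d array")
    if a[0] == 0.0:
        raise DomainError("leading coefficient of the base series must be non-zero")
    if int(K) != K or K < 1:
        raise DomainError("K must be a positive integer")
    K = int(K)
    m = float(exponent)
    a = np.concatenate([a, np.zeros(max(0, K + 1 - a.size))])[: K + 1]
    c = np.zeros(K + 1)
    c[0] = a[0] ** m
    for n in range(1, K + 1):
        k = np.arange(1, n + 1)
        c[n] = np.sum((k * (m + 1.0) - n) * a[k] * c[n - k]) / (n * a[0])
    return c


@lru_cache(maxsize=4096)
def _base_coeffs(K: int) -> tuple[float, ...]:
    """Coefficients of (1 - e^{-u}) / u = sum_k (-1)^k u^k / (k+1)!."""
    return tuple((-1.0) ** k / math.factorial(k + 1) for k in range(K + 1))


@lru_cache(maxsize=4096)
def _h_over_u_coeffs(K: int) -> tuple[float, ...]:
    """Coefficients of h(u)/u with h = 1 - e^{-u} + u e^{-u}: (-1)^k (k+2)/(k+1)!."""
    return tuple((-1.0) ** k * (k + 2) / math.factorial(k + 1) for k in range(K + 1))


@lru_cache(maxsize=4096)
def _gpow_coeffs(s: float, K: int) -> tuple[float, ...]:
    """Coefficients of [(1 - e^{-u})/u]**s, truncated at order K."""
    return tuple(series_power(np.array(_base_coeffs(K)), s, K))


def _poly_eval(coeffs, u: float) -> tuple[float, float]:
    """Evaluate the truncated polynomial; return (value, error_estimate).

    The error estimate combines the truncation tail (last retained term) with
    round-off from cancellation (the largest intermediate term times machine
    epsilon); callers weigh it by the term's prefactor against the full sum.
    """
    c = np.asarray(coeffs, dtype=float)
    if u < 1e-12:
        return float(c[0]), 0.0
    k = np.arange(c.size, dtype=float)
    with np.errstate(over="ignore"):
        terms = c * u**k
    val = float(np.sum(terms))
    tail = float(np.abs(terms[-1]))
    peak = float(np.max(np.abs(terms)))
    err = tail + peak * 1e-15
    if not np.isfinite(val):
        return 0.0, np.inf
    return val, err


def _u_of(x: float, p: NOWWParams) -> float:
    return p.alpha * float(x) ** p.beta


def _exp_series(u: float, mu: float, p: NOWWParams, cfg: SeriesConfig) -> tuple[float, bool]:
    """Truncated series for exp(-mu * G(u)**delta)."""
    if u == 0.0:
        return 1.0, True
    total = 0.0
    err = 0.0 if u < _U_RADIUS else np.inf
    term_mag = np.inf
    for i in range(0, 4 * cfg.K + 1):
        s = i * p.delta
        poly, poly_err = _poly_eval(_gpow_coeffs(s, cfg.K), u)
        with np.errstate(over="ignore"):
            pref = float(np.float64(abs(mu)) ** i / math.factorial(i) * np.float64(u) ** (2.0 * s))
        term = (-1.0) ** i * pref * poly
        total += term
        err += pref * poly_err
        term_mag = abs(term)
        if i > 0 and term_mag <= cfg.tail_tolerance * max(1.0, abs(total)):
            break
    tol = cfg.tail_tolerance * max(1.0, abs(total))
    ok = np.isfinite(total) and term_mag <= tol and err <= max(tol, 1e-9 * max(1.0, abs(total)))
    return total, bool(ok)


def cdf_power_series(x, p: NOWWParams, theta: float, cfg: SeriesConfig | None = None) -> SeriesValue:
    """Truncated series for ``F(x)**theta``; ``theta = 1`` is the CDF itself.

    ``F**theta = sum_q (-1)^q C(theta, q) exp(-q * lambda * G**delta)``; the
    q-series is finite for integer ``theta`` and converges for real
    ``theta >= 0`` because ``exp(-lambda G**delta) < 1`` for x > 0.
    """
    cfg = cfg or SeriesConfig()
    theta = float(theta)
    if theta < 0:
        raise DomainError("theta must be non-negative")
    x = float(x)
    if x < 0:
        raise DomainError("x must be non-negative")
    if x == 0.0:
        return SeriesValue(1.0 if theta == 0.0 else 0.0, True)
    u = _u_of(x, p)
    q_max = int(theta) if float(theta).is_integer() else 4 * cfg.K
    total = 0.0
    ok = True
    last = np.inf
    for q in range(q_max + 1):
        coef = (-1.0) ** q * special.binom(theta, q)
        if coef == 0.0:
            continue
        ev, e_ok = _exp_series(u, q * p.lambda_, p, cfg)
        ok &= e_ok
        term = coef * ev
        total += term
        last = abs(term)
        if not float(theta).is_integer() and q > theta and last <= cfg.tail_tolerance * max(1.0, abs(total)):
            break
    if not float(theta).is_integer():
        ok = ok and last <= cfg.tail_tolerance * max(1.0, abs(total))
    return SeriesValue(total, bool(ok))


def cdf_series(x, p: NOWWParams, cfg: SeriesConfig | None = None) -> SeriesValue:
    """Truncated series for the CDF (the ``theta = 1`` power series)."""
    return cdf_power_series(x, p, 1.0, cfg)


def pdf_series(x, p: NOWWParams, cfg: SeriesConfig | None = None) -> SeriesValue:
    """Truncated series for the density.

    ``f = lambda*delta*alpha*beta * x**(beta-1) *
    sum_i (-lambda)^i/i! * u**(2 s_i + 1) * [h(u)/u * base**s_i](u)`` with
    ``s_i = i*delta + delta - 1`` and ``h(u) = 1 - e^{-u} + u e^{-u}``.
    """
    cfg = cfg or SeriesConfig()
    x = float(x)
    if x <= 0:
        raise DomainError("x must be strictly positive for the density series")
    u = _u_of(x, p)
    hb = np.array(_h_over_u_coeffs(cfg.K))
    total = 0.0
    err = 0.0 if u < _U_RADIUS else np.inf
    last = np.inf
    for i in range(0, 4 * cfg.K + 1):
        s = i * p.delta + p.delta - 1.0
        gcoef = np.array(_gpow_coeffs(s, cfg.K))
        conv = np.convolve(hb, gcoef)[: cfg.K + 1]
        poly, poly_err = _poly_eval(conv, u)
        with np.errstate(over="ignore"):
            pref = float(np.float64(p.lambda_) ** i / math.factorial(i) * np.float64(u) ** (2.0 * s + 1.0))
        term = (-1.0) ** i * pref * poly
        total += term
        err += pref * poly_err
        last = abs(term)
        if i > 0 and last <= cfg.tail_tolerance * max(1.0, abs(total)):
            break
    tol = cfg.tail_tolerance * max(1.0, abs(total))
    ok = np.isfinite(total) and last <= tol and err <= max(tol, 1e-9 * max(1.0, abs(total)))
    value = p.lambda_ * p.delta * p.alpha * p.beta * x ** (p.beta - 1.0) * total
    return SeriesValue(value, bool(ok))


def renyi_series(theta: float, p: NOWWParams, cfg: SeriesConfig | None = None) -> SeriesValue:
    """Renyi entropy with the density evaluated through its series expansion.

    The integral ``int f**theta`` is split at a trust cutoff in u (well
    inside the formal radius, because the truncated expansion loses digits to
    cancellation before it): inside, the integrand uses :func:`pdf_series`,
    falling back to the closed-form density at any point whose series value
    is flagged; the tail uses the closed-form density.  The convergence flag
    reports whether every series evaluation inside the cutoff converged
    (i.e. no fallback was needed).
    """
    cfg = cfg or SeriesConfig()
    theta = float(theta)
    if not (theta > 0.0) or theta == 1.0:
        raise DomainError("Renyi order theta must be positive and different from 1")
    if theta * (2.0 * p.beta * p.delta - 1.0) <= -1.0:
        raise ComputationError("int f**theta diverges at the origin for these parameters")
    u_c = 1.0  # empirically mapped trust cutoff, far inside the formal radius
    x_c = (u_c / p.alpha) ** (1.0 / p.beta)
    flags = []

    def integrand(x: float) -> float:
        val, okk = pdf_series(x, p, cfg)
        flags.append(okk)
        if not okk:
            val = noww_pdf(x, p)
        return max(val, 0.0) ** theta

    import warnings

    with np.errstate(over="ignore", under="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        inner, _ = integrate.quad(integrand, 0.0, x_c, epsabs=1e-9, epsrel=1e-7, limit=400)
        hi = max(10.0 * noww_quantile(0.999, p), x_c * 1.001)
        outer, _ = integrate.quad(lambda x: noww_pdf(x, p) ** theta, x_c, hi,
                                  epsabs=1e-10, epsrel=1e-8, limit=200)
    total = inner + outer
    if total <= 0.0:
        raise ComputationError("int f**theta evaluated to a non-positive value")
    return SeriesValue(math.log(total) / (1.0 - theta), bool(all(flags)))
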