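"""Parameter estimation for the NOWW distribution.

Three estimators are provided, each applied endpoint-wise to interval data:

* maximum likelihood (``fit_mle``), maximizing the sum of log-densities;
* ordinary least squares on the CDF (``fit_lse``), minimizing
  ``sum_i [F(x_(i)) - i/(n+1)]**2`` over the sorted sample;
* weighted least squares (``fit_wls``), the same objective with weights
  ``W_i = (n+1)**2 (n+2) / (i (n - i + 1))``.

All optimization happens in log-parameter space (positivity for free), with a
seeded Latin-hypercube multi-start (default 20 starts over log-parameters in
[log 0.01, log 20]) refined by L-BFGS-B and a Nelder-Mead polish.  The
likelihood surface of this family has a long ridge towards a limiting Weibull
sub-model (alpha -> 0 with beta growing), so multi-start plus explicit bounds
handling is essential; single-start fits routinely stall far from the optimum.

The log-likelihood has two documented variants: ``"exact"`` (the default; the
log of the density that is the exact derivative of the CDF) and
``"uncorrected"`` (a historical variant that replaces the derivative factor
``log(1 - e^{-u} + u e^{-u})`` by ``-u + log(1 - e^{-u})``; it is NOT the log
of a normalized density and is exposed only for reproduction studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .core import ComputationError, DomainError, NOWWParams, noww_cdf, noww_logpdf
from .neutro import Interval, IntervalSample, NeutroParams

__all__ = [
    "FitResult",
    "NeutroFitResult",
    "PlottingWeights",
    "loglik",
    "fit_mle",
    "fit_lse",
    "fit_wls",
    "plotting_weights",
    "fit_neutrosophic",
]

_LOG_GUARD = 60.0  # |log theta| guard; beyond this the objective is vetoed
_START_BOX = (math.log(0.01), math.log(20.0))  # multi-start sampling box (log-params)
_GRAD_TOL = 1e-4  # relative gradient tolerance for the converged flag


@dataclass(frozen=True)
class FitResult:
    """Outcome of one scalar-sample fit."""

    method: str  # "MLE", "LSE" or "WLS"
    params: NOWWParams
    objective: float  # maximized log-likelihood (MLE) or minimized SSE (LSE/WLS)
    converged: bool
    n_obs: int
    n_starts_used: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": {
                "lambda": self.params.lambda_,
                "delta": self.params.delta,
                "alpha": self.params.alpha,
                "beta": self.params.beta,
            },
            "objective": self.objective,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_starts_used": self.n_starts_used,
        }


@dataclass(frozen=True)
class NeutroFitResult:
    """Endpoint-wise fits to an interval sample plus the assembled intervals."""

    lower_fit: FitResult
    upper_fit: FitResult
    interval_params: NeutroParams

    def to_dict(self) -> dict:
        return {
            "lower_fit": self.lower_fit.to_dict(),
            "upper_fit": self.upper_fit.to_dict(),
            "interval_params": {
                "lambda": self.interval_params.lambda_.as_tuple(),
                "delta": self.interval_params.delta.as_tuple(),
                "alpha": self.interval_params.alpha.as_tuple(),
                "beta": self.interval_params.beta.as_tuple(),
            },
        }


@dataclass(frozen=True)
class PlottingWeights:
    """Weighted-least-squares weights W_i = (n+1)^2 (n+2) / (i (n - i + 1))."""

    weights: np.ndarray

    @property
    def n(self) -> int:
        return len(self.weights)


def plotting_weights(n: int) -> PlottingWeights:
    if int(n) != n or n < 1:
        raise DomainError("n must be a positive integer")
    n = int(n)
    i = np.arange(1, n + 1, dtype=float)
    w = (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0))
    return PlottingWeights(weights=w)


def _check_data(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float).ravel()
    if arr.size == 0:
        raise DomainError("data must be non-empty")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("all observations must be positive and finite")
    return arr


def loglik(p: NOWWParams, data, variant: str = "exact") -> float:
    """Log-likelihood of a positive scalar sample.

    ``variant="exact"`` sums the exact log-density.  ``variant="uncorrected"``
    replaces the derivative factor log(1 - e^{-u} + u e^{-u}) of each term by
    -u + log(1 - e^{-u}); the two variants differ per observation by exactly
    log((1 - e^{-u}) e^{u} + u) - log(1 - e^{-u}).
    """
    arr = _check_data(data)
    ll = noww_logpdf(arr, p)
    base = float(np.sum(ll))
    if variant == "exact":
        return base
    if variant == "uncorrected":
        u = p.alpha * arr**p.beta
        with np.errstate(over="ignore", divide="ignore"):
            uc = np.minimum(u, 700.0)
            em = -np.expm1(-uc)
            # subtract log h(u), add (-u + log(1 - e^{-u}))
            h = em + u * np.exp(-uc)
            adjust = np.sum(-u + np.log(em) - np.log(h))
        return base + float(adjust)
    raise DomainError(f"unknown log-likelihood variant {variant!r}")


def _num_grad(fn, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(theta)
    for j in range(theta.size):
        e = np.zeros_like(theta)
        e[j] = h
        g[j] = (fn(theta + e) - fn(theta - e)) / (2.0 * h)
    return g


def _make_starts(
    starts: Sequence[NOWWParams] | None,
    n_starts: int,
    seed: int,
) -> list[np.ndarray]:
    if starts is not None:
        return [np.log(np.asarray(s.as_tuple() if isinstance(s, NOWWParams) else s, dtype=float))
                for s in starts]
    sampler = qmc.LatinHypercube(d=4, rng=np.random.default_rng(int(seed)))
    lo, hi = _START_BOX
    pts = qmc.scale(sampler.random(n=n_starts), [lo] * 4, [hi] * 4)
    return [np.asarray(row) for row in pts]


def _multistart_minimize(
    neg_objective,
    starts: Sequence[NOWWParams] | None,
    seed: int,
    bounds: tuple[float, float] | None,
) -> tuple[np.ndarray, float, bool, int]:
    """Minimize over log-parameters; returns (theta, value, converged, n_starts)."""
    if bounds is not None:
        blo, bhi = math.log(bounds[0]), math.log(bounds[1])
    else:
        blo, bhi = -_LOG_GUARD, _LOG_GUARD
    box = [(blo, bhi)] * 4

    def guarded(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > _LOG_GUARD) or np.any(theta < blo - 1e-12) or np.any(theta > bhi + 1e-12):
            return 1e12
        v = neg_objective(np.clip(theta, blo, bhi))
        return v if np.isfinite(v) else 1e12

    import warnings

    theta_starts = _make_starts(starts, 20, seed)
    best_theta, best_val = None, np.inf
    with warnings.catch_warnings():
        # the guard's veto plateau (1e12) makes finite-difference gradients
        # overflow harmlessly at infeasible probes
        warnings.simplefilter("ignore", RuntimeWarning)
        for t0 in theta_starts:
            t0 = np.clip(t0, blo, bhi)
            try:
                res = optimize.minimize(guarded, t0, method="L-BFGS-B", bounds=box)
            except Exception:  # pragma: no cover - defensive
                continue
            if np.isfinite(res.fun) and res.fun < best_val:
                best_theta, best_val = np.asarray(res.x), float(res.fun)
    if best_theta is None:
        raise ComputationError("no optimization start produced a finite objective")
    # Nelder-Mead polish (kept inside the box by the guard's veto value)
    polish = optimize.minimize(
        guarded, best_theta, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    if np.isfinite(polish.fun) and polish.fun < best_val:
        best_theta, best_val = np.clip(np.asarray(polish.x), blo, bhi), float(polish.fun)
    grad = _num_grad(guarded, best_theta)
    converged = bool(np.linalg.norm(grad) <= _GRAD_TOL * (1.0 + abs(best_val)))
    return best_theta, best_val, converged, len(theta_starts)


def fit_mle(
    data,
    starts: Sequence[NOWWParams] | None = None,
    seed: int = 0,
    variant: str = "exact",
    bounds: tuple[float, float] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the four NOWW parameters.

    ``bounds`` optionally confines all four parameters to a common [lo, hi]
    box during optimization (used by the Monte-Carlo harness); by default only
    a wide numerical guard applies.
    """
    arr = np.sort(_check_data(data))
    if arr.size < 5:
        import warnings

        warnings.warn("fewer than 5 observations: the fit is poorly identified", stacklevel=2)

    def neg(theta: np.ndarray) -> float:
        p = NOWWParams(*np.exp(theta))
        return -loglik(p, arr, variant=variant)

    theta, val, converged, n_starts = _multistart_minimize(neg, starts, seed, bounds)
    return FitResult(
        method="MLE",
        params=NOWWParams(*np.exp(theta)),
        objective=-val,
        converged=converged,
        n_obs=arr.size,
        n_starts_used=n_starts,
    )


def _fit_ls(
    data,
    weights: np.ndarray | None,
    method: str,
    starts: Sequence[NOWWParams] | None,
    seed: int,
    bounds: tuple[float, float] | None,
) -> FitResult:
    arr = np.sort(_check_data(data))
    n = arr.size
    if n < 5:
        import warnings

        warnings.warn("fewer than 5 observations: the fit is poorly identified", stacklevel=2)
    positions = np.arange(1, n + 1, dtype=float) / (n + 1.0)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    def neg(theta: np.ndarray) -> float:
        p = NOWWParams(*np.exp(theta))
        resid = noww_cdf(arr, p) - positions
        return float(np.sum(w * resid * resid))

    theta, val, converged, n_starts = _multistart_minimize(neg, starts, seed, bounds)
    return FitResult(
        method=method,
        params=NOWWParams(*np.exp(theta)),
        objective=val,
        converged=converged,
        n_obs=n,
        n_starts_used=n_starts,
    )


def fit_lse(
    data,
    seed: int = 0,
    starts: Sequence[NOWWParams] | None = None,
    bounds: tuple[float, float] | None = None,
) -> FitResult:
    """Ordinary least squares on the CDF at plotting positions i/(n+1)."""
    return _fit_ls(data, None, "LSE", starts, seed, bounds)


def fit_wls(
    data,
    seed: int = 0,
    starts: Sequence[NOWWParams] | None = None,
    bounds: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Weighted least squares with W_i = (n+1)^2 (n+2) / (i (n - i + 1)).

    ``weights`` may override the default (e.g. all ones reduces WLS to LSE).
    """
    arr = _check_data(data)
    w = plotting_weights(arr.size).weights if weights is None else weights
    return _fit_ls(data, w, "WLS", starts, seed, bounds)


_METHODS = {"mle": fit_mle, "lse": fit_lse, "wls": fit_wls}


def fit_neutrosophic(
    sample: IntervalSample,
    method: str = "mle",
    seed: int = 0,
    **kwargs,
) -> NeutroFitResult:
    """Fit the lower- and upper-endpoint scalar samples independently.

    The interval parameter estimates are assembled per parameter as
    [min, max] of the two point estimates.  A failure on either endpoint is
    reported with the failing side named.
    """
    key = method.lower()
    if key not in _METHODS:
        raise DomainError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    fitter = _METHODS[key]
    results = {}
    for side, arr in (("lower", sample.lower), ("upper", sample.upper)):
        try:
            results[side] = fitter(arr, seed=seed, **kwargs)
        except Exception as exc:
            raise ComputationError(f"{side}-endpoint fit failed: {exc}") from exc
    lo_p, hi_p = results["lower"].params, results["upper"].params
    ivs = [
        Interval(min(a, b), max(a, b))
        for a, b in zip(lo_p.as_tuple(), hi_p.as_tuple())
    ]
    return NeutroFitResult(
        lower_fit=results["lower"],
        upper_fit=results["upper"],
        interval_params=NeutroParams(*ivs),
    )
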