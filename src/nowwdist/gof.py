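"""Goodness-of-fit statistics, information criteria and model comparison.

Statistics (all computed on the fitted CDF values z_(i) = F(x_(i)) of the
sorted sample, i.e. at the estimated parameters):

* Kolmogorov-Smirnov  D  = max_i max(i/n - z_(i), z_(i) - (i-1)/n)
* Anderson-Darling    A2 = -n - (1/n) sum (2i-1) [log z_(i) + log(1 - z_(n+1-i))]
* Cramer-von Mises    W2 = sum (z_(i) - (2i-1)/(2n))**2 + 1/(12n)

The KS p-value uses the asymptotic (large-sample) Kolmogorov distribution,
evaluated from its alternating series.  A2 and W2 are the unmodified
classical statistics; no small-sample adjustment factors are applied.

Information criteria (natural logarithms, k free parameters, n observations):

    aic  = 2k - 2 logL            caic = aic + 2k(k+1)/(n-k-1)
    bic  = k log n - 2 logL       hqic = 2k log(log n) - 2 logL

``compare_models`` runs a list of plug-in models endpoint-wise over an
interval sample and emits a ranked comparison table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd

from .core import DomainError, NOWWParams, noww_cdf
from .estimate import FitResult, fit_mle, loglik
from .neutro import IntervalSample

__all__ = [
    "GoFStats",
    "CriteriaBundle",
    "information_criteria",
    "ks_statistic",
    "ks_pvalue",
    "ad_statistic",
    "cvm_statistic",
    "gof_stats",
    "Model",
    "NOWWModel",
    "compare_models",
]

_Z_CLIP = 1e-12


@dataclass(frozen=True)
class CriteriaBundle:
    aic: float
    caic: float
    bic: float
    hqic: float


@dataclass(frozen=True)
class GoFStats:
    """Goodness-of-fit bundle for one scalar sample under one fitted CDF."""

    W2: float
    A2: float
    D: float
    p_value: float
    loglik: float
    n: int
    k: int


def information_criteria(loglik: float, k: int, n: int) -> CriteriaBundle:
    """AIC/CAIC/BIC/HQIC from a maximized log-likelihood."""
    if int(k) != k or k < 0:
        raise DomainError("k must be a non-negative integer")
    if int(n) != n or n < 1:
        raise DomainError("n must be a positive integer")
    k, n = int(k), int(n)
    if n <= k + 1:
        raise DomainError(f"CAIC undefined for n={n} <= k+1={k + 1}")
    aic = 2.0 * k - 2.0 * loglik
    caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = k * math.log(n) - 2.0 * loglik
    hqic = 2.0 * k * math.log(math.log(n)) - 2.0 * loglik
    return CriteriaBundle(aic=aic, caic=caic, bic=bic, hqic=hqic)


def _fitted_z(data, cdf_fn) -> np.ndarray:
    arr = np.sort(np.asarray(data, dtype=float).ravel())
    if arr.size == 0:
        raise DomainError("data must be non-empty")
    z = np.asarray([float(cdf_fn(x)) for x in arr])
    if np.any(z < -1e-9) or np.any(z > 1.0 + 1e-9):
        raise DomainError("cdf_fn returned values outside [0, 1]")
    return np.clip(z, 0.0, 1.0)


def ks_statistic(data, cdf_fn) -> float:
    """One-sample two-sided Kolmogorov-Smirnov statistic."""
    z = _fitted_z(data, cdf_fn)
    n = z.size
    i = np.arange(1, n + 1, dtype=float)
    d_plus = np.max(i / n - z)
    d_minus = np.max(z - (i - 1.0) / n)
    return float(max(d_plus, d_minus, 0.0))

def ks_pvalue(D: float, n: int, terms: int = 100) -> float:
    """Asymptotic two-sided KS p-value from the Kolmogorov series.

    P(sqrt(n) D > t) = 2 sum_{j>=1} (-1)^{j-1} exp(-2 j^2 t^2).
    """
    if not (0.0 <= D <= 1.0):
        raise DomainError("KS statistic D must lie in [0, 1]")
    if int(n) != n or n < 1:
        raise DomainError("n must be a positive integer")
    t = math.sqrt(n) * D
    if t < 1e-8:
        return 1.0
    j = np.arange(1, terms + 1, dtype=float)
    s = 2.0 * np.sum((-1.0) ** (j - 1.0) * np.exp(-2.0 * j * j * t * t))
    return float(min(1.0, max(0.0, s)))


def _clipped_z(data, cdf_fn) -> np.ndarray:
    z = _fitted_z(data, cdf_fn)
    if np.any(z <= 0.0) or np.any(z >= 1.0):
        warnings.warn(
            "fitted CDF values at 0 or 1 clipped to the open interval for AD/CvM",
            stacklevel=3,
        )
        z = np.clip(z, _Z_CLIP, 1.0 - _Z_CLIP)
    return z


def ad_statistic(data, cdf_fn) -> float:
    """Anderson-Darling A2 (classical, unmodified)."""
    z = _clipped_z(data, cdf_fn)
    n = z.size
    i = np.arange(1, n + 1, dtype=float)
    s = np.sum((2.0 * i - 1.0) * (np.log(z) + np.log1p(-z[::-1])))
    return float(-n - s / n)


def cvm_statistic(data, cdf_fn) -> float:
    """Cramer-von Mises W2 (classical, unmodified)."""
    z = _clipped_z(data, cdf_fn)
    n = z.size
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum((z - (2.0 * i - 1.0) / (2.0 * n)) ** 2) + 1.0 / (12.0 * n))


def gof_stats(data, cdf_fn, loglik_value: float, k: int) -> GoFStats:
    """Assemble the full GoF bundle for a scalar sample and fitted CDF."""
    arr = np.asarray(data, dtype=float).ravel()
    D = ks_statistic(arr, cdf_fn)
    return GoFStats(
        W2=cvm_statistic(arr, cdf_fn),
        A2=ad_statistic(arr, cdf_fn),
        D=D,
        p_value=ks_pvalue(D, arr.size),
        loglik=loglik_value,
        n=arr.size,
        k=int(k),
    )


@dataclass(frozen=True)
class Model:
    """Plug-in model interface for the comparison table.

    ``fit(data, seed)`` must return an object with attributes ``params``,
    ``objective`` (the maximized log-likelihood) and ``converged``;
    ``cdf(x, params)`` evaluates the fitted CDF; ``k`` is the number of free
    parameters.  Competitor distributions attach here by supplying their own
    callables.
    """

    name: str
    fit: Callable
    cdf: Callable
    k: int


def _noww_fit(data, seed: int = 0, **kwargs):
    return fit_mle(data, seed=seed, **kwargs)


def _noww_cdf_fn(x, params: NOWWParams):
    return noww_cdf(x, params)


def NOWWModel(name: str = "NNOWW", frozen: dict | None = None) -> Model:
    """The built-in NOWW plug-in.

    ``frozen`` maps parameter names to fixed values (e.g. {"beta": 0.1}) to
    deliberately mis-specify the model for dominance checks; frozen
    parameters are excluded from the free-parameter count k.
    """
    if not frozen:
        return Model(name=name, fit=_noww_fit, cdf=_noww_cdf_fn, k=4)

    frozen = dict(frozen)
    names = ("lambda_", "delta", "alpha", "beta")
    for key in frozen:
        if key not in names:
            raise DomainError(f"unknown parameter {key!r}")

    def fit_frozen(data, seed: int = 0, **kwargs):
        free = [nm for nm in names if nm not in frozen]

        def neg(theta):
            vals = dict(frozen)
            for nm, t in zip(free, theta):
                vals[nm] = math.exp(t)
            p = NOWWParams(**vals)
            try:
                return -loglik(p, data)
            except Exception:
                return 1e12

        from scipy import optimize

        best = None
        rng = np.random.default_rng(seed)
        for _ in range(10):
            t0 = rng.uniform(math.log(0.05), math.log(10.0), size=len(free))
            res = optimize.minimize(neg, t0, method="Nelder-Mead",
                                    options={"maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        vals = dict(frozen)
        for nm, t in zip(free, best.x):
            vals[nm] = math.exp(t)
        params = NOWWParams(**vals)
        return FitResult(
            method="MLE",
            params=params,
            objective=-float(best.fun),
            converged=bool(best.success),
            n_obs=len(np.asarray(data).ravel()),
            n_starts_used=10,
        )

    return Model(name=name, fit=fit_frozen, cdf=_noww_cdf_fn, k=4 - len(frozen))


@dataclass
class ComparisonTable:
    """Ranked model-comparison results over the two endpoint samples."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> str:
        return self.table.to_json(orient="records")


def compare_models(
    sample: IntervalSample,
    models: Sequence[Model],
    seed: int = 0,
) -> ComparisonTable:
    """Fit every model to both endpoint samples and rank by lower-endpoint AIC.

    A model that fails on either endpoint is kept in the table with its row
    marked ``failed``; the comparison continues for the remaining models.
    """
    rows = []
    for model in models:
        for endpoint, data in (("lower", sample.lower), ("upper", sample.upper)):
            row = {"model": model.name, "endpoint": endpoint, "failed": False}
            try:
                fit = model.fit(data, seed=seed)
                ll = float(fit.objective)
                cdf_fn = lambda x, _p=fit.params: float(model.cdf(x, _p))
                crit = information_criteria(ll, model.k, len(data))
                stats = gof_stats(data, cdf_fn, ll, model.k)
                row.update(
                    negloglik=-ll,
                    aic=crit.aic, caic=crit.caic, bic=crit.bic, hqic=crit.hqic,
                    W2=stats.W2, A2=stats.A2, D=stats.D, p_value=stats.p_value,
                )
            except Exception as exc:
                row.update(
                    failed=True, error=str(exc),
                    negloglik=np.nan, aic=np.nan, caic=np.nan, bic=np.nan,
                    hqic=np.nan, W2=np.nan, A2=np.nan, D=np.nan, p_value=np.nan,
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    # rank by the lower-endpoint AIC of each model; failures sink to the bottom
    order = (
        df[df.endpoint == "lower"]
        .set_index("model")["aic"]
        .sort_values(na_position="last")
        .index
    )
    df["model"] = pd.Categorical(df["model"], categories=list(order), ordered=True)
    df = df.sort_values(["model", "endpoint"]).reset_index(drop=True)
    df["model"] = df["model"].astype(str)
    return ComparisonTable(table=df)
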