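"""Neutrosophic (interval-valued) layer of the NOWW distribution.

Interval-valued parameters and data are handled by the *direct method*: every
uncertain quantity is represented by its lower and upper value, classical
operations are evaluated at the two aligned endpoint parameter vectors, and
the two results are sorted into an interval.  Sorting is mandatory: the map
from parameters to, say, a quantile is not monotone, so the upper parameter
vector can produce the lower endpoint of the output interval.

The module also provides the truth/falsity/indeterminacy decomposition of an
interval observation:

    T = (lo + hi) / 2        (midpoint, "truth")
    F = -(hi - lo)           (negative width, "falsity")
    I = 1 - T - F            (residual, "indeterminacy")

so that T + F + I = 1 holds identically for every observation.  T, F and I
are expressed on the scale of the actual measurements (not normalised to
[0, 1]); F and I are typically negative for wide, large-valued intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import (
    DomainError,
    NOWWParams,
    noww_cdf,
    noww_hazard,
    noww_pdf,
    noww_quantile,
    noww_sf,
    raw_moment,
    renyi_entropy,
)

__all__ = [
    "Interval",
    "NeutroParams",
    "IntervalSample",
    "TFIRecord",
    "nnoww_interval",
    "decompose_tfi",
    "tfi_table",
    "TFISummary",
]


@dataclass(frozen=True)
class Interval:
    """A closed real interval [lo, hi] with lo <= hi."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo, hi = float(self.lo), float(self.hi)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise DomainError(f"interval endpoints must be finite, got [{self.lo}, {self.hi}]")
        if lo > hi:
            raise DomainError(f"interval endpoints out of order: lo={lo} > hi={hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def is_degenerate(self) -> bool:
        return self.lo == self.hi

    def as_tuple(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass(frozen=True)
class NeutroParams:
    """Interval-valued parameter vector of the NNOWW distribution."""

    lambda_: Interval
    delta: Interval
    alpha: Interval
    beta: Interval

    def __post_init__(self) -> None:
        for name in ("lambda_", "delta", "alpha", "beta"):
            iv = getattr(self, name)
            if not isinstance(iv, Interval):
                iv = Interval(*iv)
                object.__setattr__(self, name, iv)
            if iv.lo <= 0.0:
                raise DomainError(f"{name} interval must have strictly positive endpoints, got {iv}")

    @property
    def lower(self) -> NOWWParams:
        """The aligned all-lower-endpoint classical parameter vector."""
        return NOWWParams(self.lambda_.lo, self.delta.lo, self.alpha.lo, self.beta.lo)

    @property
    def upper(self) -> NOWWParams:
        """The aligned all-upper-endpoint classical parameter vector."""
        return NOWWParams(self.lambda_.hi, self.delta.hi, self.alpha.hi, self.beta.hi)

    def corners(self) -> list[NOWWParams]:
        """All 2^4 corner vectors (used by the optional conservative mode)."""
        out = []
        for l in (self.lambda_.lo, self.lambda_.hi):
            for d in (self.delta.lo, self.delta.hi):
                for a in (self.alpha.lo, self.alpha.hi):
                    for b in (self.beta.lo, self.beta.hi):
                        out.append(NOWWParams(l, d, a, b))
        return out

    @classmethod
    def from_sequence(cls, values: Sequence[float]) -> "NeutroParams":
        values = tuple(float(v) for v in values)
        if len(values) != 8:
            raise DomainError(
                "expected 8 endpoints (lambdaL,lambdaU,deltaL,deltaU,alphaL,alphaU,betaL,betaU), "
                f"got {len(values)}"
            )
        return cls(
            Interval(values[0], values[1]),
            Interval(values[2], values[3]),
            Interval(values[4], values[5]),
            Interval(values[6], values[7]),
        )


@dataclass(frozen=True)
class IntervalSample:
    """An ordered collection of interval observations."""

    observations: tuple[Interval, ...]

    def __post_init__(self) -> None:
        obs = tuple(
            o if isinstance(o, Interval) else Interval(*o) for o in self.observations
        )
        if len(obs) < 1:
            raise DomainError("an interval sample must contain at least one observation")
        object.__setattr__(self, "observations", obs)

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def lower(self) -> np.ndarray:
        return np.array([o.lo for o in self.observations])

    @property
    def upper(self) -> np.ndarray:
        return np.array([o.hi for o in self.observations])

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_arrays(cls, lo: Iterable[float], hi: Iterable[float]) -> "IntervalSample":
        return cls(tuple(Interval(a, b) for a, b in zip(lo, hi, strict=True)))


@dataclass(frozen=True)
class TFIRecord:
    """Truth/falsity/indeterminacy triple of one interval observation."""

    truth: float
    falsity: float
    indeterminacy: float

    @property
    def condition_satisfied(self) -> bool:
        return abs(self.truth + self.falsity + self.indeterminacy - 1.0) <= 1e-9


# mapping from operation name to (callable, whether arg is the first positional)
_INTERVAL_FNS: dict[str, Callable[[float, NOWWParams], float]] = {
    "cdf": lambda arg, p: float(noww_cdf(arg, p)),
    "pdf": lambda arg, p: float(noww_pdf(arg, p)),
    "sf": lambda arg, p: float(noww_sf(arg, p)),
    "hazard": lambda arg, p: float(noww_hazard(arg, p)),
    "quantile": lambda arg, p: float(noww_quantile(arg, p)),
    "raw_moment": lambda arg, p: float(raw_moment(int(arg), p)),
    "renyi": lambda arg, p: float(renyi_entropy(arg, p)),
}


def nnoww_interval(
    fn_name: str,
    arg: float,
    np_: NeutroParams,
    conservative: bool = False,
) -> Interval:
    """Evaluate a classical NOWW operation under interval parameters.

    Default (two-point direct method): evaluate at the aligned lower and upper
    endpoint vectors and sort the two results.  With ``conservative=True`` all
    sixteen corner vectors are evaluated and the enclosing [min, max] is
    returned; the conservative interval always contains the two-point one.
    """
    if fn_name not in _INTERVAL_FNS:
        raise DomainError(
            f"unknown operation {fn_name!r}; expected one of {sorted(_INTERVAL_FNS)}"
        )
    fn = _INTERVAL_FNS[fn_name]
    vectors = np_.corners() if conservative else [np_.lower, np_.upper]
    values = [fn(arg, v) for v in vectors]
    return Interval(min(values), max(values))


def decompose_tfi(obs: Interval) -> TFIRecord:
    """Truth/falsity/indeterminacy decomposition of one interval.

    T is the midpoint, F the negative width, I the residual 1 - T - F, so the
    neutrosophic condition T + F + I = 1 holds by construction.  Values live
    on the measurement scale; no normalisation to [0, 1] is applied.
    """
    if not isinstance(obs, Interval):
        obs = Interval(*obs)
    t = obs.midpoint
    f = -obs.width
    i = 1.0 - t - f
    return TFIRecord(truth=t, falsity=f, indeterminacy=i)


@dataclass(frozen=True)
class TFISummary:
    """Per-component mean/sd/min/max of a sample's T, F, I values.

    ``sd`` is the sample standard deviation with denominator n - 1.
    """

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    min: tuple[float, float, float]
    max: tuple[float, float, float]
    all_conditions_satisfied: bool


def tfi_table(sample: IntervalSample) -> tuple[list[TFIRecord], TFISummary]:
    """Decompose every observation and summarise each component.

    The standard deviation uses the n - 1 denominator (sample sd); at least
    two observations are required for it to be defined.
    """
    if sample.n < 2:
        raise DomainError("at least 2 observations are needed for the summary sd")
    records = [decompose_tfi(o) for o in sample]
    cols = np.array([[r.truth, r.falsity, r.indeterminacy] for r in records])
    summary = TFISummary(
        mean=tuple(np.mean(cols, axis=0)),
        sd=tuple(np.std(cols, axis=0, ddof=1)),
        min=tuple(np.min(cols, axis=0)),
        max=tuple(np.max(cols, axis=0)),
        all_conditions_satisfied=all(r.condition_satisfied for r in records),
    )
    return records, summary
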