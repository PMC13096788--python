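"""Data input/output: interval and scalar CSV, the heart-pulse fixture, and a
synthetic interval generator.

The bundled dataset is a sample of 50 heart pulse-count measurements recorded
as intervals [lo, hi] (beats per minute), embedded verbatim as integers.  CSV
files use a fixed dialect: comma separator, dot decimal point, UTF-8, with a
required header (``lo,hi`` for intervals, ``x`` for scalar samples).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import DomainError, NOWWParams, noww_rvs
from .neutro import Interval, IntervalSample

__all__ = [
    "DatasetMeta",
    "heart_pulse_data",
    "heart_pulse_meta",
    "read_intervals",
    "write_intervals",
    "read_scalars",
    "write_scalars",
    "synthetic_intervals",
]


class ParseError(ValueError):
    """A data file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class DatasetMeta:
    name: str
    n: int
    units: str
    source: str


# 50 heart pulse-count intervals (beats per minute), embedded verbatim.
_HEART_PULSE: tuple[tuple[int, int], ...] = (
    (44, 68), (62, 72), (56, 90), (70, 112), (54, 72),
    (70, 100), (63, 75), (72, 100), (76, 98), (86, 96),
    (86, 100), (67, 88), (89, 100), (56, 65), (87, 93),
    (43, 70), (86, 112), (65, 77), (89, 99), (90, 101),
    (77, 89), (98, 115), (54, 66), (75, 89), (85, 100),
    (67, 78), (76, 97), (95, 117), (86, 99), (66, 100),
    (77, 88), (88, 99), (83, 112), (56, 65), (45, 78),
    (87, 97), (67, 89), (84, 102), (90, 109), (91, 108),
    (56, 77), (77, 99), (73, 89), (89, 114), (64, 70),
    (56, 74), (91, 117), (67, 88), (54, 77), (92, 100),
)


def heart_pulse_data() -> IntervalSample:
    """The bundled 50-interval heart pulse-count dataset, in original order."""
    return IntervalSample(tuple(Interval(float(a), float(b)) for a, b in _HEART_PULSE))


def heart_pulse_meta() -> DatasetMeta:
    return DatasetMeta(
        name="heart_pulse",
        n=len(_HEART_PULSE),
        units="beats per minute (interval per patient)",
        source="heart pulse-count study distributed with the package; "
        "recorded as per-patient [min, max] pulse intervals",
    )


def _open_rows(path) -> list[list[str]]:
    p = Path(path)
    if not p.exists():
        raise ParseError(f"no such file: {p}")
    with io.open(p, "r", encoding="utf-8", newline="") as fh:
        return [row for row in csv.reader(fh)]


def read_intervals(path) -> IntervalSample:
    """Read an interval CSV (header ``lo,hi``); malformed rows name their line."""
    rows = _open_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file (expected header 'lo,hi')")
    header = [c.strip().lower() for c in rows[0]]
    if header[:2] != ["lo", "hi"]:
        raise ParseError(f"{path}: line 1: expected header 'lo,hi', got {rows[0]!r}")
    obs: list[Interval] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two cells 'lo,hi', got {row!r}")
        try:
            lo, hi = float(row[0]), float(row[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell in {row!r}") from exc
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ParseError(f"{path}: line {lineno}: non-finite value in {row!r}")
        if lo > hi:
            raise ParseError(f"{path}: line {lineno}: lo={lo} > hi={hi}")
        obs.append(Interval(lo, hi))
    if not obs:
        raise ParseError(f"{path}: no data rows (empty dataset)")
    return IntervalSample(tuple(obs))


def write_intervals(sample: IntervalSample, path) -> None:
    """Write an interval sample as CSV with full float precision."""
    with io.open(Path(path), "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lo", "hi"])
        for o in sample:
            w.writerow([repr(o.lo), repr(o.hi)])


def read_scalars(path) -> np.ndarray:
    """Read a scalar-sample CSV (header ``x``, one value per line)."""
    rows = _open_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file (expected header 'x')")
    header = [c.strip().lower() for c in rows[0]]
    if header[:1] != ["x"]:
        raise ParseError(f"{path}: line 1: expected header 'x', got {rows[0]!r}")
    vals: list[float] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            v = float(row[0])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell {row[0]!r}") from exc
        if not math.isfinite(v):
            raise ParseError(f"{path}: line {lineno}: non-finite value {row[0]!r}")
        vals.append(v)
    if not vals:
        raise ParseError(f"{path}: no data rows (empty dataset)")
    return np.array(vals)


def write_scalars(data, path) -> None:
    with io.open(Path(path), "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x"])
        for v in np.asarray(data, dtype=float):
            w.writerow([repr(float(v))])


def synthetic_intervals(
    p_lower: NOWWParams,
    width_mean: float,
    width_shape: float,
    n: int,
    seed: int,
) -> IntervalSample:
    """Generate interval data with NOWW-distributed lower endpoints.

    ``lo_i`` is drawn from the NOWW distribution with parameters ``p_lower``;
    the width is an independent gamma variate with the given shape and mean
    (scale = mean / shape); ``hi_i = lo_i + width_i``.  Reproducible under the
    seed.
    """
    if int(n) != n or n < 1:
        raise DomainError("n must be a positive integer")
    if not (width_mean > 0 and width_shape > 0):
        raise DomainError("width_mean and width_shape must be positive")
    lo = noww_rvs(int(n), p_lower, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    widths = rng.gamma(shape=width_shape, scale=width_mean / width_shape, size=int(n))
    return IntervalSample.from_arrays(lo, lo + widths)
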