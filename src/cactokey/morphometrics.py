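"""Summary statistics and derived ratio indices for nematode morphometrics.

Summaries follow the conventional "mean ± sd (min–max)" table layout; the
sample standard deviation uses the n−1 denominator.  Derived indices are the
de Man ratios (a, b, c, c′) plus the length ratios routinely tabulated for
cyst nematodes (L/MB, TL/H, cyst L/Diam., egg Length/Width).

Ratio-of-means caveat: an index recomputed from two published means is not
the published per-specimen mean of the index (e.g. a = 538.5/23.2 ≈ 23.2
while the per-specimen mean prints 23.4).  When raw data are given, indices
are therefore always computed per specimen; matrix-level ratios derived from
means should be labelled approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SummaryStats",
    "DerivedIndices",
    "summarize",
    "format_summary",
    "derived_indices",
    "hyaline_percent",
    "round_half_up",
    "INDEX_INPUTS",
]

#: Which measurement fields feed each index (numerator, denominator).
INDEX_INPUTS: dict[str, tuple[str, str]] = {
    "a": ("body_length", "body_width"),
    "b": ("body_length", "pharynx_length"),
    "c": ("body_length", "tail_length"),
    "c_prime": ("tail_length", "anal_body_diam"),
    "L_over_MB": ("body_length", "median_bulb_distance"),
    "TL_over_H": ("tail_length", "hyaline_length"),
    "hyaline_fraction": ("hyaline_length", "tail_length"),
    "cyst_LW": ("cyst_length", "cyst_width"),
    "egg_LW": ("egg_length", "egg_width"),
}


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class DerivedIndices:
    """Ratio indices; ``None`` marks an index whose inputs were unobserved."""

    a: float | None = None
    b: float | None = None
    c: float | None = None
    c_prime: float | None = None
    L_over_MB: float | None = None
    TL_over_H: float | None = None
    hyaline_fraction: float | None = None
    cyst_LW: float | None = None
    egg_LW: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in INDEX_INPUTS}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (1.25 → 1.3 at one decimal), unlike banker's
    rounding used by the builtin ``round``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(values: Sequence[float]) -> SummaryStats:
    """n, arithmetic mean, sample sd (n−1), min and max of a measurement set.

    For n == 1 the sd is reported as 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.any(arr <= 0):
        raise ValueError("measurements must be strictly positive")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
    )


def format_summary(s: SummaryStats, decimals: int = 1) -> str:
    """Render as ``"M ± S (LO–HI)"`` with a plain hyphen, fixed decimals,
    half-up rounding."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")

    def f(x: float) -> str:
        return f"{round_half_up(x, decimals):.{decimals}f}"

    return f"{f(s.mean)} ± {f(s.sd)} ({f(s.min)}-{f(s.max)})"


def _ratio(num: float | None, den: float | None, den_name: str) -> float | None:
    if num is None or den is None:
        return None
    if den == 0:
        raise ZeroDivisionError(f"zero denominator: {den_name}")
    return num / den


def derived_indices(measurements: Mapping[str, float]) -> DerivedIndices:
    """Compute every ratio index whose inputs are present.

    ``measurements`` maps field names (see :data:`INDEX_INPUTS`) to strictly
    positive values for a single specimen; indices with a missing input are
    returned as ``None``.
    """
    clean: dict[str, float] = {}
    for k, v in measurements.items():
        if v is None:
            continue
        v = float(v)
        if not math.isfinite(v):
            raise ValueError(f"{k}: non-finite measurement")
        if v < 0:
            raise ValueError(f"{k}: negative measurement {v}")
        clean[k] = v
    out = {}
    for index, (num_name, den_name) in INDEX_INPUTS.items():
        out[index] = _ratio(clean.get(num_name), clean.get(den_name), den_name)
    return DerivedIndices(**out)


def hyaline_percent(tail: float, hyaline: float) -> float:
    """Hyaline terminal portion of the J2 tail as a percent of tail length."""
    if tail <= 0 or hyaline <= 0:
        raise ValueError("tail and hyaline lengths must be positive")
    if hyaline > tail:
        raise ValueError(f"hyaline portion ({hyaline}) exceeds tail length ({tail})")
    return 100.0 * hyaline / tail
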