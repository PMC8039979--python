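"""Multi-access identification and pairwise diagnostic reports.

A specimen is scored against every taxon with a per-character similarity in
[0, 1]: interval observations use the containment coefficient
|obs ∩ ref| / |obs| (a precise specimen inside a broad published envelope
scores 1), point observations score 1 inside the reference range and decay
linearly with normalized distance outside it; categorical states score 1/0;
unrecorded reference states are skipped, not penalized.  The aggregate is
the unweighted mean of scored characters (optional weights are supported
but default off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .datamodel import (
    CharacterMatrix,
    MatrixError,
    NumericValue,
    SpecimenObservation,
    TaxonProfile,
    Unknown,
)

__all__ = [
    "CharacterScore",
    "CandidateScore",
    "DiagnosticFinding",
    "DiagnosticReport",
    "overlap_score",
    "score_candidates",
    "diagnostic_characters",
]

IntervalLike = Union[NumericValue, float, tuple[float, float]]


def _as_interval(x: IntervalLike) -> NumericValue:
    if isinstance(x, NumericValue):
        return x
    if isinstance(x, tuple):
        return NumericValue(float(x[0]), float(x[1]))
    return NumericValue.point(float(x))


def overlap_score(obs: IntervalLike, ref: IntervalLike) -> float:
    """Similarity of an observed value/interval to a reference interval.

    Point observation: 1 inside the reference, else ``max(0, 1 - d/w)``
    where d is the distance to the nearest endpoint and w the reference
    width (a point reference makes any mismatch score 0).  Interval
    observation: containment coefficient |obs ∩ ref| / |obs|.
    """
    o = _as_interval(obs)
    r = _as_interval(ref)
    if o.is_point:
        x = o.lo
        if r.lo <= x <= r.hi:
            return 1.0
        d = r.lo - x if x < r.lo else x - r.hi
        if r.width == 0:
            return 0.0
        return max(0.0, 1.0 - d / r.width)
    inter = min(o.hi, r.hi) - max(o.lo, r.lo)
    if inter <= 0:
        return 0.0
    return inter / o.width


@dataclass(frozen=True)
class CharacterScore:
    character: str
    score: float | None
    basis: str  # overlap | category | skipped-unknown


@dataclass(frozen=True)
class CandidateScore:
    taxon: str
    aggregate: float
    n_characters_used: int
    breakdown: tuple[CharacterScore, ...]


def score_candidates(
    obs: SpecimenObservation,
    matrix: CharacterMatrix,
    weights: Mapping[str, float] | None = None,
) -> list[CandidateScore]:
    """Rank every matrix taxon against an observation.

    Sorted by aggregate descending, ties broken alphabetically.  Reference
    cells that are unrecorded are skipped and reported with basis
    ``skipped-unknown`` so sparse matches are visibly weak.
    """
    shared = [c for c in obs.values if matrix.has_character(c)]
    if not shared:
        raise MatrixError("observation shares no characters with the matrix")
    results = []
    for prof in matrix.taxa:
        breakdown: list[CharacterScore] = []
        total = 0.0
        wsum = 0.0
        for cid in shared:
            cdef = matrix.character(cid)
            oval = obs.get(cid)
            rval = prof.get(cid)
            if isinstance(oval, Unknown):
                continue
            if isinstance(rval, Unknown):
                breakdown.append(CharacterScore(cid, None, "skipped-unknown"))
                continue
            if cdef.kind == "categorical":
                s = 1.0 if oval == rval else 0.0
                basis = "category"
            else:
                s = overlap_score(oval, rval)  # type: ignore[arg-type]
                basis = "overlap"
            w = 1.0 if weights is None else float(weights.get(cid, 1.0))
            breakdown.append(CharacterScore(cid, s, basis))
            total += w * s
            wsum += w
        n_used = sum(1 for b in breakdown if b.score is not None)
        aggregate = total / wsum if wsum > 0 else 0.0
        results.append(
            CandidateScore(
                taxon=prof.taxon,
                aggregate=aggregate,
                n_characters_used=n_used,
                breakdown=tuple(breakdown),
            )
        )
    results.sort(key=lambda c: (-c.aggregate, c.taxon.lower()))
    return results


@dataclass(frozen=True)
class DiagnosticFinding:
    character: str
    verdict: str  # disjoint | low-overlap | overlapping | categorical-differs
    #              | categorical-same | unknown
    a_value: str
    b_value: str

    @property
    def diagnostic(self) -> bool:
        return self.verdict in ("disjoint", "categorical-differs", "low-overlap")


@dataclass
class DiagnosticReport:
    taxon_a: str
    taxon_b: str
    findings: list[DiagnosticFinding]

    @property
    def diagnostic_findings(self) -> list[DiagnosticFinding]:
        return [f for f in self.findings if f.diagnostic]

    def verdict(self, character: str) -> str:
        for f in self.findings:
            if f.character == character:
                return f.verdict
        raise MatrixError(f"character {character!r} not in report")


def _overlap_fraction_smaller(a: NumericValue, b: NumericValue) -> float:
    """Shared length as a fraction of the smaller interval's width."""
    inter = min(a.hi, b.hi) - max(a.lo, b.lo)
    if inter < 0:
        return 0.0
    smaller = min(a.width, b.width)
    if smaller == 0:
        return 1.0 if inter >= 0 else 0.0
    return inter / smaller


def diagnostic_characters(
    taxon_a: str,
    taxon_b: str,
    matrix: CharacterMatrix,
    low_overlap_threshold: float = 0.25,
) -> DiagnosticReport:
    """Character-by-character comparison of two taxa.

    Numeric verdicts: ``disjoint`` (no shared point), ``low-overlap``
    (shared fraction of the smaller interval below the threshold) or
    ``overlapping``; categorical: ``categorical-differs`` /
    ``categorical-same``; ``unknown`` when either side is unrecorded.
    Diagnostic findings (disjoint, categorical-differs, low-overlap) are
    listed first.
    """
    pa = matrix.taxon(taxon_a)
    pb = matrix.taxon(taxon_b)
    findings = []
    from .datamodel import format_cell

    for cdef in matrix.registry:
        va = pa.get(cdef.id)
        vb = pb.get(cdef.id)
        if isinstance(va, Unknown) and isinstance(vb, Unknown):
            continue  # character absent on both sides: not a comparison
        if isinstance(va, Unknown) or isinstance(vb, Unknown):
            verdict = "unknown"
        elif cdef.kind == "categorical":
            verdict = "categorical-same" if va == vb else "categorical-differs"
        else:
            assert isinstance(va, NumericValue) and isinstance(vb, NumericValue)
            frac = _overlap_fraction_smaller(va, vb)
            inter = min(va.hi, vb.hi) - max(va.lo, vb.lo)
            if inter < 0:
                verdict = "disjoint"
            elif frac < low_overlap_threshold:
                verdict = "low-overlap"
            else:
                verdict = "overlapping"
        findings.append(
            DiagnosticFinding(cdef.id, verdict, format_cell(va), format_cell(vb))
        )
    order = {
        "disjoint": 0,
        "categorical-differs": 1,
        "low-overlap": 2,
        "overlapping": 3,
        "categorical-same": 4,
        "unknown": 5,
    }
    findings.sort(key=lambda f: order[f.verdict])
    return DiagnosticReport(taxon_a=pa.taxon, taxon_b=pb.taxon, findings=findings)
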