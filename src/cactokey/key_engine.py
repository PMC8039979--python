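"""Dichotomous key as a decision graph evaluated with three-valued logic.

The comparative matrix stores published ranges while key leads test means
and thresholds, so a predicate can come back *yes*, *no*, or *ambiguous*:

* ``basis="range"``: yes if the whole profile interval satisfies the
  relation, no if it wholly violates it, ambiguous if it straddles.
* ``basis="mean"``: the profile mean is tested crisply; when only a range
  is stored its midpoint stands in and the step is flagged ``proxy_mean``.
* categorical: yes/no on match, ambiguous when the state is unrecorded.

A lead's predicates are conjunctive under Kleene logic (no dominates, then
ambiguous).  Traversal follows every lead that is not definitely *no*, so
missing data widens — never blocks — the terminal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

from .datamodel import (
    BUNDLED_DATASET,
    CharacterMatrix,
    MatrixError,
    NumericValue,
    SpecimenObservation,
    TaxonProfile,
    Unknown,
    UNKNOWN,
    normalize_taxon_name,
)

__all__ = [
    "TriBool",
    "Predicate",
    "Lead",
    "Couplet",
    "Key",
    "KeyError_",
    "StepTrace",
    "Terminal",
    "TraversalResult",
    "AuditRow",
    "KeyAudit",
    "bundled_key",
    "bundled_errata",
    "load_key",
    "eval_predicate",
    "traverse",
    "validate_key",
]

_RELATIONS = ("lt", "le", "gt", "ge", "eq-category", "in-range")


class KeyError_(ValueError):
    """Structural problem in a key definition."""


class TriBool(Enum):
    YES = "yes"
    NO = "no"
    AMBIGUOUS = "ambiguous"

    def and_(self, other: "TriBool") -> "TriBool":
        """Kleene conjunction: NO dominates, else AMBIGUOUS dominates YES."""
        if TriBool.NO in (self, other):
            return TriBool.NO
        if TriBool.AMBIGUOUS in (self, other):
            return TriBool.AMBIGUOUS
        return TriBool.YES


@dataclass(frozen=True)
class Predicate:
    character: str
    relation: str  # lt | le | gt | ge | eq-category | in-range
    threshold: Union[float, str, tuple[float, float]]
    basis: str = "range"  # mean | range (numeric relations only)

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise KeyError_(f"unknown relation {self.relation!r}")
        if self.basis not in ("mean", "range"):
            raise KeyError_(f"unknown basis {self.basis!r}")
        if self.relation == "in-range" and not isinstance(self.threshold, tuple):
            object.__setattr__(self, "threshold", tuple(self.threshold))  # type: ignore[arg-type]

    def describe(self) -> str:
        if self.relation == "eq-category":
            return f"{self.character} = {self.threshold}"
        if self.relation == "in-range":
            lo, hi = self.threshold  # type: ignore[misc]
            return f"{self.character} in [{lo}, {hi}] ({self.basis})"
        sym = {"lt": "<", "le": "<=", "gt": ">", "ge": ">="}[self.relation]
        return f"{self.character} {sym} {self.threshold} ({self.basis})"


@dataclass(frozen=True)
class Lead:
    predicates: tuple[Predicate, ...]
    taxon: str | None = None
    goto: int | None = None

    def __post_init__(self) -> None:
        if (self.taxon is None) == (self.goto is None):
            raise KeyError_("a lead needs exactly one of taxon / goto")


@dataclass(frozen=True)
class Couplet:
    id: int
    leads: tuple[Lead, Lead]

    def __post_init__(self) -> None:
        if len(self.leads) != 2:
            raise KeyError_(f"couplet {self.id}: exactly two leads required")


@dataclass
class Key:
    couplets: dict[int, Couplet]
    root: int
    version: str = ""

    def __post_init__(self) -> None:
        problems = self.structural_errors()
        if problems:
            raise KeyError_("; ".join(problems))

    def structural_errors(self) -> list[str]:
        """Dangling goto targets, unreachable couplets, cycles."""
        out: list[str] = []
        if self.root not in self.couplets:
            out.append(f"root couplet {self.root} missing")
            return out
        for c in self.couplets.values():
            for lead in c.leads:
                if lead.goto is not None and lead.goto not in self.couplets:
                    out.append(f"couplet {c.id}: dangling target {lead.goto}")
        if out:
            return out
        # DFS for reachability + cycle detection
        color: dict[int, int] = {}  # 1 = on stack, 2 = done

        def visit(cid: int, stack: tuple[int, ...]) -> None:
            if color.get(cid) == 1:
                out.append(f"cycle through couplet {cid}")
                return
            if color.get(cid) == 2:
                return
            color[cid] = 1
            for lead in self.couplets[cid].leads:
                if lead.goto is not None:
                    visit(lead.goto, stack + (cid,))
            color[cid] = 2

        visit(self.root, ())
        unreachable = sorted(set(self.couplets) - set(color))
        if unreachable:
            out.append(f"unreachable couplets: {unreachable}")
        return out

    def terminal_taxa(self) -> list[str]:
        return [
            lead.taxon
            for c in self.couplets.values()
            for lead in c.leads
            if lead.taxon is not None
        ]

    def characters_used(self) -> set[str]:
        return {
            p.character
            for c in self.couplets.values()
            for lead in c.leads
            for p in lead.predicates
        }


# ---------------------------------------------------------------------------
# loading


def _parse_predicate(raw: Mapping) -> Predicate:
    threshold = raw["threshold"]
    if isinstance(threshold, list):
        threshold = tuple(float(x) for x in threshold)
    return Predicate(
        character=raw["character"],
        relation=raw["relation"],
        threshold=threshold,
        basis=raw.get("basis", "range"),
    )


def load_key(path: str | Path) -> Key:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    couplets: dict[int, Couplet] = {}
    for c in raw["couplets"]:
        leads = tuple(
            Lead(
                predicates=tuple(_parse_predicate(p) for p in lead.get("predicates", [])),
                taxon=lead.get("taxon"),
                goto=lead.get("goto"),
            )
            for lead in c["leads"]
        )
        cid = int(c["id"])
        if cid in couplets:
            raise KeyError_(f"duplicate couplet id {cid}")
        couplets[cid] = Couplet(id=cid, leads=leads)  # type: ignore[arg-type]
    return Key(couplets=couplets, root=int(raw["root"]), version=raw.get("version", ""))


def _bundle_path(dataset: str, name: str) -> Path:
    return Path(str(resources.files("cactokey").joinpath("data", dataset, name)))


def bundled_key(dataset: str = BUNDLED_DATASET) -> Key:
    """The repaired machine-readable genus key: 16 couplets, root 1."""
    return load_key(_bundle_path(dataset, "key.yaml"))


def bundled_errata(dataset: str = BUNDLED_DATASET) -> dict:
    """Transcription repairs and known printed-key/matrix tensions."""
    with open(_bundle_path(dataset, "key_errata.yaml")) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# predicate evaluation

Profile = Union[TaxonProfile, SpecimenObservation]


@dataclass(frozen=True)
class PredicateOutcome:
    verdict: TriBool
    proxy_mean: bool = False  # midpoint used in place of an unpublished mean
    missing: bool = False


def _compare_crisp(x: float, relation: str, threshold) -> bool:
    if relation == "lt":
        return x < threshold
    if relation == "le":
        return x <= threshold
    if relation == "gt":
        return x > threshold
    if relation == "ge":
        return x >= threshold
    if relation == "in-range":
        lo, hi = threshold
        return lo <= x <= hi
    raise AssertionError(relation)


def _eval_numeric_range(val: NumericValue, relation: str, threshold) -> TriBool:
    if relation == "in-range":
        lo, hi = threshold
        if val.hi < lo or val.lo > hi:
            return TriBool.NO
        if lo <= val.lo and val.hi <= hi:
            return TriBool.YES
        return TriBool.AMBIGUOUS
    at_lo = _compare_crisp(val.lo, relation, threshold)
    at_hi = _compare_crisp(val.hi, relation, threshold)
    if at_lo and at_hi:
        return TriBool.YES
    if not at_lo and not at_hi:
        return TriBool.NO
    return TriBool.AMBIGUOUS


def eval_predicate(p: Predicate, profile: Profile, matrix: CharacterMatrix) -> PredicateOutcome:
    """Three-valued evaluation of one predicate against a profile row."""
    cdef = matrix.character(p.character)  # raises MatrixError if unregistered
    val = profile.get(p.character)
    if isinstance(val, Unknown):
        return PredicateOutcome(TriBool.AMBIGUOUS, missing=True)
    if p.relation == "eq-category":
        if not isinstance(val, str):
            raise MatrixError(f"{p.character}: categorical test on a numeric value")
        verdict = TriBool.YES if val == p.threshold else TriBool.NO
        return PredicateOutcome(verdict)
    if isinstance(val, (int, float)):
        val = NumericValue.point(float(val))
    if not isinstance(val, NumericValue):
        raise MatrixError(f"{p.character}: numeric test on categorical value {val!r}")
    if p.basis == "mean":
        x, proxied = val.effective_mean()
        verdict = TriBool.YES if _compare_crisp(x, p.relation, p.threshold) else TriBool.NO
        return PredicateOutcome(verdict, proxy_mean=proxied)
    return PredicateOutcome(_eval_numeric_range(val, p.relation, p.threshold))


# ---------------------------------------------------------------------------
# traversal


@dataclass(frozen=True)
class StepTrace:
    couplet: int
    lead_index: int
    verdict: TriBool
    predicate_verdicts: tuple[TriBool, ...]
    proxy_mean: bool
    descriptions: tuple[str, ...]


@dataclass(frozen=True)
class Terminal:
    taxon: str
    path: tuple[int, ...]
    trace: tuple[StepTrace, ...]


@dataclass
class TraversalResult:
    terminals: list[Terminal]
    dead_ends: list[tuple[tuple[int, ...], tuple[StepTrace, ...]]]
    status: str  # unique | ambiguous-multiple | dead-end

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terminals:
            seen.setdefault(t.taxon, None)
        return list(seen)


def _eval_lead(lead: Lead, profile: Profile, matrix: CharacterMatrix, couplet_id: int,
               lead_index: int) -> StepTrace:
    verdicts = []
    proxy = False
    for p in lead.predicates:
        out = eval_predicate(p, profile, matrix)
        verdicts.append(out.verdict)
        proxy = proxy or out.proxy_mean
    combined = TriBool.YES
    for v in verdicts:
        combined = combined.and_(v)
    return StepTrace(
        couplet=couplet_id,
        lead_index=lead_index,
        verdict=combined,
        predicate_verdicts=tuple(verdicts),
        proxy_mean=proxy,
        descriptions=tuple(p.describe() for p in lead.predicates),
    )


def traverse(key: Key, profile: Profile, matrix: CharacterMatrix) -> TraversalResult:
    """Depth-first traversal; every lead that is not definitely NO is
    followed, so ambiguity fans out into multiple terminals.  Couplets where
    both leads fail are recorded as dead ends, not raised."""
    terminals: list[Terminal] = []
    dead_ends: list[tuple[tuple[int, ...], tuple[StepTrace, ...]]] = []

    def walk(cid: int, path: tuple[int, ...], trace: tuple[StepTrace, ...]) -> None:
        couplet = key.couplets[cid]
        path = path + (cid,)
        steps = [
            _eval_lead(lead, profile, matrix, cid, i)
            for i, lead in enumerate(couplet.leads)
        ]
        followed = False
        for lead, step in zip(couplet.leads, steps):
            if step.verdict is TriBool.NO:
                continue
            followed = True
            if lead.taxon is not None:
                terminals.append(Terminal(lead.taxon, path, trace + (step,)))
            else:
                walk(lead.goto, path, trace + (step,))  # type: ignore[arg-type]
        if not followed:
            dead_ends.append((path, trace + tuple(steps)))

    walk(key.root, (), ())
    names = {t.taxon for t in terminals}
    if not terminals:
        status = "dead-end"
    elif len(names) == 1:
        status = "unique"
    else:
        status = "ambiguous-multiple"
    return TraversalResult(terminals=terminals, dead_ends=dead_ends, status=status)


# ---------------------------------------------------------------------------
# audit


@dataclass(frozen=True)
class AuditRow:
    taxon: str
    classification: str  # CONSISTENT | AMBIGUOUS | MISROUTED
    reached: tuple[str, ...]
    own_paths: tuple[tuple[int, ...], ...]
    proxy_steps: int


@dataclass
class KeyAudit:
    rows: list[AuditRow]
    structural_errors: list[str]
    unused_characters: list[str]
    missing_terminals: list[str]  # matrix taxa never named by any lead

    def row(self, taxon: str) -> AuditRow:
        key = normalize_taxon_name(taxon)
        for r in self.rows:
            if normalize_taxon_name(r.taxon) == key:
                return r
        raise MatrixError(f"no audit row for taxon {taxon!r}")


def validate_key(key: Key, matrix: CharacterMatrix) -> KeyAudit:
    """Route every taxon's own matrix row through the key.

    CONSISTENT: only the taxon itself is reached.  AMBIGUOUS: reached along
    with others.  MISROUTED: the taxon cannot reach its own terminal (wrong
    terminal or dead end) — surfaced, never silently repaired.
    """
    structural = key.structural_errors()
    terminal_names = {normalize_taxon_name(t) for t in key.terminal_taxa()}
    missing = [
        t.taxon for t in matrix.taxa if normalize_taxon_name(t.taxon) not in terminal_names
    ]
    unused = sorted(
        c.id for c in matrix.registry if c.id not in key.characters_used()
    )
    rows = []
    for prof in matrix.taxa:
        res = traverse(key, prof, matrix)
        reached = tuple(res.taxa)
        me = normalize_taxon_name(prof.taxon)
        own = tuple(
            t.path for t in res.terminals if normalize_taxon_name(t.taxon) == me
        )
        proxies = sum(
            1
            for t in res.terminals
            for step in t.trace
            if step.proxy_mean
        )
        if not own:
            cls = "MISROUTED"
        elif len(set(normalize_taxon_name(r) for r in reached)) == 1:
            cls = "CONSISTENT"
        else:
            cls = "AMBIGUOUS"
        rows.append(
            AuditRow(
                taxon=prof.taxon,
                classification=cls,
                reached=reached,
                own_paths=own,
                proxy_steps=proxies,
            )
        )
    return KeyAudit(
        rows=rows,
        structural_errors=structural,
        unused_characters=unused,
        missing_terminals=missing,
    )
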