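"""Characters, taxa, matrices and specimen observations.

The bundled ``cactodera_v1`` dataset ships a 17-taxon comparative matrix of
cyst, second-stage-juvenile (J2) and egg characters for the genus
*Cactodera*, together with a character registry and the type-series
morphometrics of *C. tianzhuensis*.

Numeric matrix cells are intervals (a published min–max range); categorical
cells are tokens from a per-character enumeration; missing cells are an
explicit :data:`UNKNOWN`, never an empty string or zero.
"""

from __future__ import annotations

import csv
import io
import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "UNKNOWN",
    "Unknown",
    "CharacterDef",
    "NumericValue",
    "TaxonProfile",
    "CharacterMatrix",
    "SpecimenObservation",
    "MatrixError",
    "load_matrix",
    "write_matrix",
    "load_registry",
    "validate_observation",
    "bundled_morphometrics",
    "normalize_taxon_name",
    "BUNDLED_DATASET",
    "TAXON_ALIASES",
]

BUNDLED_DATASET = "cactodera_v1"

#: Alias records for spelling variants found in the literature.
TAXON_ALIASES = {"c. wessi": "C. weissi"}

_STAGES = frozenset({"cyst", "J2", "egg", "female"})

# en dash, em dash, minus sign all normalised to '-'
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})


class MatrixError(ValueError):
    """Malformed matrix data (bad cell, duplicate taxon, unknown character)."""


class Unknown:
    """Singleton marker for a character state that was not recorded."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNKNOWN"

    def __bool__(self) -> bool:
        return False


UNKNOWN = Unknown()


@dataclass(frozen=True)
class CharacterDef:
    """One entry of the character registry."""

    id: str
    label: str
    stage: str
    kind: str  # "numeric" | "categorical"
    units: str = ""
    categories: tuple[str, ...] = ()
    ratio: bool = False

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"character {self.id!r}: unknown stage {self.stage!r}")
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"character {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "numeric" and not self.units and not self.ratio:
            raise ValueError(
                f"numeric character {self.id!r} needs units or an explicit ratio flag"
            )
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"categorical character {self.id!r} enumerates no categories")


@dataclass(frozen=True)
class NumericValue:
    """An interval [lo, hi] with optional published summary statistics.

    A point value is represented as ``lo == hi``.  ``lo <= mean <= hi``
    violations are tolerated (printed tables round) and surfaced through
    :meth:`warnings` rather than raised.
    """

    lo: float
    hi: float
    mean: float | None = None
    sd: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("interval bounds must be finite")
        if self.lo > self.hi:
            raise ValueError(f"inverted interval [{self.lo}, {self.hi}]")

    @classmethod
    def point(cls, x: float) -> "NumericValue":
        return cls(x, x)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def is_point(self) -> bool:
        return self.lo == self.hi

    def effective_mean(self) -> tuple[float, bool]:
        """Published mean if present, else the midpoint; flag says proxy."""
        if self.mean is not None:
            return self.mean, False
        return self.midpoint, True

    def warnings(self) -> list[str]:
        out = []
        if self.mean is not None and not (self.lo <= self.mean <= self.hi):
            out.append(f"mean {self.mean} outside range [{self.lo}, {self.hi}]")
        if self.sd is not None and self.sd < 0:
            out.append(f"negative sd {self.sd}")
        return out


CellValue = Union[NumericValue, str, Unknown]


@dataclass
class TaxonProfile:
    """One taxon's row of the matrix: character id -> interval/category."""

    taxon: str
    values: dict[str, CellValue] = field(default_factory=dict)
    citation: str = ""
    notes: str = ""

    def get(self, character_id: str) -> CellValue:
        return self.values.get(character_id, UNKNOWN)

    def known_characters(self) -> list[str]:
        return [c for c, v in self.values.items() if not isinstance(v, Unknown)]


@dataclass
class SpecimenObservation:
    """A user's (possibly partial) measurements of one specimen or sample."""

    specimen_id: str
    values: dict[str, CellValue] = field(default_factory=dict)
    stage: str | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("observation records no characters")

    def get(self, character_id: str) -> CellValue:
        return self.values.get(character_id, UNKNOWN)


@dataclass
class CharacterMatrix:
    """A character registry plus one profile per taxon."""

    registry: list[CharacterDef]
    taxa: list[TaxonProfile]
    version: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.registry]
        if len(ids) != len(set(ids)):
            raise MatrixError("duplicate character ids in registry")
        names = [normalize_taxon_name(t.taxon) for t in self.taxa]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MatrixError(f"duplicate taxa: {', '.join(dupes)}")
        self._by_char = {c.id: c for c in self.registry}
        self._by_taxon = {normalize_taxon_name(t.taxon): t for t in self.taxa}
        for t in self.taxa:
            for cid, val in t.values.items():
                self._check_cell(t.taxon, cid, val)

    def _check_cell(self, taxon: str, cid: str, val: CellValue) -> None:
        cdef = self._by_char.get(cid)
        if cdef is None:
            raise MatrixError(f"taxon {taxon!r}: unknown character {cid!r}")
        if isinstance(val, Unknown):
            return
        if cdef.kind == "numeric" and not isinstance(val, NumericValue):
            raise MatrixError(f"taxon {taxon!r}, character {cid!r}: expected interval")
        if cdef.kind == "categorical":
            if not isinstance(val, str):
                raise MatrixError(f"taxon {taxon!r}, character {cid!r}: expected category")
            if val not in cdef.categories:
                raise MatrixError(
                    f"taxon {taxon!r}, character {cid!r}: {val!r} not in "
                    f"{{{', '.join(cdef.categories)}}}"
                )

    def character(self, character_id: str) -> CharacterDef:
        try:
            return self._by_char[character_id]
        except KeyError:
            raise MatrixError(f"character {character_id!r} not in registry") from None

    def has_character(self, character_id: str) -> bool:
        return character_id in self._by_char

    def taxon(self, name: str) -> TaxonProfile:
        key = normalize_taxon_name(name)
        try:
            return self._by_taxon[key]
        except KeyError:
            raise MatrixError(f"taxon {name!r} not in matrix") from None

    def has_taxon(self, name: str) -> bool:
        return normalize_taxon_name(name) in self._by_taxon

    def taxon_names(self) -> list[str]:
        return [t.taxon for t in self.taxa]


def normalize_taxon_name(name: str) -> str:
    """Canonical matching key: case-folded, genus abbreviated, alias-resolved.

    ``"Cactodera thornei"``, ``"C. thornei"`` and ``"c.  thornei"`` all map
    to the same key; ``"C. tianzhuensis n. sp."`` drops the "n. sp." tag.
    """
    s = name.strip().lower()
    s = re.sub(r"\bn\.\s*sp\.?$", "", s).strip()
    s = re.sub(r"^cactodera\s+", "c. ", s)
    s = re.sub(r"^c\.?\s+", "c. ", s)
    s = re.sub(r"\s+", " ", s)
    return TAXON_ALIASES.get(s, s).lower()


# ---------------------------------------------------------------------------
# cell parsing / formatting


def parse_cell(text: str, cdef: CharacterDef) -> CellValue:
    """Parse one CSV cell: '' or a lone dash is UNKNOWN; 'lo-hi' an interval;
    a bare number a point value; anything else a category token."""
    s = text.strip().translate(_DASHES)
    if s in ("", "-", "?", "NA", "na"):
        return UNKNOWN
    if cdef.kind == "categorical":
        token = s.lower()
        return token
    # allow 'a x b' two-axis cells as an interval [min, max]
    s = s.replace("×", "x")
    if re.fullmatch(r"[\d.]+\s*x\s*[\d.]+", s):
        a, b = (float(p) for p in re.split(r"\s*x\s*", s))
        return NumericValue(min(a, b), max(a, b))
    m = re.fullmatch(r"(-?[\d.]+)\s*-\s*(-?[\d.]+)", s)
    if m:
        return NumericValue(float(m.group(1)), float(m.group(2)))
    try:
        return NumericValue.point(float(s))
    except ValueError:
        raise MatrixError(f"cannot parse cell {text!r} for character {cdef.id!r}") from None


def format_cell(val: CellValue) -> str:
    if isinstance(val, Unknown):
        return "-"
    if isinstance(val, NumericValue):
        if val.is_point:
            return _fmt_num(val.lo)
        return f"{_fmt_num(val.lo)}-{_fmt_num(val.hi)}"
    return str(val)


def _fmt_num(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# registry + matrix I/O


def _data_root() -> Path:
    return Path(str(resources.files("cactokey").joinpath("data")))


def load_registry(source: str | Path = BUNDLED_DATASET) -> list[CharacterDef]:
    """Load a character registry from a bundled dataset name or a JSON file."""
    path = Path(source)
    if not path.suffix:
        path = _data_root() / str(source) / "registry.json"
    with open(path) as fh:
        raw = json.load(fh)
    return [
        CharacterDef(
            id=c["id"],
            label=c.get("label", c["id"]),
            stage=c["stage"],
            kind=c["kind"],
            units=c.get("units", ""),
            categories=tuple(c.get("categories", ())),
            ratio=bool(c.get("ratio", False)),
        )
        for c in raw["characters"]
    ]


def load_matrix(source: str | Path = BUNDLED_DATASET) -> CharacterMatrix:
    """Load a character matrix.

    ``source`` is either a bundled dataset name (``"cactodera_v1"``), a CSV
    file in the documented dialect (registry resolved from the bundled
    dataset), or a JSON file written by :func:`write_matrix`.
    """
    path = Path(source)
    if not path.suffix:  # bundled dataset name
        root = _data_root() / str(source)
        if not root.is_dir():
            raise MatrixError(f"no bundled dataset named {source!r}")
        registry = load_registry(source)
        return _read_csv(root / "matrix.csv", registry, version=str(source))
    if path.suffix.lower() == ".json":
        return _read_json(path)
    registry = load_registry(BUNDLED_DATASET)
    return _read_csv(path, registry, version=path.stem)


def _read_csv(path: Path, registry: list[CharacterDef], version: str) -> CharacterMatrix:
    by_id = {c.id: c for c in registry}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MatrixError(f"{path}: empty matrix file")
        char_cols = [c for c in reader.fieldnames if c not in ("taxon", "citation", "notes")]
        for col in char_cols:
            if col not in by_id:
                raise MatrixError(f"{path}: column {col!r} not in registry")
        taxa = []
        for row in reader:
            name = (row.get("taxon") or "").strip()
            if not name:
                raise MatrixError(f"{path}: row with empty taxon name")
            values: dict[str, CellValue] = {}
            for col in char_cols:
                try:
                    values[col] = parse_cell(row.get(col) or "", by_id[col])
                except MatrixError as exc:
                    raise MatrixError(f"taxon {name!r}, column {col!r}: {exc}") from None
            taxa.append(
                TaxonProfile(
                    taxon=name,
                    values=values,
                    citation=(row.get("citation") or "").strip(),
                    notes=(row.get("notes") or "").strip(),
                )
            )
    if not taxa:
        raise MatrixError(f"{path}: matrix has no taxa")
    return CharacterMatrix(registry=registry, taxa=taxa, version=version)


def _read_json(path: Path) -> CharacterMatrix:
    with open(path) as fh:
        raw = json.load(fh)
    if not raw.get("taxa"):
        raise MatrixError(f"{path}: matrix has no taxa")
    registry = [
        CharacterDef(
            id=c["id"],
            label=c.get("label", c["id"]),
            stage=c["stage"],
            kind=c["kind"],
            units=c.get("units", ""),
            categories=tuple(c.get("categories", ())),
            ratio=bool(c.get("ratio", False)),
        )
        for c in raw["registry"]
    ]
    taxa = []
    for t in raw["taxa"]:
        values: dict[str, CellValue] = {}
        for cid, v in t["values"].items():
            if v is None:
                values[cid] = UNKNOWN
            elif isinstance(v, dict):
                values[cid] = NumericValue(
                    lo=v["lo"], hi=v["hi"],
                    mean=v.get("mean"), sd=v.get("sd"), n=v.get("n"),
                )
            else:
                values[cid] = str(v)
        taxa.append(
            TaxonProfile(
                taxon=t["taxon"], values=values,
                citation=t.get("citation", ""), notes=t.get("notes", ""),
            )
        )
    return CharacterMatrix(registry=registry, taxa=taxa, version=raw.get("version", ""))


def write_matrix(matrix: CharacterMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix to CSV or JSON. Round-trip safe, unknowns preserved."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported format {fmt!r} (use csv or json)")
    if fmt == "json":
        payload = {
            "version": matrix.version,
            "registry": [
                {
                    "id": c.id, "label": c.label, "stage": c.stage, "kind": c.kind,
                    "units": c.units, "categories": list(c.categories), "ratio": c.ratio,
                }
                for c in matrix.registry
            ],
            "taxa": [
                {
                    "taxon": t.taxon,
                    "citation": t.citation,
                    "notes": t.notes,
                    "values": {
                        cid: (
                            None if isinstance(v, Unknown)
                            else {"lo": v.lo, "hi": v.hi, "mean": v.mean, "sd": v.sd, "n": v.n}
                            if isinstance(v, NumericValue)
                            else v
                        )
                        for cid, v in t.values.items()
                    },
                }
                for t in matrix.taxa
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    char_cols = sorted({cid for t in matrix.taxa for cid in t.values})
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["taxon", *char_cols, "citation", "notes"])
    for t in matrix.taxa:
        writer.writerow(
            [t.taxon, *(format_cell(t.get(c)) for c in char_cols), t.citation, t.notes]
        )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# observation validation


def validate_observation(
    obs: SpecimenObservation, registry: Iterable[CharacterDef]
) -> list[str]:
    """Report (never raise) problems in an observation against a registry."""
    by_id = {c.id: c for c in registry}
    warnings: list[str] = []
    for cid, val in obs.values.items():
        cdef = by_id.get(cid)
        if cdef is None:
            warnings.append(f"unknown character id {cid!r}")
            continue
        if isinstance(val, Unknown):
            continue
        if cdef.kind == "categorical":
            if not isinstance(val, str) or val not in cdef.categories:
                warnings.append(
                    f"{cid}: category {val!r} not in {{{', '.join(cdef.categories)}}}"
                )
        else:
            if isinstance(val, NumericValue):
                if val.lo <= 0:
                    warnings.append(f"{cid}: nonpositive value {val.lo}")
                warnings.extend(f"{cid}: {w}" for w in val.warnings())
            elif isinstance(val, (int, float)):
                if val <= 0:
                    warnings.append(f"{cid}: nonpositive value {val}")
            else:
                warnings.append(f"{cid}: expected a number or interval, got {val!r}")
    return warnings


def bundled_morphometrics(dataset: str = BUNDLED_DATASET) -> dict:
    """Published type-series morphometrics of *C. tianzhuensis* (stage ->
    holotype values and paratype summary statistics)."""
    path = _data_root() / dataset / "tianzhuensis_morphometrics.json"
    with open(path) as fh:
        return json.load(fh)
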