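"""Pairwise divergence arithmetic on pre-aligned nucleotide sequences.

Counts base-pair differences between equal-length aligned sequences and
reports identity the way taxonomic descriptions print it: "N bp (P.PP%)".
The default gap policy is pairwise deletion (columns where either sequence
has a gap are excluded from the comparison); ``count-as-diff`` instead
treats a residue/gap column as a difference.  N and IUPAC ambiguity codes
are compared as exact symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

__all__ = [
    "AlignedPair",
    "DivergenceResult",
    "pairwise_divergence",
    "divergence_table",
    "format_divergence",
    "read_alignment",
]

GAP_POLICIES = ("pairwise-delete", "count-as-diff")

_ALPHABET = set("ACGTUNRYSWKMBDHV-")
_GAPS = set("-")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedPair:
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a = self.seq_a.upper()
        b = self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise AlignmentError(
                f"length mismatch: {self.id_a} has {len(a)} columns, "
                f"{self.id_b} has {len(b)}"
            )
        if len(a) == 0:
            raise AlignmentError("empty alignment")
        bad = (set(a) | set(b)) - _ALPHABET
        if bad:
            raise AlignmentError(f"illegal symbols: {sorted(bad)}")


@dataclass(frozen=True)
class DivergenceResult:
    diffs: int
    compared: int
    identity: float  # percent

    def __iter__(self):
        return iter((self.diffs, self.compared, self.identity))


def pairwise_divergence(
    pair: AlignedPair, gap_policy: str = "pairwise-delete"
) -> DivergenceResult:
    """Count differing columns and percent identity over compared columns."""
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    diffs = 0
    compared = 0
    for x, y in zip(pair.seq_a, pair.seq_b):
        gap = x in _GAPS or y in _GAPS
        if gap:
            if gap_policy == "pairwise-delete":
                continue
            if x in _GAPS and y in _GAPS:
                continue  # shared gap column carries no signal either way
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise AlignmentError("no comparable columns after gap handling")
    identity = 100.0 * (compared - diffs) / compared
    return DivergenceResult(diffs=diffs, compared=compared, identity=identity)


def format_divergence(result: DivergenceResult) -> str:
    """Publication-style "8 bp (98.93%)" string, percent to two decimals."""
    return f"{result.diffs} bp ({result.identity:.2f}%)"


def read_alignment(source: Union[str, Path, Iterable[tuple[str, str]]]) -> list[tuple[str, str]]:
    """Read an aligned FASTA (or pass through (id, seq) pairs)."""
    if isinstance(source, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(source), "fasta")]
    else:
        records = [(i, s) for i, s in source]
    if not records:
        raise AlignmentError("no sequences found")
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    return records


def divergence_table(
    source: Union[str, Path, Iterable[tuple[str, str]]],
    reference: str,
    gap_policy: str = "pairwise-delete",
) -> list[dict]:
    """One row per non-reference sequence: id, diffs, compared, identity,
    and the formatted "N bp (P.PP%)" string."""
    records = read_alignment(source)
    by_id = dict(records)
    if reference not in by_id:
        raise AlignmentError(f"reference {reference!r} not in alignment")
    ref_seq = by_id[reference]
    rows = []
    for sid, seq in records:
        if sid == reference:
            continue
        res = pairwise_divergence(
            AlignedPair(reference, sid, ref_seq, seq), gap_policy=gap_policy
        )
        rows.append(
            {
                "id": sid,
                "diffs": res.diffs,
                "compared": res.compared,
                "identity": res.identity,
                "formatted": format_divergence(res),
            }
        )
    return rows
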