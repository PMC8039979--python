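"""Synthetic specimens and toy alignments with known ground truth.

Numeric values are drawn inside a taxon's published interval — either
uniformly over the strict interior, or from a truncated normal centred on
the midpoint with sd = width/6 — so that recovery experiments have an
unambiguous true answer.  Generation is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .datamodel import (
    CharacterMatrix,
    MatrixError,
    NumericValue,
    SpecimenObservation,
    Unknown,
)
from .seqdiv import AlignedPair, pairwise_divergence

__all__ = [
    "SpecimenSimSpec",
    "simulate_specimens",
    "simulate_alignment",
    "POLICIES",
]

POLICIES = ("uniform-strict-interior", "truncated-normal")

_BASES = "ACGT"


@dataclass(frozen=True)
class SpecimenSimSpec:
    taxon: str
    n: int = 1
    seed: int = 0
    policy: str = "uniform-strict-interior"
    characters: tuple[str, ...] | None = None  # None = all known characters

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")


def _draw(rng: np.random.Generator, val: NumericValue, policy: str) -> float:
    if val.is_point:
        return val.lo
    if policy == "uniform-strict-interior":
        # open-interval uniform: shrink by a hair so draws are strictly inside
        eps = 1e-9 * max(1.0, abs(val.hi))
        return float(rng.uniform(val.lo + eps, val.hi - eps))
    mid, sd = val.midpoint, val.width / 6.0
    a, b = (val.lo - mid) / sd, (val.hi - mid) / sd
    return float(truncnorm.rvs(a, b, loc=mid, scale=sd, random_state=rng))


def simulate_specimens(spec: SpecimenSimSpec, matrix: CharacterMatrix) -> list[SpecimenObservation]:
    """Draw ``spec.n`` observations from a taxon's published envelope.

    Categorical states are copied verbatim; numeric values are sampled per
    policy and are guaranteed in-interval.  A taxon with no recorded
    character among the requested subset is an error.
    """
    prof = matrix.taxon(spec.taxon)
    wanted = spec.characters or tuple(prof.values)
    usable = [
        c for c in wanted
        if not isinstance(prof.get(c), Unknown) and matrix.has_character(c)
    ]
    if not usable:
        raise MatrixError(f"taxon {spec.taxon!r}: no usable characters to simulate")
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n):
        values = {}
        for cid in usable:
            val = prof.get(cid)
            if isinstance(val, NumericValue):
                x = _draw(rng, val, spec.policy)
                assert val.lo <= x <= val.hi
                values[cid] = NumericValue.point(x)
            else:
                values[cid] = val
        out.append(SpecimenObservation(specimen_id=f"{prof.taxon}-sim-{i + 1}", values=values))
    return out


def simulate_alignment(
    length: int,
    n_seqs: int,
    diffs: int | Sequence[int],
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Build an aligned FASTA whose sequences differ from sequence 1 by an
    exact, requested number of substitutions.

    ``diffs`` is a single count applied to every non-reference sequence or a
    per-sequence list of length ``n_seqs - 1``.  Returns the FASTA text and
    a ground-truth table (one row per non-reference sequence) verified with
    :func:`cactokey.seqdiv.pairwise_divergence`.
    """
    if length < 1 or n_seqs < 2:
        raise ValueError("need length >= 1 and n_seqs >= 2")
    if isinstance(diffs, int):
        per_seq = [diffs] * (n_seqs - 1)
    else:
        per_seq = list(diffs)
        if len(per_seq) != n_seqs - 1:
            raise ValueError(f"need {n_seqs - 1} diff counts, got {len(per_seq)}")
    if any(d < 0 or d > length for d in per_seq):
        raise ValueError("each diff count must lie in [0, length]")
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list(_BASES), size=length))
    seqs = [("seq1", ref)]
    truth = []
    for i, d in enumerate(per_seq, start=2):
        positions = rng.choice(length, size=d, replace=False)
        mutated = list(ref)
        for pos in positions:
            alternatives = [b for b in _BASES if b != ref[pos]]
            mutated[pos] = alternatives[int(rng.integers(len(alternatives)))]
        sid = f"seq{i}"
        seq = "".join(mutated)
        seqs.append((sid, seq))
        check = pairwise_divergence(AlignedPair("seq1", sid, ref, seq))
        assert check.diffs == d
        truth.append(
            {"id": sid, "diffs": d, "compared": length, "identity": check.identity}
        )
    fasta = "".join(f">{sid}\n{seq}\n" for sid, seq in seqs)
    return fasta, truth
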