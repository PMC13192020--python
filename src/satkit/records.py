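"""Shared domain records: families, sequences, monomer hits, arrays.

Coordinates are 0-based half-open on the forward strand everywhere inside the
package; conversion to BED (0-based) / GFF3 (1-based) happens only at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, k: int) -> str:
    """Left-rotate ``seq`` by ``k``: rotate("ACGT", 1) == "CGTA"."""
    k %= len(seq)
    return seq[k:] + seq[:k]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SatFamily:
    """A satDNA family: identifier plus consensus monomer sequence.

    The consensus is the representative monomer against which copies are
    annotated and divergence is measured; ``monomer_length`` is its length.
    """

    family_id: str
    consensus: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", _check_dna(self.consensus, f"consensus of {self.family_id}"))
        if not self.consensus:
            raise ValueError(f"family {self.family_id}: empty consensus")

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def dimer(self) -> str:
        """Head-to-tail dimer reference (consensus doubled)."""
        return self.consensus * 2


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/scaffold of an assembly."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MonomerHit:
    """A single annotated monomer occurrence.

    ``rotation`` is the offset into the consensus at which the hit begins when
    read 5'→3' on its own strand. ``divergence`` is alignment divergence
    (mismatches + indel columns over alignment length), the quantity screened
    against the 45% annotation ceiling; K2P distance is computed separately by
    the divergence module.
    """

    family_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    rotation: int
    divergence: float
    aligned_length: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid hit interval {self.family_id}@{self.seq_id}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SatArray:
    """A run of consecutive same-family, same-strand monomers."""

    family_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    members: list[MonomerHit] = field(default_factory=list)

    @property
    def n_monomers(self) -> int:
        return len(self.members)
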