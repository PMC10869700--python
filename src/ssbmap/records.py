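"""Core in-memory records shared by every stage of the pipeline.

Coordinates are 0-based, half-open ``[start, end)`` throughout. A break
signal coordinate (``BreakRecord.pos``) marks the *signal nucleotide*:
the base immediately 3' of the nick on the broken strand, so the break
itself lies on the 5' side of that base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional

STRANDS = ("+", "-")
#: Alphabet permitted in genome sequences.
GENOME_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class Genome(Mapping[str, str]):
    """Uppercased nucleotide sequences keyed by chromosome name."""

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("genome has no chromosomes")
        clean: Dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            seq = seq.upper()
            bad = set(seq) - GENOME_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal characters: {sorted(bad)}"
                )
            clean[name] = seq
        self._sequences = clean

    def __getitem__(self, chrom: str) -> str:
        return self._sequences[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    def length(self, chrom: str) -> int:
        return len(self._sequences[chrom])

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._sequences.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{c}:{len(s)}" for c, s in self._sequences.items())
        return f"Genome({parts})"


@dataclass(frozen=True)
class GeneModel:
    """One gene represented by its canonical transcript interval.

    TSS/TES are derived from the annotation strand: for a ``+`` gene the
    TSS is ``start`` and the TES ``end - 1``; for a ``-`` gene they swap.
    The transcribed (template) strand is the opposite of the annotation
    strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    annotation_strand: str
    coding: bool = True
    expression_tpm: Optional[float] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.annotation_strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id}: bad strand {self.annotation_strand!r}"
            )
        if self.expression_tpm is not None and self.expression_tpm < 0:
            raise ValueError(f"gene {self.gene_id}: negative TPM")

    @property
    def tss(self) -> int:
        return self.start if self.annotation_strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.annotation_strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass(frozen=True)
class AlignedRead:
    """A mapped, ungapped sequencing read carrying a UMI in its name."""

    chrom: str
    start: int
    end: int
    mapping_strand: str
    umi: str
    mapq: int
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"read {self.name or '?'}: start >= end")
        if self.mapping_strand not in STRANDS:
            raise ValueError(f"read {self.name or '?'}: bad strand")
        if self.mapq < 0:
            raise ValueError(f"read {self.name or '?'}: negative MAPQ")
        bad = set(self.umi) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.name or '?'}: illegal UMI characters")

    @property
    def five_prime(self) -> int:
        """Mapped 5'-end coordinate: ``start`` for +, ``end - 1`` for -."""
        return self.start if self.mapping_strand == "+" else self.end - 1


@dataclass(frozen=True)
class BreakRecord:
    """One called SSB signal: the break is 5' of ``pos`` on ``strand``."""

    chrom: str
    pos: int
    strand: str
    mapq: int = 0

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("negative break coordinate")
        if self.strand not in STRANDS:
            raise ValueError(f"bad break strand {self.strand!r}")
        if self.mapq < 0:
            raise ValueError("negative MAPQ")


@dataclass
class SampleBreakSet:
    """All break records of one sample plus its normalization factor M."""

    sample_id: str
    breaks: List[BreakRecord] = field(default_factory=list)
    normalization_factor: Optional[float] = None

    def set_normalization(self, m: float) -> None:
        if m <= 0:
            raise ValueError("normalization factor must be positive")
        self.normalization_factor = m

    def __len__(self) -> int:
        return len(self.breaks)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("peak start >= end")


@dataclass
class PeakSet:
    """Intervals of one chromatin feature track (BED3 semantics)."""

    peaks: List[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)
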