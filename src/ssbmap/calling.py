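"""UMI deduplication and break calling.

A read from the 3'-OH capture protocol is the reverse complement of the
captured fragment, so the free 3'-OH — the break — sits immediately 5' of
the read's mapped 5' end on the *opposite* genomic strand. Calling therefore
(a) collapses PCR duplicates sharing the same mapped 5'-end and UMI and
(b) places one signal per surviving read at the nucleotide immediately
upstream of its 5' end, flipping the strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .records import AlignedRead, BreakRecord, Genome, SampleBreakSet

log = logging.getLogger(__name__)


def merge_umi(r1_name: str, r2_sequence: str, umi_length: int = 10) -> str:
    """Append a UMI (the R2 sequence) to an R1 read name with an underscore."""
    if len(r2_sequence) != umi_length:
        raise ValueError(
            f"UMI {r2_sequence!r} has length {len(r2_sequence)}, expected {umi_length}"
        )
    return f"{r1_name}_{r2_sequence}"


DedupKey = Tuple[str, str, int, str]  # chrom, mapping strand, 5'-end, UMI


def dedup_key(read: AlignedRead) -> DedupKey:
    return (read.chrom, read.mapping_strand, read.five_prime, read.umi)


def deduplicate(reads: List[AlignedRead]) -> List[AlignedRead]:
    """Keep one read per (chrom, strand, mapped 5'-end, exact UMI) key.

    Among duplicates the read with the highest MAPQ survives, ties broken
    by input order; output order is first-occurrence order of the keys.
    """
    best: Dict[DedupKey, AlignedRead] = {}
    for read in reads:
        key = dedup_key(read)
        incumbent = best.get(key)
        if incumbent is None or read.mapq > incumbent.mapq:
            best[key] = read
    return list(best.values())


def call_break(read: AlignedRead, genome: Genome) -> Optional[BreakRecord]:
    """Position one break signal for one read, or None if it falls off the
    chromosome.

    For a read mapped to "+" the signal nucleotide is ``start - 1`` on "-";
    for a read mapped to "-" it is ``end`` (one past the rightmost base,
    i.e. immediately 5' in read orientation) on "+".
    """
    if read.chrom not in genome:
        raise ValueError(f"read on unknown chromosome {read.chrom!r}")
    if read.mapping_strand == "+":
        pos, strand = read.start - 1, "-"
    else:
        pos, strand = read.end, "+"
    if pos < 0 or pos >= genome.length(read.chrom):
        return None
    return BreakRecord(chrom=read.chrom, pos=pos, strand=strand, mapq=read.mapq)


@dataclass
class CallStats:
    """Read accounting across the processing steps."""

    n_input: int = 0
    n_deduplicated: int = 0
    n_below_mapq: int = 0
    n_off_genome: int = 0
    n_emitted: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "input": self.n_input,
            "deduplicated": self.n_deduplicated,
            "below_mapq": self.n_below_mapq,
            "off_genome": self.n_off_genome,
            "emitted": self.n_emitted,
        }


def call_breaks(
    reads: List[AlignedRead],
    genome: Genome,
    min_mapq: int = 0,
    sample_id: str = "sample",
) -> Tuple[SampleBreakSet, CallStats]:
    """Deduplicate, filter by MAPQ, and call one break per surviving read."""
    stats = CallStats(n_input=len(reads))
    survivors = deduplicate(reads)
    stats.n_deduplicated = len(survivors)
    breaks: List[BreakRecord] = []
    for read in survivors:
        if read.mapq < min_mapq:
            stats.n_below_mapq += 1
            continue
        record = call_break(read, genome)
        if record is None:
            stats.n_off_genome += 1
            continue
        breaks.append(record)
    stats.n_emitted = len(breaks)
    log.info(
        "call_breaks[%s]: input=%d dedup=%d below_mapq=%d off_genome=%d emitted=%d",
        sample_id,
        stats.n_input,
        stats.n_deduplicated,
        stats.n_below_mapq,
        stats.n_off_genome,
        stats.n_emitted,
    )
    return SampleBreakSet(sample_id=sample_id, breaks=breaks), stats
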