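"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV. The break-record schema is exactly four
columns — chromosome, 0-based signal coordinate, strand, MAPQ — one line
per break signal, duplicates meaning abundance.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Union

from Bio import SeqIO

from .records import (
    AlignedRead,
    BreakRecord,
    GeneModel,
    Genome,
    Peak,
    PeakSet,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its declared schema."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Genome:
    """Read a genome FASTA; sequences are uppercased, order preserved."""
    sequences = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate chromosome name {record.id!r}")
        seq = str(record.seq)
        if not seq:
            raise FormatError(f"chromosome {record.id!r} has an empty sequence")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    try:
        return Genome(sequences)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_fasta(genome: Genome, path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genes and expression


def read_genes(
    path: PathLike,
    expression_path: Optional[PathLike] = None,
    *,
    allow_missing_expression: bool = False,
) -> List[GeneModel]:
    """Read a gene table (gene_id, chrom, start, end, strand, coding) and
    optionally join a TPM expression table by gene_id.

    Genes absent from the expression table raise ``FormatError`` unless
    ``allow_missing_expression`` is set, in which case their TPM is None.
    """
    tpm = {}
    if expression_path is not None:
        for lineno, fields in _tsv_rows(expression_path, 2, "expression"):
            gene_id, raw = fields[0], fields[1]
            if gene_id == "gene_id":  # header
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{expression_path}:{lineno}: non-numeric TPM {raw!r}"
                ) from exc
            if value < 0:
                raise FormatError(f"{expression_path}:{lineno}: negative TPM")
            if gene_id in tpm:
                raise FormatError(
                    f"{expression_path}:{lineno}: duplicate gene_id {gene_id!r}"
                )
            tpm[gene_id] = value

    genes: List[GeneModel] = []
    seen = set()
    for lineno, fields in _tsv_rows(path, 6, "gene table"):
        gene_id, chrom, start, end, strand, coding = fields[:6]
        if gene_id == "gene_id":
            continue
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if coding not in ("0", "1", "True", "False", "true", "false"):
            raise FormatError(f"{path}:{lineno}: bad coding flag {coding!r}")
        expression = None
        if expression_path is not None:
            if gene_id in tpm:
                expression = tpm[gene_id]
            elif not allow_missing_expression:
                raise FormatError(
                    f"gene {gene_id!r} missing from expression table {expression_path}"
                )
        try:
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    annotation_strand=strand,
                    coding=coding in ("1", "True", "true"),
                    expression_tpm=expression,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tcoding\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t"
                f"{g.annotation_strand}\t{int(g.coding)}\n"
            )


def write_expression(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for g in genes:
            if g.expression_tpm is None:
                continue
            fh.write(f"{g.gene_id}\t{g.expression_tpm:.6g}\n")


# ---------------------------------------------------------------------------
# Alignments


def parse_umi_from_name(name: str, umi_length: int = 10) -> str:
    """Extract the UMI stored after the LAST underscore of a read name."""
    if "_" not in name:
        raise FormatError(f"read name {name!r} carries no UMI suffix")
    umi = name.rsplit("_", 1)[1]
    if len(umi) != umi_length:
        raise FormatError(
            f"UMI {umi!r} in read {name!r} has length {len(umi)}, expected {umi_length}"
        )
    if set(umi) - set("ACGTN"):
        raise FormatError(f"UMI {umi!r} in read {name!r} has illegal characters")
    return umi


def read_alignments(path: PathLike, umi_length: int = 10) -> List[AlignedRead]:
    """Read a BED-like alignment TSV: chrom, start, end, name, mapq, strand.

    The UMI is the read-name suffix after the last underscore.
    """
    reads: List[AlignedRead] = []
    for lineno, fields in _tsv_rows(path, 6, "alignments"):
        chrom, start, end, name, mapq, strand = fields[:6]
        try:
            start_i, end_i, mapq_i = int(start), int(end), int(mapq)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer field") from exc
        umi = parse_umi_from_name(name, umi_length)
        try:
            reads.append(
                AlignedRead(
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    mapping_strand=strand,
                    umi=umi,
                    mapq=mapq_i,
                    name=name,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_alignments(reads: Iterable[AlignedRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            name = r.name or f"read{i}_{r.umi}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.mapq}\t{r.mapping_strand}\n"
            )


def read_alignments_sam(path: PathLike, umi_length: int = 10) -> List[AlignedRead]:
    """Read mapped reads from SAM/BAM, applying the same UMI-in-name rule.

    Reads whose alignment is not one ungapped interval (any CIGAR operation
    other than M/=/X) are rejected and counted in a warning.
    """
    import pysam

    reads: List[AlignedRead] = []
    n_rejected = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if any(op not in (0, 7, 8) for op, _ in (aln.cigartuples or [])):
                n_rejected += 1
                continue
            umi = parse_umi_from_name(aln.query_name, umi_length)
            reads.append(
                AlignedRead(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    mapping_strand="-" if aln.is_reverse else "+",
                    umi=umi,
                    mapq=aln.mapping_quality,
                    name=aln.query_name,
                )
            )
    if n_rejected:
        log.warning("rejected %d split/clipped alignments", n_rejected)
    return reads


# ---------------------------------------------------------------------------
# Break records


def read_breaks_tsv(path: PathLike) -> List[BreakRecord]:
    breaks: List[BreakRecord] = []
    for lineno, fields in _tsv_rows(path, 4, "breaks", exact=True):
        chrom, pos, strand, mapq = fields
        try:
            pos_i, mapq_i = int(pos), int(mapq)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer field") from exc
        try:
            breaks.append(BreakRecord(chrom=chrom, pos=pos_i, strand=strand, mapq=mapq_i))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return breaks


def write_breaks_tsv(breaks: Iterable[BreakRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for b in breaks:
            fh.write(f"{b.chrom}\t{b.pos}\t{b.strand}\t{b.mapq}\n")


def validate_breaks(
    breaks: Iterable[BreakRecord],
    genome: Genome,
    *,
    on_unknown: str = "error",
) -> List[BreakRecord]:
    """Check breaks against a genome; unknown chromosomes or out-of-range
    coordinates raise by default, or are skipped with a warning count under
    ``on_unknown='skip'``."""
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    kept: List[BreakRecord] = []
    n_skipped = 0
    for b in breaks:
        if b.chrom not in genome or b.pos >= genome.length(b.chrom):
            if on_unknown == "error":
                raise ValueError(
                    f"break {b.chrom}:{b.pos} outside the genome "
                    "(unknown chromosome or coordinate past its end)"
                )
            n_skipped += 1
            continue
        kept.append(b)
    if n_skipped:
        log.warning("skipped %d breaks outside the genome", n_skipped)
    return kept


# ---------------------------------------------------------------------------
# Peaks


def read_peaks(path: PathLike) -> PeakSet:
    """Read a BED3+ peak file; columns past the third are ignored."""
    peaks: List[Peak] = []
    for lineno, fields in _tsv_rows(path, 3, "peaks"):
        chrom, start, end = fields[:3]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        try:
            peaks.append(Peak(chrom=chrom, start=start_i, end=end_i))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(peaks)


def write_peaks(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# shared


def _tsv_rows(path: PathLike, min_fields: int, what: str, exact: bool = False):
    """Yield (lineno, fields) for nonempty lines, enforcing a column count."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if exact and len(fields) != min_fields:
                raise FormatError(
                    f"{path}:{lineno}: {what} line has {len(fields)} columns, "
                    f"expected exactly {min_fields}"
                )
            if len(fields) < min_fields:
                raise FormatError(
                    f"{path}:{lineno}: {what} line has {len(fields)} columns, "
                    f"expected at least {min_fields}"
                )
            yield lineno, fields
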