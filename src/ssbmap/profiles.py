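"""Metagene profiles, divergent-transcription flank counts and sequence
context around break signals.

Gene-anchored coordinates put the TSS at 0 with the gene pointing rightward.
A break's strand class is ``transcribed`` if it lies on the gene's template
strand (opposite the annotation strand), else ``non_transcribed``.

Offset convention for sequence context: offset 0 is the signal nucleotide,
i.e. the first base downstream of (3' of) the break on the broken strand;
a logo's "position 1" is offset +1 of the context matrix.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quantify import _count_in, index_breaks, transcribed_strand
from .records import BreakRecord, GeneModel, Genome

log = logging.getLogger(__name__)

_CI_Z = 1.959963984540054  # two-sided 95% normal quantile


def to_gene_coordinates(
    brk: BreakRecord, gene: GeneModel
) -> Tuple[int, str]:
    """(signed offset of the break from the TSS in gene orientation,
    strand class)."""
    if brk.chrom != gene.chrom:
        raise ValueError("break and gene on different chromosomes")
    if gene.annotation_strand == "+":
        offset = brk.pos - gene.tss
    else:
        offset = gene.tss - brk.pos
    strand_class = (
        "transcribed" if brk.strand == transcribed_strand(gene) else "non_transcribed"
    )
    return offset, strand_class


def _gene_window_positions(index, gene: GeneModel, lo: int, hi: int):
    """Per strand class, gene-oriented offsets (relative to TSS) of breaks
    with offset in [lo, hi)."""
    out = {}
    plus = gene.annotation_strand == "+"
    for strand_class in ("transcribed", "non_transcribed"):
        strand = (
            transcribed_strand(gene)
            if strand_class == "transcribed"
            else gene.annotation_strand
        )
        pos = index.get((gene.chrom, strand))
        if pos is None:
            out[strand_class] = np.empty(0, dtype=np.int64)
            continue
        if plus:
            g_lo, g_hi = gene.tss + lo, gene.tss + hi
            window = pos[np.searchsorted(pos, g_lo) : np.searchsorted(pos, g_hi)]
            out[strand_class] = window - gene.tss
        else:
            g_lo, g_hi = gene.tss - hi + 1, gene.tss - lo + 1
            window = pos[np.searchsorted(pos, g_lo) : np.searchsorted(pos, g_hi)]
            out[strand_class] = gene.tss - window
    return out


def _mean_ci(per_gene: np.ndarray) -> Tuple[float, float, float]:
    n = len(per_gene)
    mean = float(per_gene.mean())
    if n < 2:
        return mean, mean, mean
    se = float(per_gene.std(ddof=1)) / math.sqrt(n)
    return mean, mean - _CI_Z * se, mean + _CI_Z * se


def metagene_profile(
    breaks: Iterable[BreakRecord],
    genes: Sequence[GeneModel],
    genome: Genome,
    m: float,
    upstream: int = 5_000,
    downstream: int = 5_000,
    body_bins: int = 20,
    flank_bin: int = 250,
) -> pd.DataFrame:
    """Mean normalized break density per bin across a gene set, with 95% CI.

    Flank bins are absolute (``flank_bin`` bases); gene-body bins are
    relative (each a fraction ``1/body_bins`` of that gene's length), so a
    gene's bin length in kb is ``L / body_bins / 1000``. Per gene and bin,
    density = count / (bin_kb * M); the profile is the across-gene mean.
    Genes whose window leaves the chromosome are excluded and counted.

    Columns: region (upstream/body/downstream), bin, bin_center (bases for
    flanks, fraction of gene length for the body), strand_class, mean,
    ci_low, ci_high, n_genes.
    """
    if not genes:
        raise ValueError("empty gene set")
    if upstream % flank_bin or downstream % flank_bin:
        raise ValueError("flank length must be a multiple of the flank bin")
    index = index_breaks(breaks)
    n_up, n_down = upstream // flank_bin, downstream // flank_bin

    kept: List[GeneModel] = []
    n_excluded = 0
    for g in genes:
        clen = genome.length(g.chrom)
        if g.annotation_strand == "+":
            lo, hi = g.tss - upstream, g.tes + 1 + downstream
        else:
            lo, hi = g.tss - (g.length - 1) - downstream, g.tss + upstream + 1
        if lo < 0 or hi > clen:
            n_excluded += 1
            continue
        kept.append(g)
    if n_excluded:
        log.warning("metagene: excluded %d genes with truncated windows", n_excluded)
    if not kept:
        raise ValueError("no genes with complete windows")

    n_genes = len(kept)
    dens = {
        sc: np.zeros((n_genes, n_up + body_bins + n_down)) for sc in
        ("transcribed", "non_transcribed")
    }
    flank_kb = flank_bin / 1000.0
    for i, g in enumerate(kept):
        offsets = _gene_window_positions(index, g, -upstream, g.length + downstream)
        body_bin_kb = g.length / body_bins / 1000.0
        for sc, offs in offsets.items():
            up = offs[offs < 0]
            if len(up):
                idx = (up + upstream) // flank_bin
                np.add.at(dens[sc][i], idx, 1.0 / flank_kb)
            body = offs[(offs >= 0) & (offs < g.length)]
            if len(body):
                idx = np.minimum(
                    (body * body_bins // g.length).astype(int), body_bins - 1
                )
                np.add.at(dens[sc][i], n_up + idx, 1.0 / body_bin_kb)
            down = offs[offs >= g.length]
            if len(down):
                idx = (down - g.length) // flank_bin
                np.add.at(dens[sc][i], n_up + body_bins + idx, 1.0 / flank_kb)
    rows = []
    for sc in ("transcribed", "non_transcribed"):
        dens[sc] /= m
        for j in range(n_up + body_bins + n_down):
            if j < n_up:
                region, b = "upstream", j
                center = -upstream + (j + 0.5) * flank_bin
            elif j < n_up + body_bins:
                region, b = "body", j - n_up
                center = (b + 0.5) / body_bins  # fraction of gene length
            else:
                region, b = "downstream", j - n_up - body_bins
                center = (b + 0.5) * flank_bin
            mean, lo_ci, hi_ci = _mean_ci(dens[sc][:, j])
            rows.append(
                {
                    "region": region,
                    "bin": b,
                    "bin_center": center,
                    "strand_class": sc,
                    "mean": mean,
                    "ci_low": lo_ci,
                    "ci_high": hi_ci,
                    "n_genes": n_genes,
                }
            )
    return pd.DataFrame(rows)


LENGTH_GROUP_LABELS = ("<=10kb", "<=22kb", "<=50kb", ">50kb")


def gene_length_group(
    gene: GeneModel, thresholds_kb: Sequence[float] = (10.0, 22.0, 50.0)
) -> str:
    for t, label in zip(thresholds_kb, LENGTH_GROUP_LABELS):
        if gene.length_kb <= t:
            return label
    return LENGTH_GROUP_LABELS[-1]


def tss_profile_by_length(
    breaks: Iterable[BreakRecord],
    genes: Sequence[GeneModel],
    genome: Genome,
    m: float,
    window: int = 5_000,
    bin_size: int = 100,
    thresholds_kb: Sequence[float] = (10.0, 22.0, 50.0),
) -> Dict[str, pd.DataFrame]:
    """TSS-centered absolute-bin profiles, genes stratified by length.

    The window is TSS-anchored and not clipped at the TES. Returns one
    profile per nonempty length group; empty groups are omitted with a
    warning. Columns as in :func:`metagene_profile` with ``bin_center`` in
    bases relative to the TSS.
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of the bin size")
    index = index_breaks(breaks)
    n_bins = 2 * window // bin_size
    groups: Dict[str, List[GeneModel]] = {l: [] for l in LENGTH_GROUP_LABELS}
    n_excluded = 0
    for g in genes:
        clen = genome.length(g.chrom)
        if g.tss - window < 0 or g.tss + window + 1 > clen:
            n_excluded += 1
            continue
        groups[gene_length_group(g, thresholds_kb)].append(g)
    if n_excluded:
        log.warning("tss profile: excluded %d genes near chromosome ends", n_excluded)

    bin_kb = bin_size / 1000.0
    out: Dict[str, pd.DataFrame] = {}
    for label, members in groups.items():
        if not members:
            log.warning("tss profile: empty gene-length group %s omitted", label)
            continue
        dens = {
            sc: np.zeros((len(members), n_bins))
            for sc in ("transcribed", "non_transcribed")
        }
        for i, g in enumerate(members):
            offsets = _gene_window_positions(index, g, -window, window)
            for sc, offs in offsets.items():
                idx = (offs + window) // bin_size
                np.add.at(dens[sc][i], idx, 1.0 / bin_kb)
        rows = []
        for sc in ("transcribed", "non_transcribed"):
            dens[sc] /= m
            for j in range(n_bins):
                mean, lo_ci, hi_ci = _mean_ci(dens[sc][:, j])
                rows.append(
                    {
                        "bin": j,
                        "bin_center": -window + (j + 0.5) * bin_size,
                        "strand_class": sc,
                        "mean": mean,
                        "ci_low": lo_ci,
                        "ci_high": hi_ci,
                        "n_genes": len(members),
                    }
                )
        out[label] = pd.DataFrame(rows)
    return out


def gc_profile(
    genes: Sequence[GeneModel],
    genome: Genome,
    window: int = 5_000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Strand-specific G content per TSS-anchored bin over a gene set.

    In gene orientation the non-transcribed (sense) strand reads as the
    reference for "+" genes; its G fraction at a position equals the C
    fraction of the transcribed strand at that position (complementarity).
    Columns: bin, bin_center, strand_class, g_fraction, n_genes.
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of the bin size")
    n_bins = 2 * window // bin_size
    counts = {sc: np.zeros(n_bins) for sc in ("transcribed", "non_transcribed")}
    totals = np.zeros(n_bins)
    n_used = 0
    for g in genes:
        clen = genome.length(g.chrom)
        if g.tss - window < 0 or g.tss + window + 1 > clen:
            continue
        n_used += 1
        if g.annotation_strand == "+":
            seq = genome[g.chrom][g.tss - window : g.tss + window]
            sense = np.frombuffer(seq.encode(), dtype="S1")
        else:
            seq = genome[g.chrom][g.tss - window + 1 : g.tss + window + 1]
            arr = np.frombuffer(seq.encode(), dtype="S1")[::-1]
            comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A", b"N": b"N"}
            sense = np.array([comp[bytes(x)] for x in arr], dtype="S1")
        valid = sense != b"N"
        bins = np.arange(2 * window) // bin_size
        np.add.at(totals, bins[valid], 1.0)
        np.add.at(counts["non_transcribed"], bins[valid & (sense == b"G")], 1.0)
        np.add.at(counts["transcribed"], bins[valid & (sense == b"C")], 1.0)
    if n_used == 0:
        raise ValueError("no genes with complete windows")
    rows = []
    for sc in ("transcribed", "non_transcribed"):
        frac = np.divide(counts[sc], totals, out=np.zeros(n_bins), where=totals > 0)
        for j in range(n_bins):
            rows.append(
                {
                    "bin": j,
                    "bin_center": -window + (j + 0.5) * bin_size,
                    "strand_class": sc,
                    "g_fraction": float(frac[j]),
                    "n_genes": n_used,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Divergent-transcription flanks


def flank_counts(
    breaks: Iterable[BreakRecord],
    genes: Sequence[GeneModel],
    m: float,
    flank: int = 5_000,
    genome: Optional[Genome] = None,
) -> Tuple[pd.DataFrame, int]:
    """Per-gene normalized counts in the two divergent-transcription
    branches: the 5-kb region downstream of the TSS on the transcribed
    strand, and the 5-kb region upstream of the TSS on the non-transcribed
    strand. C uses L = ``flank`` kb. Genes with truncated flanks are
    excluded; the count of exclusions is returned alongside.

    Columns: gene_id, downstream_ts_C, upstream_nts_C.
    """
    index = index_breaks(breaks)
    flank_kb = flank / 1000.0
    rows = []
    n_excluded = 0
    for g in genes:
        plus = g.annotation_strand == "+"
        if plus:
            down = (g.tss, g.tss + flank)
            up = (g.tss - flank, g.tss)
        else:
            down = (g.tss - flank + 1, g.tss + 1)
            up = (g.tss + 1, g.tss + flank + 1)
        lo = min(down[0], up[0])
        hi = max(down[1], up[1])
        if lo < 0 or (genome is not None and hi > genome.length(g.chrom)):
            n_excluded += 1
            continue
        n_down = _count_in(index, g.chrom, transcribed_strand(g), *down)
        n_up = _count_in(index, g.chrom, g.annotation_strand, *up)
        rows.append(
            {
                "gene_id": g.gene_id,
                "downstream_ts_C": n_down / (flank_kb * m),
                "upstream_nts_C": n_up / (flank_kb * m),
            }
        )
    if n_excluded:
        log.warning("flank counts: excluded %d genes with truncated flanks", n_excluded)
    return pd.DataFrame(rows, columns=["gene_id", "downstream_ts_C", "upstream_nts_C"]), n_excluded


def background_threshold(
    flanks: pd.DataFrame,
    tiers: Dict[str, str],
    column: str = "upstream_nts_C",
) -> Tuple[float, pd.DataFrame]:
    """Endogenous-background threshold: the upper quartile (linear
    interpolation) of the flank count among not-expressed genes; also the
    per-tier fraction of genes at or below it."""
    df = flanks.copy()
    df["tier"] = df["gene_id"].map(tiers)
    ref = df.loc[df["tier"] == "not_expressed", column].to_numpy()
    if len(ref) < 4:
        raise ValueError("need at least 4 unexpressed genes for the threshold")
    threshold = float(np.percentile(ref, 75))
    rows = []
    for tier, sub in df.groupby("tier"):
        vals = sub[column].to_numpy()
        rows.append(
            {
                "tier": tier,
                "n": len(vals),
                "fraction_below": float((vals <= threshold).mean()),
            }
        )
    return threshold, pd.DataFrame(rows)


def select_breaks_in_regions(
    breaks: Iterable[BreakRecord],
    genes: Sequence[GeneModel],
    flank: int = 5_000,
) -> List[Tuple[BreakRecord, str]]:
    """Breaks in the regions most affected by transcription-coupled
    incision: gene bodies on the transcribed strand (tag ``body``) and the
    ``flank`` bases upstream of the TSS on the non-transcribed strand
    (tag ``upstream``). A break matching several genes is kept once per
    matching rule occurrence."""
    out: List[Tuple[BreakRecord, str]] = []
    for b in breaks:
        for g in genes:
            if b.chrom != g.chrom:
                continue
            plus = g.annotation_strand == "+"
            if b.strand == transcribed_strand(g) and g.start <= b.pos < g.end:
                out.append((b, "body"))
            elif b.strand == g.annotation_strand:
                if plus and g.tss - flank <= b.pos < g.tss:
                    out.append((b, "upstream"))
                elif not plus and g.tss < b.pos <= g.tss + flank:
                    out.append((b, "upstream"))
    return out


# ---------------------------------------------------------------------------
# Sequence context


def context_matrix(
    breaks: Iterable[BreakRecord],
    genome: Genome,
    up: int = 5,
    down: int = 10,
) -> pd.DataFrame:
    """Base counts and fractions per offset around break signals.

    Offset 0 is the signal nucleotide. For a "+" break at ``pos`` offset k
    maps to reference position ``pos + k``; for a "-" break to ``pos - k``
    with the base complemented. Breaks whose window leaves the chromosome
    are excluded and counted in the log. Fractions are over non-N bases.

    Columns: offset, base, count, fraction, n_contexts.
    """
    offsets = np.arange(-up, down + 1)
    counts = {b: np.zeros(len(offsets), dtype=np.int64) for b in "ACGTN"}
    n_used = 0
    n_excluded = 0
    comp = str.maketrans("ACGTN", "TGCAN")
    for brk in breaks:
        seq = genome[brk.chrom]
        if brk.strand == "+":
            lo, hi = brk.pos - up, brk.pos + down
            if lo < 0 or hi >= len(seq):
                n_excluded += 1
                continue
            window = seq[lo : hi + 1]
        else:
            lo, hi = brk.pos - down, brk.pos + up
            if lo < 0 or hi >= len(seq):
                n_excluded += 1
                continue
            window = seq[lo : hi + 1].translate(comp)[::-1]
        n_used += 1
        for k, base in enumerate(window):
            counts[base][k] += 1
    if n_excluded:
        log.warning("context: excluded %d breaks with truncated windows", n_excluded)
    rows = []
    for j, off in enumerate(offsets):
        non_n = sum(counts[b][j] for b in "ACGT")
        for base in "ACGT":
            rows.append(
                {
                    "offset": int(off),
                    "base": base,
                    "count": int(counts[base][j]),
                    "fraction": counts[base][j] / non_n if non_n else np.nan,
                    "n_contexts": n_used,
                }
            )
    return pd.DataFrame(rows)


def logo_summary(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, float]:
    """Per-offset information content (2 - Shannon entropy, bits) and the G
    fraction at offset +1 — the base one position downstream of the signal
    nucleotide, i.e. two downstream of the break itself."""
    if matrix.empty or int(matrix["n_contexts"].max()) < 1:
        raise ValueError("empty context matrix")
    rows = []
    g_plus1 = float("nan")
    for off, sub in matrix.groupby("offset"):
        fractions = sub.set_index("base")["fraction"]
        f = fractions.reindex(list("ACGT")).to_numpy(dtype=float)
        nz = f[f > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        rows.append({"offset": int(off), "information_bits": 2.0 - entropy})
        if off == 1:
            g_plus1 = float(fractions["G"])
    return pd.DataFrame(rows), g_plus1
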