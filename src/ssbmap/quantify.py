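"""Per-sample normalization and per-gene / per-bin break quantification.

The sample normalization factor M is the mean break density (breaks per kb)
over the transcribed strands of not-expressed genes — the endogenous
reference class — so that after normalization the mean normalized count C
of that class is exactly 1. Normalized counts follow C = N / (L_kb * M).
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import BreakRecord, GeneModel, Genome

TIER_LABELS = (
    "not_expressed",
    "<=25%",
    "<=50%",
    "<=70%",
    "<=80%",
    "<=90%",
    "<=95%",
    "<=100%",
)
_TIER_CUTS = (25.0, 50.0, 70.0, 80.0, 90.0, 95.0, 100.0)

STRAND_CLASSES = ("transcribed", "non_transcribed")


def transcribed_strand(gene: GeneModel) -> str:
    """Genomic strand of the gene's template (transcribed/antisense) strand."""
    return "-" if gene.annotation_strand == "+" else "+"


def index_breaks(
    breaks: Iterable[BreakRecord],
) -> Dict[Tuple[str, str], np.ndarray]:
    """Sorted position arrays keyed by (chrom, strand) for fast counting."""
    grouped: Dict[Tuple[str, str], List[int]] = {}
    for b in breaks:
        grouped.setdefault((b.chrom, b.strand), []).append(b.pos)
    return {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in grouped.items()}


def _count_in(index, chrom: str, strand: str, start: int, end: int) -> int:
    pos = index.get((chrom, strand))
    if pos is None:
        return 0
    return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def count_gene_breaks(
    breaks: Iterable[BreakRecord], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Raw break counts per gene and strand class over the genomic gene body
    ``[start, end)``. Breaks shared by overlapping genes count for both.

    Returns a DataFrame with columns gene_id, strand_class, N, L_kb.
    """
    index = index_breaks(breaks)
    rows = []
    for g in genes:
        ts = transcribed_strand(g)
        for strand_class, strand in (
            ("transcribed", ts),
            ("non_transcribed", g.annotation_strand),
        ):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "strand_class": strand_class,
                    "N": _count_in(index, g.chrom, strand, g.start, g.end),
                    "L_kb": g.length_kb,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "strand_class", "N", "L_kb"])


def assign_tiers(
    genes: Sequence[GeneModel], tpm_zero_threshold: float = 0.0
) -> Dict[str, str]:
    """Expression tiers: TPM <= threshold is ``not_expressed``; expressed
    genes are split at the 25/50/70/80/90/95/100 average-rank percentiles,
    so equal TPM values never straddle a tier boundary."""
    tiers: Dict[str, str] = {}
    expressed = []
    for g in genes:
        tpm = g.expression_tpm
        if tpm is None:
            raise ValueError(f"gene {g.gene_id} has no expression value")
        if tpm <= tpm_zero_threshold:
            tiers[g.gene_id] = "not_expressed"
        else:
            expressed.append(g)
    if expressed:
        tpms = np.array([g.expression_tpm for g in expressed])
        pct = stats.rankdata(tpms, method="average") / len(tpms) * 100.0
        for g, p in zip(expressed, pct):
            for cut, label in zip(_TIER_CUTS, TIER_LABELS[1:]):
                if p <= cut + 1e-9:
                    tiers[g.gene_id] = label
                    break
    return tiers


def normalization_factor(
    gene_counts: pd.DataFrame, tiers: Dict[str, str]
) -> float:
    """M = mean of N / L_kb over transcribed strands of not-expressed genes."""
    ref = gene_counts[
        (gene_counts["strand_class"] == "transcribed")
        & (gene_counts["gene_id"].map(tiers) == "not_expressed")
    ]
    if ref.empty:
        raise ValueError("normalization reference class empty: no unexpressed genes")
    m = float((ref["N"] / ref["L_kb"]).mean())
    if m == 0:
        raise ValueError(
            "normalization factor is zero (no breaks in the reference class); "
            "consider a pseudocount"
        )
    return m


def normalize_counts(gene_counts: pd.DataFrame, m: float) -> pd.DataFrame:
    """Add the normalized count column C = N / (L_kb * M)."""
    if m <= 0:
        raise ValueError("normalization factor must be positive")
    out = gene_counts.copy()
    out["C"] = out["N"] / (out["L_kb"] * m)
    return out


def summarize_tiers(
    gene_counts: pd.DataFrame, tiers: Dict[str, str]
) -> pd.DataFrame:
    """Box-plot style summary of C per tier and strand class: n, mean,
    median, quartiles, and whisker bounds at 1.5x IQR (whiskers extend to
    the furthest datapoint inside the fences)."""
    df = gene_counts.copy()
    df["tier"] = df["gene_id"].map(tiers)
    rows = []
    for tier in TIER_LABELS:
        for strand_class in STRAND_CLASSES:
            values = df.loc[
                (df["tier"] == tier) & (df["strand_class"] == strand_class), "C"
            ].to_numpy()
            if len(values) == 0:
                rows.append(
                    {
                        "tier": tier,
                        "strand_class": strand_class,
                        "n": 0,
                        "mean": np.nan,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "whisker_low": np.nan,
                        "whisker_high": np.nan,
                    }
                )
                continue
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            iqr = q3 - q1
            inside = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
            rows.append(
                {
                    "tier": tier,
                    "strand_class": strand_class,
                    "n": len(values),
                    "mean": float(values.mean()),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "whisker_low": float(inside.min()),
                    "whisker_high": float(inside.max()),
                }
            )
    return pd.DataFrame(rows)


def spearman_expression_correlation(
    gene_counts: pd.DataFrame,
    genes: Sequence[GeneModel],
    strand_class: str,
) -> float:
    """Spearman rho of (TPM, C) over all genes of one strand class, average
    ranks for ties. Constant inputs yield NaN with a warning, never a
    silent 0."""
    if strand_class not in STRAND_CLASSES:
        raise ValueError(f"unknown strand class {strand_class!r}")
    tpm = {g.gene_id: g.expression_tpm for g in genes}
    sub = gene_counts[gene_counts["strand_class"] == strand_class]
    if len(sub) < 3:
        raise ValueError("need at least 3 genes")
    x = sub["gene_id"].map(tpm).to_numpy(dtype=float)
    y = sub["C"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# Genomic bins


def bin_genome(
    breaks: Iterable[BreakRecord],
    genome: Genome,
    width: int = 100_000,
    strand_mode: str = "merged",
    m: float = 1.0,
) -> pd.DataFrame:
    """Tile each chromosome with half-open bins of ``width`` bases and count
    breaks per bin (the last bin may be short; its true length is used for
    normalization). C = N / (bin_kb * M).

    Columns: chrom, bin, start, end [, strand], N, C.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if strand_mode not in ("merged", "separate"):
        raise ValueError("strand_mode must be 'merged' or 'separate'")
    index = index_breaks(breaks)
    strands = ("+", "-") if strand_mode == "separate" else (None,)
    rows = []
    for chrom in genome:
        clen = genome.length(chrom)
        n_bins = math.ceil(clen / width)
        for b in range(n_bins):
            start, end = b * width, min((b + 1) * width, clen)
            bin_kb = (end - start) / 1000.0
            for strand in strands:
                if strand is None:
                    n = _count_in(index, chrom, "+", start, end) + _count_in(
                        index, chrom, "-", start, end
                    )
                else:
                    n = _count_in(index, chrom, strand, start, end)
                row = {
                    "chrom": chrom,
                    "bin": b,
                    "start": start,
                    "end": end,
                    "N": n,
                    "C": n / (bin_kb * m),
                }
                if strand is not None:
                    row["strand"] = strand
                rows.append(row)
    return pd.DataFrame(rows)


def fold_change_vs_median(bintrack: pd.DataFrame) -> pd.Series:
    """Each bin's C divided by the sample median C over bins."""
    med = float(bintrack["C"].median())
    if med == 0:
        raise ValueError(
            "median bin count is zero; exclude empty scaffolds before computing "
            "fold changes"
        )
    return bintrack["C"] / med
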