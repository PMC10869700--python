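"""Nicking-endonuclease validation metrics and bin-level statistics.

A nicking endonuclease with a known recognition motif (e.g. Nb.BsrDI,
cutting immediately 5' of CATTGC) provides ground truth for the whole
capture-and-call pipeline: precision is the fraction of break records whose
downstream sequence reads as the motif on their own strand, sensitivity the
fraction of genomic motif sites hit by at least one break at exactly the
expected signal coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import BreakRecord, GeneModel, Genome, PeakSet, reverse_complement

MotifSite = Tuple[str, int, str]  # chrom, signal position, strand


def find_motif_sites(genome: Genome, motif: str) -> List[MotifSite]:
    """All motif occurrences on both strands; the signal position is the
    first base of the motif read on its own strand (break 5' of the motif).

    Overlapping occurrences are all reported; order is (chrom, pos, strand).
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    rc = reverse_complement(motif)
    m = len(motif)
    sites: List[MotifSite] = []
    for chrom in genome:
        seq = genome[chrom]
        start = seq.find(motif)
        while start != -1:
            sites.append((chrom, start, "+"))
            start = seq.find(motif, start + 1)
        # a reverse-complement match at [i, i+m) reads as the motif on "-",
        # whose first base sits at the rightmost reference coordinate
        start = seq.find(rc)
        while start != -1:
            sites.append((chrom, start + m - 1, "-"))
            start = seq.find(rc, start + 1)
    sites.sort()
    return sites


@dataclass
class ValidationResult:
    """Precision/sensitivity of break calling against a known nickase."""

    n_breaks: int = 0
    n_matching: int = 0
    precision: Optional[float] = None
    n_sites: int = 0
    n_detected: int = 0
    sensitivity: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "n_breaks": self.n_breaks,
            "n_matching": self.n_matching,
            "precision": self.precision,
            "n_sites": self.n_sites,
            "n_detected": self.n_detected,
            "sensitivity": self.sensitivity,
        }


def break_matches_motif(brk: BreakRecord, genome: Genome, motif: str) -> bool:
    """True iff the |motif| bases starting at the signal nucleotide, read on
    the break's strand, equal the motif. Windows running off the chromosome
    count as non-matching."""
    m = len(motif)
    seq = genome[brk.chrom]
    if brk.strand == "+":
        if brk.pos + m > len(seq):
            return False
        return seq[brk.pos : brk.pos + m] == motif
    if brk.pos - m + 1 < 0:
        return False
    return reverse_complement(seq[brk.pos - m + 1 : brk.pos + 1]) == motif


def motif_precision(
    breaks: Sequence[BreakRecord], genome: Genome, motif: str
) -> ValidationResult:
    """Fraction of break records (multiplicity counted) whose context reads
    as the motif. An empty break set leaves precision undefined (None)."""
    motif = motif.upper()
    result = ValidationResult(n_breaks=len(breaks))
    if not breaks:
        return result
    result.n_matching = sum(break_matches_motif(b, genome, motif) for b in breaks)
    result.precision = result.n_matching / result.n_breaks
    return result


def motif_sensitivity(
    breaks: Iterable[BreakRecord],
    sites: Sequence[MotifSite],
    slop: int = 0,
    result: Optional[ValidationResult] = None,
) -> ValidationResult:
    """Fraction of motif sites with >= 1 break at exactly the expected
    (chrom, pos, strand); ``slop`` relaxes the coordinate match by +-slop
    bases for exploratory use (default 0: exact)."""
    if not sites:
        raise ValueError("no motif sites")
    result = result or ValidationResult()
    observed = {(b.chrom, b.pos, b.strand) for b in breaks}
    if slop == 0:
        detected = sum(1 for s in sites if s in observed)
    else:
        detected = sum(
            1
            for c, p, st in sites
            if any((c, p + d, st) in observed for d in range(-slop, slop + 1))
        )
    result.n_sites = len(sites)
    result.n_detected = detected
    result.sensitivity = detected / len(sites)
    return result


def validate_nickase(
    breaks: Sequence[BreakRecord], genome: Genome, motif: str
) -> ValidationResult:
    """Precision and sensitivity of a break set against a nickase motif."""
    result = motif_precision(breaks, genome, motif)
    sites = find_motif_sites(genome, motif)
    return motif_sensitivity(breaks, sites, result=result)


# ---------------------------------------------------------------------------
# Treated-vs-control bin statistics


@dataclass
class MannWhitneyResult:
    p_value: float
    statistic: float
    degenerate: bool = False


def mannwhitney_treated_vs_control(
    treated: Sequence[float], control: Sequence[float]
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U test of the alternative that the treated
    per-bin distribution is stochastically greater than the control.

    Small tie-free samples use the exact U distribution; otherwise the
    normal approximation with tie correction. All-identical input in both
    groups is degenerate: p = 1 with a flag.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 1 or len(control) < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([treated, control])
    if np.ptp(pooled) == 0:
        u = len(treated) * len(control) / 2.0
        return MannWhitneyResult(p_value=1.0, statistic=u, degenerate=True)
    res = stats.mannwhitneyu(treated, control, alternative="greater", method="auto")
    return MannWhitneyResult(p_value=float(res.pvalue), statistic=float(res.statistic))


# ---------------------------------------------------------------------------
# Correlation with external feature tracks


def peak_abundance_per_bin(bintrack: pd.DataFrame, peaks: PeakSet) -> np.ndarray:
    """Number of peak intervals overlapping each bin of a merged-strand bin
    track (count mode; a peak spanning several bins counts in each)."""
    values = np.zeros(len(bintrack), dtype=float)
    lookup = {}
    for i, row in enumerate(bintrack.itertuples(index=False)):
        lookup.setdefault(row.chrom, []).append((row.start, row.end, i))
    for p in peaks:
        for start, end, i in lookup.get(p.chrom, ()):
            if p.start < end and p.end > start:
                values[i] += 1
    return values


def expression_per_bin(
    bintrack: pd.DataFrame, genes: Sequence[GeneModel]
) -> np.ndarray:
    """Summed TPM of genes whose TSS falls inside each bin."""
    values = np.zeros(len(bintrack), dtype=float)
    # simple interval scan; bin tracks are small (1e4-1e5 rows)
    rows = list(bintrack.itertuples(index=False))
    by_chrom = {}
    for i, row in enumerate(rows):
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end, i))
    for g in genes:
        tpm = g.expression_tpm or 0.0
        for start, end, i in by_chrom.get(g.chrom, ()):
            if start <= g.tss < end:
                values[i] += tpm
                break
    return values


def feature_correlation(bintrack: pd.DataFrame, feature) -> float:
    """Spearman rho between per-bin normalized break counts and a feature
    track (a ``PeakSet`` -> overlapping-peak counts, a ``GeneModel``
    sequence -> summed TPM of TSSs per bin, or a precomputed per-bin
    vector). Zero-variance features yield NaN with a flag via warning."""
    if isinstance(feature, PeakSet):
        values = peak_abundance_per_bin(bintrack, feature)
    elif isinstance(feature, (list, tuple)) and feature and isinstance(
        feature[0], GeneModel
    ):
        values = expression_per_bin(bintrack, feature)
    else:
        values = np.asarray(feature, dtype=float)
        if len(values) != len(bintrack):
            raise ValueError("feature vector length does not match the bin grid")
    c = bintrack["C"].to_numpy(dtype=float)
    if np.ptp(values) == 0 or np.ptp(c) == 0:
        import warnings

        warnings.warn("constant input: feature correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(c, values)
    return float(rho)
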