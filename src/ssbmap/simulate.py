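"""Synthetic genomes, gene sets, planted break landscapes and UMI-tagged reads.

The generator emulates the statistical structure the downstream analysis
assumes: expression-proportional break rates on transcribed strands with an
exponential decay downstream of the TSS, a weaker divergent branch on the
non-transcribed strand upstream of the TSS, a promoter dead zone devoid of
induced breaks, a uniform endogenous background on both strands, a guanine
preference one base downstream of the incision, and PCR duplication of
UMI-tagged reads. Every draw is derived from ``SimulationConfig.seed`` so
outputs are byte-for-byte reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import AlignedRead, BreakRecord, GeneModel, Genome

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# distinct RNG streams per stage so stages stay independently reproducible
_STREAM_GENOME = 0
_STREAM_GENES = 1
_STREAM_PLANT = 2
_STREAM_READS = 3
_STREAM_NICKASE = 4


def g_plus2_weight_for_fraction(g_fraction: float, target: float) -> float:
    """Multiplicative G-context weight giving an expected planted G fraction
    ``target`` at offset +1 on an i.i.d. genome with per-strand G content
    ``g_fraction``."""
    if not 0 < g_fraction < 1 or not 0 < target < 1:
        raise ValueError("fractions must be in (0, 1)")
    return target * (1 - g_fraction) / ((1 - target) * g_fraction)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated experiment.

    Rates are breaks per kilobase per strand; lengths are bases. The
    transcribed-strand intensity of a gene with expression ``tpm`` is
    ``breaks_per_kb_at_reference_tpm * tpm / reference_tpm`` at the TSS,
    decaying as ``exp(-d / tss_decay_length)`` with downstream distance d.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    gc_fraction: float = 0.41
    n_genes: int = 100
    gene_length_bounds: Tuple[int, int] = (5_000, 100_000)
    unexpressed_fraction: float = 0.2
    tpm_lognormal: Tuple[float, float] = (2.0, 1.5)  # (mu, sigma) of log TPM
    breaks_per_kb_at_reference_tpm: float = 2.0
    reference_tpm: float = 10.0
    tss_decay_length: float = 1_500.0
    divergent_ratio: float = 0.5
    divergent_extent: int = 5_000
    promoter_dead_zone: int = 100
    background_rate: float = 0.2
    g_plus2_weight: float = 5.817  # planted G fraction 0.60 at default GC
    read_length: int = 100
    mean_fragment: int = 300
    duplication_rate: float = 0.3
    umi_length: int = 10

    def __post_init__(self):
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if not 0 <= self.unexpressed_fraction <= 1:
            raise ValueError("unexpressed_fraction must be in [0, 1]")
        if not 0 <= self.divergent_ratio <= 1:
            raise ValueError("divergent_ratio must be in [0, 1]")
        if self.g_plus2_weight < 1:
            raise ValueError("g_plus2_weight must be >= 1")
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0, 1)")
        for name in ("breaks_per_kb_at_reference_tpm", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Planted breaks with provenance labels and per-gene expectations."""

    breaks: List[BreakRecord]
    labels: List[str]  # parallel: transcribed / divergent / background / nickase
    gene_expectations: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.breaks)

    def subset(self, label: str) -> List[BreakRecord]:
        return [b for b, l in zip(self.breaks, self.labels) if l == label]


# ---------------------------------------------------------------------------
# Genome and genes


def simulate_genome_and_genes(
    config: SimulationConfig,
) -> Tuple[Genome, List[GeneModel]]:
    """One i.i.d.-base chromosome with non-overlapping genes spaced by at
    least ``2 * divergent_extent`` and random strands; an exact
    ``unexpressed_fraction`` of genes gets TPM 0, the rest log-normal TPM."""
    rng = config.rng(_STREAM_GENOME)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=config.genome_length, p=p)
    sequence = _BASES[idx].tobytes().decode()
    genome = Genome({"chr1": sequence})

    rng = config.rng(_STREAM_GENES)
    lo, hi = config.gene_length_bounds
    lengths = np.exp(
        rng.uniform(math.log(lo), math.log(hi), size=config.n_genes)
    ).astype(int)
    spacing = 2 * config.divergent_extent
    needed = int(lengths.sum()) + (config.n_genes + 1) * spacing
    if needed > config.genome_length:
        raise ValueError(
            f"cannot pack {config.n_genes} genes into {config.genome_length} bases; "
            f"need >= {needed} (increase genome_length)"
        )
    slack = config.genome_length - needed
    extra = rng.multinomial(slack, np.full(config.n_genes + 1, 1 / (config.n_genes + 1)))
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    n_off = int(round(config.unexpressed_fraction * config.n_genes))
    off = set(rng.choice(config.n_genes, size=n_off, replace=False).tolist())
    mu, sigma = config.tpm_lognormal
    tpms = rng.lognormal(mu, sigma, size=config.n_genes)
    if off:
        tpms[list(off)] = 0.0

    genes: List[GeneModel] = []
    cursor = 0
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        cursor += spacing + int(extra[i])
        start = cursor
        end = start + int(lengths[i])
        cursor = end
        genes.append(
            GeneModel(
                gene_id=f"gene{i:0{width}d}",
                chrom="chr1",
                start=start,
                end=end,
                annotation_strand=str(strands[i]),
                coding=True,
                expression_tpm=float(tpms[i]),
            )
        )
    return genome, genes


# ---------------------------------------------------------------------------
# Break planting


def _seq_array(genome: Genome, chrom: str) -> np.ndarray:
    return np.frombuffer(genome[chrom].encode(), dtype="S1")


def _context_is_g(seq: np.ndarray, pos: np.ndarray, strand_plus: bool) -> np.ndarray:
    """True where the base at offset +1 downstream of the signal nucleotide
    is G (strand-aware; off-chromosome contexts count as non-G)."""
    n = len(seq)
    if strand_plus:
        ctx = pos + 1
        ok = ctx < n
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = seq[ctx[ok]] == b"G"
    else:
        ctx = pos - 1
        ok = ctx >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = seq[ctx[ok]] == b"C"  # G on "-" == C on the reference
    return out


def _draw_with_g_preference(
    n: int,
    draw: Callable[[int, np.random.Generator], np.ndarray],
    seq: np.ndarray,
    strand_plus: bool,
    weight: float,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> np.ndarray:
    """Rejection-sample ``n`` positions from ``draw`` so that G-context sites
    carry weight ``weight`` relative to 1 (count preserved)."""
    out = np.empty(n, dtype=np.int64)
    need = n
    filled = 0
    for _ in range(max_rounds):
        if need == 0:
            break
        cand = draw(need, rng)
        valid = (cand >= 0) & (cand < len(seq))
        cand = cand[valid]
        if weight > 1 and len(cand):
            is_g = _context_is_g(seq, cand, strand_plus)
            accept = is_g | (rng.random(len(cand)) < 1.0 / weight)
            cand = cand[accept]
        k = len(cand)
        out[filled : filled + k] = cand
        filled += k
        need -= k
    if need:
        raise RuntimeError("rejection sampling failed to converge")
    return out


def plant_breaks(
    genome: Genome, genes: Sequence[GeneModel], config: SimulationConfig
) -> TruthSet:
    """Draw an inhomogeneous-Poisson break landscape.

    Per gene: transcribed-strand intensity proportional to TPM with
    exponential decay downstream of the TSS over the gene body; a divergent
    branch on the non-transcribed strand upstream of the TSS (scaled by
    ``divergent_ratio``, same decay, zero inside the promoter dead zone,
    truncated at ``divergent_extent``). Plus uniform background on both
    strands genome-wide. G-context preference applies to every branch.
    """
    rng = config.rng(_STREAM_PLANT)
    w = config.g_plus2_weight
    decay = config.tss_decay_length
    dz, ext = config.promoter_dead_zone, config.divergent_extent

    chrom_seqs = {c: _seq_array(genome, c) for c in genome}
    breaks: List[BreakRecord] = []
    labels: List[str] = []
    expect_rows = []

    for gene in genes:
        seq = chrom_seqs[gene.chrom]
        tpm = gene.expression_tpm or 0.0
        rate_per_base = (
            config.breaks_per_kb_at_reference_tpm / 1000.0 * tpm / config.reference_tpm
        )
        L = gene.length
        plus = gene.annotation_strand == "+"
        tss = gene.tss
        ts_strand = "-" if plus else "+"  # transcribed (template) strand
        body_mass = 1.0 - math.exp(-L / decay)
        lam_ts = rate_per_base * decay * body_mass
        div_mass = math.exp(-dz / decay) - math.exp(-ext / decay)
        lam_div = config.divergent_ratio * rate_per_base * decay * div_mass

        n_ts = int(rng.poisson(lam_ts))
        if n_ts:

            def draw_body(k, r, _m=body_mass):
                d = (-decay * np.log(1.0 - r.random(k) * _m)).astype(np.int64)
                return tss + d if plus else tss - d

            pos = _draw_with_g_preference(
                n_ts, draw_body, seq, ts_strand == "+", w, rng
            )
            for p in pos:
                breaks.append(BreakRecord(gene.chrom, int(p), ts_strand))
                labels.append("transcribed")

        n_div = int(rng.poisson(lam_div))
        if n_div:
            e_dz, e_ext = math.exp(-dz / decay), math.exp(-ext / decay)

            def draw_div(k, r):
                u = (-decay * np.log(e_dz - r.random(k) * (e_dz - e_ext))).astype(
                    np.int64
                )
                return tss - 1 - u if plus else tss + 1 + u

            pos = _draw_with_g_preference(
                n_div, draw_div, seq, gene.annotation_strand == "+", w, rng
            )
            for p in pos:
                breaks.append(BreakRecord(gene.chrom, int(p), gene.annotation_strand))
                labels.append("divergent")

        expect_rows.append(
            {
                "gene_id": gene.gene_id,
                "tpm": tpm,
                "length_kb": gene.length_kb,
                "expected_transcribed": lam_ts,
                "expected_divergent": lam_div,
                "expected_background_per_strand": config.background_rate
                * gene.length_kb,
            }
        )

    for chrom in genome:
        seq = chrom_seqs[chrom]
        lam_bg = config.background_rate * len(seq) / 1000.0
        for strand in ("+", "-"):
            n_bg = int(rng.poisson(lam_bg))
            if not n_bg:
                continue

            def draw_bg(k, r, _n=len(seq)):
                return r.integers(0, _n, size=k)

            pos = _draw_with_g_preference(n_bg, draw_bg, seq, strand == "+", w, rng)
            for p in pos:
                breaks.append(BreakRecord(chrom, int(p), strand))
                labels.append("background")

    return TruthSet(
        breaks=breaks, labels=labels, gene_expectations=pd.DataFrame(expect_rows)
    )


def calibrate_rate_for_fold(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    fold: float,
    top_tier: str = "<=100%",
) -> float:
    """Value of ``breaks_per_kb_at_reference_tpm`` for which the expected
    normalized break count of the top expression tier is ``fold`` times the
    unexpressed reference (whose expectation is 1 by construction).

    Solves ``1 + rate * mean_top{(tpm/ref)(decay/L)(1 - e^{-L/decay})} / bg
    == fold`` for ``rate``, using the same tiering rule as quantification.
    """
    from .quantify import assign_tiers

    if fold <= 1:
        raise ValueError("fold must exceed 1")
    tiers = assign_tiers(genes)
    decay = config.tss_decay_length
    factors = [
        (g.expression_tpm / config.reference_tpm)
        * (decay / g.length)
        * (1.0 - math.exp(-g.length / decay))
        for g in genes
        if tiers[g.gene_id] == top_tier
    ]
    if not factors:
        raise ValueError(f"no genes in tier {top_tier!r}")
    return (fold - 1.0) * config.background_rate / float(np.mean(factors))


# ---------------------------------------------------------------------------
# Reads


def breaks_to_reads(
    truth: TruthSet, genome: Genome, config: SimulationConfig
) -> Tuple[List[AlignedRead], int]:
    """Inverse of break calling: one primary UMI-tagged read per planted
    break, plus PCR duplicates sharing coordinates and UMI with probability
    ``duplication_rate``. Breaks whose read cannot fit >= 20 bases on the
    chromosome are skipped and counted (second return value).
    """
    rng = config.rng(_STREAM_READS)
    n = len(truth.breaks)
    fragments = np.maximum(
        20, np.rint(rng.normal(config.mean_fragment, config.mean_fragment / 4, n))
    ).astype(int)
    umi_idx = rng.integers(0, 4, size=(n, config.umi_length))
    dup = rng.random(n) < config.duplication_rate

    reads: List[AlignedRead] = []
    n_skipped = 0
    for i, brk in enumerate(truth.breaks):
        chrom_len = genome.length(brk.chrom)
        umi = _BASES[umi_idx[i]].tobytes().decode()
        if brk.strand == "+":
            # captured fragment extends leftward; read maps "-" ending at pos
            length = min(config.read_length, int(fragments[i]), brk.pos)
            start, end, strand = brk.pos - length, brk.pos, "-"
        else:
            length = min(config.read_length, int(fragments[i]), chrom_len - brk.pos - 1)
            start, end, strand = brk.pos + 1, brk.pos + 1 + length, "+"
        if length < 20:
            n_skipped += 1
            continue
        read = AlignedRead(
            chrom=brk.chrom,
            start=start,
            end=end,
            mapping_strand=strand,
            umi=umi,
            mapq=60,
            name=f"sim{i}_{umi}",
        )
        reads.append(read)
        if dup[i]:
            reads.append(read)
    return reads, n_skipped


# ---------------------------------------------------------------------------
# Nickase control


def simulate_nickase(
    genome: Genome,
    motif: str,
    efficiency: float,
    background_rate: float,
    config: SimulationConfig,
) -> TruthSet:
    """Plant breaks at every motif occurrence (both strands) independently
    with probability ``efficiency``, plus uniform background breaks.

    The signal nucleotide is the first base of the motif read on its own
    strand, so the break sits immediately 5' of the motif.
    """
    from .validation import find_motif_sites

    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    rng = config.rng(_STREAM_NICKASE)
    sites = find_motif_sites(genome, motif)
    keep = rng.random(len(sites)) < efficiency
    breaks: List[BreakRecord] = [
        BreakRecord(c, p, s) for (c, p, s), k in zip(sites, keep) if k
    ]
    labels = ["nickase"] * len(breaks)
    for chrom in genome:
        lam = background_rate * genome.length(chrom) / 1000.0
        for strand in ("+", "-"):
            n_bg = int(rng.poisson(lam))
            pos = rng.integers(0, genome.length(chrom), size=n_bg)
            for p in pos:
                breaks.append(BreakRecord(chrom, int(p), strand))
                labels.append("background")
    return TruthSet(breaks=breaks, labels=labels)
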