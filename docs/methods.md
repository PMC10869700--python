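# Methods

## Break positioning and deduplication

A 3'-OH capture read is the reverse complement of the captured fragment, so
the free 3'-OH — the nick — sits immediately 5' of the read's mapped 5' end
on the opposite genomic strand. `call_break` therefore places the signal of
a "+"-mapped read `[start, end)` at `start - 1` on "-", and of a "-"-mapped
read at `end` on "+". The recorded coordinate is the *signal nucleotide*,
the first base 3' of the nick on the broken strand; all downstream modules
(context matrices, motif validation) share this convention, and the
simulator's `breaks_to_reads` is its exact inverse, which the round-trip
tests exploit as a bidirectional oracle.

PCR deduplication keys on (chromosome, mapping strand, mapped 5'-end
coordinate, exact UMI). The 5' end rather than the full interval defines
the molecule because sonication randomizes the 3' end while ligation fixes
the 5' end. Exact UMI matching only — no edit-distance clustering; with
4^10 random UMIs, coincidental collisions between distinct molecules at the
same coordinate are negligible (expected well below one per 10^5 reads at
typical per-position multiplicities) and are logged, not corrected. Among
duplicates the highest-MAPQ read survives, ties broken by input order; the
choice affects only the recorded MAPQ, never the break coordinate, and is
fixed for determinism. Reads are treated as ungapped intervals; the SAM
reader rejects split or clipped alignments with a counter. No MAPQ filter
is applied by default (`min_mapq=0`); the threshold is exposed because the
TSV schema retains MAPQ for downstream filtering.

## Normalization

Sequencing depth varies across samples, so counts are scaled by a
per-sample factor estimated from a class of features expected to carry only
endogenous background: the transcribed strands of unexpressed genes.
`M(s)` is the arithmetic mean of `N/L_kb` over that class and
`C = N / (L_kb * M)`, which makes the reference-class mean exactly 1 (an
identity the tests assert to machine precision) and makes every `C`
invariant under uniform depth scaling. "Unexpressed" means TPM exactly 0 by
default (`tpm_zero_threshold` configurable); no gene-length floor is
applied to the reference class. `M` is always computed from the sample's
own counts, never shared. If the reference class is empty or has zero
counts, normalization fails loudly rather than silently producing
divisions by zero.

## Expression tiers

Expressed genes are ranked by TPM and cut at the 25/50/70/80/90/95/100
percentiles computed on *average ranks*, so tied TPM values share a
percentile and can never straddle a tier boundary (this also reproduces the
slightly unequal tier sizes seen with real expression tables, where ties
are common at low TPM). Box summaries report mean, median, quartiles and
whiskers at the furthest datapoint within 1.5x IQR.

## Profiles

Gene-anchored coordinates place the TSS at 0 with the gene pointing
rightward; a break is `transcribed`-class if it lies on the template strand
(opposite the annotation strand). Metagene profiles use absolute bins in
the flanks and relative bins (fraction `1/body_bins` of each gene's length)
in the body, per-gene densities `count / (bin_kb * M)`, and the across-gene
mean with a 95% CI of `mean ± 1.96 * SE` (normal approximation — adequate
for the gene-set sizes here, tens of genes and up; calibration is checked
empirically, see below). Genes whose windows leave the chromosome are
excluded and counted rather than zero-padded, which would bias edge bins
downward. Relative-bin boundaries are real-valued `k * L / body_bins`; a
break on a boundary belongs to the higher bin (half-open, matching the
genomic convention everywhere else). TSS-centered profiles stratify genes
into length groups (<=10, <=22, <=50, >50 kb, boundaries inclusive) with
the window anchored at the TSS and deliberately *not* clipped at the TES.

Divergent-transcription flanks are the 5 kb downstream of the TSS on the
transcribed strand and 5 kb upstream on the non-transcribed strand, both
normalized with L = 5 kb. The endogenous-background threshold is the upper
quartile (linear interpolation) of the upstream flank count among
unexpressed genes.

## Sequence context

Offset 0 of a context matrix is the signal nucleotide; the break lies
between offsets -1 and 0. A logo's "position 1" is offset +1 here, i.e.
the second base downstream of the break. For "-" breaks offsets map to
`pos - offset` with complemented bases. Windows leaving the chromosome are
excluded and counted; fractions are over non-N bases. Information content
per offset is `2 - H` bits with Shannon entropy `H` over the A/C/G/T
fractions. Context selection for incision-preference analysis keeps breaks
on gene-body transcribed strands and on non-transcribed strands within
5 kb upstream of the TSS, counting every break record (multiplicity =
abundance) rather than one per position — positions hit by many molecules
are evidence, not artifacts, after UMI deduplication.

## Nickase validation

A site of a nicking-endonuclease motif is the first base of the motif read
on its own strand (for a reverse-complement match at `[i, i+m)` on the
reference, the site is `i+m-1` on "-"). Precision counts break records
(with multiplicity) whose downstream `m` bases read as the motif; records
whose window runs off the chromosome count as non-matching and are
reported. Sensitivity requires exact (chromosome, position, strand)
coincidence — the incision coordinate is deterministic under this
chemistry, so no tolerance window is justified; a `slop` parameter exists
for exploration only and defaults to 0. The Mann-Whitney treated-vs-control
comparison is one-sided (treated stochastically greater), using the exact U
distribution for small tie-free samples and the tie-corrected normal
approximation otherwise; all-identical input is flagged degenerate with
p = 1. Per-bin feature abundance for correlation tracks is the
overlapping-peak count (coverage mode behind a flag) or summed TPM of TSSs
in the bin.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, as
a multiplicative inhomogeneous-Poisson model — the minimal generative law
under which count data scale proportionally with intensity and
parameter-recovery tests are meaningful:

- transcribed-strand intensity per base:
  `(breaks_per_kb_at_reference_tpm / 1000) * (TPM / reference_tpm) *
  exp(-d / tss_decay_length)` for distance `d` downstream of the TSS over
  the gene body;
- a divergent branch on the non-transcribed strand upstream of the TSS:
  the same decay scaled by `divergent_ratio` (default 0.5 — divergent
  initiation about half as active as genic), truncated at
  `divergent_extent` (5 kb) and zero within the `promoter_dead_zone`
  (100 b);
- uniform background on both strands genome-wide (`background_rate`
  breaks/kb/strand);
- a guanine preference at offset +1 implemented by rejection resampling
  with weight `g_plus2_weight` for G-context positions (count-preserving);
  `g_plus2_weight_for_fraction` converts a target G fraction into the
  weight for a given genome composition.

Genes are packed non-overlapping with at least `2 * divergent_extent`
spacing on one i.i.d.-base chromosome; an exact `unexpressed_fraction` of
genes gets TPM 0 and the rest log-normal TPM (mu 2.0, sigma 1.5 — a
realistic heavy-tailed expression spread). Reads are 100 b, fragments
normal around 300 b (sd = mean/4, floored at 20 b), UMIs 10 nt uniform,
and PCR duplicates are appended per molecule with probability
`duplication_rate` (default 0.3). Defaults for GC (0.41) and the
unexpressed fraction (0.2) mirror human-genome composition and the
fraction of silent protein-coding genes in a transformed cell line.
`calibrate_rate_for_fold` solves analytically for the damage rate that
makes the expected top-tier mean `C` a chosen multiple of the unexpressed
reference, so contrast-recovery tests compare against a planted value
rather than a measured one. Every draw derives from `seed` via independent
named streams; outputs are byte-identical under a fixed seed.

What the generator does **not** model — and hence what passing tests do not
show about real data: sequencing errors and base qualities, mappability and
alignment artifacts, chromatin-state-dependent background, read-through
transcription past the TES, antisense gene bodies, UMI errors, and any
non-Poisson overdispersion of damage across cells. Recovery results bound
algorithmic correctness, not biological effect sizes.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen for statistical
power: 10^4 breaks for round-trip and context recovery, ~1.5-Mb genomes
(~650 motif sites) for nickase metrics, 1,000 genes at deep coverage
(background 8 breaks/kb) for fold and correlation recovery, 300 genes for
profile geometry, and 200 background-only simulations of 40 flat genes for
CI calibration against the known flat truth. The CI coverage check feeds
the *true* density as the normalization constant so that it isolates the
interval machinery from normalization noise. The information-content check
for "no preference elsewhere" uses a 50% GC genome, since at skewed
composition the base frequencies themselves carry ~0.026 bits at every
offset and would mask the planted-signal contrast.

## Known limitations

- Overlapping genes double-count shared breaks by design (no exclusivity),
  matching whole-gene summation; callers needing exclusive assignment must
  pre-filter annotations.
- The normal-approximation CI undercovers slightly for very small gene
  sets (|G| < ~20) with near-empty bins; a bootstrap alternative is the
  obvious extension.
- `select_breaks_in_regions` is a quadratic scan, adequate for the region
  sizes used here but not for whole-genome annotations with millions of
  breaks.
- The simulator plants no signal beyond the TES, so the elevated
  post-TES signal seen in real data has no recovery test.
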