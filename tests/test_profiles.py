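import math

import numpy as np
import pandas as pd
import pytest

from ssbmap import (
    GeneModel,
    Genome,
    background_threshold,
    context_matrix,
    flank_counts,
    gc_profile,
    logo_summary,
    metagene_profile,
    select_breaks_in_regions,
    to_gene_coordinates,
    tss_profile_by_length,
)
from ssbmap.profiles import gene_length_group
from ssbmap.records import BreakRecord, reverse_complement


def mk_gene(gene_id, start, end, strand="+", tpm=1.0, chrom="chr1"):
    return GeneModel(gene_id, chrom, start, end, strand, True, tpm)


class TestGeneCoordinates:
    def test_minus_gene_flip(self):
        gene = mk_gene("g", 100, 300, "-")  # TSS = 299
        offset, sc = to_gene_coordinates(BreakRecord("chr1", 199, "+"), gene)
        assert offset == 100
        assert sc == "transcribed"  # "+" is the template of a "-" gene

    def test_break_at_tss(self):
        gene = mk_gene("g", 100, 300, "+")
        offset, _ = to_gene_coordinates(BreakRecord("chr1", 100, "-"), gene)
        assert offset == 0

    def test_reflection_symmetry(self):
        """Mirrored breaks around mirrored genes give identical offsets and
        strand classes."""
        n = 1000
        fwd = mk_gene("f", 100, 300, "+")
        rev = mk_gene("r", n - 300, n - 100, "-")
        rng = np.random.default_rng(0)
        for _ in range(50):
            pos = int(rng.integers(0, n))
            strand = "+" if rng.random() < 0.5 else "-"
            mirrored_pos = n - 1 - pos
            mirrored_strand = "-" if strand == "+" else "+"
            a = to_gene_coordinates(BreakRecord("chr1", pos, strand), fwd)
            b = to_gene_coordinates(
                BreakRecord("chr1", mirrored_pos, mirrored_strand), rev
            )
            assert a == b


class TestMetagene:
    def _uniform_world(self, rng, n_genes=30, gene_len=4000, density_per_kb=10.0):
        spacing = 12_000
        genes = []
        breaks = []
        cursor = spacing
        for i in range(n_genes):
            start, end = cursor, cursor + gene_len
            cursor = end + spacing
            strand = "+" if i % 2 == 0 else "-"
            genes.append(mk_gene(f"g{i}", start, end, strand))
            lo, hi = start - 6000, end + 6000
            for s in "+-":
                n = rng.poisson(density_per_kb * (hi - lo) / 1000)
                for p in rng.integers(lo, hi, size=n):
                    breaks.append(BreakRecord("chr1", int(p), s))
        genome = Genome({"chr1": "A" * (cursor + spacing)})
        return genome, genes, breaks

    def test_flat_profile_on_uniform_breaks(self, rng):
        genome, genes, breaks = self._uniform_world(rng)
        profile = metagene_profile(breaks, genes, genome, m=10.0)
        # density 10/kb, M=10 -> every bin mean should be ~1
        assert profile["mean"].between(0.7, 1.3).all()
        within = (profile["ci_low"] <= 1.0) & (1.0 <= profile["ci_high"])
        assert within.mean() > 0.85

    def test_conservation_of_counts(self, rng):
        genome, genes, breaks = self._uniform_world(rng, n_genes=5)
        gene = genes[0]
        upstream, downstream = 5000, 5000
        profile = metagene_profile(
            [b for b in breaks], [gene], genome, m=1.0,
            upstream=upstream, downstream=downstream,
        )
        # reconstruct raw counts from densities and compare to a direct scan
        raw = 0.0
        for row in profile.itertuples(index=False):
            bin_kb = (
                250 / 1000.0 if row.region in ("upstream", "downstream")
                else gene.length / 20 / 1000.0
            )
            raw += row.mean * bin_kb
        if gene.annotation_strand == "+":
            lo, hi = gene.tss - upstream, gene.tes + 1 + downstream
        else:
            lo, hi = gene.tes - downstream, gene.tss + 1 + upstream
        direct = sum(1 for b in breaks if lo <= b.pos < hi)
        assert raw == pytest.approx(direct, rel=1e-9)

    def test_gene_near_edge_excluded(self, rng):
        genome = Genome({"chr1": "A" * 20_000})
        edge_gene = mk_gene("edge", 1000, 3000, "+")  # upstream flank cut
        ok_gene = mk_gene("ok", 8000, 12_000, "+")
        profile = metagene_profile([], [edge_gene, ok_gene], genome, m=1.0)
        assert profile["n_genes"].unique().tolist() == [1]

    def test_empty_gene_set_raises(self):
        genome = Genome({"chr1": "A" * 1000})
        with pytest.raises(ValueError):
            metagene_profile([], [], genome, m=1.0)


class TestTssProfile:
    def test_length_group_boundaries_inclusive(self):
        assert gene_length_group(mk_gene("g", 0, 22_000)) == "<=22kb"
        assert gene_length_group(mk_gene("g", 0, 22_001)) == "<=50kb"
        assert gene_length_group(mk_gene("g", 0, 9_000)) == "<=10kb"
        assert gene_length_group(mk_gene("g", 0, 50_001)) == ">50kb"

    def test_window_not_clipped_at_tes(self, rng):
        """A short gene's TSS window extends past its TES and still counts."""
        genome = Genome({"chr1": "A" * 40_000})
        gene = mk_gene("g", 20_000, 21_000, "+")  # 1 kb gene, window +-5 kb
        past_tes = BreakRecord("chr1", 23_000, "-")  # 3 kb after TSS, past TES
        profiles = tss_profile_by_length([past_tes], [gene], genome, m=1.0)
        prof = profiles["<=10kb"]
        hit = prof[(prof.strand_class == "transcribed") & (prof["mean"] > 0)]
        assert len(hit) == 1
        assert hit["bin_center"].iloc[0] == pytest.approx(3050)


class TestGcProfile:
    def test_iid_genome_flat_quarter(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200_000))
        genome = Genome({"chr1": seq})
        genes = [
            mk_gene(f"g{i}", 20_000 * (i + 1), 20_000 * (i + 1) + 5000,
                    "+" if i % 2 else "-")
            for i in range(8)
        ]
        prof = gc_profile(genes, genome, window=5000, bin_size=500)
        n_per_bin = 8 * 500
        sd = math.sqrt(0.25 * 0.75 / n_per_bin)
        assert (prof["g_fraction"] - 0.25).abs().max() < 4 * sd

    def test_complementarity_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 40_000))
        genome = Genome({"chr1": seq})
        gene = mk_gene("g", 20_000, 25_000, "+")
        prof = gc_profile([gene], genome, window=2000, bin_size=100)
        ts = prof[prof.strand_class == "transcribed"].set_index("bin")["g_fraction"]
        nts = prof[prof.strand_class == "non_transcribed"]
        # per-position: G on one strand is C on the other; verify totals per bin
        for row in nts.itertuples(index=False):
            window = seq[20_000 - 2000 + row.bin * 100 :
                         20_000 - 2000 + (row.bin + 1) * 100]
            assert row.g_fraction == pytest.approx(window.count("G") / 100)
            assert ts[row.bin] == pytest.approx(window.count("C") / 100)


class TestFlanks:
    def test_truncated_flank_excluded(self):
        genome = Genome({"chr1": "A" * 30_000})
        near_start = mk_gene("a", 2000, 8000, "+")  # upstream flank below 0
        fine = mk_gene("b", 10_000, 20_000, "+")
        df, n_excluded = flank_counts([], [near_start, fine], m=1.0, genome=genome)
        assert n_excluded == 1
        assert df["gene_id"].tolist() == ["b"]

    def test_flank_windows_strand_aware(self):
        genome = Genome({"chr1": "A" * 40_000})
        gene = mk_gene("g", 20_000, 30_000, "-")  # TSS at 29_999
        downstream_break = BreakRecord("chr1", 28_000, "+")  # template of "-"
        upstream_break = BreakRecord("chr1", 32_000, "-")
        df, _ = flank_counts(
            [downstream_break, upstream_break], [gene], m=1.0, genome=genome
        )
        row = df.iloc[0]
        assert row["downstream_ts_C"] == pytest.approx(1 / 5)
        assert row["upstream_nts_C"] == pytest.approx(1 / 5)

    def test_background_only_flanks_balanced(self, rng):
        genome = Genome({"chr1": "A" * 2_000_000})
        genes = [
            mk_gene(f"g{i}", 20_000 * (i + 1), 20_000 * (i + 1) + 8000,
                    "+" if i % 2 else "-", tpm=float(i))
            for i in range(80)
        ]
        breaks = [
            BreakRecord("chr1", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(0, 2_000_000, size=40_000)
        ]
        df, _ = flank_counts(breaks, genes, m=10.0, genome=genome)
        ratio = df["upstream_nts_C"].mean() / df["downstream_ts_C"].mean()
        assert 0.85 < ratio < 1.15


class TestBackgroundThreshold:
    def _flanks(self, values, tier):
        return (
            pd.DataFrame(
                {"gene_id": [f"g{i}" for i in range(len(values))],
                 "downstream_ts_C": 0.0,
                 "upstream_nts_C": values}
            ),
            {f"g{i}": tier for i in range(len(values))},
        )

    def test_upper_quartile_linear_interpolation(self):
        df, tiers = self._flanks([0.0, 1.0, 2.0, 3.0], "not_expressed")
        threshold, _ = background_threshold(df, tiers)
        assert threshold == pytest.approx(2.25)

    def test_all_equal_reference(self):
        df, tiers = self._flanks([2.0, 2.0, 2.0, 2.0], "not_expressed")
        threshold, fractions = background_threshold(df, tiers)
        assert threshold == 2.0
        assert fractions.set_index("tier")["fraction_below"]["not_expressed"] == 1.0

    def test_too_few_unexpressed_raises(self):
        df, tiers = self._flanks([1.0, 2.0], "not_expressed")
        with pytest.raises(ValueError):
            background_threshold(df, tiers)


class TestRegionSelection:
    def test_tags_and_boundaries(self):
        gene = mk_gene("g", 10_000, 20_000, "+")
        body_ts = BreakRecord("chr1", 15_000, "-")
        upstream_nts = BreakRecord("chr1", 10_000 - 4_999, "+")
        upstream_ts = BreakRecord("chr1", 8_000, "-")  # wrong strand upstream
        body_nts = BreakRecord("chr1", 15_000, "+")  # wrong strand in body
        tagged = select_breaks_in_regions(
            [body_ts, upstream_nts, upstream_ts, body_nts], [gene]
        )
        assert (body_ts, "body") in tagged
        assert (upstream_nts, "upstream") in tagged
        assert len(tagged) == 2


def brute_force_context(brk, genome, up, down):
    seq = genome[brk.chrom]
    bases = []
    for off in range(-up, down + 1):
        p = brk.pos + off if brk.strand == "+" else brk.pos - off
        if not 0 <= p < len(seq):
            return None
        base = seq[p]
        if brk.strand == "-":
            base = reverse_complement(base)
        bases.append(base)
    return "".join(bases)


class TestContextMatrix:
    def test_hand_extraction(self):
        genome = Genome({"chr1": "AAACATTGCAAA"})
        matrix = context_matrix([BreakRecord("chr1", 3, "+")], genome, up=2, down=6)
        extracted = "".join(
            matrix[(matrix.offset == off) & (matrix["count"] == 1)]["base"].iloc[0]
            for off in range(-2, 7)
        )
        assert extracted == "AACATTGCA"[:9]
        assert (
            matrix[(matrix.offset == 0) & (matrix.base == "C")]["count"].iloc[0] == 1
        )

    def test_minus_strand_is_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        genome = Genome({"chr1": seq})
        minus = context_matrix([BreakRecord("chr1", 50, "-")], genome, up=3, down=5)
        minus_ctx = brute_force_context(BreakRecord("chr1", 50, "-"), genome, 3, 5)
        # the same site read on "-" is the reverse complement of the
        # mirrored reference window
        assert minus_ctx == reverse_complement(seq[50 - 5 : 50 + 4])
        for off, base in zip(range(-3, 6), minus_ctx):
            assert (
                minus[(minus.offset == off) & (minus.base == base)]["count"].iloc[0]
                == 1
            )

    def test_matches_brute_force_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        genome = Genome({"chr1": seq})
        breaks = [
            BreakRecord("chr1", int(p), "+" if rng.random() < 0.5 else "-")
            for p in rng.integers(0, 5000, size=800)
        ]
        up, down = 4, 7
        matrix = context_matrix(breaks, genome, up=up, down=down)
        expected = {off: {b: 0 for b in "ACGT"} for off in range(-up, down + 1)}
        n_ok = 0
        for brk in breaks:
            ctx = brute_force_context(brk, genome, up, down)
            if ctx is None:
                continue
            n_ok += 1
            for off, base in zip(range(-up, down + 1), ctx):
                expected[off][base] += 1
        assert int(matrix["n_contexts"].iloc[0]) == n_ok
        for row in matrix.itertuples(index=False):
            assert row.count == expected[row.offset][row.base]

    def test_edge_windows_excluded_and_counted(self):
        genome = Genome({"chr1": "ACGTACGTAC"})
        matrix = context_matrix(
            [BreakRecord("chr1", 1, "+"), BreakRecord("chr1", 5, "+")],
            genome,
            up=2,
            down=2,
        )
        assert int(matrix["n_contexts"].iloc[0]) == 1


class TestLogoSummary:
    def _matrix(self, fractions, n=100):
        rows = []
        for off in (0, 1):
            for base, f in zip("ACGT", fractions):
                rows.append(
                    {"offset": off, "base": base, "count": int(f * n),
                     "fraction": f, "n_contexts": n}
                )
        return pd.DataFrame(rows)

    def test_uniform_is_zero_bits(self):
        info, _ = logo_summary(self._matrix([0.25] * 4))
        assert info["information_bits"].abs().max() < 1e-12

    def test_fixed_base_is_two_bits(self):
        info, _ = logo_summary(self._matrix([1.0, 0.0, 0.0, 0.0]))
        assert info["information_bits"].iloc[0] == pytest.approx(2.0)

    def test_entropy_by_hand(self):
        f = [0.1, 0.2, 0.3, 0.4]
        h = -sum(x * math.log2(x) for x in f)
        info, _ = logo_summary(self._matrix(f))
        assert info["information_bits"].iloc[0] == pytest.approx(2 - h)
        assert info["information_bits"].iloc[0] == pytest.approx(0.15363, abs=1e-4)

    def test_g_fraction_at_offset_plus_one(self):
        _, g = logo_summary(self._matrix([0.1, 0.2, 0.3, 0.4]))
        assert g == pytest.approx(0.3)
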