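"""Sequence context at incision sites.

Plants breaks with a guanine preference one base downstream of the signal
nucleotide (60% G at offset +1, i.e. position +2 relative to the break) and
recovers it from the context matrix. Offset 0 is the signal nucleotide —
the first base 3' of the nick on the broken strand.
"""

import ssbmap as sm

config = sm.SimulationConfig(
    seed=21, genome_length=1_200_000, n_genes=5, gene_length_bounds=(5_000, 10_000),
    unexpressed_fraction=1.0, background_rate=4.5, gc_fraction=0.5,
    g_plus2_weight=sm.g_plus2_weight_for_fraction(0.25, 0.60),
)
genome, genes = sm.simulate_genome_and_genes(config)
truth = sm.plant_breaks(genome, genes, config)

matrix = sm.context_matrix(truth.breaks, genome, up=5, down=10)
info, g_plus1 = sm.logo_summary(matrix)

print(f"{len(truth.breaks)} break contexts")
print(f"G fraction at offset +1 (position +2 relative to the break): {g_plus1:.3f}")
print("information content (bits) per offset:")
print(info.round(4).to_string(index=False))
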