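"""Build a relative-entropy structure logo from start-region windows.

Simulates 77-nt windows (40 nt upstream of the start codon + first 37 nt
of the ORF, codon removed) with SD consensus sites planted 3-7 nt
upstream in 60% of genes, then computes the per-position deviation from
the set's own base composition in bits.  Letter heights are signed:
positive (upright) for over-represented bases, negative (inverted) for
under-represented ones.
"""

from kevtools import (
    SimulationConfig,
    background_frequencies,
    logo_matrix,
    max_information_position,
    simulate_start_regions,
)

sim = SimulationConfig(n_genes=150, sd_plant_prob=0.6, seed=5)
windows, truth = simulate_start_regions(sim)
print(f"{len(windows)} windows, {int(truth['sd_planted'].sum())} with planted SD")

background = background_frequencies(windows)
print("background (A,C,G,T):", tuple(round(p, 3) for p in background.p))

columns = logo_matrix(windows, background)
top = max_information_position(columns)
print(f"max information: {top.information_bits:.2f} bit at position {top.position:+d}")

print("positions -14..-4 (information in bits, tallest letter):")
bases = "ACGT"
for c in columns:
    if -14 <= c.position <= -4:
        tallest = max(range(4), key=lambda i: abs(c.heights[i]))
        sign = "+" if c.heights[tallest] >= 0 else "-"
        print(f"  {c.position:+3d}  {c.information_bits:.3f}  {sign}{bases[tallest]}")
# The information peak falls inside the planted SD region (G/A positions
# of TAAGGAGG), just as a real gene set shows its ribosome-binding site.
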