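"""Estimate per-dinucleotide cleavage rates and the CpG methylation contrast.

Simulates a 100-kb genome with CpG islands and a bisulfite-style methylation
map, draws 200,000 break events under a model where methylated CpGs cleave
1.5x more readily than anything else, then estimates the 18-class cleavage
rate table from the break coordinates alone.
"""

from cleavescan import compute_cleavage_rates
from cleavescan.simulate import (
    FragmentationModel,
    SyntheticGenomeSpec,
    simulate_breaks,
    simulate_genome,
)

genome, islands, methylmap = simulate_genome(SyntheticGenomeSpec(seed=7))
model = FragmentationModel(n_reads=200_000, seed=8)  # CmG weight 1.5 by default
events = simulate_breaks(genome, model, methylmap)

table = compute_cleavage_rates(genome, events, methylmap)
print(table.table.round(4))
print(f"\nN = {table.N} events, window = {2 * table.half_width} bp")
ratio = table.rate("CmG") / table.rate("CuG")
print(f"r(CmG) / r(CuG) = {ratio:.3f}")
print(
    "\nEvery rate r(XY) is the break count at XY normalised by the local\n"
    "genomic abundance of XY; r(CmG)/r(CuG) near 1.5 recovers the simulated\n"
    "methylated-CpG cleavage preference from fragment positions alone."
)
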