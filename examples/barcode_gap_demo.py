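"""Barcode-gap analysis for one simulated genus.

Decomposes pairwise K2P distances among the genus' vouchers into intra- and
interspecific classes, decides whether a gap exists, and classifies two
hypothetical queries against the maximum-intraspecific threshold.
"""

from herbcode import SimulationConfig, classify_by_gap, detect_gap, split_distances
from herbcode.distances import distance_matrix
from herbcode.seqstore import build_aligned_set
from herbcode.simulate import simulate_reference_library

config = SimulationConfig(
    n_genera=1, species_per_genus=3, refs_per_species=5, n_offtarget_genera=0,
    p_authentic=1.0, p_congeneric_sub=0.0, p_intergeneric_sub=0.0,
    seq_length_per_marker={"matK": 500}, seed=9,
)
library = simulate_reference_library(config)
aligned = build_aligned_set(library.sequences["matK"])
dm = distance_matrix(aligned, model="K2P")
intra, inter = split_distances(dm, aligned.species)
gap = detect_gap("Genus01", "matK", intra, inter)

print(f"{len(intra)} intraspecific and {len(inter)} interspecific pairs")
print(f"max intraspecific divergence: {gap.max_intra:.5f}")
print(f"min interspecific divergence: {gap.min_inter:.5f}")
print(f"barcode gap exists: {gap.gap_exists}")
# With a gap, the max-intraspecific value is the species threshold: queries
# further than it from every conspecific voucher are substitutions.
for d in (0.001, 0.02):
    print(f"query at distance {d}: {classify_by_gap(d, gap)}")
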