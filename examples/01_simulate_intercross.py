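"""Simulate an F8 advanced intercross and inspect its genotypes.

Two founder lines fixed for alternative alleles (Red Junglefowl "R",
White Leghorn "W") are crossed and intercrossed for eight generations
under Haldane meiosis.  Repeated intercrossing erodes marker linkage
(map expansion) while drift moves allele frequencies away from 0.5.
"""

import numpy as np

from combqtl import SimConfig, simulate_ail_genotypes, simulate_map

cfg = SimConfig(seed=1)  # 5 chromosomes x 200 cM, 10 cM spacing, 300 birds
gmap = simulate_map(cfg)
geno = simulate_ail_genotypes(gmap, cfg)

freq_w = geno.codes.mean(axis=0) / 2.0
het = (geno.codes == 1).mean()
print(f"map: {gmap.n_markers} markers on {len(gmap.chromosomes)} chromosomes")
print(f"F{geno.generation} population: {geno.n_individuals} individuals, "
      f"{len(set(geno.family))} families")
print(f"heterozygosity {het:.3f} (F8 expectation ~0.5 with drift)")
print(f"W-allele frequency: mean {freq_w.mean():.3f}, "
      f"range [{freq_w.min():.3f}, {freq_w.max():.3f}]")
# Markers far from 0.5 reflect 7 generations of drift at the breeding
# population size; the founders start every marker at exactly 0.5.
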