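"""Sperm-to-soma DMR persistence on a reduced synthetic genome.

Calls DMRs in two tissues of the same simulated cohort, intersects them on
the shared 100-bp grid, tests the overlap against the hypergeometric
expectation, and classifies shared DMRs by sign concordance.
"""

import numpy as np

from epipersist import methyl, persistence
from epipersist.simulate import SimConfig, simulate_rrbs

config = SimConfig(seed=7)
config.chromosome_lengths = {"chr1": 1_000_000}

records, groups, tiling, truth = simulate_rrbs(config)
dmr_sets, tables = {}, {}
for tissue in ("sperm", "soma"):
    g = groups[tissue]
    tables[tissue] = methyl.aggregate_cpgs(records[tissue], tiling, g["ctrl"] + g["cko"])
    result = methyl.diff_methylation(tables[tissue], g["cko"], g["ctrl"])
    dmr_sets[tissue] = methyl.dmr_set(result)

universe = np.intersect1d(tables["sperm"].tile_ids, tables["soma"].tile_ids)
shared = persistence.intersect_dmrs(dmr_sets["sperm"], dmr_sets["soma"])
report = persistence.classify_persistence(
    shared,
    universe=universe.size,
    sperm_n=len(dmr_sets["sperm"]),
    soma_n=len(dmr_sets["soma"]),
)
print(report.to_text())
# The shared count exceeds the chance expectation by orders of magnitude,
# and nearly all shared DMRs are concordant-hypermethylated: the planted
# "persistent" fraction (80% of sperm DMR tiles carry the same shift in
# soma) dominates the intersection.
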