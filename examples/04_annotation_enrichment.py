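"""Test whether DMRs are enriched in an annotation class.

DMR locations are compared with width-matched random regions using a
two-sided Fisher exact test; a class is flagged when FDR < 0.05 and the
odds ratio exceeds 1.5.
"""

import numpy as np
import pandas as pd

from methylotype.enrichment import enrich_dmrs

rng = np.random.default_rng(0)
genome = {"chr1": 1_000_000}
islands = pd.DataFrame({
    "chrom": "chr1",
    "start": [i * 10_000 for i in range(100)],
    "end": [i * 10_000 + 1_000 for i in range(100)],
})
# place 600 "DMRs" with 2x odds of landing in an island (10% of the genome)
p_island = 2 * 0.1 / (2 * 0.1 + 0.9)
starts = [
    int(rng.integers(100) * 10_000 + rng.integers(0, 900))
    if rng.random() < p_island else int(rng.integers(0, 999_900))
    for _ in range(600)
]
dmrs = pd.DataFrame({"chrom": "chr1", "start": starts,
                     "end": [s + 100 for s in starts]})

table = enrich_dmrs(dmrs, {"cpg_island": islands}, genome, seed=1)
row = table.iloc[0]
print(f"DMRs in islands: {row['n_dmr_in']}/{row['n_dmr_in'] + row['n_dmr_out']}")
print(f"random in islands: {row['n_rand_in']}/{row['n_rand_in'] + row['n_rand_out']}")
print(f"odds ratio {row['odds_ratio']:.2f}, FDR {row['fdr']:.2g}, enriched: {row['enriched']}")
# An odds ratio near 2 with a small FDR reflects the planted 2x placement
# preference; random regions estimate the background occupancy.
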