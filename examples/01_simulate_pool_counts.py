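"""Simulate pooled resequencing counts for a small two-breed panel.

Builds two breed pools (20 diploids each, ~26x depth) diverged under
Balding-Nichols drift (F = 0.1), samples pooled reads at 1% error, and
prints what the raw count table looks like before any filtering.
"""

import numpy as np

from sweepscan import BreedModel, sample_pool_reads, simulate_frequencies

models = [BreedModel("lowland", 20, 0.1, 26.0), BreedModel("highland", 20, 0.1, 26.0)]
sim = simulate_frequencies({"chr1": 500_000}, models, snp_per_kb=2.5, seed=11)
counts = sample_pool_reads(sim, models, error_rate=0.01, mean_qual=35.0, seed=12)

print(f"simulated {len(counts)} biallelic sites on a 500-kb chromosome")
print(f"mean depth per pool: {counts.depth.mean(axis=0).round(1)}")
print(f"mean minor-allele read frequency: {np.nanmean(counts.maf()):.3f}")
print("\nfirst three sites:")
for i in range(3):
    site = counts[i]
    per_pool = ", ".join(
        f"{b}: {c.n_ref}/{c.n_alt}" for b, c in site.counts.items()
    )
    print(f"  {site.chrom}:{site.pos} {site.ref_allele}>{site.alt_allele}  ({per_pool})")
print("\nn_ref/n_alt are reads supporting each allele in the pooled library;")
print("allele frequencies, F_ST and H_p are all computed from these counts.")
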