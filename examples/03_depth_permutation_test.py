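"""The read-depth permutation test on its own, with a tiny exhaustive case.

The test pools the candidate region's per-base depths with an equally long
background stretch, redraws region-sized subsets and compares their means
against the observed region mean: p = (1 + #{resampled mean <= observed}) /
(R + 1).  Small pools are enumerated exhaustively.
"""

import numpy as np

from cnvlossverify.depth_tests import DepthTestConfig, permutation_depth_test, sample_background

# exhaustive: region [0,0] vs background [2,2] -> C(4,2)=6 subsets,
# exactly one ({0,0}) has mean <= 0, so p = (1+1)/(6+1) = 2/7
r = permutation_depth_test(np.array([0, 0]), np.array([2, 2]))
print(f"exhaustive toy case: p = {r.p_value:.4f} (expected 2/7 = {2/7:.4f})")

# a realistic case: a 1 kb zero-depth region against 4x background
rng = np.random.default_rng(0)
chrom_depth = rng.poisson(4.0, 100_000)
chrom_depth[40_000:41_000] = 0  # a homozygous loss
region = chrom_depth[40_000:41_000]
bg = sample_background(chrom_depth, 1000, [(40_000, 41_000)], seed=1)
r = permutation_depth_test(region, bg, DepthTestConfig(n_resamples=999, seed=2))
print(f"1 kb zero-depth region at 4x: p = {r.p_value:.4f} (floor = 1/1000)")

# and a null region: p should be unremarkable
null = chrom_depth[10_000:11_000]
bg2 = sample_background(chrom_depth, 1000, [(10_000, 11_000), (40_000, 41_000)], seed=3)
r2 = permutation_depth_test(null, bg2, DepthTestConfig(n_resamples=999, seed=4))
print(f"null region:                  p = {r2.p_value:.4f} (uniform under H0)")
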