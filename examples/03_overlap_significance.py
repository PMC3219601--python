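"""Overlap significance with a genome-structure-aware null.

Two cistromes that share 30% of their sites are compared against a null that
rotates and block-permutes one cistrome (blocks of R*S*chromosome length,
default R=0.2, S=0.4), preserving local clustering; an unrelated cistrome is
shown for contrast.
"""

import numpy as np

from pioneerscan import GenomeDomain, GenomicInterval, GSCParams, IntervalSet, gsc_test

L = 1_000_000
rng = np.random.default_rng(1)

def peaks(starts, label):
    return IntervalSet(
        [GenomicInterval("chr1", int(s), int(s) + 200) for s in starts], label
    ).canonicalized()

a = peaks(rng.integers(0, L - 200, size=150), "A")
shared = [iv.start for iv in a.intervals if rng.random() < 0.3]
b_related = peaks(shared + list(rng.integers(0, L - 200, size=100)), "B")
b_unrelated = peaks(rng.integers(0, L - 200, size=150), "C")

domain = GenomeDomain({"chr1": L})
params = GSCParams(region_fraction=0.2, subregion_fraction=0.4,
                   n_samples=999, seed=7)
for b in (b_related, b_unrelated):
    res = gsc_test(a, b, domain, params)
    print(f"A vs {b.label}: observed {res.observed} bp, "
          f"null {res.null_mean:.0f} +- {res.null_sd:.0f} bp, "
          f"z = {res.z:.1f}, p = {res.p_value:.4g}")
# The related cistrome shows an overlap far above the resampling null
# (p at the add-one minimum of 1/1000); the unrelated one does not.
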