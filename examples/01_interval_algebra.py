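"""Member-level cistrome algebra: build two small peak sets, intersect and
subtract them, and count shared base pairs.

Subtraction here removes whole binding sites that touch the other set (the
operation that defines e.g. "FoxA1-independent ER-alpha sites"), not base
pairs; the bp-overlap count is what the resampling significance test uses.
"""

from pioneerscan import (
    GenomicInterval,
    IntervalSet,
    basepair_overlap,
    intersect_members,
    subtract_members,
)

era = IntervalSet(
    [
        GenomicInterval("chr1", 1_000, 1_200),
        GenomicInterval("chr1", 5_000, 5_200),
        GenomicInterval("chr2", 3_000, 3_200),
    ],
    label="ERa",
)
foxa1 = IntervalSet(
    [GenomicInterval("chr1", 5_150, 5_350), GenomicInterval("chr2", 9_000, 9_200)],
    label="FoxA1",
)

shared = intersect_members(era, foxa1)
independent = subtract_members(era, foxa1)
print(f"ERa sites: {len(era)}  bound also by FoxA1: {len(shared)}  "
      f"FoxA1-independent: {len(independent)}")
print(f"base pairs covered by both cistromes: {basepair_overlap(era, foxa1)}")
# Of the 3 ERa sites exactly one touches a FoxA1 site (sharing 50 bp), so the
# FoxA1-independent ERa cistrome keeps the other two whole sites.
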