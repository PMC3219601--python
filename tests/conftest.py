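"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's fast paths: interval
questions are answered by all-pairs loops or per-base boolean vectors, and
2x2 exact p-values by direct hypergeometric enumeration, so the tests check
the implementation against genuinely independent computations.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

from pioneerscan.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_pos: int = 10_000,
    max_len: int = 300,
    label: str = "set",
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, min(start + length, max_pos)))
    return IntervalSet(ivs, label)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    if a.chrom != b.chrom:
        return False
    return any(
        a.start <= p < a.end for p in range(b.start, b.end)
    )


def brute_members_overlapping(a: IntervalSet, b: IntervalSet) -> list[bool]:
    out = []
    for iv in a:
        out.append(
            any(
                iv.chrom == jv.chrom
                and max(iv.start, jv.start) < min(iv.end, jv.end)
                for jv in b
            )
        )
    return out


def perbase_overlap_bp(a: IntervalSet, b: IntervalSet, max_pos: int = 10_000) -> int:
    total = 0
    for chrom in set(a.chroms()) | set(b.chroms()):
        cov_a = np.zeros(max_pos, dtype=bool)
        cov_b = np.zeros(max_pos, dtype=bool)
        for iv in a:
            if iv.chrom == chrom:
                cov_a[iv.start : iv.end] = True
        for iv in b:
            if iv.chrom == chrom:
                cov_b[iv.start : iv.end] = True
        total += int(np.sum(cov_a & cov_b))
    return total


def hypergeom_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summation of all tables with fixed margins whose
    probability does not exceed the observed table's."""
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    pmf_obs = hypergeom.pmf(a, n, k, n1)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = hypergeom.pmf(support, n, k, n1)
    return float(pmf[pmf <= pmf_obs * (1 + 1e-9)].sum())
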