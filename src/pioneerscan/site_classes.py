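"""Three-way cistrome partitioning into the 7 exclusive Venn classes.

Each member site of each input cistrome is assigned the label subset of all
inputs it overlaps by >=1 bp (including its own).  Because peak overlap is
not transitive, the same class can count slightly differently depending on
which factor's members anchor the count; counts are therefore reported per
reference factor, and summary tables quote a stated reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet, members_hit, write_bed

__all__ = ["VennPartition", "venn_partition", "class_label", "ALL_CLASSES"]


def class_label(subset: frozenset[str] | set[str]) -> str:
    """Canonical class name: factor labels joined by '&' in input order."""
    return "&".join(sorted(subset))


def _all_classes(labels: list[str]) -> list[frozenset[str]]:
    out = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            out.append(frozenset(combo))
    return out


ALL_CLASSES = _all_classes  # alias; callers pass the three factor labels


@dataclass
class VennPartition:
    """Per-reference-factor partition of three cistromes into Venn classes.

    ``classes[ref][subset]`` holds the members of cistrome ``ref`` whose
    overlap pattern is exactly ``subset`` (a frozenset of factor labels that
    always contains ``ref``).
    """

    labels: list[str]
    classes: dict[str, dict[frozenset[str], IntervalSet]]
    reference_counts: dict[str, int]

    def counts(self, reference: str) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.classes[reference].items()}

    def class_sites(self, subset: frozenset[str] | set[str],
                    reference: str | None = None) -> IntervalSet:
        """Sites of one Venn class, anchored on ``reference`` (default: the
        first factor named in ``subset`` by input order)."""
        subset = frozenset(subset)
        if reference is None:
            reference = next(l for l in self.labels if l in subset)
        if reference not in subset:
            raise ValueError(f"reference {reference!r} not in class {set(subset)}")
        return self.classes[reference].get(
            subset, IntervalSet([], label=class_label(subset))
        )

    def summary(self, reference: str) -> pd.DataFrame:
        """Counts and percentages of each class, from one factor's members."""
        total = self.reference_counts[reference]
        rows = []
        for subset in _all_classes(self.labels):
            if reference not in subset:
                continue
            n = len(self.classes[reference].get(subset, ()))
            rows.append(
                {
                    "class": class_label(subset),
                    "n_sites": n,
                    "percent": 100.0 * n / total if total else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def write_beds(self, outdir: str | Path, reference: str | None = None) -> list[Path]:
        """One BED per non-empty class (anchored per reference factor)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        refs = [reference] if reference else self.labels
        for ref in refs:
            for subset, iset in self.classes[ref].items():
                if len(iset) == 0:
                    continue
                path = outdir / f"{ref}__{class_label(subset).replace('&', '_')}.bed"
                write_bed(iset, path)
                written.append(path)
        return written


def venn_partition(*cistromes: IntervalSet) -> VennPartition:
    """Partition three (or two) labelled cistromes into exclusive Venn classes.

    Input sets should be canonicalized.  Labels must be unique and non-empty.
    """
    labels = [c.label for c in cistromes]
    if len(set(labels)) != len(labels) or any(not l for l in labels):
        raise ValueError("cistromes must carry unique non-empty labels")
    merged = {c.label: c.merged_arrays() for c in cistromes}
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))

    classes: dict[str, dict[frozenset[str], IntervalSet]] = {}
    for ref in cistromes:
        buckets: dict[frozenset[str], list] = {}
        per_chrom = ref.by_chrom()
        hit_flags: dict[str, dict[str, np.ndarray]] = {}
        for chrom, (s, e) in per_chrom.items():
            hit_flags[chrom] = {
                other.label: members_hit(s, e, merged[other.label].get(chrom, empty))
                for other in cistromes
                if other.label != ref.label
            }
        # iterate members in original (sorted-by-chrom) order
        idx: dict[str, int] = {chrom: 0 for chrom in per_chrom}
        for iv in sorted(ref, key=lambda iv: iv.sort_key()):
            i = idx[iv.chrom]
            idx[iv.chrom] += 1
            subset = {ref.label}
            for other_label, flags in hit_flags[iv.chrom].items():
                if flags[i]:
                    subset.add(other_label)
            buckets.setdefault(frozenset(subset), []).append(iv)
        classes[ref.label] = {
            subset: IntervalSet(ivs, label=class_label(subset))
            for subset, ivs in buckets.items()
        }
    return VennPartition(
        labels=labels,
        classes=classes,
        reference_counts={c.label: len(c) for c in cistromes},
    )
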