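"""Genomic intervals: BED I/O, and set algebra under the >=1 bp overlap rule.

Coordinates are BED-convention throughout: 0-based, half-open ``[start, end)``.
Two intervals overlap iff they share at least one base pair, i.e. they are on
the same chromosome and ``max(starts) < min(ends)``; book-ended intervals
(``end == start``) do not overlap.

Set operations come in two flavours:

* **member-level** (:func:`intersect_members`, :func:`subtract_members`) —
  whole input intervals are kept or dropped depending on whether they touch
  the other set.  This is the natural currency for cistromes, where a binding
  *site* is the unit of analysis (e.g. "FoxA1-independent ER-alpha sites").
* **base-pair-level** (:func:`basepair_overlap`, :func:`subtract_bp`) —
  positions are counted or removed individually, after merging each set into
  non-overlapping runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeDomain",
    "overlaps",
    "intersect_members",
    "subtract_members",
    "subtract_bp",
    "basepair_overlap",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint; deterministic for odd and even widths."""
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with a label.

    Duplicates are permitted on construction; :meth:`canonicalized` sorts and
    removes exact-coordinate duplicates.  Per-chromosome merged coordinate
    arrays (used by all bp-level computations) are built lazily and cached.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet(label={self.label!r}, n={len(self)})"

    def canonicalized(self) -> "IntervalSet":
        """Sorted by (chrom, start, end), exact-duplicate members collapsed."""
        seen: set[tuple[str, int, int]] = set()
        out: list[GenomicInterval] = []
        for iv in sorted(self.intervals, key=GenomicInterval.sort_key):
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                out.append(iv)
        return IntervalSet(out, self.label)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_bp(self) -> int:
        """Base pairs covered (overlapping members counted once)."""
        return sum(
            int(np.sum(e - s)) for s, e in self.merged_arrays().values()
        )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Member starts/ends per chromosome, sorted by start (not merged)."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        res: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in out.items():
            pairs.sort()
            arr = np.asarray(pairs, dtype=np.int64)
            res[chrom] = (arr[:, 0], arr[:, 1])
        return res

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (non-overlapping, sorted) coordinate runs."""
        if self._merged is None:
            self._merged = {
                chrom: merge_runs(s, e) for chrom, (s, e) in self.by_chrom().items()
            }
        return self._merged


@dataclass(frozen=True)
class GenomeDomain:
    """Chromosome lengths; the coordinate domain for resampling and simulation."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains(self, iset: IntervalSet) -> bool:
        for iv in iset:
            length = self.chrom_lengths.get(iv.chrom)
            if length is None or iv.end > length:
                return False
        return True


# ---------------------------------------------------------------------------
# low-level coordinate-array helpers (shared with gsc/signal modules)
# ---------------------------------------------------------------------------

def merge_runs(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals into non-overlapping runs.

    Book-ended intervals ([0,5) and [5,9)) are merged into one run, so the
    result is strictly separated; bp counts are unaffected either way.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    cummax = np.maximum.accumulate(ends)
    # a new run begins where the start exceeds the running max end so far
    new_run = np.empty(starts.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > cummax[:-1]
    run_id = np.cumsum(new_run) - 1
    out_starts = starts[new_run]
    out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_run))
    del run_id
    return out_starts, out_ends


def runs_overlap_bp(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> int:
    """Base pairs covered by both of two merged run lists (one chromosome)."""
    as_, ae = a
    bs, be = b
    if as_.size == 0 or bs.size == 0:
        return 0
    # For each a-run, clip every b-run against it via searchsorted windows.
    lo = np.searchsorted(be, as_, side="right")
    hi = np.searchsorted(bs, ae, side="left")
    total = 0
    for i in range(as_.size):
        j0, j1 = lo[i], hi[i]
        if j1 > j0:
            seg = np.minimum(be[j0:j1], ae[i]) - np.maximum(bs[j0:j1], as_[i])
            total += int(seg.sum())
    return total


def members_hit(
    starts: np.ndarray, ends: np.ndarray, other: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Boolean mask: which members [starts, ends) overlap the merged runs `other`."""
    bs, be = other
    if bs.size == 0:
        return np.zeros(starts.shape, dtype=bool)
    idx = np.searchsorted(bs, ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = be[idx[hit]] > starts[hit]
    return hit


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def _hit_mask_by_member(a: IntervalSet, b: IntervalSet) -> list[bool]:
    merged_b = b.merged_arrays()
    flags: dict[tuple[str, int, int], bool] = {}
    for chrom, (s, e) in a.by_chrom().items():
        other = merged_b.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        hits = members_hit(s, e, other)
        for start, end, h in zip(s.tolist(), e.tolist(), hits.tolist()):
            flags[(chrom, start, end)] = h
    return [flags[(iv.chrom, iv.start, iv.end)] for iv in a]


def intersect_members(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Members of ``a`` (whole, untruncated) overlapping >=1 member of ``b``."""
    mask = _hit_mask_by_member(a, b)
    return IntervalSet(
        [iv for iv, h in zip(a, mask) if h], label=f"{a.label}&{b.label}"
    )


def subtract_members(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Members of ``a`` overlapping no member of ``b`` (whole-site removal)."""
    mask = _hit_mask_by_member(a, b)
    return IntervalSet(
        [iv for iv, h in zip(a, mask) if not h], label=f"{a.label}-{b.label}"
    )


def subtract_bp(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair-level subtraction: positions of ``a`` not covered by ``b``.

    Returns merged fragments, not original members.
    """
    merged_b = b.merged_arrays()
    out: list[GenomicInterval] = []
    for chrom, (as_, ae) in a.merged_arrays().items():
        bs, be = merged_b.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        for s, e in zip(as_.tolist(), ae.tolist()):
            pos = s
            j0 = np.searchsorted(be, s, side="right")
            j1 = np.searchsorted(bs, e, side="left")
            for j in range(j0, j1):
                if bs[j] > pos:
                    out.append(GenomicInterval(chrom, pos, int(bs[j])))
                pos = max(pos, int(be[j]))
            if pos < e:
                out.append(GenomicInterval(chrom, pos, e))
    return IntervalSet(out, label=f"{a.label}-{b.label}(bp)")


def basepair_overlap(a: IntervalSet, b: IntervalSet) -> int:
    """Total base positions covered by both sets (each merged first)."""
    merged_b = b.merged_arrays()
    total = 0
    for chrom, runs_a in a.merged_arrays().items():
        if chrom in merged_b:
            total += runs_overlap_bp(runs_a, merged_b[chrom])
    return total


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3+ file (tab- or space-separated; track/browser/# lines skipped)."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, label=label if label is not None else path.stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED; name/score columns emitted only where present."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in iset:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(f"{iv.score:g}")
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeDomain:
    """Read a two-column 'chrom<TAB>length' file."""
    lengths: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            lengths[parts[0]] = int(parts[1])
    return GenomeDomain(lengths)


def write_chrom_sizes(domain: GenomeDomain, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, length in domain.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
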