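"""Accessibility/occupancy signal tracks and aggregation around binding sites.

Tracks are per-chromosome vectors at a fixed bin width (WIG-style).  The
central operation averages the signal at each offset in a symmetric window
around site centers, per site class — the standard "aggregate profile" view
of whether a class of binding sites sits in open chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .intervals import GenomeDomain, IntervalSet, intersect_members

__all__ = [
    "SignalTrack",
    "AggregateProfile",
    "read_wig",
    "write_wig",
    "aggregate_profile",
    "fraction_in_peaks",
]


@dataclass
class SignalTrack:
    """Per-chromosome signal vectors at fixed ``bin_width`` bp resolution."""

    values: dict[str, np.ndarray]
    bin_width: int = 1

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @classmethod
    def zeros(cls, domain: GenomeDomain, bin_width: int = 1) -> "SignalTrack":
        return cls(
            {
                chrom: np.zeros(-(-length // bin_width))
                for chrom, length in domain.chrom_lengths.items()
            },
            bin_width=bin_width,
        )

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin_width])


@dataclass(frozen=True)
class AggregateProfile:
    """Mean signal by offset from site center for one site class."""

    class_label: str
    offsets: np.ndarray  # bp relative to center, symmetric about 0
    mean_signal: np.ndarray
    n_sites: int
    n_dropped: int = 0  # sites whose window left the chromosome

    @property
    def peak_height(self) -> float:
        return float(self.mean_signal.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_signal": self.mean_signal}
        )


# ---------------------------------------------------------------------------
# WIG I/O (fixedStep / variableStep)
# ---------------------------------------------------------------------------

def read_wig(path: str | Path, domain: GenomeDomain | None = None) -> SignalTrack:
    """Read a wiggle file into a span-1 track; unspecified positions are 0.

    Chromosome vector lengths come from ``domain`` when given, otherwise from
    the last covered position.
    """
    entries: dict[str, list[tuple[int, int, float]]] = {}
    mode: str | None = None
    chrom = ""
    step = span = 1
    pos = 0
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                if "chrom" not in fields:
                    raise ValueError(f"{path}:{lineno}: header lacks chrom=")
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    if "start" not in fields:
                        raise ValueError(f"{path}:{lineno}: fixedStep lacks start=")
                    pos = int(fields["start"]) - 1  # wiggle is 1-based
                    step = int(fields.get("step", 1))
                else:
                    mode = "variable"
                entries.setdefault(chrom, [])
                continue
            if mode is None:
                raise ValueError(f"{path}:{lineno}: data before any step header")
            parts = line.split()
            if mode == "fixed":
                entries[chrom].append((pos, span, float(parts[0])))
                pos += step
            else:
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: variableStep needs pos value")
                entries[chrom].append((int(parts[0]) - 1, span, float(parts[1])))

    values: dict[str, np.ndarray] = {}
    lengths = dict(domain.chrom_lengths) if domain else {}
    for chrom, triples in entries.items():
        length = lengths.get(
            chrom, max(p + s for p, s, _ in triples) if triples else 0
        )
        vec = np.zeros(length)
        for p, s, v in triples:
            vec[p : min(p + s, length)] = v
        values[chrom] = vec
    if domain:
        for chrom, length in domain.chrom_lengths.items():
            values.setdefault(chrom, np.zeros(length))
    return SignalTrack(values, bin_width=1)


def write_wig(track: SignalTrack, path: str | Path, name: str = "signal") -> None:
    """Write a fixedStep wiggle at the track's bin width (zero runs skipped)."""
    bw = track.bin_width
    with Path(path).open("w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom, vec in track.values.items():
            nz = np.flatnonzero(vec)
            if nz.size == 0:
                continue
            # contiguous nonzero runs as separate fixedStep blocks
            breaks = np.flatnonzero(np.diff(nz) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [nz.size - 1]])
            for s_idx, e_idx in zip(starts, ends):
                first = int(nz[s_idx])
                fh.write(
                    f"fixedStep chrom={chrom} start={first * bw + 1} "
                    f"step={bw} span={bw}\n"
                )
                for i in range(first, int(nz[e_idx]) + 1):
                    fh.write(f"{vec[i]:g}\n")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_profile(
    track: SignalTrack, sites: IntervalSet, flank: int = 2000
) -> AggregateProfile:
    """Mean signal at each bp offset in [-flank, +flank] across site centers.

    Sites whose window would leave the chromosome are dropped (and counted),
    not zero-padded, so edge effects cannot deflate the mean.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if len(sites) == 0:
        raise ValueError("cannot aggregate over an empty site set")
    if track.bin_width != 1:
        raise ValueError("aggregate_profile expects a span-1 track")
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(offsets.size)
    n_used = 0
    n_dropped = 0
    for iv in sites:
        vec = track.values.get(iv.chrom)
        center = iv.center
        if vec is None or center - flank < 0 or center + flank + 1 > vec.size:
            n_dropped += 1
            continue
        total += vec[center - flank : center + flank + 1]
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites dropped at chromosome edges")
    return AggregateProfile(
        class_label=sites.label,
        offsets=offsets,
        mean_signal=total / n_used,
        n_sites=n_used,
        n_dropped=n_dropped,
    )


def fraction_in_peaks(sites: IntervalSet, peaks: IntervalSet) -> float:
    """Fraction of sites overlapping >=1 called peak (member-level)."""
    if len(sites) == 0:
        raise ValueError("sites must be non-empty")
    return len(intersect_members(sites, peaks)) / len(sites)
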