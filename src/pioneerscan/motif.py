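"""Position weight matrices: TRANSFAC I/O, log-odds scanning, cistrome screening.

A PWM holds raw base counts per motif position.  Scoring smooths the counts
with a pseudocount, converts to per-position base frequencies and scores a
window as the summed log2 odds against a background base distribution.  A
cistrome "screen" asks, for each peak, whether any window on either strand
reaches a score threshold, and reports the fraction of peaks with a hit.

The default threshold is matrix-adaptive: the smallest score whose
single-window tail probability under the background model is at most a target
p-value, computed by exact dynamic programming over the discretised score
distribution (no sampling involved).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .intervals import IntervalSet

__all__ = [
    "PWM",
    "MotifScreenResult",
    "parse_transfac",
    "read_transfac",
    "write_transfac",
    "score_window",
    "window_scores",
    "threshold_for_pvalue",
    "screen_cistrome",
    "compare_screen_fractions",
    "load_fasta",
    "write_fasta",
]

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# complement permutation over the ACGT axis (A<->T, C<->G)
_COMPL = np.array([3, 2, 1, 0], dtype=np.intp)


def _encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes (A0 C1 G2 T3, anything else N=4)."""
    table = np.full(256, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """A position count matrix with background model and pseudocount."""

    id: str
    counts: np.ndarray  # (L, 4) nonnegative, columns A C G T
    background: np.ndarray | None = None  # base probabilities, sums to 1
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError("counts must be an L x 4 matrix with L >= 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocount-smoothed per-position base frequencies."""
        smoothed = self.counts + self.pseudocount
        return smoothed / smoothed.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2-odds matrix; 5th column is the neutral N score (0)."""
        lo = np.log2(self.frequencies / self.background[None, :])
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse-complement strand (background unchanged;
        the default background is complement-symmetric)."""
        return PWM(
            id=self.id,
            counts=self.counts[::-1, _COMPL].copy(),
            background=self.background[_COMPL].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifScreenResult:
    """Outcome of screening one cistrome for one motif."""

    n_peaks: int
    n_with_hit: int
    threshold: float
    scanned_both_strands: bool = True

    @property
    def fraction(self) -> float:
        return self.n_with_hit / self.n_peaks if self.n_peaks else float("nan")


# ---------------------------------------------------------------------------
# TRANSFAC I/O
# ---------------------------------------------------------------------------

def parse_transfac(text: str) -> PWM:
    """Parse a single TRANSFAC matrix record.

    Recognises ID/AC lines for the identifier, an optional ``P0/PO`` header
    giving column order, and position lines ``NN c1 c2 c3 c4 [consensus]``.
    """
    matrix_id = ""
    col_order = [0, 1, 2, 3]
    rows: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("XX") or line.startswith("//"):
            continue
        tag, _, rest = line.partition(" ")
        if tag in ("ID", "AC", "NA") and rest.strip():
            if not matrix_id or tag == "ID":
                matrix_id = rest.strip().split()[0]
            continue
        if tag in ("P0", "PO"):
            letters = rest.split()[:4]
            try:
                col_order = [BASES.index(b.upper()) for b in letters]
            except ValueError as exc:
                raise ValueError(f"bad column header: {line!r}") from exc
            continue
        if tag.isdigit():
            parts = rest.split()
            if len(parts) < 4:
                raise ValueError(f"position line with <4 counts: {line!r}")
            try:
                vals = [float(x) for x in parts[:4]]
            except ValueError as exc:
                raise ValueError(f"non-numeric count in line: {line!r}") from exc
            if any(v < 0 for v in vals):
                raise ValueError(f"negative count in line: {line!r}")
            row = [0.0] * 4
            for v, col in zip(vals, col_order):
                row[col] = v
            rows.append(row)
    if not rows:
        raise ValueError("no matrix position lines found")
    return PWM(id=matrix_id or "matrix", counts=np.asarray(rows))


def read_transfac(path: str | Path) -> PWM:
    return parse_transfac(Path(path).read_text())


def write_transfac(pwm: PWM, path: str | Path | None = None) -> str:
    """Serialise a PWM as a TRANSFAC record; returns the text."""
    buf = io.StringIO()
    buf.write(f"ID {pwm.id}\nXX\nP0      A      C      G      T\n")
    for i, row in enumerate(pwm.counts, start=1):
        cells = "  ".join(f"{v:7g}" for v in row)
        cons = BASES[int(np.argmax(row))]
        buf.write(f"{i:02d}  {cells}  {cons}\n")
    buf.write("XX\n//\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_window(window: str, pwm: PWM) -> float:
    """Log2-odds score of one window (forward strand); N contributes 0."""
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != motif length {len(pwm)}")
    codes = _encode(window)
    return float(pwm.log_odds[np.arange(len(pwm)), codes].sum())


def window_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Scores of every length-L window of ``seq`` on the forward strand."""
    L = len(pwm)
    codes = _encode(seq)
    if codes.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return pwm.log_odds[np.arange(L)[None, :], win].sum(axis=1)


def best_hit_score(seq: str, pwm: PWM, both_strands: bool = True) -> float:
    """Best window score over the sequence (both strands by default)."""
    fwd = window_scores(seq, pwm)
    best = fwd.max() if fwd.size else -np.inf
    if both_strands:
        rev = window_scores(seq, pwm.reverse_complement())
        if rev.size:
            best = max(best, rev.max())
    return float(best)


def threshold_for_pvalue(
    pwm: PWM, pvalue: float = 1e-4, precision: float = 1e-3
) -> float:
    """Smallest score with background tail probability <= ``pvalue``.

    Exact dynamic programming over the discretised per-window score
    distribution under the background base model; ``precision`` is the
    discretisation step in bits.
    """
    if not 0 < pvalue < 1:
        raise ValueError("pvalue must be in (0, 1)")
    lo = pwm.log_odds[:, :4]
    q = np.rint(lo / precision).astype(np.int64)  # millibit bins
    offset = 0
    dist = np.array([1.0])
    bg = np.asarray(pwm.background, dtype=float)
    for row in q:
        rmin, rmax = int(row.min()), int(row.max())
        new = np.zeros(dist.size + (rmax - rmin), dtype=float)
        for base in range(4):
            shift = int(row[base]) - rmin
            new[shift : shift + dist.size] += bg[base] * dist
        dist = new
        offset += rmin
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(-tail, -pvalue)  # first bin with tail <= pvalue
    if idx >= dist.size:
        idx = dist.size - 1
    return (offset + idx) * precision


def screen_cistrome(
    peaks: IntervalSet,
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float | None = None,
    both_strands: bool = True,
) -> MotifScreenResult:
    """Fraction of peaks with >=1 window scoring at or above the threshold.

    ``genome`` maps chromosome name to sequence.  A peak extending beyond its
    chromosome is an error naming the peak.
    """
    if threshold is None:
        threshold = threshold_for_pvalue(pwm)
    n_hit = 0
    for iv in peaks:
        seq = genome.get(iv.chrom)
        if seq is None or iv.end > len(seq):
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} outside genome bounds"
            )
        if best_hit_score(seq[iv.start : iv.end], pwm, both_strands) >= threshold:
            n_hit += 1
    return MotifScreenResult(
        n_peaks=len(peaks),
        n_with_hit=n_hit,
        threshold=float(threshold),
        scanned_both_strands=both_strands,
    )


def compare_screen_fractions(a: MotifScreenResult, b: MotifScreenResult) -> float:
    """Two-sided Fisher exact p for hit fractions differing between cistromes."""
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("both screens must cover at least one peak")
    table = [
        [a.n_with_hit, a.n_peaks - a.n_with_hit],
        [b.n_with_hit, b.n_peaks - b.n_with_hit],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# FASTA I/O (thin wrappers over Biopython)
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a multi-record FASTA as {name: uppercase sequence}."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
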