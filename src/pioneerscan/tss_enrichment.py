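"""TSS-window association of binding-site classes with responsive genes.

A gene is "associated" with a site class if at least one site of that class
overlaps the window ``[tss - w, tss + w)`` around its transcription start
site (default w = 20 kb; strand-independent).  The enrichment statistic for a
class is the proportion of responsive genes associated, divided by the
proportion of null-list genes associated, with a two-sided Fisher exact
p-value on the underlying 2x2 table.  One ratio per (class, responsive set)
makes up the "radar" table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, members_hit
from .site_classes import VennPartition, class_label

__all__ = [
    "GeneAnnotation",
    "EnrichmentRatio",
    "genes_with_site",
    "enrichment_ratio",
    "radar_table",
    "read_tss_table",
    "write_tss_table",
]

DEFAULT_WINDOW = 20_000


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class EnrichmentRatio:
    class_label: str
    responsive_set: str
    n_resp_with: int
    n_resp: int
    n_null_with: int
    n_null: int
    ratio: float
    p_value: float
    flagged: bool = False  # degenerate ratio (zero null-with count or empty class)


def genes_with_site(
    sites: IntervalSet,
    genes: Sequence[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
) -> set[str]:
    """Gene ids with >=1 site overlapping [tss - window, tss + window)."""
    if window <= 0:
        raise ValueError("window must be positive")
    merged = sites.merged_arrays()
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: set[str] = set()
    for chrom, gs in by_chrom.items():
        runs = merged.get(chrom, empty)
        starts = np.array([max(0, g.tss - window) for g in gs], dtype=np.int64)
        ends = np.array([g.tss + window for g in gs], dtype=np.int64)
        hits = members_hit(starts, ends, runs)
        out.update(g.gene_id for g, h in zip(gs, hits) if h)
    return out


def enrichment_ratio(
    class_sites: IntervalSet,
    responsive: set[str],
    null_genes: set[str],
    genes: Sequence[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
    responsive_name: str = "responsive",
    proportion_normalized: bool = True,
) -> EnrichmentRatio:
    """Responsive-over-null association ratio for one site class.

    With ``proportion_normalized`` (default) the ratio compares proportions,
    which hovers near 1 for unrelated classes regardless of list sizes; the
    raw-count ratio is available for literal gene-count comparisons.
    """
    if responsive & null_genes:
        raise ValueError("responsive and null gene lists must be disjoint")
    if not responsive or not null_genes:
        raise ValueError("responsive and null gene lists must be non-empty")
    with_site = genes_with_site(class_sites, genes, window)
    a = len(responsive & with_site)
    b = len(responsive) - a
    c = len(null_genes & with_site)
    d = len(null_genes) - c
    flagged = False
    if proportion_normalized:
        if c == 0:
            ratio = float("inf") if a > 0 else float("nan")
            flagged = True
        else:
            ratio = (a / len(responsive)) / (c / len(null_genes))
    else:
        ratio = a / c if c else float("inf")
        flagged = c == 0
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentRatio(
        class_label=class_sites.label or "sites",
        responsive_set=responsive_name,
        n_resp_with=a,
        n_resp=len(responsive),
        n_null_with=c,
        n_null=len(null_genes),
        ratio=ratio,
        p_value=p,
        flagged=flagged,
    )


def radar_table(
    partition: VennPartition,
    responsive_sets: Mapping[str, set[str]],
    null_genes: set[str],
    genes: Sequence[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """One enrichment ratio per (Venn class, responsive gene set).

    Genes associated with sites of several classes count toward each class
    independently.  Empty classes are emitted with NaN ratio and a flag.
    """
    rows = []
    from .site_classes import _all_classes

    for subset in _all_classes(partition.labels):
        sites = partition.class_sites(subset)
        for name, resp in responsive_sets.items():
            if len(sites) == 0:
                rows.append(
                    EnrichmentRatio(
                        class_label=class_label(subset), responsive_set=name,
                        n_resp_with=0, n_resp=len(resp), n_null_with=0,
                        n_null=len(null_genes), ratio=float("nan"),
                        p_value=float("nan"), flagged=True,
                    ).__dict__
                )
                continue
            er = enrichment_ratio(
                sites, resp, null_genes, genes, window, responsive_name=name
            )
            rows.append({**er.__dict__, "class_label": class_label(subset)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation I/O: 4-column TSS table (gene_id, chrom, tss, strand) or BED6
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotation from a TSV table or BED6.

    BED6 lines (chrom start end name score strand) use the strand-aware
    start as TSS; 4-column tables are (gene_id, chrom, tss, strand).
    """
    genes: list[GeneAnnotation] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) >= 6 and f[1].isdigit() and f[2].isdigit():
                chrom, start, end, name, _, strand = f[:6]
                tss = int(start) if strand == "+" else int(end) - 1
                genes.append(GeneAnnotation(name, chrom, tss, strand))
            elif len(f) >= 3:
                gene_id, chrom, tss = f[0], f[1], int(f[2])
                strand = f[3] if len(f) > 3 else "+"
                genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
            else:
                raise ValueError(f"{path}:{lineno}: unrecognised annotation line")
    return genes


def write_tss_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")
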