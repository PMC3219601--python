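"""Synthetic data with planted ground truth for every pipeline stage.

One :class:`SyntheticDesign` drives all generators, and a single root seed
makes every output reproducible byte-for-byte.  The generators emulate the
structure the analysis measures — designed Venn overlap between three
cistromes, motif occurrences planted at a known per-site probability,
responsive genes whose TSSs sit near designed site classes at a designed
enrichment over null genes, estrogen response abolished under knockdown for
a designed fraction of genes, accessibility bumps whose amplitude depends on
site class, and outcome probabilities tied to expression strata.

The default design scales the real study's geometry down to a 30 Mb
three-chromosome toy genome; headline planted parameters keep the study's
values (200 bp peaks, 71% knockdown-dependent responsive genes, 85% motif
planting, ~50% of the ER-alpha cistrome shared with PBX1).
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import CTRL, ESTROGEN, KNOCKDOWN, VEHICLE, ExpressionStudy
from .intervals import GenomeDomain, GenomicInterval, IntervalSet, merge_runs
from .motif import PWM
from .outcome import SurvivalCohort
from .signal import SignalTrack
from .tss_enrichment import GeneAnnotation

__all__ = [
    "SyntheticDesign",
    "SyntheticDataset",
    "default_pwm",
    "gen_genome",
    "gen_cistromes",
    "plant_motifs",
    "gen_genes",
    "gen_expression",
    "gen_track",
    "gen_cohort",
    "generate_all",
]

FACTORS = ("ERa", "FoxA1", "PBX1")
CLASS_LABELS = (
    "ERa", "FoxA1", "PBX1",
    "ERa&FoxA1", "ERa&PBX1", "FoxA1&PBX1",
    "ERa&FoxA1&PBX1",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_venn_counts() -> dict[str, int]:
    # scaled-down mimic of the study's overlap structure: about half of the
    # ER-alpha cistrome shared with PBX1, the majority also bound by FoxA1
    return {
        "ERa": 25, "FoxA1": 45, "PBX1": 60,
        "ERa&FoxA1": 35, "ERa&PBX1": 25, "FoxA1&PBX1": 40,
        "ERa&FoxA1&PBX1": 45,
    }


def _default_openness() -> dict[str, float]:
    # openness ordered shared > PBX1-unique > FoxA1-unique
    return {
        "ERa": 0.5, "FoxA1": 1.0, "PBX1": 2.0,
        "ERa&FoxA1": 1.0, "ERa&PBX1": 2.0, "FoxA1&PBX1": 3.0,
        "ERa&FoxA1&PBX1": 3.0,
    }


@dataclass
class SyntheticDesign:
    """All planted parameters of the synthetic study."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000,
                                 "chr3": 10_000_000}
    )
    gc_content: float = 0.41
    peak_width: int = 200
    venn_counts: dict[str, int] = field(default_factory=_default_venn_counts)
    motif_plant_prob: float = 0.85

    # gene / expression design
    n_genes: int = 10_000
    n_responsive: int = 500
    dependent_fraction: float = 0.71
    n_samples_per_cell: int = 3
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    tss_window: int = 20_000
    class_gene_base_rate: float = 0.1
    enrichment_factor: float = 2.0
    dependent_linked_classes: tuple[str, ...] = ("PBX1", "ERa&PBX1")
    independent_linked_classes: tuple[str, ...] = ("ERa&FoxA1&PBX1",)

    # accessibility track design
    openness_amplitudes: dict[str, float] = field(default_factory=_default_openness)
    track_baseline: float = 0.5
    track_noise_sd: float = 0.2
    bump_sd: float = 100.0

    # cohort design
    cohort_n: int = 300
    high_fraction: float = 0.10
    event_prob_high: float = 0.5
    event_prob_low: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.motif_plant_prob, self.dependent_fraction,
                  self.gc_content, self.event_prob_high, self.event_prob_low,
                  self.class_gene_base_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 0 for n in self.venn_counts.values()):
            raise ValueError("venn counts must be nonnegative")
        if any(l < 10_000 for l in self.chrom_lengths.values()):
            raise ValueError("chromosomes must be >= 10 kb")

    @property
    def domain(self) -> GenomeDomain:
        return GenomeDomain(dict(self.chrom_lengths))

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-scoped generator derived from the root seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


def default_pwm() -> PWM:
    """Synthetic stand-in for a PBX1-class homeodomain matrix.

    A constructed 8-position count matrix with the TGATTGAT-like consensus
    typical of PBX-family sites; it is a synthetic object, not a database
    matrix, and is used only to plant and recover motifs in synthetic data.
    """
    consensus = "TGATTGAT"
    counts = []
    for base in consensus:
        row = [2.0, 2.0, 2.0, 2.0]
        row["ACGT".index(base)] = 30.0
        counts.append(row)
    return PWM(id="PBX1_SYNTH", counts=np.asarray(counts))


# ---------------------------------------------------------------------------
# genome and cistromes
# ---------------------------------------------------------------------------

def gen_genome(
    design: SyntheticDesign, rng: np.random.Generator | None = None
) -> dict[str, bytearray]:
    """I.i.d. random genome at the designed GC content, as mutable bytes."""
    rng = rng if rng is not None else design.rng(1)
    gc = design.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, bytearray] = {}
    for chrom, length in design.chrom_lengths.items():
        codes = rng.choice(4, size=length, p=probs)
        genome[chrom] = bytearray(_BASES[codes].tobytes())
    return genome


def genome_as_strings(genome: Mapping[str, bytearray | str]) -> dict[str, str]:
    return {
        c: (s if isinstance(s, str) else bytes(s).decode("ascii"))
        for c, s in genome.items()
    }


@dataclass
class CistromeTruth:
    """Designed cistromes with exact per-class ground truth."""

    cistromes: dict[str, IntervalSet]
    class_sites: dict[str, IntervalSet]

    def designed_counts(self) -> dict[str, int]:
        return {label: len(s) for label, s in self.class_sites.items()}


def _place_separated_centers(
    design: SyntheticDesign,
    n_total: int,
    min_separation: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Uniform site centers with pairwise separation >= min_separation."""
    chroms = list(design.chrom_lengths)
    lengths = np.array([design.chrom_lengths[c] for c in chroms], dtype=float)
    margin = min_separation // 2 + design.peak_width
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    out: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 200 * n_total + 1000
    while len(out) < n_total:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "domain too small to place the designed sites without collision"
            )
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom = chroms[ci]
        hi = design.chrom_lengths[chrom] - margin
        if hi <= margin:
            continue
        center = int(rng.integers(margin, hi))
        pos_list = placed[chrom]
        i = bisect.bisect_left(pos_list, center)
        if i > 0 and center - pos_list[i - 1] < min_separation:
            continue
        if i < len(pos_list) and pos_list[i] - center < min_separation:
            continue
        pos_list.insert(i, center)
        out.append((chrom, center))
    return out


def gen_cistromes(
    design: SyntheticDesign, rng: np.random.Generator | None = None
) -> CistromeTruth:
    """Place the designed number of loci per Venn class, without collisions.

    Loci of different classes are separated by more than twice the TSS
    window, so each locus "owns" its neighbourhood and planted gene-class
    links stay unambiguous.  Shared-class loci appear as the identical
    interval in every member cistrome.
    """
    rng = rng if rng is not None else design.rng(2)
    n_total = sum(design.venn_counts.get(l, 0) for l in CLASS_LABELS)
    min_sep = 2 * design.tss_window + 2 * design.peak_width
    centers = _place_separated_centers(design, n_total, min_sep, rng)
    half = design.peak_width // 2

    class_sites: dict[str, IntervalSet] = {}
    per_factor: dict[str, list[GenomicInterval]] = {f: [] for f in FACTORS}
    k = 0
    for label in CLASS_LABELS:
        members = label.split("&")
        ivs = []
        for _ in range(design.venn_counts.get(label, 0)):
            chrom, center = centers[k]
            k += 1
            iv = GenomicInterval(
                chrom, center - half, center - half + design.peak_width,
                name=label,
            )
            ivs.append(iv)
            for f in members:
                per_factor[f].append(iv)
        class_sites[label] = IntervalSet(ivs, label=label)
    cistromes = {
        f: IntervalSet(ivs, label=f).canonicalized()
        for f, ivs in per_factor.items()
    }
    return CistromeTruth(cistromes=cistromes, class_sites=class_sites)


def plant_motifs(
    genome: dict[str, bytearray],
    sites: IntervalSet,
    pwm: PWM,
    prob: float,
    rng: np.random.Generator,
    consensus: bool = True,
) -> pd.DataFrame:
    """Write motif occurrences into ``genome`` within selected sites.

    Each site is selected Bernoulli(prob); the motif (consensus by default,
    otherwise a sequence sampled from the PWM frequencies) is written at a
    uniform offset on a random strand.  Returns a per-site truth table.
    """
    L = len(pwm)
    if L >= min((len(iv) for iv in sites), default=L + 1):
        raise ValueError("motif longer than the narrowest site")
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    records = []
    for iv in sites:
        planted = bool(rng.random() < prob)
        strand, offset = "", -1
        if planted:
            if consensus:
                word = pwm.consensus.encode()
            else:
                freqs = pwm.frequencies
                word = bytes(
                    _BASES[rng.choice(4, p=freqs[i] / freqs[i].sum())]
                    for i in range(L)
                )
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                word = word.translate(comp)[::-1]
            offset = int(rng.integers(0, len(iv) - L + 1))
            start = iv.start + offset
            genome[iv.chrom][start : start + L] = word
        records.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "planted": planted, "strand": strand, "offset": offset,
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    genes: list[GeneAnnotation]
    table: pd.DataFrame  # gene_id, group, linked_class

    @property
    def responsive(self) -> set[str]:
        t = self.table
        return set(t.gene_id[t.group.isin(["dependent", "independent"])])

    @property
    def dependent(self) -> set[str]:
        return set(self.table.gene_id[self.table.group == "dependent"])

    @property
    def null(self) -> set[str]:
        return set(self.table.gene_id[self.table.group == "null"])


def _allowed_runs(
    design: SyntheticDesign, class_sites: Mapping[str, IntervalSet]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome complement of all site neighbourhoods (TSS-safe zones)."""
    pad = design.tss_window + design.peak_width
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for sites in class_sites.values():
        for iv in sites:
            forbidden.setdefault(iv.chrom, []).append(
                (max(0, iv.start - pad), iv.end + pad)
            )
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in design.chrom_lengths.items():
        pairs = sorted(forbidden.get(chrom, []))
        if pairs:
            arr = np.asarray(pairs, dtype=np.int64)
            fs, fe = merge_runs(arr[:, 0], arr[:, 1])
        else:
            fs = np.empty(0, np.int64)
            fe = np.empty(0, np.int64)
        starts = np.concatenate([[0], fe])
        ends = np.concatenate([fs, [length]])
        keep = ends > starts
        out[chrom] = (starts[keep], ends[keep])
    return out


def gen_genes(
    design: SyntheticDesign,
    class_sites: Mapping[str, IntervalSet],
    rng: np.random.Generator | None = None,
) -> GeneTruth:
    """TSS annotation with a planted class->gene linkage.

    Every gene draws one site class (or none): null genes pick each class
    with the base rate; responsive genes pick their linked classes at
    ``enrichment_factor`` times the base rate.  A gene linked to a class gets
    its TSS within the +-window of one site of that class; unlinked genes are
    placed outside every site neighbourhood, so the designed with-site
    proportions are exact by construction.
    """
    rng = rng if rng is not None else design.rng(3)
    labels = [l for l in CLASS_LABELS if len(class_sites.get(l, ())) > 0]
    base = design.class_gene_base_rate
    n_dep = int(round(design.dependent_fraction * design.n_responsive))

    allowed = _allowed_runs(design, class_sites)
    chroms = list(allowed)
    run_lengths = {
        c: (allowed[c][1] - allowed[c][0]).astype(float) for c in chroms
    }
    chrom_weights = np.array([run_lengths[c].sum() for c in chroms])
    if chrom_weights.sum() <= 0:
        raise ValueError("no site-free space left for unlinked gene placement")
    chrom_weights = chrom_weights / chrom_weights.sum()

    genes: list[GeneAnnotation] = []
    rows = []
    w = design.tss_window
    for i in range(design.n_genes):
        if i < n_dep:
            group, linked = "dependent", design.dependent_linked_classes
        elif i < design.n_responsive:
            group, linked = "independent", design.independent_linked_classes
        else:
            group, linked = "null", ()
        probs = np.array(
            [
                base * (design.enrichment_factor if l in linked else 1.0)
                for l in labels
            ]
        )
        if probs.sum() > 1:
            raise ValueError("class assignment probabilities exceed 1")
        u = rng.random()
        cum = np.cumsum(probs)
        choice = int(np.searchsorted(cum, u))
        gene_id = f"g{i:05d}"
        if choice < len(labels):
            label = labels[choice]
            sites = class_sites[label]
            site = sites.intervals[int(rng.integers(0, len(sites)))]
            tss = int(site.center + rng.integers(-(w - 1), w))
            tss = max(0, min(tss, design.chrom_lengths[site.chrom] - 1))
            chrom = site.chrom
        else:
            label = ""
            ci = int(rng.choice(len(chroms), p=chrom_weights))
            chrom = chroms[ci]
            rs, re = allowed[chrom]
            lens = run_lengths[chrom]
            ri = int(rng.choice(lens.size, p=lens / lens.sum()))
            tss = int(rng.integers(rs[ri], re[ri]))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
        rows.append({"gene_id": gene_id, "group": group, "linked_class": label})
    return GeneTruth(genes=genes, table=pd.DataFrame(rows))


def gen_expression(
    design: SyntheticDesign,
    gene_truth: GeneTruth,
    rng: np.random.Generator | None = None,
) -> ExpressionStudy:
    """2x2 (siRNA x treatment) log2 expression matrix with planted response.

    Responsive genes gain ``effect_size`` under estrogen; for dependent genes
    the gain is abolished in the knockdown arm.  Detection flags are all true
    by default (the detection filter is exercised separately).
    """
    rng = rng if rng is not None else design.rng(4)
    n = design.n_samples_per_cell
    gene_ids = [g.gene_id for g in gene_truth.genes]
    n_genes = len(gene_ids)
    groups = gene_truth.table.set_index("gene_id").loc[gene_ids, "group"].to_numpy()

    cells = [
        (CTRL, VEHICLE), (CTRL, ESTROGEN),
        (KNOCKDOWN, VEHICLE), (KNOCKDOWN, ESTROGEN),
    ]
    samples = []
    design_rows = []
    for sirna, treatment in cells:
        for r in range(1, n + 1):
            samples.append(f"{sirna}_{treatment}_{r}")
            design_rows.append({"sirna": sirna, "treatment": treatment})
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n_genes)
    mat = np.empty((n_genes, len(samples)))
    responsive = np.isin(groups, ["dependent", "independent"])
    dependent = groups == "dependent"
    for j, sample in enumerate(samples):
        sirna = design_rows[j]["sirna"]
        treatment = design_rows[j]["treatment"]
        mean = baseline.copy()
        if treatment == ESTROGEN:
            gains = responsive & ~(dependent & (sirna == KNOCKDOWN))
            mean[gains] += design.effect_size
        mat[:, j] = mean + rng.normal(0.0, design.noise_sd, size=n_genes)
    return ExpressionStudy(
        matrix=pd.DataFrame(mat, index=gene_ids, columns=samples),
        design=pd.DataFrame(design_rows, index=samples),
    )


# ---------------------------------------------------------------------------
# accessibility track and cohort
# ---------------------------------------------------------------------------

def gen_track(
    design: SyntheticDesign,
    class_sites: Mapping[str, IntervalSet],
    rng: np.random.Generator | None = None,
) -> SignalTrack:
    """Baseline noise plus class-scaled Gaussian openness bumps at site centers."""
    rng = rng if rng is not None else design.rng(5)
    values: dict[str, np.ndarray] = {}
    for chrom, length in design.chrom_lengths.items():
        noise = rng.normal(design.track_baseline, design.track_noise_sd, size=length)
        values[chrom] = np.clip(noise, 0.0, None).astype(np.float32)
    half_support = int(4 * design.bump_sd)
    xs = np.arange(-half_support, half_support + 1)
    bump = np.exp(-0.5 * (xs / design.bump_sd) ** 2).astype(np.float32)
    for label, sites in class_sites.items():
        amp = design.openness_amplitudes.get(label, 0.0)
        if amp == 0.0:
            continue
        for iv in sites:
            vec = values[iv.chrom]
            c = iv.center
            lo = max(0, c - half_support)
            hi = min(vec.size, c + half_support + 1)
            vec[lo:hi] += amp * bump[lo - (c - half_support) : hi - (c - half_support)]
    return SignalTrack({c: v.astype(float) for c, v in values.items()}, bin_width=1)


def gen_cohort(
    design: SyntheticDesign, rng: np.random.Generator | None = None
) -> SurvivalCohort:
    """Cohort whose top expression stratum carries elevated event probability.

    Cumulative event probabilities at years 1/3/5 are 0.4p / 0.7p / p with p
    the stratum's 5-year probability; exponential event times matched to the
    5-year probability support the Kaplan-Meier view (censored at 5 years).
    """
    rng = rng if rng is not None else design.rng(6)
    n = design.cohort_n
    expr = rng.normal(0.0, 1.0, size=n)
    k = max(1, int(n * design.high_fraction))
    high_idx = np.argsort(-expr, kind="stable")[:k]
    p5 = np.full(n, design.event_prob_low)
    p5[high_idx] = design.event_prob_high
    u = rng.random(n)
    rows = []
    for i in range(n):
        status = {}
        for year, frac in ((1, 0.4), (3, 0.7), (5, 1.0)):
            status[f"status_y{year}"] = (
                "event" if u[i] < frac * p5[i] else "event-free"
            )
        if p5[i] > 0:
            rate = -np.log(max(1e-12, 1.0 - p5[i])) / 5.0
            t = float(rng.exponential(1.0 / rate))
        else:
            t = np.inf
        censored = t > 5.0
        rows.append(
            {
                "expression": float(expr[i]),
                **status,
                "time": min(t, 5.0),
                "censored": censored,
            }
        )
    table = pd.DataFrame(rows, index=[f"s{i:04d}" for i in range(n)])
    return SurvivalCohort(table=table)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    design: SyntheticDesign
    genome: dict[str, bytearray]
    pwm: PWM
    motif_truth: pd.DataFrame
    cistromes: CistromeTruth
    gene_truth: GeneTruth
    study: ExpressionStudy
    track: SignalTrack
    cohort: SurvivalCohort

    @property
    def domain(self) -> GenomeDomain:
        return self.design.domain


def generate_all(
    design: SyntheticDesign, with_genome: bool = True, with_track: bool = True
) -> SyntheticDataset:
    """Generate every pipeline input from one design (deterministic per seed)."""
    cistromes = gen_cistromes(design)
    pwm = default_pwm()
    if with_genome:
        genome = gen_genome(design)
        all_sites = IntervalSet(
            [iv for s in cistromes.class_sites.values() for iv in s],
            label="all_sites",
        )
        motif_truth = plant_motifs(
            genome, all_sites, pwm, design.motif_plant_prob, design.rng(7)
        )
    else:
        genome = {}
        motif_truth = pd.DataFrame()
    gene_truth = gen_genes(design, cistromes.class_sites)
    study = gen_expression(design, gene_truth)
    track = (
        gen_track(design, cistromes.class_sites)
        if with_track
        else SignalTrack({}, bin_width=1)
    )
    cohort = gen_cohort(design)
    return SyntheticDataset(
        design=design, genome=genome, pwm=pwm, motif_truth=motif_truth,
        cistromes=cistromes, gene_truth=gene_truth, study=study,
        track=track, cohort=cohort,
    )


def write_truth_sidecars(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Serialise the design and all planted ground truth as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "design.json").write_text(json.dumps(asdict(dataset.design), indent=2))
    if len(dataset.motif_truth):
        dataset.motif_truth.to_csv(outdir / "motif_truth.tsv", sep="\t", index=False)
    dataset.gene_truth.table.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    counts = pd.DataFrame(
        sorted(dataset.cistromes.designed_counts().items()),
        columns=["class", "n_sites"],
    )
    counts.to_csv(outdir / "venn_truth.tsv", sep="\t", index=False)
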