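"""End-to-end orchestration: generate/load inputs, run every stage, report.

The pipeline composes the library stages in dependency order:

    inputs -> motif screen -> overlap significance (GSC) -> Venn partition
           -> TSS radar enrichment -> expression dependency -> accessibility
           profiles -> outcome stratification

and produces a :class:`RunReport` holding every stage's table, headline
scalars, and three qualitative checks that summarise the analysis: whether
knockdown-dependent genes are enriched near PBX1-unique and PBX1&ER-alpha
shared sites, whether openness is greatest at shared sites, and whether
high expressers fare worse.  All randomness flows from one root seed, so a
report is exactly reproducible from its configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import expression as expr
from . import synthetic as syn
from .gsc import GSCParams, gsc_test
from .intervals import read_bed, read_chrom_sizes, subtract_members, write_bed
from .motif import (
    compare_screen_fractions,
    load_fasta,
    read_transfac,
    screen_cistrome,
)
from .outcome import fisher_outcome, km_estimate, read_cohort, signature_association, stratify
from .signal import aggregate_profile, read_wig
from .site_classes import venn_partition
from .synthetic import SyntheticDesign, generate_all, genome_as_strings
from .tss_enrichment import radar_table, read_tss_table

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All stage parameters plus either a synthetic design or input paths."""

    outdir: str | None = None
    seed: int = 0
    design: SyntheticDesign | None = None
    # file inputs (used when design is None)
    era_bed: str | None = None
    foxa1_bed: str | None = None
    pbx1_bed: str | None = None
    genome_fasta: str | None = None
    chrom_sizes: str | None = None
    pwm_file: str | None = None
    tss_table: str | None = None
    expression_prefix: str | None = None
    wig_file: str | None = None
    cohort_file: str | None = None
    # stage parameters (defaults follow the analysis conventions)
    window: int = 20_000
    region_fraction: float = 0.2
    subregion_fraction: float = 0.4
    gsc_samples: int = 500
    alpha: float = 0.01
    var_model: str = "moderated"
    direction: str = "up"
    flank: int = 2_000
    stratify_fraction: float = 0.10
    p_cut: float = 0.01
    or_cut: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.p_cut < 1:
            raise ValueError("significance levels must be in (0, 1)")
        if self.design is None and self.era_bed is None:
            # default run is fully synthetic
            self.design = SyntheticDesign(seed=self.seed)


@dataclass
class RunReport:
    config: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)
    checks: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        payload = {
            "config": self.config,
            "scalars": self.scalars,
            "checks": self.checks,
            "warnings": self.warnings,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=str))


def _config_echo(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    return d


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; any stage failure raises naming the stage."""
    report = RunReport(config=_config_echo(config))
    stage = "inputs"
    try:
        if config.design is not None:
            dataset = generate_all(config.design)
            cistromes = dataset.cistromes.cistromes
            class_sites = dataset.cistromes.class_sites
            genome = genome_as_strings(dataset.genome)
            domain = dataset.domain
            pwm = dataset.pwm
            genes = dataset.gene_truth.genes
            study = dataset.study
            track = dataset.track
            cohort = dataset.cohort
        else:
            dataset = None
            cistromes = {
                "ERa": read_bed(config.era_bed, label="ERa").canonicalized(),
                "FoxA1": read_bed(config.foxa1_bed, label="FoxA1").canonicalized(),
                "PBX1": read_bed(config.pbx1_bed, label="PBX1").canonicalized(),
            }
            class_sites = None
            genome = load_fasta(config.genome_fasta) if config.genome_fasta else None
            domain = (
                read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
            )
            pwm = read_transfac(config.pwm_file) if config.pwm_file else None
            genes = read_tss_table(config.tss_table) if config.tss_table else None
            study = (
                expr.read_study(config.expression_prefix)
                if config.expression_prefix
                else None
            )
            track = read_wig(config.wig_file, domain) if config.wig_file else None
            cohort = read_cohort(config.cohort_file) if config.cohort_file else None

        era, foxa1, pbx1 = (cistromes[k] for k in ("ERa", "FoxA1", "PBX1"))

        # --- motif screen -------------------------------------------------
        stage = "motif_screen"
        if genome is not None and pwm is not None:
            screen_all = screen_cistrome(era, genome, pwm)
            foxa1_independent = subtract_members(era, foxa1)
            screen_indep = screen_cistrome(foxa1_independent, genome, pwm)
            p_diff = compare_screen_fractions(screen_all, screen_indep)
            report.tables["motif_screen"] = pd.DataFrame(
                [
                    {"cistrome": "ERa", "n_peaks": screen_all.n_peaks,
                     "n_with_hit": screen_all.n_with_hit,
                     "fraction": screen_all.fraction},
                    {"cistrome": "ERa_FoxA1_independent",
                     "n_peaks": screen_indep.n_peaks,
                     "n_with_hit": screen_indep.n_with_hit,
                     "fraction": screen_indep.fraction},
                ]
            )
            report.scalars["motif_fraction_era"] = screen_all.fraction
            report.scalars["motif_fraction_fox_independent"] = screen_indep.fraction
            report.scalars["motif_fraction_compare_p"] = p_diff
        else:
            report.warnings.append("motif_screen skipped: no genome/PWM input")

        # --- overlap significance ----------------------------------------
        stage = "gsc"
        if domain is not None:
            params = GSCParams(
                region_fraction=config.region_fraction,
                subregion_fraction=config.subregion_fraction,
                n_samples=config.gsc_samples,
                seed=config.seed + 1,
            )
            res = gsc_test(era, pbx1, domain, params)
            report.tables["gsc"] = pd.DataFrame(
                [
                    {"a": "ERa", "b": "PBX1", "observed_bp": res.observed,
                     "null_mean": res.null_mean, "null_sd": res.null_sd,
                     "z": res.z, "p_value": res.p_value}
                ]
            )
            report.scalars["gsc_z_era_pbx1"] = res.z
            report.scalars["gsc_p_era_pbx1"] = res.p_value
        else:
            report.warnings.append("gsc skipped: no genome domain")

        # --- venn partition ----------------------------------------------
        stage = "venn"
        partition = venn_partition(era, foxa1, pbx1)
        report.tables["venn_era"] = partition.summary("ERa")
        report.tables["venn_pbx1"] = partition.summary("PBX1")
        venn_all = []
        for ref in partition.labels:
            s = partition.summary(ref)
            s.insert(0, "reference", ref)
            venn_all.append(s)
        report.tables["venn_all"] = pd.concat(venn_all, ignore_index=True)
        era_with_pbx1 = sum(
            n for subset, n in partition.counts("ERa").items() if "PBX1" in subset
        )
        report.scalars["era_fraction_overlapping_pbx1"] = era_with_pbx1 / len(era)

        # --- expression dependency ---------------------------------------
        stage = "expression"
        responsive_sets = None
        if study is not None:
            normalized = expr.median_reference_normalize(study)
            filtered = expr.filter_detected(normalized, min_detected_samples=1)
            resp, de_ctrl, de_kd = expr.estrogen_response_analysis(
                filtered, alpha=config.alpha, var_model=config.var_model,
                direction=config.direction,
            )
            resp_both, _, _ = expr.estrogen_response_analysis(
                filtered, alpha=config.alpha, var_model=config.var_model,
                direction="both",
            )
            report.tables["de_ctrl"] = de_ctrl.table.reset_index(names="gene_id")
            report.scalars["n_responsive"] = float(len(resp.responsive_all))
            report.scalars["n_dependent"] = float(len(resp.dependent))
            report.scalars["dependent_fraction"] = resp.dependent_fraction
            report.scalars["dependent_fraction_bidirectional"] = (
                resp_both.dependent_fraction
            )
            responsive_sets = resp
        else:
            report.warnings.append("expression skipped: no study input")

        # --- TSS radar enrichment ----------------------------------------
        stage = "radar"
        if genes is not None and responsive_sets is not None:
            all_ids = {g.gene_id for g in genes}
            null_genes = all_ids - responsive_sets.responsive_all
            radar = radar_table(
                partition,
                {
                    "all_responsive": responsive_sets.responsive_all & all_ids,
                    "dependent": responsive_sets.dependent & all_ids,
                },
                null_genes,
                genes,
                window=config.window,
            )
            report.tables["radar"] = radar
            dep = radar[radar.responsive_set == "dependent"].set_index("class_label")
            linked = ["PBX1", "ERa&PBX1"]
            others = [c for c in dep.index if c not in linked]
            linked_ok = all(
                dep.loc[c, "ratio"] > 1.3 for c in linked if c in dep.index
            )
            ranked = dep["ratio"].dropna().sort_values(ascending=False)
            top_two = set(ranked.index[:2])
            report.checks["dependent_enriched_at_pbx1_classes"] = (
                linked_ok and top_two == set(linked)
            )
            for c in linked:
                if c in dep.index:
                    report.scalars[f"radar_dependent_{c}"] = float(dep.loc[c, "ratio"])
        else:
            report.warnings.append("radar skipped: needs gene annotation and DE")

        # --- accessibility profiles --------------------------------------
        stage = "signal"
        if track is not None and track.values:
            source = class_sites if class_sites is not None else {
                label: partition.class_sites(frozenset(label.split("&")))
                for label in ("FoxA1&PBX1", "PBX1", "FoxA1")
            }
            heights = {}
            rows = []
            for label in ("FoxA1&PBX1", "PBX1", "FoxA1"):
                sites = source.get(label)
                if sites is None or len(sites) == 0:
                    continue
                prof = aggregate_profile(track, sites, flank=config.flank)
                heights[label] = prof.peak_height
                rows.append(
                    {"class": label, "n_sites": prof.n_sites,
                     "peak_height": prof.peak_height}
                )
            report.tables["openness"] = pd.DataFrame(rows)
            if len(heights) == 3:
                report.checks["openness_shared_gt_pbx1_gt_foxa1"] = (
                    heights["FoxA1&PBX1"] > heights["PBX1"] > heights["FoxA1"]
                )
                report.scalars["openness_shared_minus_foxa1"] = (
                    heights["FoxA1&PBX1"] - heights["FoxA1"]
                )
        else:
            report.warnings.append("signal skipped: no track input")

        # --- outcome -------------------------------------------------------
        stage = "outcome"
        if cohort is not None:
            high, low = stratify(cohort, fraction=config.stratify_fraction)
            rows = []
            for year in cohort.years:
                cmp = fisher_outcome(cohort, high, low, year)
                rows.append(dataclasses.asdict(cmp))
            outcome_table = pd.DataFrame(rows)
            report.tables["outcome"] = outcome_table
            last = rows[-1]
            report.scalars["outcome_or_y5"] = last["odds_ratio"]
            report.scalars["outcome_p_y5"] = last["p_value"]
            report.checks["poor_outcome_in_high_expressers"] = (
                last["odds_ratio"] > 1 and last["p_value"] < config.p_cut
            )
            if cohort.has_times:
                sub = cohort.table.loc[high]
                km = km_estimate(sub["time"], sub["censored"])
                report.scalars["km_high_s5"] = km.survival_at(5.0)
                sub = cohort.table.loc[low]
                km = km_estimate(sub["time"], sub["censored"])
                report.scalars["km_low_s5"] = km.survival_at(5.0)
        else:
            report.warnings.append("outcome skipped: no cohort input")

        # --- signature association (planted vs recovered) -----------------
        stage = "signature"
        if dataset is not None and responsive_sets is not None:
            universe = set(dataset.study.matrix.index)
            if responsive_sets.dependent and dataset.gene_truth.dependent:
                assoc = signature_association(
                    responsive_sets.dependent,
                    dataset.gene_truth.dependent,
                    universe,
                    p_cut=config.p_cut,
                    or_cut=config.or_cut,
                )
                report.scalars["signature_or"] = assoc.odds_ratio
                report.scalars["signature_p"] = assoc.p_value
                report.checks["recovered_signature_matches_planted"] = (
                    assoc.significant
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.outdir:
        report.write(config.outdir)
        if config.design is not None and dataset is not None:
            syn.write_truth_sidecars(dataset, Path(config.outdir) / "truth")
            for label, iset in cistromes.items():
                write_bed(iset, Path(config.outdir) / f"{label}.bed")
    return report


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; a ``design:`` mapping becomes a
    :class:`SyntheticDesign`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    design_raw = raw.pop("design", None)
    config = PipelineConfig(**raw)
    if design_raw is not None:
        for key in ("venn_counts", "openness_amplitudes", "chrom_lengths"):
            if key in design_raw and isinstance(design_raw[key], dict):
                design_raw[key] = {str(k): v for k, v in design_raw[key].items()}
        for key in ("dependent_linked_classes", "independent_linked_classes"):
            if key in design_raw:
                design_raw[key] = tuple(design_raw[key])
        config.design = SyntheticDesign(**design_raw)
    return config
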