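# Methods

This note records the models, conventions, parameter choices and known
limitations behind each stage of the package.

## Coordinates and interval algebra

All intervals are BED-convention: 0-based, half-open `[start, end)`.
Two intervals overlap iff they share ≥ 1 bp (`max(starts) < min(ends)`);
book-ended intervals do not overlap. Strand is ignored throughout the
interval algebra (cistromes are unstranded).

Subtraction and intersection are *member-level* by default: whole sites are
kept or removed depending on whether they touch the other set. This matches
how site sets such as "FoxA1-independent ERα binding sites" are defined — a
set of sites, not fragments. A bp-level subtraction (`subtract_bp`) exists
for coverage-style questions. Base-pair counts always operate on sets merged
into non-overlapping runs, so duplicated or overlapping members are never
double-counted.

## Motif model and screening

A PWM stores raw counts; scoring smooths each cell with a pseudocount
(default 1.0), forms per-position frequencies, and scores a window as the
summed log2 odds against the background (uniform by default). `N` bases
contribute 0 bits, so masked sequence neither creates nor destroys hits.
Both strands are scanned; a peak is a hit when ≥ 1 window reaches the
threshold.

The default threshold is matrix-adaptive: the smallest score whose
single-window tail probability under the background model is ≤ 1e-4,
computed by exact dynamic programming over the discretised score
distribution (1 millibit steps). This makes thresholds reproducible and
comparable across matrices without reference to any external tool's hidden
default; absolute screened fractions from other software will differ by
their threshold convention, so cross-cistrome *comparisons* (Fisher exact on
the 2×2 hit table) are the robust statistic.

The bundled `default_pwm()` is a synthetic stand-in — an 8-position matrix
with a TGATTGAT homeodomain-like consensus, counts 30 for the consensus base
and 2 elsewhere. It exists to plant and recover motifs in synthetic data and
is not a database matrix.

## Overlap significance (GSC-style block resampling)

Naive overlap nulls assume independent placement of sites and overstate
significance because regulatory elements cluster. The resampling null here
preserves clustering at a chosen scale: each chromosome is conceptually
divided into a sampling region covering a fraction *R* (default 0.2) tiled
by sub-blocks covering a fraction *S* of the region (default 0.4), giving
translocation blocks of length `R·S·chrom_length`. Each resample applies

1. a uniform circular rotation of the second set's merged runs, and
2. a random permutation of the whole tiles of that block length
   (a sub-block-length remainder tile stays in place; the rotation
   re-phases it every sample),

both of which preserve within-block interval arrangement and total covered
base pairs exactly. A first implementation that translocated blocks to
independent uniform positions was measurably anti-conservative, because
independently placed blocks can land on one another and the merged null set
loses coverage; the measure-preserving scheme calibrates (type-I rate 0.058
over 600 independent 1 Mb replicates at α = 0.05, inside the binomial
band).

The statistic is the marginal base-pair overlap; the p-value is one-sided
for enrichment with the add-one estimator `(1 + #{null ≥ obs})/(n + 1)`,
which cannot return 0 and has granularity `1/(n+1)`. Chromosomes are
resampled independently, so block length scales with chromosome length.
Bonferroni correction (`min(1, m·p)`) is provided for families of
comparisons. This is a *GSC-style* null: it reproduces the published
method's purpose (robustness to genomic clustering, parameterised by the
same -R/-S fractions) with a fully specified algorithm, not a line-for-line
reimplementation of the original software's internal segmentation.

## Venn partitioning

Peak overlap is not transitive, so three-way Venn counts depend on which
factor's members anchor them. Each member of each cistrome is assigned the
label subset of all inputs it overlaps; counts are reported per reference
factor, and summary tables state the reference (ERα by convention for
ERα-centric percentages). Per reference, the classes are provably a
partition: disjoint and exhaustive over that factor's members.

## TSS-window enrichment ("radar" statistic)

A gene is associated with a site class when ≥ 1 site of that class overlaps
the window `[tss − w, tss + w)`, default w = 20 kb, symmetric and
strand-independent. The enrichment ratio for a class is the associated
proportion among responsive genes divided by the associated proportion among
null genes. The proportion (not raw-count) ratio is the default because a
count ratio depends on list sizes and cannot hover near 1 for unequal
lists; a raw-count mode exists behind a flag. Genes associated with several
classes count toward each class independently. Significance per class is a
two-sided Fisher exact test on the 2×2 (responsive/null × with/without
site) — the minimal assumption given only binary association calls.

## Expression analysis

The microarray-style workflow is: log2 matrix → median-reference
normalization → detection filtering → per-gene two-class tests at raw
p < α (default 0.01) → gene sets.

**Normalization.** The reference is the per-gene median across arrays; each
array is shifted by the median (over detected genes) of its difference to
the reference. Because shifting moves the median-reference itself, the
shift is iterated to a fixed point (tolerance 1e-9, geometric convergence);
at the fixed point every array's median difference to the reference of the
returned matrix is zero and the operation is idempotent.

**Per-gene tests.** With 3 replicates per cell, per-gene variance estimates
have 4 degrees of freedom and per-gene t-tests are badly underpowered: at
effect 2.0, sd 0.5, α = 0.01 the Welch test has ≈ 0.43 power and the pooled
test ≈ 0.63. The default is therefore a variance-moderated t-test in the
random-variance/empirical-Bayes tradition standard for array data: a scaled
inverse-χ² prior (d₀, s₀²) is fitted to the per-gene pooled variances by
moment-matching on log variances (trigamma inversion), posterior variances
`(d₀s₀² + d s²)/(d₀ + d)` are used with d₀ + d degrees of freedom, and when
the observed spread of variances does not exceed sampling spread the test
reduces to a common-variance z-test. Under the synthetic generator's
homoscedastic noise this test is calibrated (type-I ≈ 0.009–0.011 at
α = 0.01 over 10 000 null genes) and has ≈ 0.99 power at the planted
effect. `var_model="welch"` and `"pooled"` select the classical tests.
No multiple-testing correction is applied by default, mirroring the raw
p < 0.01 convention; a Benjamini–Hochberg mode exists.

**Dependency.** A control-arm responsive gene is knockdown-dependent when
it is no longer significant in the knockdown arm (loss of significance).
The headline dependent fraction is computed on *induced* (up-regulated)
genes, the usual reading of "induced target genes"; the bidirectional
fraction is also reported. An alternative call — fold-change attenuation
> 50% in the knockdown arm — is available and surfaced separately, since
loss-of-significance and attenuation can disagree near the threshold.
Note the estimated fraction is biased slightly upward relative to the
planted truth (~0.73 recovered for 0.71 planted): false-positive responsive
genes are almost always classified dependent, and power < 1 sends a few
truly independent genes into the dependent set.

**Four-class ANOVA** across the 2×2 design cells (one-way, per gene) is
provided for the "any difference across groups" question; constant genes
get p = 1 by convention.

## Accessibility signal

Tracks are per-chromosome vectors at fixed bin width (WIG fixedStep and
variableStep are read and written; unspecified positions are 0). The
aggregate profile is the mean signal at each bp offset in ±flank (default
2 kb) around site centers, with the floor-midpoint center convention.
Sites whose window would leave the chromosome are dropped and counted, not
zero-padded, so edge effects cannot deflate means. The profile is linear in
the track and mirror-symmetric under coordinate reflection.

## Outcome analysis

Metastasis-free status at fixed follow-ups (1/3/5 years) is binary per
sample; samples with unknown status are dropped per-year (complete-case)
and counted. Strata are the top and bottom `⌊n·fraction⌋` samples by
expression (default 10%; 25% gives the quartile convention), ranked
descending with stable order on ties (warned). The comparison is a
two-sided Fisher exact test; the odds ratio uses the Haldane 0.5 correction
only when a cell is zero, and only for display — never inside the exact p.
Kaplan–Meier curves use the product-limit estimator (lifelines) with
censored samples at risk through their censoring time. Signature
association is a Fisher exact test on the 2×2 overlap of two gene sets in a
stated universe, significant at p < 0.01 and OR > 2.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure each stage measures, on a
scaled-down genome (default three 10 Mb chromosomes, i.i.d. bases at GC
0.41):

* **Cistromes** — designed per-class site counts (200 bp peaks), placed
  with pairwise separation > 2·window so each locus owns its TSS
  neighbourhood; shared-class sites are the identical interval in every
  member cistrome, so designed Venn counts are recovered exactly.
  The default counts scale the real study's structure (~54% of ERα shared
  with PBX1, most ERα also bound by FoxA1).
* **Motifs** — consensus occurrences written at uniform offsets on random
  strands in Bernoulli(0.85)-selected sites (PWM-sampled mode available);
  consensus planting makes planted sites unambiguous hits so threshold
  sensitivity can be tested separately.
* **Genes** — each gene draws one site class (or none): null genes at a
  base rate of 0.1 per class, responsive genes at 2× the base rate for
  their linked classes (dependent genes → PBX1-unique and PBX1&ERα;
  independent responsive genes → the triple class). Linked genes get a TSS
  inside the ±20 kb window of one site of the class; unlinked genes are
  placed outside every site neighbourhood by exact complement sampling, so
  designed association rates hold by construction.
* **Expression** — baseline N(8, 1) per gene, +2.0 log2 under estrogen for
  responsive genes, the gain abolished under knockdown for the planted 71%,
  N(0, 0.5) noise, 3 replicates per cell, detection flags true.
* **Track** — baseline 0.5 with sd-0.2 noise (clipped at 0) plus Gaussian
  bumps (sd 100 bp) at site centers, amplitudes 3.0/2.0/1.0 for
  shared/PBX1-unique/FoxA1-unique classes.
* **Cohort** — 300 samples, N(0,1) expression; the top decile carries
  5-year event probability 0.5 versus 0.1 elsewhere, with cumulative
  year-1/3/5 fractions 0.4p/0.7p/p and exponential event times censored at
  5 years for the KM view.

What it does **not** emulate: read-level noise, peak-calling uncertainty,
mappability or GC structure, probe effects, heteroscedastic gene variances,
correlated genes, linked loci closer than the separation bound, or
covariate-confounded cohorts. Passing tests therefore demonstrate that the
statistics recover planted structure under their own assumptions — not that
those assumptions hold in any particular real dataset.

## Problem sizes and numerical conventions

Default analysis sizes were chosen so a full synthetic run completes in
seconds on one core: ~275 sites across 7 classes, 10 000 genes,
12 arrays, a 30 Mb genome, 500 resamples for the overlap null (add-one
granularity 1/501). Tie-breaks: stable input order for expression ranking;
floor midpoints for site centers; exact-duplicate members collapsed by
canonicalization. Degenerate inputs are flagged rather than silently
propagated: empty sets in the GSC test return p = 1 with a degenerate flag,
zero null-with counts report an infinite ratio with a flag, zero cells use
the Haldane display correction.

## Known limitations

* The GSC-style null is exchangeable-by-construction at one block scale;
  real genomes cluster at many scales, and p-values inherit the add-one
  granularity of the resample count.
* The moderated test assumes variances exchangeable across genes; with
  strongly heteroscedastic data the Welch mode is the conservative choice.
* The loss-of-significance dependency call inherits the threshold effects
  of raw p < 0.01 gene sets; its estimated fraction is upward-biased by
  false-positive responsive genes (quantified above).
* Fisher exact comparisons on small strata are conservative and
  discrete: at event probabilities 0.5 vs 0.1 with 30 per stratum the
  exact two-sided power at α = 0.01 is 0.742 (by enumeration), a bound no
  implementation of this design can exceed.
* Kaplan–Meier pooling across heterogeneous cohorts is not implemented
  beyond per-study analysis with count summation.
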