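# pioneerscan

Integrative cistrome analysis for pioneer-factor studies in regulatory
genomics. The package chains the computations used to establish that a
chromatin-binding factor (here modelled on PBX1 acting alongside FoxA1 at
ERα enhancers in breast cancer cells) behaves as a *pioneer factor*: it
binds before the hormone signal, marks open chromatin, and licenses a
specific estrogen-responsive transcriptional program with prognostic value.

It is a library first — the importable API plus the narrative scripts in
`examples/` are the main interface — with a thin `pioneerscan` command-line
wrapper for the shell-run stages (`run`, `generate`, `screen`, `gsc`,
`venn`, `radar`, `de`, `profile`, `outcome`).

## What it computes

Given three cistromes (ERα, FoxA1, PBX1 as BED intervals), a genome, a
PWM, a gene annotation, a 2×2 siRNA×treatment expression study, an
accessibility track and an outcome cohort, the pipeline produces:

* **Motif screen** — fraction of peaks with a PWM hit. Windows are scored
  as log2-odds, `sum_i log2(p_i(b)/q(b))` with pseudocount-smoothed
  frequencies `p` and background `q`; a peak is a hit when any window on
  either strand reaches a threshold chosen so the per-window background
  tail probability is ≤ 1e-4 (exact DP over the score distribution).
* **Overlap significance (GSC-style)** — observed base-pair overlap of two
  cistromes against a block-resampling null (blocks of
  `R·S·chrom_length`, defaults R = 0.2, S = 0.4) built from a circular
  rotation plus a random permutation of whole tiles, preserving local
  clustering; one-sided add-one p-value `(1 + #{null ≥ obs})/(n + 1)`.
* **Venn partition** — the 7 exclusive membership classes of three
  cistromes under the ≥ 1 bp overlap rule, counted per reference factor.
* **TSS radar enrichment** — for each site class, the proportion of
  responsive genes with a site within ±20 kb of their TSS divided by the
  same proportion among null-list genes, with a Fisher exact p per class.
* **Expression dependency** — median-reference normalization, detection
  filtering, per-gene two-class tests at raw p < 0.01 (variance-moderated
  by default; Welch/pooled available) and a four-class ANOVA; a responsive
  gene is *knockdown-dependent* when its estrogen response is lost under
  siRNA knockdown, and the headline statistic is the dependent fraction of
  induced genes.
* **Accessibility by class** — mean signal profiles around site centers
  per Venn class, and fractions of sites inside called peaks.
* **Outcome** — top/bottom expression deciles compared by Fisher exact
  test on metastasis-free status at 1/3/5-year follow-ups, Kaplan–Meier
  product-limit curves, and gene-signature 2×2 association with the
  conventional p < 0.01, OR > 2 call.

Every stage is exercisable on synthetic data with planted ground truth
(`pioneerscan.synthetic`): designed Venn counts, planted motif rates,
class-linked responsive genes, a planted dependent fraction (default 0.71),
class-ordered openness amplitudes, and expression-linked event
probabilities — all deterministic under one seed.

## Worked example

```sh
python examples/05_expression_dependency.py
```

```
estrogen-induced genes (control arm, p<0.01): 529
still induced under knockdown: 185
knockdown-dependent: 385 (72.8%; planted 71%)
```

The synthetic study plants 500 responsive genes out of 10 000 (log2 effect
2.0, noise sd 0.5, 3 replicates per design cell) and abolishes the estrogen
response under knockdown for 71% of them. The analysis recovers 385 of 529
detected induced genes as knockdown-dependent — 72.8%, within sampling
error of the planted fraction. The remaining examples cover interval
algebra, motif screening, overlap significance (a 30%-sharing design gives
z ≈ 26 against the resampling null while an unrelated cistrome gives
z ≈ 0), the Venn/radar statistics, openness ordering and outcome
stratification; each prints the numbers it computes and what they mean.

The full pipeline is one call:

```python
from pioneerscan import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=0))
print(report.scalars, report.checks)
```

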