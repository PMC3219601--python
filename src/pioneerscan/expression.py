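"""Microarray-style differential expression and knockdown dependency.

The workflow mirrors classic two-colour/bead-array practice: log2 intensity
matrix -> median-reference normalization -> detection filtering -> per-gene
two-class tests at raw p < alpha -> gene sets.  "Estrogen-responsive" genes
are those differing between vehicle (O) and estrogen (E2) within an siRNA
arm; a responsive gene is "knockdown-dependent" when its response is lost in
the knockdown arm.

Per-gene tests with 3 replicates per cell have very few degrees of freedom,
so the default test moderates per-gene variances with an empirical-Bayes
prior fitted across all genes (the random-variance approach standard in
array analysis); plain Welch and pooled-variance t-tests are available via
``var_model``.  No multiple-testing correction is applied by default — gene
sets are defined by the raw p < 0.01 rule — but a Benjamini-Hochberg mode
exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExpressionStudy",
    "DEResult",
    "ResponsiveGenes",
    "median_reference_normalize",
    "filter_detected",
    "two_class_ttest",
    "four_class_anova",
    "dependent_genes",
    "dependent_by_attenuation",
    "estrogen_response_analysis",
]

Cell = tuple[str, str]  # (sirna, treatment)

CTRL = "siCTRL"
KNOCKDOWN = "siPBX1"
VEHICLE = "O"
ESTROGEN = "E2"


@dataclass
class ExpressionStudy:
    """log2 expression matrix (genes x samples) with design and detection flags.

    ``design`` is indexed by sample with columns ``sirna`` and ``treatment``.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    detected: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if not set(self.matrix.columns) <= set(self.design.index):
            raise ValueError("every sample column needs a design row")
        for col in ("sirna", "treatment"):
            if col not in self.design.columns:
                raise ValueError(f"design table lacks column {col!r}")
        if self.detected is None:
            self.detected = pd.DataFrame(
                True, index=self.matrix.index, columns=self.matrix.columns
            )
        if self.detected.shape != self.matrix.shape:
            raise ValueError("detected flags must match the matrix shape")

    def samples_in_cell(self, cell: Cell) -> list[str]:
        sirna, treatment = cell
        mask = (self.design["sirna"] == sirna) & (self.design["treatment"] == treatment)
        return [s for s in self.matrix.columns if s in self.design.index[mask]]

    def cells(self) -> list[Cell]:
        pairs = self.design.loc[list(self.matrix.columns), ["sirna", "treatment"]]
        return sorted(set(map(tuple, pairs.itertuples(index=False))))


@dataclass
class DEResult:
    """Per-gene two-class test: means, difference, t, p, significance call."""

    table: pd.DataFrame  # columns: mean_a, mean_b, diff, t, df, p, significant
    contrast: tuple[Cell, Cell]
    alpha: float
    var_model: str

    def significant_genes(
        self, direction: Literal["both", "up", "down"] = "both"
    ) -> set[str]:
        t = self.table
        mask = t["significant"]
        if direction == "up":
            mask = mask & (t["diff"] > 0)
        elif direction == "down":
            mask = mask & (t["diff"] < 0)
        return set(t.index[mask])

    @property
    def directions(self) -> dict[str, int]:
        return dict(zip(self.table.index, np.sign(self.table["diff"]).astype(int)))


@dataclass
class ResponsiveGenes:
    """Responsive genes under control, under knockdown, and the dependent split."""

    responsive_all: set[str]
    responsive_knockdown: set[str]
    dependent: set[str]
    directions: dict[str, int] = field(default_factory=dict)
    flagged: bool = False

    @property
    def dependent_fraction(self) -> float:
        if not self.responsive_all:
            return float("nan")
        return len(self.dependent) / len(self.responsive_all)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def median_reference_normalize(
    study: ExpressionStudy, tol: float = 1e-9, max_iter: int = 500
) -> ExpressionStudy:
    """Median-reference normalization of log2 intensities.

    The reference is the per-gene median across arrays; each array is
    shifted by the median (over its detected genes) of its gene-by-gene
    difference to the reference, so that afterwards the median difference of
    every array to the reference is zero.  Because shifting the arrays moves
    the median-reference itself, the shift is iterated until the largest
    per-array shift falls below ``tol``; at that fixed point the defining
    property holds for the reference of the returned matrix and a repeated
    application is a no-op (idempotence).
    """
    if study.matrix.shape[1] < 3:
        raise ValueError("median-reference normalization needs >= 3 arrays")
    mat = study.matrix.to_numpy(dtype=float).copy()
    det = study.detected.to_numpy(dtype=bool)
    for j in range(mat.shape[1]):
        if not det[:, j].any():
            raise ValueError(
                f"array {study.matrix.columns[j]!r} has no detected genes"
            )
    for _ in range(max_iter):
        reference = np.median(mat, axis=1)
        shifts = np.array(
            [
                np.median(mat[det[:, j], j] - reference[det[:, j]])
                for j in range(mat.shape[1])
            ]
        )
        mat -= shifts[None, :]
        if np.abs(shifts).max() < tol:
            break
    return ExpressionStudy(
        matrix=pd.DataFrame(mat, index=study.matrix.index, columns=study.matrix.columns),
        design=study.design,
        detected=study.detected.copy(),
        normalized=True,
    )


def filter_detected(study: ExpressionStudy, min_detected_samples: int = 1) -> ExpressionStudy:
    """Drop genes detected in fewer than ``min_detected_samples`` samples."""
    keep = study.detected.sum(axis=1) >= min_detected_samples
    return ExpressionStudy(
        matrix=study.matrix.loc[keep],
        design=study.design,
        detected=study.detected.loc[keep],
        normalized=study.normalized,
    )


# ---------------------------------------------------------------------------
# per-gene tests
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes scaled-inverse-chi2 prior (d0, s0^2) for gene variances.

    Moment-matching on log variances: if s2/s0^2 ~ F(df, d0) then
    Var(log s2) = trigamma(df/2) + trigamma(d0/2).  Returns d0 = inf when the
    observed spread does not exceed the sampling spread (common variance).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2[ok].mean()) if ok.any() else 0.0
    z = np.log(s2[ok])
    evar = float(np.var(z, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2))
    if excess <= 1e-8:
        d0 = np.inf
        log_s0 = float(np.mean(z)) - float(special.digamma(df / 2)) + np.log(df / 2)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            float(np.mean(z))
            - float(special.digamma(df / 2))
            + np.log(df / 2)
            + float(special.digamma(d0 / 2))
            - np.log(d0 / 2)
        )
    return d0, float(np.exp(log_s0))


def two_class_ttest(
    study: ExpressionStudy,
    contrast: tuple[Cell, Cell] = ((CTRL, VEHICLE), (CTRL, ESTROGEN)),
    alpha: float = 0.01,
    var_model: Literal["moderated", "welch", "pooled"] = "moderated",
    fdr: bool = False,
) -> DEResult:
    """Per-gene two-class unpaired t-test between two design cells.

    ``diff`` is mean(cell_b) - mean(cell_a), so with the default contrast a
    positive difference means estrogen-induced.  Genes with zero variance in
    both classes and equal means get p = 1 by convention.
    """
    cell_a, cell_b = contrast
    samples_a = study.samples_in_cell(cell_a)
    samples_b = study.samples_in_cell(cell_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 samples per class")
    xa = study.matrix[samples_a].to_numpy(dtype=float)
    xb = study.matrix[samples_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    diff = mean_b - mean_a
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)

    if var_model == "welch":
        tstat, p = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        df = np.full(diff.shape, float(na + nb - 2))
    elif var_model == "pooled":
        tstat, p = stats.ttest_ind(xb, xa, axis=1, equal_var=True)
        df = np.full(diff.shape, float(na + nb - 2))
    elif var_model == "moderated":
        d = na + nb - 2
        s2 = ((na - 1) * va + (nb - 1) * vb) / d
        d0, s0 = _fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_total = 1e6  # effectively a z-test on the common variance
        else:
            s2_post = (d0 * s0 + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = diff / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        df = np.full(diff.shape, float(df_total))
    else:
        raise ValueError(f"unknown var_model {var_model!r}")

    p = np.asarray(p, dtype=float)
    tstat = np.asarray(tstat, dtype=float)
    degenerate = (va == 0) & (vb == 0)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0) & ~np.isfinite(p)] = 0.0
    tstat[~np.isfinite(tstat)] = 0.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    if fdr:
        from statsmodels.stats.multitest import multipletests

        significant = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        significant = p < alpha
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": diff,
            "t": tstat,
            "df": df,
            "p": p,
            "significant": significant,
        },
        index=study.matrix.index,
    )
    return DEResult(table=table, contrast=contrast, alpha=alpha, var_model=var_model)


def four_class_anova(study: ExpressionStudy, alpha: float = 0.01) -> pd.DataFrame:
    """One-way ANOVA per gene across all four design cells.

    Returns a table with F, p, significant; constant genes get p = 1.
    """
    cells = study.cells()
    if len(cells) != 4:
        raise ValueError(f"expected 4 design cells, found {len(cells)}")
    groups = [
        study.matrix[study.samples_in_cell(cell)].to_numpy(dtype=float)
        for cell in cells
    ]
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >= 2 samples in every design cell")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*groups, axis=1)
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    all_vals = np.hstack(groups)
    constant = np.ptp(all_vals, axis=1) == 0
    p[constant] = 1.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    f = np.nan_to_num(f, nan=0.0)
    return pd.DataFrame(
        {"F": f, "p": p, "significant": p < alpha}, index=study.matrix.index
    )


# ---------------------------------------------------------------------------
# dependency
# ---------------------------------------------------------------------------

def dependent_genes(
    responsive_ctrl: set[str],
    responsive_knockdown: set[str],
    directions: Mapping[str, int] | None = None,
) -> ResponsiveGenes:
    """Knockdown-dependent = responsive under control but not under knockdown."""
    dependent = set(responsive_ctrl) - set(responsive_knockdown)
    return ResponsiveGenes(
        responsive_all=set(responsive_ctrl),
        responsive_knockdown=set(responsive_knockdown),
        dependent=dependent,
        directions=dict(directions or {}),
        flagged=not responsive_ctrl,
    )


def dependent_by_attenuation(
    de_ctrl: DEResult, de_knockdown: DEResult, min_attenuation: float = 0.5
) -> ResponsiveGenes:
    """Alternative dependency call: fold-change attenuated by more than
    ``min_attenuation`` in the knockdown arm, among control-responsive genes."""
    resp = de_ctrl.significant_genes()
    d_ctrl = de_ctrl.table["diff"]
    d_kd = de_knockdown.table["diff"].reindex(d_ctrl.index)
    attenuated = set(
        d_ctrl.index[
            (np.abs(d_kd) < (1.0 - min_attenuation) * np.abs(d_ctrl)).to_numpy()
        ]
    )
    return ResponsiveGenes(
        responsive_all=resp,
        responsive_knockdown=de_knockdown.significant_genes(),
        dependent=resp & attenuated,
        directions=de_ctrl.directions,
        flagged=not resp,
    )


def estrogen_response_analysis(
    study: ExpressionStudy,
    alpha: float = 0.01,
    var_model: Literal["moderated", "welch", "pooled"] = "moderated",
    direction: Literal["both", "up", "down"] = "up",
    ctrl: str = CTRL,
    knockdown: str = KNOCKDOWN,
    vehicle: str = VEHICLE,
    treatment: str = ESTROGEN,
) -> tuple[ResponsiveGenes, DEResult, DEResult]:
    """Full responsive/dependent analysis on one 2x2 study.

    Tests vehicle-vs-treatment within the control arm and within the
    knockdown arm, then splits control-responsive genes by loss of
    significance under knockdown.  ``direction='up'`` (default) restricts to
    treatment-induced genes, the usual reading of an "induced target gene";
    use 'both' for bidirectional response.
    """
    de_ctrl = two_class_ttest(
        study, ((ctrl, vehicle), (ctrl, treatment)), alpha, var_model
    )
    de_kd = two_class_ttest(
        study, ((knockdown, vehicle), (knockdown, treatment)), alpha, var_model
    )
    resp = dependent_genes(
        de_ctrl.significant_genes(direction),
        de_kd.significant_genes(direction),
        de_ctrl.directions,
    )
    return resp, de_ctrl, de_kd


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_study(study: ExpressionStudy, prefix: str | Path) -> None:
    prefix = Path(prefix)
    study.matrix.to_csv(f"{prefix}_matrix.tsv", sep="\t")
    study.design.to_csv(f"{prefix}_design.tsv", sep="\t")
    study.detected.astype(int).to_csv(f"{prefix}_detected.tsv", sep="\t")


def read_study(prefix: str | Path) -> ExpressionStudy:
    prefix = Path(prefix)
    matrix = pd.read_csv(f"{prefix}_matrix.tsv", sep="\t", index_col=0)
    design = pd.read_csv(f"{prefix}_design.tsv", sep="\t", index_col=0)
    detected = pd.read_csv(f"{prefix}_detected.tsv", sep="\t", index_col=0).astype(bool)
    return ExpressionStudy(matrix=matrix, design=design, detected=detected)
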