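"""Expression-stratified outcome analysis.

Patients are ranked by the expression of one gene; the top and bottom
fractions (default 10%, quartile mode available) form high/low strata whose
metastasis-free status at fixed follow-up years (1/3/5) is compared by
two-sided Fisher exact test.  Kaplan-Meier product-limit curves serve the
time-to-event view, and gene-signature association uses a 2x2 overlap table
against a gene universe with the conventional p < 0.01 and OR > 2 call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCohort",
    "StratifiedComparison",
    "KMCurve",
    "SignatureAssociation",
    "stratify",
    "fisher_outcome",
    "km_estimate",
    "signature_association",
    "read_cohort",
    "write_cohort",
]

Status = Literal["event", "event-free", "unknown"]
FOLLOWUP_YEARS = (1, 3, 5)


@dataclass
class SurvivalCohort:
    """Per-sample expression and event-free status at fixed follow-up years.

    ``table`` is indexed by sample id with columns ``expression``,
    ``status_y{1,3,5}`` (values event/event-free/unknown) and optionally
    ``time``/``censored`` for Kaplan-Meier analysis.
    """

    table: pd.DataFrame
    years: tuple[int, ...] = FOLLOWUP_YEARS

    def __post_init__(self) -> None:
        if "expression" not in self.table.columns:
            raise ValueError("cohort table needs an 'expression' column")
        for y in self.years:
            col = f"status_y{y}"
            if col not in self.table.columns:
                raise ValueError(f"cohort table lacks {col!r}")
            bad = ~self.table[col].isin(["event", "event-free", "unknown"])
            if bad.any():
                raise ValueError(f"invalid status values in {col!r}")
        # an event at an earlier follow-up must persist at later ones
        for y_early, y_late in zip(self.years, self.years[1:]):
            early = self.table[f"status_y{y_early}"]
            late = self.table[f"status_y{y_late}"]
            clash = (early == "event") & (late == "event-free")
            if clash.any():
                raise ValueError(
                    f"status inconsistency: event at year {y_early} but "
                    f"event-free at year {y_late}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def has_times(self) -> bool:
        return {"time", "censored"} <= set(self.table.columns)


@dataclass(frozen=True)
class StratifiedComparison:
    year: int
    n_high: int
    events_high: int
    n_low: int
    events_low: int
    odds_ratio: float
    p_value: float
    n_unknown_dropped: int = 0
    or_corrected: bool = False  # Haldane 0.5 applied for display OR


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray  # S(t) just after each time, non-increasing
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class SignatureAssociation:
    overlap: int
    n_a: int
    n_b: int
    n_universe: int
    odds_ratio: float
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def stratify(
    cohort: SurvivalCohort, fraction: float = 0.10
) -> tuple[list[str], list[str]]:
    """Split samples into (high, low) expression strata of size floor(n*fraction).

    Ranking is by expression descending; ties fall back to stable input
    order with a warning.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(cohort)
    k = int(n * fraction)
    if k < 1 or n < 2 * k:
        raise ValueError(f"cohort of {n} too small for fraction {fraction}")
    expr = cohort.table["expression"]
    if expr.duplicated().any():
        boundary_sensitive = expr.sort_values(ascending=False, kind="stable")
        if (
            boundary_sensitive.iloc[k - 1] == boundary_sensitive.iloc[k]
            or boundary_sensitive.iloc[-k] == boundary_sensitive.iloc[-k - 1]
        ):
            warnings.warn(
                "expression ties at a stratum boundary; split is by stable "
                "input order",
                stacklevel=2,
            )
    order = expr.sort_values(ascending=False, kind="stable").index
    return list(order[:k]), list(order[-k:][::-1])


def fisher_outcome(
    cohort: SurvivalCohort,
    high: Sequence[str],
    low: Sequence[str],
    year: int,
) -> StratifiedComparison:
    """Two-sided Fisher exact comparison of event rates at one follow-up year.

    Samples with unknown status are dropped (complete-case) and counted.
    The odds ratio uses the Haldane 0.5 correction only when a cell is zero,
    and only for display; the exact p never uses the correction.
    """
    col = f"status_y{year}"
    if col not in cohort.table.columns:
        raise ValueError(f"no follow-up at year {year}")
    status = cohort.table[col]

    def tally(ids: Sequence[str]) -> tuple[int, int, int]:
        s = status.loc[list(ids)]
        return (
            int((s == "event").sum()),
            int((s == "event-free").sum()),
            int((s == "unknown").sum()),
        )

    ev_h, free_h, unk_h = tally(high)
    ev_l, free_l, unk_l = tally(low)
    if ev_h + free_h == 0 or ev_l + free_l == 0:
        raise ValueError("a stratum is empty after dropping unknown statuses")
    table = [[ev_h, free_h], [ev_l, free_l]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    corrected = 0 in (ev_h, free_h, ev_l, free_l)
    if corrected:
        a, b, c, d = ev_h + 0.5, free_h + 0.5, ev_l + 0.5, free_l + 0.5
    else:
        a, b, c, d = ev_h, free_h, ev_l, free_l
    return StratifiedComparison(
        year=year,
        n_high=ev_h + free_h,
        events_high=ev_h,
        n_low=ev_l + free_l,
        events_low=ev_l,
        odds_ratio=(a * d) / (b * c),
        p_value=p,
        n_unknown_dropped=unk_h + unk_l,
        or_corrected=corrected,
    )


def km_estimate(
    times: Sequence[float], censored: Sequence[bool] | None = None
) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``censored[i]`` True means sample i was lost event-free at ``times[i]``;
    censored samples remain at risk through their censoring time.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("event times must be >= 0")
    if censored is None:
        censored = np.zeros(times.shape, dtype=bool)
    observed = ~np.asarray(censored, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    event_times = np.unique(times[observed])
    surv = np.array([float(kmf.predict(t)) for t in event_times])
    at_risk = np.array([int((times >= t).sum()) for t in event_times])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def signature_association(
    sig_a: set[str],
    sig_b: set[str],
    universe: set[str],
    p_cut: float = 0.01,
    or_cut: float = 2.0,
) -> SignatureAssociation:
    """2x2 overlap association of two gene signatures within a universe.

    Significant iff Fisher exact p < ``p_cut`` and odds ratio > ``or_cut``
    (Haldane-corrected for display when a cell is zero).
    """
    if not sig_a or not sig_b:
        raise ValueError("signatures must be non-empty")
    if not (sig_a <= universe and sig_b <= universe):
        raise ValueError("signatures must be subsets of the universe")
    k = len(sig_a & sig_b)
    a, b = k, len(sig_a) - k
    c = len(sig_b) - k
    d = len(universe) - len(sig_a) - len(sig_b) + k
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return SignatureAssociation(
        overlap=k,
        n_a=len(sig_a),
        n_b=len(sig_b),
        n_universe=len(universe),
        odds_ratio=float(odds),
        p_value=p,
        significant=p < p_cut and odds > or_cut,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path) -> SurvivalCohort:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalCohort(table=table)


def write_cohort(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t")
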