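"""Stratification, Fisher outcome comparison, Kaplan-Meier, signature overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pioneerscan.outcome import (
    SurvivalCohort,
    fisher_outcome,
    km_estimate,
    read_cohort,
    signature_association,
    stratify,
    write_cohort,
)

from conftest import hypergeom_two_sided_p


def make_cohort(expr, statuses_y5=None, times=None, censored=None):
    n = len(expr)
    y5 = statuses_y5 if statuses_y5 is not None else ["event-free"] * n
    table = pd.DataFrame(
        {
            "expression": expr,
            "status_y1": ["event-free"] * n,
            "status_y3": ["event-free"] * n,
            "status_y5": y5,
        },
        index=[f"s{i}" for i in range(n)],
    )
    if times is not None:
        table["time"] = times
        table["censored"] = censored
    return SurvivalCohort(table=table)


class TestStratify:
    def test_decile_split_sizes(self, rng):
        cohort = make_cohort(rng.normal(size=100))
        high, low = stratify(cohort, 0.10)
        assert len(high) == len(low) == 10
        expr = cohort.table["expression"]
        assert min(expr[high]) > max(expr[low])

    def test_quartile_mode(self, rng):
        cohort = make_cohort(rng.normal(size=100))
        high, low = stratify(cohort, 0.25)
        assert len(high) == len(low) == 25

    def test_all_equal_warns_and_is_deterministic(self):
        cohort = make_cohort(np.zeros(40))
        with pytest.warns(UserWarning):
            high1, low1 = stratify(cohort, 0.25)
        with pytest.warns(UserWarning):
            high2, low2 = stratify(cohort, 0.25)
        assert high1 == high2 and low1 == low2

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            stratify(make_cohort(np.arange(5.0)), 0.10)

    def test_status_consistency_enforced(self):
        table = pd.DataFrame(
            {
                "expression": [1.0],
                "status_y1": ["event"],
                "status_y3": ["event-free"],
                "status_y5": ["event"],
            },
            index=["s0"],
        )
        with pytest.raises(ValueError):
            SurvivalCohort(table=table)


class TestFisherOutcome:
    def _cohort_with_events(self, events_high, events_low, n=10):
        expr = np.concatenate([np.arange(n) + 100.0, np.arange(n)])
        status = (
            ["event"] * events_high + ["event-free"] * (n - events_high)
            + ["event"] * events_low + ["event-free"] * (n - events_low)
        )
        return make_cohort(expr, statuses_y5=status)

    def test_p_matches_enumeration_oracle(self):
        cohort = self._cohort_with_events(8, 1)
        high, low = stratify(cohort, 0.5)
        cmp = fisher_outcome(cohort, high, low, 5)
        assert cmp.p_value == pytest.approx(
            hypergeom_two_sided_p(8, 2, 1, 9), rel=1e-9
        )
        assert cmp.p_value == pytest.approx(
            stats.fisher_exact([[8, 2], [1, 9]])[1], rel=1e-12
        )

    def test_identical_rates_or_one_p_one(self):
        cohort = self._cohort_with_events(4, 4)
        high, low = stratify(cohort, 0.5)
        cmp = fisher_outcome(cohort, high, low, 5)
        assert cmp.odds_ratio == pytest.approx(1.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected(self):
        cohort = self._cohort_with_events(6, 0)
        high, low = stratify(cohort, 0.5)
        cmp = fisher_outcome(cohort, high, low, 5)
        assert cmp.or_corrected and np.isfinite(cmp.odds_ratio)
        assert cmp.odds_ratio == pytest.approx((6.5 * 10.5) / (4.5 * 0.5))

    def test_or_inverts_under_group_swap(self):
        cohort = self._cohort_with_events(7, 2)
        high, low = stratify(cohort, 0.5)
        fwd = fisher_outcome(cohort, high, low, 5)
        rev = fisher_outcome(cohort, low, high, 5)
        assert fwd.odds_ratio == pytest.approx(1.0 / rev.odds_ratio)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_unknowns_dropped_and_counted(self):
        cohort = self._cohort_with_events(5, 1)
        cohort.table.loc["s0", ["status_y1", "status_y3", "status_y5"]] = "unknown"
        high, low = stratify(cohort, 0.5)
        cmp = fisher_outcome(cohort, high, low, 5)
        assert cmp.n_unknown_dropped == 1
        assert cmp.n_high == 9

    def test_exact_power_against_enumeration(self, rng):
        """Empirical detection rate at 0.5 vs 0.1 (n=30) agrees with the exact
        enumeration of the two binomials (which puts it near 0.74)."""
        exact = 0.0
        for a in range(31):
            pa = stats.binom.pmf(a, 30, 0.5)
            for b in range(31):
                if stats.fisher_exact([[a, 30 - a], [b, 30 - b]])[1] < 0.01:
                    exact += pa * stats.binom.pmf(b, 30, 0.1)
        hits = 0
        reps = 200
        for _ in range(reps):
            eh = rng.binomial(30, 0.5)
            el = rng.binomial(30, 0.1)
            hits += stats.fisher_exact([[eh, 30 - eh], [el, 30 - el]])[1] < 0.01
        rate = hits / reps
        assert abs(rate - exact) < 3 * np.sqrt(exact * (1 - exact) / reps)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([1.0, 2.0, 3.0], censored=[True, True, True])
        assert km.survival_at(10.0) == 1.0

    def test_hand_worked_censored_example(self):
        # n=5: event t=1, censored t=2, event t=3 -> S(3) = (4/5)*(2/3)
        km = km_estimate([1, 2, 3, 4, 5], censored=[False, True, False, True, True])
        assert km.survival_at(3.0) == pytest.approx((4 / 5) * (2 / 3))

    def test_matches_empirical_sf_on_random_uncensored_data(self, rng):
        times = np.round(rng.exponential(2.0, size=40), 3)
        km = km_estimate(times)
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0])


class TestSignatureAssociation:
    def test_identical_signatures_significant(self):
        universe = {f"g{i}" for i in range(1000)}
        sig = {f"g{i}" for i in range(50)}
        assoc = signature_association(sig, sig, universe)
        assert assoc.significant and assoc.odds_ratio > 100

    def test_exact_hypergeometric_oracle(self):
        universe = {f"g{i}" for i in range(10_000)}
        sig_a = {f"g{i}" for i in range(100)}
        sig_b = {f"g{i}" for i in range(70, 170)}  # overlap 30
        assoc = signature_association(sig_a, sig_b, universe)
        assert assoc.overlap == 30
        assert assoc.p_value == pytest.approx(
            hypergeom_two_sided_p(30, 70, 70, 9830), rel=1e-9
        )
        assert assoc.odds_ratio == pytest.approx((30 * 9830) / (70 * 70))

    def test_independent_signatures_calibrated(self, rng):
        universe = list(range(10_000))
        uset = set(universe)
        sig_hits = 0
        reps = 400
        for _ in range(reps):
            a = set(rng.choice(universe, 100, replace=False).tolist())
            b = set(rng.choice(universe, 100, replace=False).tolist())
            k = len(a & b)
            p = hypergeom_two_sided_p(k, 100 - k, 100 - k, 9800 + k)
            assoc = signature_association(a, b, uset, p_cut=0.01, or_cut=0.0)
            sig_hits += assoc.p_value < 0.01
        # discrete Fisher is conservative: rate at or below ~1%
        assert sig_hits / reps < 0.025

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            signature_association({"x"}, {"y"}, {"y"})


class TestCohortIO:
    def test_roundtrip(self, tmp_path, rng):
        cohort = make_cohort(rng.normal(size=20))
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        np.testing.assert_allclose(
            back.table["expression"], cohort.table["expression"]
        )
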