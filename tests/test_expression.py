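"""Normalization, detection filtering, per-gene tests, dependency split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pioneerscan import expression as ex


def make_study(matrix: np.ndarray, n_per_cell: int = 3, detected=None):
    cells = [
        (ex.CTRL, ex.VEHICLE), (ex.CTRL, ex.ESTROGEN),
        (ex.KNOCKDOWN, ex.VEHICLE), (ex.KNOCKDOWN, ex.ESTROGEN),
    ]
    samples, rows = [], []
    for sirna, treat in cells:
        for r in range(n_per_cell):
            samples.append(f"{sirna}_{treat}_{r}")
            rows.append({"sirna": sirna, "treatment": treat})
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    det = None
    if detected is not None:
        det = pd.DataFrame(detected, index=genes, columns=samples)
    return ex.ExpressionStudy(
        matrix=pd.DataFrame(matrix, index=genes, columns=samples),
        design=pd.DataFrame(rows, index=samples),
        detected=det,
    )


class TestNormalization:
    def test_constant_array_shift_removed_and_median_property_holds(self, rng):
        base = rng.normal(8, 1, size=(201, 12))
        shifted = base.copy()
        shifted[:, 3] += 1.7
        study = make_study(shifted)
        normed = ex.median_reference_normalize(study)
        out = normed.matrix.to_numpy()
        # the artificial array offset is removed (up to the overall register)
        np.testing.assert_allclose(out[:, 3] - base[:, 3],
                                   np.full(201, (out[:, 3] - base[:, 3])[0]),
                                   atol=1e-9)
        ref = np.median(out, axis=1)
        for j in range(12):
            assert np.median(out[:, j] - ref) == pytest.approx(0.0, abs=1e-8)

    def test_identical_arrays_unchanged(self):
        mat = np.tile(np.arange(50, dtype=float)[:, None], (1, 12))
        study = make_study(mat)
        normed = ex.median_reference_normalize(study)
        np.testing.assert_allclose(normed.matrix.to_numpy(), mat)

    def test_idempotent(self, rng):
        study = make_study(rng.normal(8, 1, size=(300, 12)))
        once = ex.median_reference_normalize(study)
        twice = ex.median_reference_normalize(once)
        np.testing.assert_allclose(
            twice.matrix.to_numpy(), once.matrix.to_numpy(), atol=1e-10
        )

    def test_all_undetected_array_rejected(self, rng):
        det = np.ones((50, 12), dtype=bool)
        det[:, 2] = False
        study = make_study(rng.normal(size=(50, 12)), detected=det)
        with pytest.raises(ValueError):
            ex.median_reference_normalize(study)


class TestFilterDetected:
    def test_counting_matches_brute_force(self, rng):
        det = rng.random((100, 12)) < 0.5
        study = make_study(rng.normal(size=(100, 12)), detected=det)
        for k in (0, 1, 5, 12):
            kept = ex.filter_detected(study, k)
            assert len(kept.matrix) == int((det.sum(axis=1) >= k).sum())
        assert len(ex.filter_detected(study, 0).matrix) == 100


class TestTwoClassTTest:
    def test_constant_gene_not_responsive(self, rng):
        mat = rng.normal(8, 1, size=(20, 12))
        mat[0] = 5.0
        de = ex.two_class_ttest(make_study(mat))
        assert de.table.loc["g0", "p"] == 1.0
        assert not de.table.loc["g0", "significant"]

    @pytest.mark.parametrize("var_model", ["moderated", "welch", "pooled"])
    def test_planted_effect_detected_all_models(self, rng, var_model):
        mat = rng.normal(8, 0.3, size=(50, 12))
        mat[0, 3:6] += 5.0  # huge estrogen gain in the control arm
        de = ex.two_class_ttest(make_study(mat), var_model=var_model)
        assert de.table.loc["g0", "significant"]
        assert de.table.loc["g0", "diff"] > 0
        assert "g0" in de.significant_genes("up")
        assert "g0" not in de.significant_genes("down")

    def test_responsive_sets_shrink_with_alpha(self, rng):
        mat = rng.normal(8, 0.5, size=(500, 12))
        mat[:50, 3:6] += rng.uniform(0.5, 2.0, size=(50, 3))
        study = make_study(mat)
        sizes = [
            len(ex.two_class_ttest(study, alpha=a).significant_genes())
            for a in (0.05, 0.01, 0.001)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_welch_matches_scipy_per_gene(self, rng):
        mat = rng.normal(8, 1, size=(30, 12))
        de = ex.two_class_ttest(make_study(mat), var_model="welch")
        t, p = stats.ttest_ind(mat[:, 3:6], mat[:, 0:3], axis=1, equal_var=False)
        np.testing.assert_allclose(de.table["p"].to_numpy(), p, rtol=1e-10)

    def test_moderated_near_z_when_variances_common(self, rng):
        """With a shared true variance the prior dominates and the moderated
        statistic approaches the known-variance z-test."""
        sd = 0.5
        mat = rng.normal(8, sd, size=(5000, 12))
        de = ex.two_class_ttest(make_study(mat), var_model="moderated")
        diff = de.table["diff"].to_numpy()
        z = diff / (sd * np.sqrt(2 / 3))
        p_z = 2 * stats.norm.sf(np.abs(z))
        # p-values strongly correlated with the oracle z-test
        assert np.corrcoef(np.log10(de.table["p"] + 1e-12),
                           np.log10(p_z + 1e-12))[0, 1] > 0.95


class TestFourClassAnova:
    def test_shifted_cell_detected_at_closed_form_power(self, rng):
        """Rejection rate for a 3-sigma one-cell shift matches the noncentral
        F oracle within binomial tolerance."""
        n_sim = 800
        sd = 1.0
        mat = rng.normal(8, sd, size=(n_sim, 12))
        mat[:, 9:12] += 3 * sd
        res = ex.four_class_anova(make_study(mat))
        lam = 3 * (3.0 ** 2) * (3 / 4)  # n * sum((mu_i - mu_bar)^2) / sigma^2
        crit = stats.f.ppf(0.99, 3, 8)
        power = stats.ncf.sf(crit, 3, 8, lam)
        rate = res["significant"].mean()
        tol = 3 * np.sqrt(power * (1 - power) / n_sim)
        assert abs(rate - power) < tol

    def test_null_calibration(self, rng):
        mat = rng.normal(8, 1, size=(4000, 12))
        rate = ex.four_class_anova(make_study(mat))["significant"].mean()
        assert 0.005 < rate < 0.016

    def test_constant_gene_p_one(self, rng):
        mat = rng.normal(8, 1, size=(5, 12))
        mat[2] = 3.0
        res = ex.four_class_anova(make_study(mat))
        assert res.loc["g2", "p"] == 1.0


class TestDependency:
    def test_identical_sets_fraction_zero(self):
        r = ex.dependent_genes({"a", "b"}, {"a", "b"})
        assert r.dependent == set() and r.dependent_fraction == 0.0

    def test_empty_knockdown_fraction_one(self):
        r = ex.dependent_genes({"a", "b"}, set())
        assert r.dependent == {"a", "b"} and r.dependent_fraction == 1.0

    def test_empty_responsive_flagged_nan(self):
        r = ex.dependent_genes(set(), {"a"})
        assert r.flagged and np.isnan(r.dependent_fraction)

    def test_attenuation_mode_agrees_on_clean_effects(self, rng):
        mat = rng.normal(8, 0.2, size=(100, 12))
        mat[:20, 3:6] += 3.0          # responsive in control
        mat[10:20, 9:12] += 3.0       # response retained under knockdown
        study = make_study(mat)
        de_c = ex.two_class_ttest(study, ((ex.CTRL, ex.VEHICLE), (ex.CTRL, ex.ESTROGEN)))
        de_k = ex.two_class_ttest(
            study, ((ex.KNOCKDOWN, ex.VEHICLE), (ex.KNOCKDOWN, ex.ESTROGEN))
        )
        by_significance = ex.dependent_genes(
            de_c.significant_genes(), de_k.significant_genes()
        )
        by_attenuation = ex.dependent_by_attenuation(de_c, de_k)
        expected = {f"g{i}" for i in range(10)}
        assert by_significance.dependent == expected
        assert by_attenuation.dependent == expected


class TestStudyIO:
    def test_roundtrip(self, tmp_path, rng):
        study = make_study(rng.normal(size=(20, 12)))
        ex.write_study(study, tmp_path / "toy")
        back = ex.read_study(tmp_path / "toy")
        np.testing.assert_allclose(back.matrix.to_numpy(), study.matrix.to_numpy())
        assert list(back.design.columns) == ["sirna", "treatment"]
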