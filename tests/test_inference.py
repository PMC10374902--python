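"""Tests of Holm correction, partial-correlation associations, group and
condition contrasts, the voxel-wise GLM and score-conditioned reconstruction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connectopy.inference import (
    StatsConfig,
    associate_coefficients,
    fit_coefficient_score_model,
    glm_voxelwise,
    group_ttest,
    holm_correct,
    paired_ttest,
    reconstruct_at_score,
)
from connectopy.trend import TSMModel, build_basis


def holm_reference(pvals, alpha):
    """Independent step-down reference implementation."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rejected = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            rejected[idx] = True
        else:
            break
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted, rejected


class TestHolm:
    def test_worked_example_one_rejection(self):
        """(0.001, 0.02, 0.03, 0.04) at alpha 0.05: thresholds are 0.0125,
        0.0167, 0.025, 0.05, so exactly the first p survives."""
        adjusted, rejected = holm_correct([0.001, 0.02, 0.03, 0.04], alpha=0.05)
        assert rejected.sum() == 1 and rejected[0]

    def test_all_ones(self):
        adjusted, rejected = holm_correct([1.0, 1.0, 1.0], alpha=0.05)
        assert not rejected.any()
        np.testing.assert_allclose(adjusted, 1.0)

    def test_single_pvalue_uncorrected(self):
        adjusted, rejected = holm_correct([0.04], alpha=0.05)
        assert rejected[0] and adjusted[0] == pytest.approx(0.04)

    def test_exhaustive_agreement_with_reference(self):
        """Every subset (sizes 1..4) of a 6-value p grid matches the
        independent step-down reference exactly."""
        grid = [0.001, 0.011, 0.02, 0.031, 0.26, 0.74]
        for size in range(1, 5):
            for combo in itertools.combinations(grid, size):
                adj, rej = holm_correct(list(combo), alpha=0.05)
                adj_ref, rej_ref = holm_reference(list(combo), alpha=0.05)
                np.testing.assert_allclose(adj, adj_ref, atol=1e-12)
                assert np.array_equal(rej, rej_ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_bounded(self, pvals):
        adjusted, rejected = holm_correct(pvals, alpha=0.05)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-12)
        assert np.all((adjusted >= 0) & (adjusted <= 1))
        # rejection iff adjusted p <= alpha
        assert np.array_equal(rejected, adjusted <= 0.05)


class TestAssociateCoefficients:
    def test_score_equal_to_coefficient(self):
        rng = np.random.default_rng(0)
        coeffs = rng.standard_normal((40, 3))
        covs = pd.DataFrame({"age": rng.normal(17, 5, 40)})
        res = associate_coefficients(coeffs, coeffs[:, 1], covariates=covs)
        assert res.loc[1, "partial_r"] == pytest.approx(1.0, abs=1e-8)
        assert res.loc[1, "rejected"]

    def test_score_equal_to_covariate_is_null(self):
        """Residualization removes a score that is purely a covariate."""
        rng = np.random.default_rng(1)
        n = 100
        age = rng.normal(17, 5, n)
        coeffs = rng.standard_normal((n, 4)) + 0.3 * age[:, None]
        res = associate_coefficients(coeffs, age, covariates=pd.DataFrame({"age": age}))
        assert np.all(np.abs(res["partial_r"]) < 2 / np.sqrt(n))
        assert not res["rejected"].any()

    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        coeffs = rng.standard_normal((30, 5))
        score = rng.standard_normal(30)
        res = associate_coefficients(coeffs, score)
        for j in range(5):
            r_ref, p_ref = stats.pearsonr(coeffs[:, j], score)
            assert res.loc[j, "partial_r"] == pytest.approx(r_ref, abs=1e-12)
            assert res.loc[j, "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_missing_scores_dropped_listwise(self):
        rng = np.random.default_rng(3)
        coeffs = rng.standard_normal((25, 2))
        score = rng.standard_normal(25)
        score[[3, 7]] = np.nan
        res = associate_coefficients(coeffs, score)
        assert res["n"].iloc[0] == 23

    def test_planted_effect_survives_holm_others_do_not(self):
        rng = np.random.default_rng(4)
        n = 60
        coeffs = rng.standard_normal((n, 9))
        score = 3.0 * coeffs[:, 2] + 0.5 * rng.standard_normal(n)
        covs = pd.DataFrame({
            "age": rng.normal(17, 5, n),
            "sex": rng.choice(["M", "F"], n),
            "site": rng.choice(["a", "b", "c"], n),
        })
        res = associate_coefficients(coeffs, score, covariates=covs)
        assert res.loc[2, "rejected"]
        assert res.drop(index=2)["rejected"].sum() == 0

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            associate_coefficients(np.random.default_rng(0).standard_normal((20, 2)), np.ones(20))

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(5)
        age = rng.normal(17, 5, 30)
        covs = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(ValueError, match="collinear"):
            associate_coefficients(rng.standard_normal((30, 2)), rng.standard_normal(30), covs)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(6)
        res = associate_coefficients(rng.standard_normal((40, 6)), rng.standard_normal(40))
        assert np.all(res["p_holm"] >= res["p"] - 1e-12)


class TestGroupTtest:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((10, 4))
        res = group_ttest(A, A.copy())
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_large_shift_all_rejected(self):
        """Groups 5 pooled SDs apart at n=30/30: power is ~1 for every term."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((30, 5))
        B = rng.standard_normal((30, 5)) + 5.0
        res = group_ttest(A, B)
        assert res["rejected"].all()
        # closed-form check for one term
        t_ref, p_ref = stats.ttest_ind(A[:, 0], B[:, 0])
        assert res.loc[0, "t"] == pytest.approx(t_ref)

    def test_label_permutation_calibrated(self):
        """Permuting group labels of a null cohort keeps the family-wise
        rejection rate at or below alpha + 2 MC standard errors."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        n_perm, hits = 300, 0
        for _ in range(n_perm):
            perm = rng.permutation(40)
            res = group_ttest(X[perm[:20]], X[perm[20:]])
            hits += res["rejected"].any()
        rate = hits / n_perm
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_perm)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            group_ttest(np.ones((1, 2)), np.ones((5, 2)))

    def test_welch_variant(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((20, 2))
        B = 3 * rng.standard_normal((25, 2)) + 1
        res = group_ttest(A, B, config=StatsConfig(ttest_variant="welch"))
        t_ref, p_ref = stats.ttest_ind(A[:, 0], B[:, 0], equal_var=False)
        assert res.loc[0, "t"] == pytest.approx(t_ref)


class TestPairedTtest:
    def test_equal_conditions_null(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((12, 3))
        res = paired_ttest(A, A.copy())
        np.testing.assert_allclose(res["t"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_constant_shift_zero_variance_errors(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest(A, A + 0.5)

    def test_unmatched_subjects_rejected(self):
        A = np.zeros((4, 2))
        with pytest.raises(ValueError, match="do not match"):
            paired_ttest(A, A, subject_ids=(["a", "b", "c", "d"], ["a", "b", "c", "e"]))

    def test_planted_condition_effect_on_z_terms_only(self):
        """A condition shift planted on the z terms survives Holm there and
        nowhere else."""
        rng = np.random.default_rng(2)
        terms = ["x1", "y1", "z1", "x2", "y2", "z2"]
        rest = pd.DataFrame(rng.standard_normal((40, 6)), columns=terms)
        task = rest + rng.normal(0, 0.1, size=rest.shape)
        task[["z1", "z2"]] += 1.0
        res = paired_ttest(rest, task).set_index("term")
        assert res.loc["z1", "rejected"] and res.loc["z2", "rejected"]
        assert not res.drop(index=["z1", "z2"])["rejected"].any()


class TestGlmVoxelwise:
    def _design(self, rng, n):
        return pd.DataFrame({
            "diagnosis": rng.integers(0, 2, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.normal(17, 5, n),
            "score": rng.normal(70, 10, n),
        })

    def test_duplicated_column_rank_error(self):
        rng = np.random.default_rng(0)
        design = self._design(rng, 30)
        design["score2"] = design["score"]
        with pytest.raises(ValueError, match="rank"):
            glm_voxelwise(rng.standard_normal((30, 10)), design, "score")

    def test_parametric_t_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n, V = 40, 5
        design = self._design(rng, n)
        Y = rng.standard_normal((n, V))
        out = glm_voxelwise(Y, design, "score", method="holm")
        X = sm.add_constant(design[["diagnosis", "sex", "age", "score"]].to_numpy())
        for v in range(V):
            fit = sm.OLS(Y[:, v], X).fit()
            assert out["t"][v] == pytest.approx(fit.tvalues[-1], abs=1e-8)

    def test_null_fwer_calibrated(self):
        """Max-T permutation control: family-wise error across voxels stays
        near alpha over replicate null cohorts."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            design = self._design(rng, 24)
            Y = rng.standard_normal((24, 60))
            out = glm_voxelwise(
                Y, design, "score", config=StatsConfig(n_permutations=200, seed=rep)
            )
            hits += out["significant"].any()
        assert hits / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_planted_effect_localized(self):
        """Effect planted only in high-gradient voxels: at least 80% of
        flagged voxels lie in that stratum."""
        rng = np.random.default_rng(7)
        n, V = 60, 200
        g = np.linspace(0, 1, V)
        design = self._design(rng, n)
        Y = rng.standard_normal((n, V))
        stratum = g > 0.8
        Y[:, stratum] += 0.8 * (design["score"].to_numpy()[:, None] - 70) / 10
        out = glm_voxelwise(Y, design, "score", config=StatsConfig(n_permutations=300, seed=0))
        flagged = np.flatnonzero(out["significant"])
        assert flagged.size > 0
        assert np.mean(stratum[flagged]) >= 0.8


class TestReconstructAtScore:
    def _cohort(self, slope, seed=0, n=50):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, size=(300, 3))
        basis = build_basis(coords, 2)
        terms = basis.terms
        score = rng.normal(70, 5, n)
        coeffs = rng.normal(0, 0.05, size=(n, len(terms)))
        z1 = terms.index("z1")
        coeffs[:, z1] += slope * (score - 70) / 5 + 0.5
        intercepts = np.full(n, 0.5)
        avg = TSMModel(order=2, intercept=0.5, coefficients=coeffs.mean(axis=0),
                       terms=terms, bic=0.0, explained_variance=0.0, residual_ss=0.0)
        model = fit_coefficient_score_model(
            pd.DataFrame(coeffs, columns=terms), score, intercepts=intercepts
        )
        return model, basis, avg, score

    def test_mean_score_reproduces_average(self):
        model, basis, avg, score = self._cohort(slope=0.3)
        profile, maps = reconstruct_at_score(model, [score.mean()], basis, avg)
        from connectopy.trend import reconstruct

        np.testing.assert_allclose(maps[0], reconstruct(avg, basis), atol=1e-8)
        assert profile["rmse"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_planted_coupling_rmse_decreases_toward_mean(self):
        model, basis, avg, score = self._cohort(slope=0.3)
        pts = np.linspace(score.min(), score.mean(), 3)
        profile, _ = reconstruct_at_score(model, pts, basis, avg)
        rmse = profile["rmse"].to_numpy()
        assert rmse[0] > rmse[1] > rmse[2]

    def test_null_coupling_rmse_flat(self):
        model0, basis, avg0, score = self._cohort(slope=0.0, seed=1)
        model1, _, avg1, _ = self._cohort(slope=0.3, seed=1)
        pts = np.linspace(score.min(), score.mean(), 3)
        p0, _ = reconstruct_at_score(model0, pts, basis, avg0)
        p1, _ = reconstruct_at_score(model1, pts, basis, avg1)
        assert p0["rmse"].max() < 0.2 * p1["rmse"].max()

    def test_extrapolation_warns(self):
        model, basis, avg, score = self._cohort(slope=0.3)
        with pytest.warns(RuntimeWarning, match="outside"):
            reconstruct_at_score(model, [score.max() + 50], basis, avg)
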