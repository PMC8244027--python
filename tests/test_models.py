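"""Two-stage residual models: robust fits, orthogonalisation, FDR, suite."""

import numpy as np
import pytest

from rsfavasc.cohort import csf_mean_value
from rsfavasc.factors import CardioHealthFactors, normality_transform
from rsfavasc.cohort import MEASURE_NAMES
from rsfavasc.models import (
    ModelSpec,
    batched_lstsq,
    correlate_residuals_age,
    fdr_bh,
    fit_first_stage,
    orthogonalize_gmv,
    prepare_covariates,
    run_model,
    run_model_suite,
)


def _design(rng, n, p):
    X = rng.standard_normal((n, p))
    X[:, 0] = 1.0
    return X


class TestFirstStage:
    def test_exact_linear_data_zero_residuals(self, rng):
        X = _design(rng, 50, 4)
        beta = rng.standard_normal(4)
        resid, coef = fit_first_stage(X @ beta, X, robust=True)
        assert np.abs(resid).max() < 1e-8
        assert np.allclose(coef, beta, atol=1e-8)

    def test_ols_residuals_orthogonal_to_design(self, rng):
        X = _design(rng, 80, 5)
        y = rng.standard_normal(80)
        resid, _ = fit_first_stage(y, X, robust=False)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_robust_beats_ols_under_gross_outliers(self):
        wins = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = 100
            X = _design(r, n, 3)
            beta = np.array([1.0, 2.0, -1.5])
            y = X @ beta + 0.3 * r.standard_normal(n)
            out = r.choice(n, size=10, replace=False)
            y[out] += r.normal(0, 15, size=10)
            b_rob, _ = batched_lstsq(X, y, robust=True)
            b_ols, _ = batched_lstsq(X, y, robust=False)
            if np.linalg.norm(b_rob - beta) < np.linalg.norm(b_ols - beta):
                wins += 1
        assert wins >= 45

    def test_robust_matches_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        n = 200
        X = _design(rng, n, 4)
        y = X @ np.array([0.5, 1.0, -2.0, 0.3]) + rng.standard_normal(n)
        y[:8] += 12.0
        b_ours, _ = batched_lstsq(X, y, robust=True)
        rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
        assert np.abs(b_ours - rlm.params).max() < 1e-4

    def test_batched_matches_loop(self, rng):
        n, V, p = 60, 30, 4
        Xb = rng.standard_normal((V, n, p))
        Xb[:, :, 0] = 1.0
        Y = rng.standard_normal((n, V))
        Y[:5] += 5.0
        beta, resid = batched_lstsq(Xb, Y, robust=True)
        for v in [0, 7, 29]:
            b1, r1 = batched_lstsq(Xb[v], Y[:, v], robust=True)
            assert np.allclose(beta[v], b1, atol=1e-10)
            assert np.allclose(resid[:, v], r1, atol=1e-10)

    def test_rank_deficient_design_raises(self, rng):
        X = _design(rng, 40, 3)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            fit_first_stage(rng.standard_normal(40), X)

    def test_missing_values_rejected(self, rng):
        X = _design(rng, 40, 3)
        y = rng.standard_normal(40)
        y[0] = np.nan
        with pytest.raises(ValueError, match="missing|non-finite"):
            fit_first_stage(y, X)


class TestOrthogonalizeGmv:
    def test_exact_function_of_cvh_vanishes(self, rng):
        cvh = rng.standard_normal((100, 3))
        gmv = cvh @ rng.standard_normal((3, 4)) + 2.0
        out = orthogonalize_gmv(gmv, cvh)
        assert np.abs(out).max() < 1e-8

    def test_output_orthogonal_to_scores(self, rng):
        cvh = rng.standard_normal((150, 3))
        gmv = rng.standard_normal((150, 5)) + cvh @ rng.standard_normal((3, 5))
        out = orthogonalize_gmv(gmv, cvh)
        cc = (out - out.mean(0)).T @ (cvh - cvh.mean(0))
        assert np.abs(cc).max() < 1e-8

    def test_independent_gmv_unchanged(self, rng):
        cvh = rng.standard_normal((500, 3))
        gmv = rng.standard_normal((500, 4))
        out = orthogonalize_gmv(gmv, cvh)
        for j in range(4):
            assert np.corrcoef(out[:, j], gmv[:, j])[0, 1] >= 0.99


class TestStageTwo:
    def test_residuals_equal_age(self, rng):
        age = rng.uniform(18, 88, 60)
        res = correlate_residuals_age(age.copy(), age)
        assert res.r[0] == pytest.approx(1.0)
        assert res.p[0] < 1e-50

    def test_design_containing_age_zeroes_correlation(self, rng):
        n = 80
        age = rng.uniform(18, 88, n)
        X = np.column_stack([np.ones(n), age, rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        resid, _ = fit_first_stage(y, X, robust=False)
        res = correlate_residuals_age(resid, age)
        assert abs(res.r[0]) < 1e-10

    def test_matches_textbook_formula(self, rng):
        from scipy import stats as sps

        for _ in range(10):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25) + 0.4 * x
            res = correlate_residuals_age(y, x)
            r_ref, p_ref = sps.pearsonr(y, x)
            assert res.r[0] == pytest.approx(r_ref, abs=1e-12)
            assert res.p[0] == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_target_excluded(self, rng):
        age = rng.uniform(18, 88, 40)
        resid = np.column_stack([np.full(40, 2.0), rng.standard_normal(40)])
        res = correlate_residuals_age(resid, age)
        assert res.excluded[0] and not res.excluded[1]
        assert np.isnan(res.r[0])
        assert not res.fdr_mask[0]


class TestFdrBh:
    def _brute_force(self, p, q):
        # literal step-up enumeration
        m = len(p)
        order = np.argsort(p)
        ps = np.asarray(p)[order]
        kmax = 0
        for i in range(1, m + 1):
            if ps[i - 1] <= i * q / m:
                kmax = i
        mask = np.zeros(m, dtype=bool)
        if kmax:
            mask[order[:kmax]] = True
        return mask

    def test_worked_example_all_rejected(self):
        mask, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert mask.all()

    def test_all_ones_none_rejected(self):
        mask, crit = fdr_bh(np.ones(10), q=0.05)
        assert not mask.any() and crit == 0.0

    def test_matches_brute_force_enumeration(self):
        for seed in range(200):
            r = np.random.default_rng(seed)
            m = int(r.integers(1, 40))
            p = r.uniform(0, 1, m) ** r.uniform(0.5, 3)
            mask, _ = fdr_bh(p, q=0.05)
            assert np.array_equal(mask, self._brute_force(p, 0.05))

    def test_empty_vector(self):
        mask, crit = fdr_bh(np.array([]))
        assert mask.size == 0

    def test_false_discovery_rate_controlled_under_null(self):
        # global null: realized FDR (= rejection fraction of any) <= q + margin
        fdr_events = 0
        reps = 300
        for seed in range(reps):
            p = np.random.default_rng(seed).uniform(0, 1, 200)
            mask, _ = fdr_bh(p, q=0.05)
            fdr_events += mask.any()
        assert fdr_events / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestModelSuite:
    @pytest.fixture(scope="class")
    def analysis_inputs(self, desk_cohort):
        spec, subj, truth, maps = desk_cohort
        cvh = normality_transform(subj[MEASURE_NAMES])
        scores = CardioHealthFactors(n_factors=3).fit(cvh).transform(cvh)
        covs = prepare_covariates(
            subj, csf_signal=csf_mean_value(maps["rsfa"], truth.tissue_labels)
        )
        return spec, truth, maps, scores, covs

    def test_model_iv_abolishes_age_effect(self, analysis_inputs):
        spec, truth, maps, scores, covs = analysis_inputs
        results = run_model_suite(
            maps["rsfa"].values, ModelSpec.suite("I,IV"), covs,
            cvh=scores, cbf=maps["cbf"].values, gmv=maps["gmv"].values,
        )
        assert results["I"].n_significant > 50
        assert results["IV"].n_significant == 0

    def test_model_i_discoveries_inside_planted_supports(self, analysis_inputs):
        spec, truth, maps, scores, covs = analysis_inputs
        res = run_model(maps["rsfa"].values, ModelSpec.standard("I"), covs)
        affected = np.zeros(maps["rsfa"].values.shape[1], dtype=bool)
        for j in range(spec.n_sources):
            if abs(truth.age_effect_per_component[j]) > 0.1:
                affected |= truth.support(j, frac=0.02)
        sig = res.fdr_mask
        assert sig.sum() > 0
        assert (sig & affected).sum() / sig.sum() > 0.9

    def test_model_v_with_unrelated_gmv_matches_model_i(self, analysis_inputs):
        spec, truth, maps, scores, covs = analysis_inputs
        rng = np.random.default_rng(0)
        gmv_null = rng.standard_normal(maps["gmv"].values.shape)
        res_i = run_model(maps["rsfa"].values, ModelSpec.standard("I"), covs)
        res_v = run_model(maps["rsfa"].values, ModelSpec.standard("V"), covs,
                          gmv=gmv_null)
        a, b = res_i.fdr_mask, res_v.fdr_mask
        jaccard = (a & b).sum() / max(1, (a | b).sum())
        assert jaccard >= 0.8

    def test_component_level_agrees_with_voxel_level_sign(self, analysis_inputs):
        spec, truth, maps, scores, covs = analysis_inputs
        # component-level: true loadings as targets; strongest component's
        # residual-age correlation has the planted sign
        res = run_model(truth.true_loadings["rsfa"], ModelSpec.standard("I"),
                        covs, level="component")
        j = int(np.argmax(np.abs(truth.age_effect_per_component)))
        assert np.sign(res.r[j]) == np.sign(truth.age_effect_per_component[j])

    def test_robust_flag_off_is_deterministic_ols(self, analysis_inputs):
        spec, truth, maps, scores, covs = analysis_inputs
        a = run_model(maps["rsfa"].values[:, :50], ModelSpec.standard("I", robust=False), covs)
        b = run_model(maps["rsfa"].values[:, :50], ModelSpec.standard("I", robust=False), covs)
        assert np.array_equal(a.r, b.r)

    def test_model_invariants(self):
        spec = ModelSpec.standard("IV")
        assert spec.predictors == ("CBF", "CVH")
        assert ModelSpec.standard("I").predictors == ()
        assert ModelSpec.standard("VI").predictors == ("GMV_orth_CVH",)
        assert ModelSpec.standard("V").needs_csf_covariate
        with pytest.raises(ValueError):
            ModelSpec.standard("VII")
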