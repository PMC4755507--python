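"""Inference layer: Welch t-tests, the per-substrate OLS model against an
independent normal-equations oracle, BH/Bonferroni corrections, fold
changes and kinetic profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from kinaray.diffstats import (
    anova_vs_null,
    bh_fdr,
    bonferroni,
    build_differential_table,
    design_matrix,
    fit_linear_model,
    fit_many,
    fold_change_table,
    kinetic_profile,
    log2_fold_change,
    substrate_ttest,
)
from kinaray.preprocess import IntensityMatrix
from kinaray.synthetic import SimulationDesign, simulate_intensity_matrix, simulate_truth
from tests.conftest import make_samples


def welch_oracle(a, b):
    """Direct evaluation of the Welch statistic and Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestSubstrateTTest:
    def test_identical_groups_null(self):
        r = substrate_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = substrate_ttest([0.0, 0.0], [1.0, 1.0])
        assert r.degenerate and r.pvalue == 0.0

    def test_matches_welch_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 2, rng.integers(2, 8))
            r = substrate_ttest(a, b)
            t, p = welch_oracle(a, b)
            assert r.statistic == pytest.approx(t, abs=1e-10)
            assert r.pvalue == pytest.approx(p, abs=1e-10)

    def test_group_size_precondition(self):
        with pytest.raises(ValueError):
            substrate_ttest([1.0], [1.0, 2.0])


def normal_equations_oracle(X, y):
    """Brute-force OLS: solve X'X b = X'y, classical SEs and t-tests."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(XtX)))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


class TestFitLinearModel:
    def test_noise_free_planted_effect_recovered_exactly(self, noise_free_matrix):
        matrix, truth, _ = noise_free_matrix
        for i, sid in enumerate(matrix.values.index):
            fit = fit_linear_model(matrix.values.loc[sid].to_numpy(),
                                   matrix.samples, substrate_id=sid)
            assert fit.coef("cell[Treg]") == pytest.approx(
                truth.cell_effect[i], abs=1e-10)

    def test_matches_normal_equations_oracle_on_random_designs(self):
        rng = np.random.default_rng(1)
        samples = make_samples()
        X, names, _ = design_matrix(samples)
        for _ in range(100):
            y = rng.normal(10, 1, len(samples))
            fit = fit_linear_model(y, samples)
            beta, se, t, p = normal_equations_oracle(X, y)
            assert np.allclose(fit.params, beta, atol=1e-8)
            assert np.allclose(fit.bse, se, atol=1e-8)
            assert np.allclose(fit.pvalues, p, atol=1e-8)

    def test_missing_values_dropped(self):
        rng = np.random.default_rng(2)
        samples = make_samples()
        y = rng.normal(10, 1, len(samples))
        y[5] = np.nan
        fit = fit_linear_model(y, samples)
        assert fit.df_resid == 23 - 7

    def test_rank_deficiency_names_covariate(self):
        # replicate 2 occurs exactly at time 5, so the two dummies coincide
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "cell_type": ["Treg", "Teff"] * 3,
            "time_min": [0, 0, 5, 5, 15, 15],
            "replicate": [1, 1, 2, 2, 1, 1],
            "slide_id": ["a"] * 6,
        })
        y = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_model(y, samples)

    def test_anova_f_equals_t_squared_for_single_term(self):
        rng = np.random.default_rng(3)
        samples = make_samples()
        for _ in range(10):
            y = rng.normal(0, 1, len(samples))
            fit = fit_linear_model(y, samples)
            t_cell = fit.tvalues[fit.names.index("cell[Treg]")]
            assert fit.anova_F == pytest.approx(t_cell ** 2, rel=1e-10)
            assert fit.anova_p == pytest.approx(
                fit.coef_p("cell[Treg]"), rel=1e-10)

    def test_fit_many_agrees_with_per_substrate_fits(self):
        rng = np.random.default_rng(4)
        samples = make_samples()
        Y = pd.DataFrame(rng.normal(10, 1, (15, len(samples))),
                         index=[f"S{i}" for i in range(15)],
                         columns=list(samples["sample_id"]))
        many = fit_many(Y, samples)
        for sid in Y.index:
            fit = fit_linear_model(Y.loc[sid].to_numpy(), samples)
            for j, name in enumerate(fit.names):
                assert many.loc[sid, f"beta_{name}"] == pytest.approx(
                    fit.params[j], abs=1e-10)
                assert many.loc[sid, f"p_{name}"] == pytest.approx(
                    fit.pvalues[j], abs=1e-10)
            assert many.loc[sid, "anova_F"] == pytest.approx(fit.anova_F,
                                                             rel=1e-10)


class TestAnovaVsNull:
    def test_intercept_only_null_uses_all_terms(self):
        rng = np.random.default_rng(5)
        samples = make_samples()
        y = rng.normal(0, 1, len(samples))
        F1, p1 = anova_vs_null(y, samples, null_model="celltype")
        F2, p2 = anova_vs_null(y, samples, null_model="intercept")
        assert F1 != F2  # different nested comparisons

    def test_bonferroni_attached(self):
        rng = np.random.default_rng(6)
        samples = make_samples()
        y = rng.normal(0, 1, len(samples))
        F, p, bp = anova_vs_null(y, samples, m=850)
        assert bp == pytest.approx(min(1.0, 850 * p))

    def test_unknown_null_model_raises(self):
        samples = make_samples()
        with pytest.raises(ValueError, match="null_model"):
            anova_vs_null(np.zeros(len(samples)), samples, null_model="bogus")


class TestMultipleTesting:
    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_evaluated_step_up(self):
        # q_(i) = min_{j>=i} (4/j) p_(j): all give 0.04
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_ps(self):
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 200)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bh_monotone_and_bounded(self, ps):
        q = bh_fdr(ps)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)  # sorted by p => sorted by q
        assert np.all(q >= np.asarray(ps) - 1e-15)

    @given(st.floats(0, 1), st.integers(1, 10000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bonferroni_cap(self, p, m):
        bp = bonferroni(p, m)
        assert 0 <= bp <= 1
        assert bp == pytest.approx(min(1.0, m * p))

    def test_bonferroni_examples(self):
        assert bonferroni(1e-5, 850) == pytest.approx(8.5e-3)
        assert bonferroni(0.01, 850) == 1.0


class TestFoldChangeAndProfiles:
    def _matrix(self, vals):
        samples = make_samples()
        ids = [f"SUB{i + 1:04d}" for i in range(vals.shape[0])]
        df = pd.DataFrame(vals, index=ids, columns=list(samples["sample_id"]))
        return IntensityMatrix(values=df, samples=samples)

    def test_equal_means_zero_fc(self):
        m = self._matrix(np.full((3, 24), 9.0))
        assert log2_fold_change(m, "SUB0001", 0) == 0.0

    def test_planted_unit_fc(self):
        d = SimulationDesign(n_substrates=5, effect_fraction=1.0,
                             effect_size_log2=1.0, noise_sd=0.0,
                             missing_rate=0.0, seed=0)
        truth = simulate_truth(d)
        m = simulate_intensity_matrix(truth, d)
        for i, sid in enumerate(m.values.index):
            for t in d.time_points_min:
                assert log2_fold_change(m, sid, t) == pytest.approx(
                    truth.cell_effect[i], abs=1e-12)

    def test_hand_computed_difference_of_means(self):
        vals = np.full((1, 24), 5.0)
        m = self._matrix(vals)
        cols = list(m.samples["sample_id"])
        m.values.loc["SUB0001", [c for c in cols if c.startswith("Treg_t0")]] = [6.0, 7.0, 8.0]
        m.values.loc["SUB0001", [c for c in cols if c.startswith("Teff_t0")]] = [5.0, 5.5, 6.0]
        assert log2_fold_change(m, "SUB0001", 0) == pytest.approx(7.0 - 5.5)

    def test_one_side_missing_gives_nan(self):
        vals = np.full((1, 24), 5.0)
        m = self._matrix(vals)
        cols = [c for c in m.samples["sample_id"] if c.startswith("Treg_t0")]
        m.values.loc["SUB0001", cols] = np.nan
        assert np.isnan(log2_fold_change(m, "SUB0001", 0))

    def test_fold_change_table_matches_scalar(self):
        rng = np.random.default_rng(8)
        m = self._matrix(rng.normal(10, 1, (4, 24)))
        fc = fold_change_table(m)
        for sid in m.values.index:
            for t in (0, 5, 15, 60):
                assert fc.loc[sid, f"log2FC_t{t}"] == pytest.approx(
                    log2_fold_change(m, sid, t))

    def test_kinetic_profile_means(self):
        vals = np.full((1, 24), 5.0)
        m = self._matrix(vals)
        cols = [c for c in m.samples["sample_id"] if c.startswith("Treg_t5")]
        m.values.loc["SUB0001", cols] = [1.0, 2.0, 3.0]
        prof = kinetic_profile(m, "SUB0001")
        means = prof["means"].set_index(["cell_type", "time_min"])["mean"]
        assert means[("Treg", 5)] == 2.0
        assert means[("Teff", 5)] == 5.0

    def test_kinetic_profile_mean_over_nonmissing(self):
        vals = np.full((1, 24), 5.0)
        m = self._matrix(vals)
        cols = [c for c in m.samples["sample_id"] if c.startswith("Treg_t5")]
        m.values.loc["SUB0001", cols] = [1.0, np.nan, 3.0]
        prof = kinetic_profile(m, "SUB0001")
        means = prof["means"].set_index(["cell_type", "time_min"])["mean"]
        assert means[("Treg", 5)] == 2.0


class TestDifferentialTable:
    def test_table_shape_ranking_and_bonferroni(self):
        d = SimulationDesign(n_substrates=60, effect_fraction=0.2,
                             noise_sd=0.3, missing_rate=0.0, seed=9)
        truth = simulate_truth(d)
        m = simulate_intensity_matrix(truth, d)
        tbl = build_differential_table(m)
        assert len(tbl) == 60
        assert tbl["p_celltype"].is_monotonic_increasing
        assert np.allclose(tbl["bonferroni_p"],
                           np.minimum(1.0, 60 * tbl["anova_p"]))
        # BH monotone within the cell-type family
        srt = tbl.sort_values("p_celltype")
        assert srt["q_celltype"].is_monotonic_increasing
        # strong planted effects rank ahead of nulls
        top = set(tbl.head(10)["substrate_id"])
        diff_ids = set(np.array(truth.substrate_ids)[truth.is_differential])
        assert len(top & diff_ids) >= 8
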