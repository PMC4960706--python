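import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radpipe.splines import natural_spline_basis
from radpipe.synthetic import SimulationConfig, gen_timecourse
from radpipe.timecourse import (
    classify_early_late,
    fit_spline_model,
    moderated_f_test,
    static_de,
    timecourse_de,
)

from conftest import make_design


def _expr_from_design(design, values_fn, genes=("gA", "gB")):
    data = {
        s: [values_fn(g, row["condition"], row["time_h"], row["replicate"]) for g in genes]
        for s, row in design.iterrows()
    }
    return pd.DataFrame(data, index=list(genes))


class TestFitSplineModel:
    def test_identical_conditions_give_zero_treatment_coefficients(self):
        design = make_design(n_reps=2)
        expr = _expr_from_design(design, lambda g, c, t, r: np.log2(t + 2.0))
        fits = fit_spline_model(expr, design)
        gcols = [c for c in fits.coefficients.columns if c.startswith("g")]
        np.testing.assert_allclose(fits.coefficients[gcols], 0.0, atol=1e-10)
        np.testing.assert_allclose(fits.rss_null, fits.rss_full, atol=1e-10)

    def test_constant_offset_loads_only_on_g0(self):
        design = make_design(n_reps=2)
        expr = _expr_from_design(
            design, lambda g, c, t, r: 5.0 + np.sqrt(t) + (1.0 if c == "treated" else 0.0)
        )
        fits = fit_spline_model(expr, design)
        assert fits.coefficients["g0"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-8)
        for col in ("g1", "g2", "g3"):
            assert fits.coefficients[col].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        design = make_design(timepoints=(1.0, 4.0, 10.0, 24.0), n_reps=2)
        genes = ["g1", "g2"]
        expr = pd.DataFrame(
            rng.normal(7, 1, (2, len(design))), index=genes, columns=design.index
        )
        basis = natural_spline_basis(np.array([1.0, 4.0, 10.0, 24.0]), df=3)
        fits = fit_spline_model(expr, design, basis=basis)
        # oracle: explicit (X'X)^{-1} X'y per gene
        t = design["time_h"].to_numpy(float)
        x = (design["condition"] == "treated").to_numpy(float)
        B = basis.evaluate(t)
        X = np.column_stack([np.ones_like(x), B, x, x[:, None] * B])
        for g in genes:
            y = expr.loc[g].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(
                fits.coefficients.loc[g].to_numpy(), beta, atol=1e-8
            )

    def test_rank_deficient_design_raises(self):
        design = make_design(n_reps=2)
        expr = _expr_from_design(design, lambda g, c, t, r: 1.0)
        design = design.copy()
        design["condition"] = "treated"  # single condition -> collinear with intercept
        with pytest.raises(ValueError):
            fit_spline_model(expr, design)


@pytest.fixture(scope="module")
def fits():
    cfg = SimulationConfig(n_genes=300, prop_de=0.1, seed=21)
    expr, design, _ = gen_timecourse(cfg)
    return fit_spline_model(expr, design)


class TestModeratedF:
    def test_d0_zero_equals_ordinary_f(self, fits):
        table = moderated_f_test(fits, d0=0.0)
        d = fits.df_resid
        F_ord = (fits.rss_null - fits.rss_full) / fits.q / (fits.rss_full / d)
        p_ord = stats.f.sf(F_ord, fits.q, d)
        np.testing.assert_allclose(table["F"], F_ord, atol=1e-10)
        np.testing.assert_allclose(table["p_value"], p_ord, atol=1e-10)

    def test_d0_infinite_pools_variances(self, fits):
        table = moderated_f_test(fits, d0=np.inf, s0_sq=0.05)
        F_pool = (fits.rss_null - fits.rss_full) / fits.q / 0.05
        np.testing.assert_allclose(table["F"], F_pool, atol=1e-10)

    def test_fdr_at_least_p(self, fits):
        table = moderated_f_test(fits)
        assert np.all(table["fdr"] >= table["p_value"] - 1e-15)


class TestTimecourseDE:
    def test_null_pvalues_uniform(self, null_timecourse):
        expr, design, _ = null_timecourse
        table = timecourse_de(expr, design)
        ks = stats.kstest(table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_recovers_truth_with_controlled_fdr(self, small_timecourse):
        expr, design, truth = small_timecourse
        table = timecourse_de(expr, design)
        called = set(table.index[table["de"]])
        sens = len(called & truth.de_genes) / len(truth.de_genes)
        fdr = len(called - truth.de_genes) / max(len(called), 1)
        assert sens >= 0.8
        assert fdr <= 0.1

    def test_single_gene_fdr_equals_p(self, small_timecourse):
        expr, design, _ = small_timecourse
        with pytest.warns(UserWarning):
            table = timecourse_de(expr.iloc[:1], design)
        assert table["fdr"].iloc[0] == pytest.approx(table["p_value"].iloc[0])

    def test_invariant_to_column_permutation_and_gene_shift(self, small_timecourse):
        expr, design, _ = small_timecourse
        base = timecourse_de(expr, design)
        rng = np.random.default_rng(1)
        perm = rng.permutation(expr.columns)
        shifted = expr[perm] + 3.5  # constant shift per gene
        table = timecourse_de(shifted, design)
        np.testing.assert_allclose(base["p_value"], table["p_value"], atol=1e-9)


class TestStaticDE:
    def _groups(self, log2fc, noise_sd=0.01, n=4, n_genes=60, seed=5):
        rng = np.random.default_rng(seed)
        base = rng.normal(7, 1, n_genes)
        A = pd.DataFrame(
            base[:, None] + log2fc + rng.normal(0, noise_sd, (n_genes, n)),
            index=[f"g{i}" for i in range(n_genes)],
        )
        B = pd.DataFrame(
            base[:, None] + rng.normal(0, noise_sd, (n_genes, n)),
            index=[f"g{i}" for i in range(n_genes)],
        )
        return A, B

    def test_boundary_lfc_is_not_flagged(self):
        rng = np.random.default_rng(5)
        # exact binary fractions so group means (over 4 samples) are exact
        B = pd.DataFrame(
            7.0 + rng.integers(-64, 64, (60, 4)) / 1024.0,
            index=[f"g{i}" for i in range(60)],
        )
        A = B + 0.5  # per-gene mean difference exactly 0.5
        table = static_de(A, B)
        np.testing.assert_allclose(table["log2fc"], 0.5, atol=1e-12)
        assert not table["de"].any()  # strict ">" at the 0.5 boundary

    def test_large_fold_change_flagged_up(self):
        # fold change 16.417 (log2 = 4.04) with tiny variance
        A, B = self._groups(np.log2(16.417), noise_sd=0.01)
        table = static_de(A, B)
        assert table["de"].all()
        assert table["fc"].mean() == pytest.approx(16.417, rel=0.01)

    def test_identical_groups_not_flagged(self):
        A, B = self._groups(0.0, noise_sd=0.05)
        table = static_de(A, B)
        assert not table["de"].any()

    def test_too_few_samples_raises(self):
        A, B = self._groups(1.0)
        with pytest.raises(ValueError, match="two samples"):
            static_de(A.iloc[:, :1], B)


class TestEarlyLate:
    def _expr_with_fc(self, fc_by_time):
        design = make_design(n_reps=2)
        def value(g, c, t, r):
            base = 5.0
            if c == "treated":
                return base + np.log2(fc_by_time.get(t, 1.0))
            return base
        return _expr_from_design(design, value, genes=("gX",)), design

    def test_early_only(self):
        expr, design = self._expr_with_fc({7.0: 2.5})
        out = classify_early_late(expr, design, ["gX"])
        assert bool(out.loc["gX", "early"]) and not bool(out.loc["gX", "late"])

    def test_late_only_downregulation(self):
        expr, design = self._expr_with_fc({72.0: 0.4})
        out = classify_early_late(expr, design, ["gX"])
        assert not bool(out.loc["gX", "early"]) and bool(out.loc["gX", "late"])

    def test_boundary_fc_exactly_two_not_flagged(self):
        expr, design = self._expr_with_fc({t: 2.0 for t in (0.25, 2, 7, 12, 24, 48, 72, 96)})
        out = classify_early_late(expr, design, ["gX"])
        assert not bool(out.loc["gX", "early"]) and not bool(out.loc["gX", "late"])

    def test_24h_counts_as_day_one(self):
        expr, design = self._expr_with_fc({24.0: 3.0})
        out = classify_early_late(expr, design, ["gX"])
        assert bool(out.loc["gX", "early"]) and not bool(out.loc["gX", "late"])

    def test_missing_gene_raises(self):
        expr, design = self._expr_with_fc({})
        with pytest.raises(ValueError, match="absent"):
            classify_early_late(expr, design, ["nope"])

    def test_replicate_permutation_invariance(self, small_timecourse):
        expr, design, truth = small_timecourse
        genes = sorted(truth.de_genes)[:10]
        base = classify_early_late(expr, design, genes)
        # shuffle replicate labels within each (condition, time) group
        design2 = design.copy()
        rng = np.random.default_rng(3)
        for (c, t), grp in design2.groupby(["condition", "time_h"]):
            design2.loc[grp.index, "replicate"] = rng.permutation(grp["replicate"].to_numpy())
        out = classify_early_late(expr, design2, genes)
        pd.testing.assert_frame_equal(base, out)
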