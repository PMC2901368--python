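import math

import numpy as np
import pytest
from scipy import stats

from probeanova import (
    f_quantile_diagnostic,
    f_theoretical_df,
    nested_anova_decomposition,
    nested_f_statistic,
    stabilize_rounding,
    simulate_probe_dataset,
    SimulationConfig,
)
from .conftest import make_design
from .oracles import brute_force_nested_ss, reml_f_via_nlme

# fixed 2-treatment x 2-array-per-level x 2-probe integer dataset
TOY_Y = np.array([[4.0, 6.0, 10.0, 12.0], [2.0, 4.0, 9.0, 13.0]])


class TestAnovaDecomposition:
    def test_constant_data_all_ss_zero(self, design_3v3):
        table = nested_anova_decomposition(np.full((3, 6), 7.0), design_3v3)
        for src in ("treatment", "subject", "probe", "interaction", "residual"):
            assert getattr(table, f"ss_{src}") == pytest.approx(0.0, abs=1e-12)

    def test_location_invariance(self, design_3v3, rng):
        y = rng.normal(5, 1, size=(4, 6))
        t1 = nested_anova_decomposition(y, design_3v3)
        t2 = nested_anova_decomposition(y + 17.3, design_3v3)
        for src in ("treatment", "subject", "probe", "interaction", "residual"):
            assert getattr(t1, f"ss_{src}") == pytest.approx(
                getattr(t2, f"ss_{src}"), rel=1e-9, abs=1e-9
            )

    def test_toy_matches_brute_force_oracle(self, design_2v2):
        table = nested_anova_decomposition(TOY_Y, design_2v2)
        oracle = brute_force_nested_ss(TOY_Y, n1=2)
        assert table.ss_treatment == pytest.approx(oracle["treatment"], rel=1e-12)
        assert table.ss_subject == pytest.approx(oracle["subject"], rel=1e-12)
        assert table.ss_probe == pytest.approx(oracle["probe"], rel=1e-12)
        assert table.ss_interaction == pytest.approx(oracle["interaction"], rel=1e-10)
        assert table.ss_residual == pytest.approx(oracle["residual"], rel=1e-10, abs=1e-10)

    def test_ss_partition_and_df_total(self, design_4v4, rng):
        y = rng.normal(0, 1, size=(5, 8))
        table = nested_anova_decomposition(y, design_4v4)
        total = ((y - y.mean()) ** 2).sum()
        assert table.ss_total == pytest.approx(total, rel=1e-8)
        assert table.df_total == y.size - 1

    def test_missing_cells_direct_to_reml(self, design_3v3):
        y = np.random.default_rng(0).normal(size=(3, 6))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="REML"):
            nested_anova_decomposition(y, design_3v3)


class TestFStatistic:
    def test_constant_gene_degenerate_zero(self, design_3v3):
        res = nested_f_statistic(np.full((2, 6), 3.0), design_3v3)
        assert res.degenerate and res.f_statistic == 0.0

    def test_scale_invariance(self, design_3v3, rng):
        y = rng.normal(8, 1, size=(3, 6))
        f1 = nested_f_statistic(y, design_3v3).f_statistic
        f2 = nested_f_statistic(3.0 * y, design_3v3).f_statistic
        assert f2 == pytest.approx(f1, rel=1e-9)

    def test_zero_subject_nonzero_treatment_is_inf_sentinel(self, design_2v2):
        # identical arrays within each level, different means between levels
        y = np.array([[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 5.0, 5.0]])
        res = nested_f_statistic(y, design_2v2)
        assert res.degenerate and math.isinf(res.f_statistic)

    def test_seeded_gene_matches_nlme_reml(self, design_3v3, rng):
        y = (
            5.0
            + np.array([0, 0, 0, 1.0, 1.0, 1.0])[None, :]
            + rng.normal(0, 0.5, 6)[None, :]
            + rng.normal(0, 1.0, 2)[:, None]
            + rng.normal(0, 0.3, (2, 6))
        )
        f_closed = nested_f_statistic(y, design_3v3).f_statistic
        (f_oracle,) = reml_f_via_nlme([(y, 3)])
        assert f_closed == pytest.approx(f_oracle, rel=1e-6)

    def test_internal_reml_engine_agrees_on_balanced(self, design_3v3, rng):
        # subject variation well above residual keeps the REML optimum
        # interior, where the closed-form equivalence holds
        y = rng.normal(6, 0.3, size=(3, 6)) + rng.normal(0, 1.0, 6)[None, :]
        f_closed = nested_f_statistic(y, design_3v3).f_statistic
        res = nested_f_statistic(y, design_3v3, engine="reml", round_digits=None)
        assert res.engine == "reml" and res.converged
        assert res.f_statistic == pytest.approx(f_closed, rel=1e-6)

    def test_reml_engine_handles_missing_cell(self, design_3v3, rng):
        y = rng.normal(6, 1, size=(3, 6)) + rng.normal(0, 0.5, 6)[None, :]
        y[1, 2] = np.nan
        res = nested_f_statistic(y, design_3v3, engine="reml")
        assert np.isfinite(res.f_statistic) and res.f_statistic >= 0

    def test_single_probe_collapses_to_oneway_anova(self, design_3v3):
        y = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = nested_f_statistic(y, design_3v3)
        f_ref, _ = stats.f_oneway(y[0, :3], y[0, 3:])
        assert res.single_probe and not res.degenerate
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-9)
        assert (res.df_num, res.df_den) == (1, 4)

    def test_variance_components_nonnegative(self, design_3v3, rng):
        for _ in range(20):
            y = rng.normal(0, 1, size=(2, 6))
            res = nested_f_statistic(y, design_3v3)
            assert res.var_subject >= 0 and res.var_resid >= 0

    def test_too_few_arrays_rejected(self):
        design = make_design(1, 1)
        with pytest.raises(ValueError, match="at least 3"):
            nested_f_statistic(np.ones((2, 2)), design)


class TestStabilizeRounding:
    def test_rounding_definition_and_fixed_point(self, small_dataset):
        m = small_dataset.probe_matrix
        m1 = stabilize_rounding(m, 5)
        assert np.all(m1.values == np.round(m.values, 5))
        m2 = stabilize_rounding(m1, 5)
        np.testing.assert_array_equal(m2.values, m1.values)

    def test_negative_digits_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            stabilize_rounding(small_dataset.probe_matrix, -1)

    def test_f_perturbation_is_small(self, design_3v3, rng):
        y = rng.normal(6, 1, size=(4, 6))
        f_raw = nested_f_statistic(y, design_3v3).f_statistic
        f_rounded = nested_f_statistic(np.round(y, 5), design_3v3).f_statistic
        assert abs(f_raw - f_rounded) < 1e-3


class TestTheoreticalDf:
    @pytest.mark.parametrize("n,expected", [(4, (1, 6)), (3, (1, 4)), (2, (1, 2))])
    def test_df_values(self, n, expected):
        assert f_theoretical_df(make_design(n, n)) == expected

    def test_null_f_follows_theoretical_df_by_simulation(self, rng):
        # under the null the mean-square ratio must be F(1, N-2): check both
        # candidate denominators, only sum(n_i) - g fits
        design = make_design(4, 4)
        fs = np.empty(4000)
        for i in range(4000):
            y = rng.normal(0, 0.5, 8)[None, :] + rng.normal(0, 0.3, (3, 8))
            fs[i] = nested_f_statistic(y, design).f_statistic
        p_good = stats.kstest(fs, "f", args=(1, 6)).pvalue
        p_bad = stats.kstest(fs, "f", args=(1, 21)).pvalue
        assert p_good > 0.01
        assert p_bad < 1e-3


class TestQuantileDiagnostic:
    def test_f_draws_hug_identity_line(self, rng):
        draws = stats.f.rvs(1, 6, size=3000, random_state=rng)
        theo, emp = f_quantile_diagnostic(draws, (1, 6))
        # compare on the central 95% (extreme quantiles are noisy)
        n = len(theo)
        sl = slice(int(0.02 * n), int(0.95 * n))
        assert np.max(np.abs(theo[sl] - emp[sl]) / (theo[sl] + 0.1)) < 0.25

    def test_constant_statistics(self):
        theo, emp = f_quantile_diagnostic(np.full(20, 2.0), (1, 6))
        assert np.all(emp == 2.0) and len(theo) == 20

    def test_too_few_statistics_rejected(self):
        with pytest.raises(ValueError):
            f_quantile_diagnostic(np.ones(5), (1, 6))
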