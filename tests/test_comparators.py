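import math

import numpy as np
import pytest

from probeanova import (
    EBHyperparams,
    ProbesetExpressionMatrix,
    block_statistic,
    contrast_vector,
    estimate_eb_hyperparams,
    firstp_stat,
    fold_change,
    moderated_t,
    rmanova_stats,
)
from .conftest import make_design
from .oracles import literal_rmanova

TOY_RM = np.array([[1.0, 3.0, 6.0, 8.0], [2.0, 2.0, 7.0, 5.0]])  # 2 probes, 2v2


def _expr(values, design):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ProbesetExpressionMatrix(
        values=values,
        probeset_ids=tuple(f"g{i}" for i in range(values.shape[0])),
        array_ids=design.array_ids,
    )


class TestFoldChange:
    def test_contrast_vector_2v2(self, design_2v2):
        np.testing.assert_allclose(
            contrast_vector(design_2v2), [0.5, 0.5, -0.5, -0.5]
        )

    def test_mean_difference(self, design_2v2):
        e = _expr([[3.0, 3.0, 1.5, 1.5]], design_2v2)
        assert fold_change(e, design_2v2)[0] == pytest.approx(1.5)
        assert fold_change(e, design_2v2, "treatment_minus_control")[0] == pytest.approx(-1.5)

    def test_equal_means_zero(self, design_3v3):
        e = _expr([[2, 3, 4, 4, 3, 2]], design_3v3)
        assert fold_change(e, design_3v3)[0] == pytest.approx(0.0)


class TestRmanova:
    def test_identical_level_medians_zero(self, design_2v2):
        y = np.array([[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 5.0, 6.0]])
        s1, s2 = rmanova_stats(y, design_2v2)
        assert s1 == 0.0 and s2 == 0.0

    def test_scale_free(self, design_2v2):
        s1, s2 = rmanova_stats(TOY_RM, design_2v2)
        d1, d2 = rmanova_stats(2.0 * TOY_RM, design_2v2)
        assert d1 == pytest.approx(s1, rel=1e-12)
        assert d2 == pytest.approx(s2, rel=1e-12)

    def test_toy_matches_literal_transcription(self, design_2v2):
        s1, s2 = rmanova_stats(TOY_RM, design_2v2)
        o1, o2 = literal_rmanova(TOY_RM, n1=2)
        assert s1 == pytest.approx(o1, rel=1e-12)
        assert s2 == pytest.approx(o2, rel=1e-12)

    def test_zero_within_spread_sentinel(self, design_2v2):
        y = np.array([[1.0, 1.0, 2.0, 2.0]])
        s1, s2 = rmanova_stats(y, design_2v2)
        assert math.isinf(s1) and math.isinf(s2)

    def test_constant_gene_degenerates_to_zero(self, design_2v2):
        s1, s2 = rmanova_stats(np.full((2, 4), 3.0), design_2v2)
        assert s1 == 0.0 and s2 == 0.0


class TestFirstp:
    def test_constant_probe_contributes_zero(self, design_3v3):
        y = np.vstack([np.full(6, 2.0), np.full(6, 2.0)])
        assert firstp_stat(y, design_3v3) == 0.0

    def test_degenerate_rules_median_half(self, design_2v2):
        # probe 1 constant (1 - p = 0); probe 2 zero residual, unequal means (1)
        y = np.array([[1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 5.0, 5.0]])
        assert firstp_stat(y, design_2v2) == pytest.approx(0.5)

    def test_bounded_and_null_centred(self, design_3v3, rng):
        stats = []
        for _ in range(300):
            y = rng.normal(0, 1, size=(5, 6))
            s = firstp_stat(y, design_3v3)
            assert 0.0 <= s <= 1.0
            stats.append(s)
        # under the null, per-probe p is uniform, so median(1-p) centres near 0.5
        assert abs(np.mean(stats) - 0.5) < 0.05


class TestEBHyperparams:
    def test_equal_variances_give_infinite_d0(self):
        hp = estimate_eb_hyperparams(np.full(50, 2.0), d=4)
        assert math.isinf(hp.d0)
        assert hp.s0_sq == pytest.approx(2.0, rel=1e-6)

    def test_parameter_recovery(self, rng):
        d0, s0_sq, d = 4.0, 1.0, 2.0
        n = 5000
        # s^2 | sigma^2 ~ sigma^2 chi2_d / d, 1/sigma^2 ~ chi2_d0 / (d0 s0^2)
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, size=n)
        s_sq = sigma_sq * rng.chisquare(d, size=n) / d
        hp = estimate_eb_hyperparams(s_sq, d=d)
        assert abs(hp.d0 - d0) < 1.0
        assert abs(hp.s0_sq - s0_sq) < 0.1

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            estimate_eb_hyperparams(np.array([1.0, 2.0]), d=2)

    def test_matches_r_limma_fitfdist(self, rng):
        import subprocess, tempfile, pathlib

        s_sq = (0.5 + rng.gamma(2.0, 0.7, size=400)) ** 2
        hp = estimate_eb_hyperparams(s_sq, d=4)
        with tempfile.TemporaryDirectory() as tmp:
            tmp = pathlib.Path(tmp)
            np.savetxt(tmp / "s.txt", s_sq)
            (tmp / "f.R").write_text(
                'suppressMessages(library(limma))\n'
                's <- scan("%s")\n'
                'fit <- fitFDist(s, df1=4)\n'
                'cat(fit$scale, fit$df2, sep="\\n")\n' % (tmp / "s.txt")
            )
            out = subprocess.run(
                ["Rscript", "--vanilla", str(tmp / "f.R")],
                check=True, capture_output=True, text=True,
            ).stdout.split()
        s0_ref, d0_ref = float(out[0]), float(out[1])
        assert hp.s0_sq == pytest.approx(s0_ref, rel=1e-3)
        assert hp.d0 == pytest.approx(d0_ref, rel=1e-3)


class TestModeratedT:
    def _fit(self, design, values, hyper):
        return moderated_t(_expr(values, design), design, hyper=hyper)

    def test_d0_zero_equals_ordinary_t(self, design_3v3, rng):
        vals = rng.normal(5, 1, size=(20, 6))
        fit = self._fit(design_3v3, vals, EBHyperparams(d0=1e-12, s0_sq=1.0))
        np.testing.assert_allclose(fit.t_moderated, fit.t_ordinary, rtol=1e-6)

    def test_d0_infinite_pins_variance_to_prior(self, design_3v3, rng):
        vals = rng.normal(5, 1, size=(20, 6))
        fit = self._fit(design_3v3, vals, EBHyperparams(d0=math.inf, s0_sq=0.7))
        np.testing.assert_allclose(fit.s_tilde_sq, 0.7)

    def test_shrinkage_stays_between_variances(self, design_3v3, rng):
        vals = rng.normal(5, 1, size=(50, 6))
        fit = self._fit(design_3v3, vals, EBHyperparams(d0=4.0, s0_sq=1.0))
        lo = np.minimum(fit.s_sq, 1.0)
        hi = np.maximum(fit.s_sq, 1.0)
        assert np.all(fit.s_tilde_sq >= lo - 1e-12)
        assert np.all(fit.s_tilde_sq <= hi + 1e-12)
        assert fit.df_moderated > fit.d

    def test_worked_shrinkage_value(self):
        # beta=1, v=0.5, s^2=2, d=2, d0=4, s0^2=1:
        # s_tilde^2 = (4*1 + 2*2)/6 = 8/6; t = 1/sqrt(0.5 * 8/6) ~ 1.2247
        s_tilde_sq = (4 * 1.0 + 2 * 2.0) / (4 + 2)
        t = 1.0 / math.sqrt(0.5 * s_tilde_sq)
        design = make_design(2, 2)
        # realize s^2 = 2, beta1 = 1 with 2v2 data (v = 1/2 + 1/2 = 1):
        # here v=1, so scale the worked value accordingly
        vals = [[1.0, 3.0, 3.0, 5.0]]  # beta1 = 2, s^2 = 2, d = 2
        fit = self._fit(design, vals, EBHyperparams(d0=4.0, s0_sq=1.0))
        assert fit.s_sq[0] == pytest.approx(2.0)
        assert fit.s_tilde_sq[0] == pytest.approx(s_tilde_sq)
        assert fit.t_moderated[0] == pytest.approx(2.0 / math.sqrt(1.0 * s_tilde_sq))
        assert t == pytest.approx(1.2247, abs=1e-4)

    def test_monotone_in_effect_size(self, design_3v3):
        hyper = EBHyperparams(d0=4.0, s0_sq=1.0)
        base = np.array([1.0, 2.0, 3.0, 0.0, 0.0, 0.0])
        tvals = []
        for beta in (0.5, 1.0, 2.0, 4.0):
            vals = base - np.array([0, 0, 0, beta, beta, beta])
            fit = self._fit(design_3v3, [list(vals)], hyper)
            tvals.append(abs(fit.t_moderated[0]))
        assert np.all(np.diff(tvals) > 0)

    def test_p_values_within_unit_interval(self, design_3v3, rng):
        vals = rng.normal(0, 1, size=(30, 6))
        fit = moderated_t(_expr(vals, design_3v3), design_3v3, hyper="estimate")
        assert np.all((fit.p_value >= 0) & (fit.p_value <= 1))


class TestBlockStatisticInterface:
    @pytest.mark.parametrize("method", ["nfm", "fc", "rmanova1", "rmanova2", "firstp"])
    def test_permutation_equivariance(self, method, design_3v3, rng):
        """Relabelling arrays consistently in data and design leaves stats unchanged."""
        y = rng.normal(5, 1, size=(4, 6))
        stat = block_statistic(method)
        s0 = stat(y, design_3v3)
        perm = rng.permutation(6)
        labels = [design_3v3.labels[j] for j in perm]
        assert stat(y[:, perm], design_3v3.relabelled(labels)) == pytest.approx(
            s0, rel=1e-9
        )

    def test_moderated_t_needs_fixed_hyper(self):
        with pytest.raises(ValueError):
            block_statistic("moderated_t")

    def test_moderated_t_block(self, design_3v3, rng):
        stat = block_statistic("moderated_t", hyper=EBHyperparams(d0=4.0, s0_sq=1.0))
        y = rng.normal(5, 1, size=(3, 6))
        assert stat(y, design_3v3) >= 0.0
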