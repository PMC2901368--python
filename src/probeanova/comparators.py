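"""Comparator test statistics for two-group differential expression.

Alongside the nested-factorial F these provide the reference surface for
benchmarking: the naive log2 fold change (FC), a median-based robustified
MANOVA on probe vectors (RMANOVA1/2), a "first principles" per-probe ANOVA
median statistic (FIRSTP), and the empirical-Bayes moderated t with
variance shrinkage across genes.  All statistics share one ranking
interface: larger absolute value = more evidence of differential
expression, so each plugs into the pooled permutation machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special, stats

from .containers import ProbesetExpressionMatrix, SampleDesign

__all__ = [
    "contrast_vector",
    "fold_change",
    "RMANOVAMatrices",
    "rmanova_matrices",
    "rmanova_stats",
    "firstp_stat",
    "EBHyperparams",
    "estimate_eb_hyperparams",
    "moderated_t",
    "moderated_t_from_components",
    "LimmaFit",
    "block_statistic",
]

#: Sentinel for degenerate ratio statistics (zero within-spread, non-zero
#: between-spread): ranks above every finite value.
RATIO_INFINITE = math.inf


def contrast_vector(design: SampleDesign) -> np.ndarray:
    """Per-array contrast coefficients c: +1/n1 for level 1, -1/n2 for level 2.

    ``c @ expression`` is the log2 fold change, level 1 (control) minus
    level 2 (treatment).
    """
    n1, n2 = design.n_per_level
    idx0, idx1 = design.level_columns()
    c = np.empty(design.n_arrays)
    c[idx0] = 1.0 / n1
    c[idx1] = -1.0 / n2
    return c


def fold_change(
    e: ProbesetExpressionMatrix, design: SampleDesign, direction: str = "control_minus_treatment"
) -> np.ndarray:
    """Per-gene log2 fold change: difference of group mean expressions.

    The ranking statistic is the absolute value, so ``direction`` (the
    sign convention) never affects ROC results.
    """
    c = contrast_vector(design)
    fc = e.values @ c
    if direction == "treatment_minus_control":
        fc = -fc
    elif direction != "control_minus_treatment":
        raise ValueError(f"unknown direction {direction!r}")
    return fc


@dataclass(frozen=True)
class RMANOVAMatrices:
    """Robust between/within error matrices for one gene's probe vectors."""

    W: np.ndarray  # within-treatment error matrix, L x L
    B: np.ndarray  # between-treatment error matrix, L x L
    level_medians: tuple[np.ndarray, np.ndarray]
    overall_median: np.ndarray


def rmanova_matrices(y: np.ndarray, design: SampleDesign) -> RMANOVAMatrices:
    """Median-centred MANOVA error matrices.

    Treating each array's probe intensities as an L-vector ``y_j(i)``, the
    robust centre of treatment level i is the component-wise median
    ``mu_(i)``, and the overall robust centre ``mu`` the component-wise
    median across all arrays.  Then

        W = sum_i sum_{j in i} (y_j(i) - mu_(i)) (y_j(i) - mu_(i))'
        B = sum_i n_i (mu_(i) - mu) (mu_(i) - mu)'

    the within- and between-treatment error matrices of classical MANOVA
    with medians in place of means.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    idx0, idx1 = design.level_columns()
    L = y.shape[0]
    mu_levels = []
    W = np.zeros((L, L))
    B = np.zeros((L, L))
    mu = np.median(y, axis=1)
    for idx in (idx0, idx1):
        block = y[:, idx]
        mu_i = np.median(block, axis=1)
        mu_levels.append(mu_i)
        dev = block - mu_i[:, None]
        W += dev @ dev.T
        d = mu_i - mu
        B += len(idx) * np.outer(d, d)
    return RMANOVAMatrices(
        W=W, B=B, level_medians=(mu_levels[0], mu_levels[1]), overall_median=mu
    )


def rmanova_stats(y: np.ndarray, design: SampleDesign) -> tuple[float, float]:
    """The two robustified-MANOVA ratio statistics for one gene.

    Both compare between-treatment to within-treatment error, in the spirit
    of a one-way ANOVA F but on the whole probe vector:

        RMANOVA1 = tr(B) / tr(W)
        RMANOVA2 = median_l ( B_ll / W_ll )    (component-wise median)

    Both are non-negative and scale-free (numerator and denominator are
    quadratic in the data).  When the within-treatment spread is zero in
    every component the ratios are undefined: the statistics degenerate to
    0 if B is also zero, else to the ``+inf`` sentinel.  Component ratios
    with ``W_ll = 0`` follow the same rule inside the median.
    """
    mats = rmanova_matrices(y, design)
    trW = float(np.trace(mats.W))
    trB = float(np.trace(mats.B))
    if trW == 0.0:
        stat1 = 0.0 if trB == 0.0 else RATIO_INFINITE
    else:
        stat1 = trB / trW
    b_diag = np.diag(mats.B)
    w_diag = np.diag(mats.W)
    ratios = np.empty(len(b_diag))
    for l, (b, w) in enumerate(zip(b_diag, w_diag)):
        if w == 0.0:
            ratios[l] = 0.0 if b == 0.0 else RATIO_INFINITE
        else:
            ratios[l] = b / w
    return stat1, float(np.median(ratios))


def firstp_stat(y: np.ndarray, design: SampleDesign) -> float:
    """"First principles" statistic: median over probes of (1 - p_l).

    Each probe gets a one-way ANOVA p-value ``p_l`` for equal treatment
    means.  Probes constant across all arrays carry no evidence and are
    reset to ``p_l = 1``; probes with zero residual variance but unequal
    group means carry maximal evidence, ``p_l = 0``.  The gene statistic
    is the median of ``1 - p_l`` over probes and lies in [0, 1]; larger
    means more evidence of differential expression.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    idx0, idx1 = design.level_columns()
    one_minus_p = np.empty(y.shape[0])
    for l in range(y.shape[0]):
        a, b = y[l, idx0], y[l, idx1]
        if np.ptp(y[l]) == 0.0:
            one_minus_p[l] = 0.0  # constant probe: p_l reset to 1
            continue
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if ss_within == 0.0:
            # zero residual variance with unequal means: maximal evidence
            one_minus_p[l] = 1.0
            continue
        df1 = 1
        df2 = len(a) + len(b) - 2
        ss_between = (
            len(a) * (a.mean() - y[l].mean()) ** 2
            + len(b) * (b.mean() - y[l].mean()) ** 2
        )
        f = (ss_between / df1) / (ss_within / df2)
        one_minus_p[l] = 1.0 - float(stats.f.sf(f, df1, df2))
    return float(np.median(one_minus_p))


@dataclass(frozen=True)
class EBHyperparams:
    """Hyperparameters of the scaled-inverse-chi-square variance prior.

    ``d0`` is the prior degrees of freedom (``inf`` when the gene-level
    variances show no dispersion beyond sampling noise) and ``s0_sq`` the
    prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone map)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_eb_hyperparams(s_sq: np.ndarray, d: float | np.ndarray) -> EBHyperparams:
    """Moment estimation of (d0, s0^2) from per-gene sample variances.

    Under the hierarchical model, ``s_k^2`` follows a scaled F distribution,
    and ``log s_k^2`` has closed-form mean and variance in terms of digamma
    and trigamma functions.  Matching the empirical moments of ``log s^2``
    yields ``d0`` (via the inverse trigamma) and ``s0^2``.  When the
    empirical dispersion of ``log s^2`` does not exceed its theoretical
    sampling floor, ``d0 = inf`` and ``s0^2`` is the (geometric-mean based)
    common variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s_sq.shape)
    ok = (d >= 1) & (s_sq >= 0)
    s_sq, d = s_sq[ok], d[ok]
    if len(s_sq) < 10:
        raise ValueError("need at least 10 genes with positive df")
    if np.all(s_sq == 0):
        raise ValueError("all gene variances are zero")
    # offset exact zeros as in standard practice (log of zero variance)
    floor = s_sq[s_sq > 0].min() * 1e-8
    z = np.log(np.maximum(s_sq, floor))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(
        np.mean(special.polygamma(1, d / 2.0))
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        # no dispersion beyond sampling noise: common variance, infinite prior df
        d0 = math.inf
        s0_sq = float(np.mean(s_sq))
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_t_from_components(
    beta1: np.ndarray | float,
    v: float,
    s_sq: np.ndarray | float,
    d: float,
    hyper: EBHyperparams,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior variance, moderated t, and its df from summary components.

    ``beta1`` is the effect estimate with unscaled variance ``v`` and
    residual variance ``s_sq`` on ``d`` degrees of freedom.  Returns
    ``(s_tilde_sq, t_moderated, df_moderated)`` with

        s_tilde_sq = (d0 s0^2 + d s^2) / (d0 + d)
        t_moderated = beta1 / sqrt(v s_tilde_sq)
    """
    beta1 = np.asarray(beta1, dtype=float)
    s_sq = np.asarray(s_sq, dtype=float)
    if math.isinf(hyper.d0):
        s_tilde_sq = np.broadcast_to(hyper.s0_sq, s_sq.shape).astype(float)
        df_mod = math.inf
    else:
        s_tilde_sq = (hyper.d0 * hyper.s0_sq + d * s_sq) / (hyper.d0 + d)
        df_mod = hyper.d0 + d
    t_mod = beta1 / np.sqrt(v * s_tilde_sq)
    return s_tilde_sq, t_mod, df_mod


@dataclass
class LimmaFit:
    """Per-gene quantities of the moderated-t fit (arrays over genes)."""

    beta1: np.ndarray
    s_sq: np.ndarray
    d: float
    v: float
    t_ordinary: np.ndarray
    s_tilde_sq: np.ndarray
    t_moderated: np.ndarray
    df_moderated: float
    p_value: np.ndarray
    hyper: EBHyperparams


def moderated_t(
    e: ProbesetExpressionMatrix,
    design: SampleDesign,
    hyper: EBHyperparams | str = "estimate",
) -> LimmaFit:
    """Empirical-Bayes moderated t-statistic per gene.

    Each gene is fit by least squares with a treatment dummy (control = 0,
    treatment = 1), giving the effect ``beta1`` with unscaled variance
    ``v = 1/n1 + 1/n2``, residual variance ``s_k^2`` on ``d = N - 2``
    degrees of freedom, and the ordinary ``t = beta1 / sqrt(v s^2)``.  The
    posterior variance shrinks each ``s_k^2`` toward the prior ``s0^2``:

        s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)

    and the moderated ``t_tilde = beta1 / sqrt(v s_tilde^2)`` is referred
    to a t distribution on ``d0 + d`` degrees of freedom.
    """
    n1, n2 = design.n_per_level
    N = design.n_arrays
    d = float(N - 2)
    if d < 1:
        raise ValueError("need at least 3 arrays for a residual df >= 1")
    idx0, idx1 = design.level_columns()
    mean0 = e.values[:, idx0].mean(axis=1)
    mean1 = e.values[:, idx1].mean(axis=1)
    beta1 = mean1 - mean0  # treatment minus control under dummy coding
    rss = ((e.values[:, idx0] - mean0[:, None]) ** 2).sum(axis=1) + (
        (e.values[:, idx1] - mean1[:, None]) ** 2
    ).sum(axis=1)
    s_sq = rss / d
    v = 1.0 / n1 + 1.0 / n2

    if isinstance(hyper, str):
        if hyper != "estimate":
            raise ValueError(f"unknown hyper mode {hyper!r}")
        hyper = estimate_eb_hyperparams(s_sq, d)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = beta1 / np.sqrt(v * s_sq)
    t_ord = np.where(s_sq == 0, np.sign(beta1) * np.inf, t_ord)
    t_ord = np.where((s_sq == 0) & (beta1 == 0), 0.0, t_ord)

    s_tilde_sq, t_mod, df_mod = moderated_t_from_components(beta1, v, s_sq, d, hyper)
    if math.isinf(df_mod):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_mod)
    return LimmaFit(
        beta1=beta1,
        s_sq=s_sq,
        d=d,
        v=v,
        t_ordinary=t_ord,
        s_tilde_sq=s_tilde_sq,
        t_moderated=t_mod,
        df_moderated=df_mod,
        p_value=p,
        hyper=hyper,
    )


def block_statistic(method: str, **kwargs) -> Callable[[np.ndarray, SampleDesign], float]:
    """Per-gene ``(probe block, design) -> statistic`` adapters.

    These give every method the common sign-free ranking interface used by
    the pooled permutation null.  Probeset-level methods (``fc``,
    ``moderated_t``) summarize the block by its probe mean first; sign-
    carrying statistics return their absolute value.  ``moderated_t``
    requires fixed ``hyper=EBHyperparams(...)`` since hyperparameters are
    estimated across genes, not per gene.
    """
    from .nested_anova import nested_f_statistic  # local to avoid cycle

    if method == "nfm":

        def stat(block, design):
            return nested_f_statistic(block, design).f_statistic

    elif method == "fc":

        def stat(block, design):
            block = np.atleast_2d(np.asarray(block, dtype=float))
            return abs(float(contrast_vector(design) @ block.mean(axis=0)))

    elif method == "rmanova1":

        def stat(block, design):
            return rmanova_stats(block, design)[0]

    elif method == "rmanova2":

        def stat(block, design):
            return rmanova_stats(block, design)[1]

    elif method == "firstp":

        def stat(block, design):
            return firstp_stat(block, design)

    elif method == "moderated_t":
        hyper = kwargs.get("hyper")
        if not isinstance(hyper, EBHyperparams):
            raise ValueError("moderated_t block statistic needs fixed hyper=")

        def stat(block, design):
            block = np.atleast_2d(np.asarray(block, dtype=float))
            expr = block.mean(axis=0)[None, :]
            fit = moderated_t(
                ProbesetExpressionMatrix(
                    values=expr,
                    probeset_ids=("g",),
                    array_ids=design.array_ids,
                ),
                design,
                hyper=hyper,
            )
            return abs(float(fit.t_moderated[0]))

    else:
        raise ValueError(f"unknown method {method!r}")
    return stat
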