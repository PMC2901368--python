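"""The nested factorial model for probe-level differential expression.

For one gene, the log2 perfect-match intensity of probe ``l`` on array
``j`` within treatment level ``i`` is modelled as

    Y_ijl = mu + T_i + S_j(i) + P_l + (TP)_il + (SP)_jl(i)

where ``T_i`` is the fixed treatment effect, ``S_j(i)`` the random subject
(array) effect nested within treatment, ``P_l`` the probe effect,
``(TP)_il`` the treatment x probe interaction, and ``(SP)_jl(i)`` serves
as the error term.  Arrays are nested within treatment while probes cross
both, so the treatment effect is tested against the subject-within-
treatment stratum:

    F = MS(treatment) / MS(subject within treatment)

with degrees of freedom ``(g - 1, sum(n_i) - g)``.  For a complete probe
x array matrix the design is balanced and this closed-form mean-square
ratio equals the treatment F of the REML-fitted mixed model, so no
iterative fit is needed; a REML engine remains available for unbalanced
(masked-cell) data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ProbeIntensityMatrix, SampleDesign, Scale

__all__ = [
    "NFMAnovaTable",
    "NFMResult",
    "nested_anova_decomposition",
    "nested_f_statistic",
    "stabilize_rounding",
    "f_theoretical_df",
    "f_quantile_diagnostic",
    "fit_all_genes",
]

#: Sentinel ranking above every finite statistic (zero subject variation
#: with non-zero treatment variation).
F_INFINITE = math.inf


@dataclass(frozen=True)
class NFMAnovaTable:
    """Balanced nested-factorial sums of squares for one gene.

    Sources: treatment, subject within treatment, probe, treatment x probe,
    residual (the subject x probe stratum used as error).
    """

    ss_treatment: float
    ss_subject: float
    ss_probe: float
    ss_interaction: float
    ss_residual: float
    df_treatment: int
    df_subject: int
    df_probe: int
    df_interaction: int
    df_residual: int

    @property
    def ss_total(self) -> float:
        return (
            self.ss_treatment
            + self.ss_subject
            + self.ss_probe
            + self.ss_interaction
            + self.ss_residual
        )

    @property
    def df_total(self) -> int:
        return (
            self.df_treatment
            + self.df_subject
            + self.df_probe
            + self.df_interaction
            + self.df_residual
        )

    def mean_square(self, source: str) -> float:
        ss = getattr(self, f"ss_{source}")
        df = getattr(self, f"df_{source}")
        return ss / df if df > 0 else float("nan")


@dataclass(frozen=True)
class NFMResult:
    """Treatment F for one gene under the nested factorial model."""

    f_statistic: float
    df_num: int
    df_den: int
    var_subject: float
    var_resid: float
    engine: str = "closed_form"
    converged: bool = True
    degenerate: bool = False
    single_probe: bool = False


def _check_layout(y: np.ndarray, design: SampleDesign) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.shape[1] != design.n_arrays:
        raise ValueError(
            f"gene block has {y.shape[1]} columns but design has "
            f"{design.n_arrays} arrays"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError(
            "missing or non-finite cells: the closed-form engine requires a "
            "complete (balanced) probe x array block; use the REML engine for "
            "unbalanced data"
        )
    design.require_min_total(3)
    return y


def nested_anova_decomposition(y: np.ndarray, design: SampleDesign) -> NFMAnovaTable:
    """Classical balanced sums of squares for one gene's probe x array block.

    ``y`` has one row per probe (L rows) and one column per array, columns
    in the design's array order.
    """
    y = _check_layout(y, design)
    L, _ = y.shape
    idx0, idx1 = design.level_columns()
    n = (len(idx0), len(idx1))
    groups = (idx0, idx1)

    grand = y.mean()
    # treatment: L * n_i observations behind each level mean
    ss_t = sum(L * n_i * (y[:, g].mean() - grand) ** 2 for g, n_i in zip(groups, n))
    # subject (array) within treatment: L observations behind each array mean
    ss_s = sum(
        L * (y[:, j].mean() - y[:, g].mean()) ** 2 for g in groups for j in g
    )
    # probe: N observations behind each probe mean
    N = design.n_arrays
    probe_means = y.mean(axis=1)
    ss_p = float(N * ((probe_means - grand) ** 2).sum())
    # treatment x probe
    ss_tp = 0.0
    for g, n_i in zip(groups, n):
        cell = y[:, g].mean(axis=1)  # per-probe mean within level
        ss_tp += n_i * ((cell - y[:, g].mean() - probe_means + grand) ** 2).sum()
    ss_total = float(((y - grand) ** 2).sum())
    ss_e = max(ss_total - ss_t - ss_s - ss_p - ss_tp, 0.0)

    g_levels = design.g
    df_s = sum(n_i - 1 for n_i in n)
    return NFMAnovaTable(
        ss_treatment=float(ss_t),
        ss_subject=float(ss_s),
        ss_probe=ss_p,
        ss_interaction=float(ss_tp),
        ss_residual=ss_e,
        df_treatment=g_levels - 1,
        df_subject=df_s,
        df_probe=L - 1,
        df_interaction=(g_levels - 1) * (L - 1),
        df_residual=(L - 1) * df_s,
    )


_ZERO_TOL = 1e-12


def nested_f_statistic(
    y: np.ndarray,
    design: SampleDesign,
    *,
    engine: str = "closed_form",
    round_digits: int | None = 5,
) -> NFMResult:
    """Treatment F-statistic for one gene.

    ``F = MS(treatment) / MS(subject within treatment)`` with degrees of
    freedom ``(g - 1, sum(n_i) - g)``.  Degenerate cases: if the subject
    mean square is zero the statistic is 0 (no treatment variation either)
    or the ``+inf`` sentinel (treatment variation present), both flagged so
    permutation ranking keeps a total order.

    With ``engine="reml"`` the mixed model is fitted iteratively (supports
    missing cells); intensities are first rounded to ``round_digits``
    decimals, which stabilizes convergence of the iterative fit.
    """
    if engine == "reml":
        return _reml_f_statistic(y, design, round_digits=round_digits)
    if engine != "closed_form":
        raise ValueError(f"unknown engine {engine!r}")

    y = _check_layout(y, design)
    L = y.shape[0]
    table = nested_anova_decomposition(y, design)
    ms_t = table.mean_square("treatment")
    ms_s = table.mean_square("subject")
    ms_e = table.mean_square("residual") if L > 1 else 0.0

    # relative tolerance so pure location shifts of constant data stay degenerate
    scale = max(float(np.abs(y - y.mean()).max()) ** 2, 1.0)
    if ms_s <= _ZERO_TOL * scale:
        degenerate_f = 0.0 if ms_t <= _ZERO_TOL * scale else F_INFINITE
        return NFMResult(
            f_statistic=degenerate_f,
            df_num=table.df_treatment,
            df_den=table.df_subject,
            var_subject=0.0,
            var_resid=float(ms_e) if L > 1 else 0.0,
            degenerate=True,
            single_probe=(L == 1),
        )

    var_resid = float(ms_e) if L > 1 else float(ms_s)
    var_subject = max((ms_s - ms_e) / L, 0.0) if L > 1 else 0.0
    return NFMResult(
        f_statistic=float(ms_t / ms_s),
        df_num=table.df_treatment,
        df_den=table.df_subject,
        var_subject=float(var_subject),
        var_resid=var_resid,
        single_probe=(L == 1),
    )


def _reml_f_statistic(
    y: np.ndarray, design: SampleDesign, round_digits: int | None
) -> NFMResult:
    """Iterative REML fit of the mixed model; tolerates missing cells (NaN).

    Profiles the fixed effects out by GLS and maximizes the restricted
    likelihood over (sigma^2_subject, sigma^2_resid); the treatment F is the
    squared Wald statistic of the average treatment contrast.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    design.require_min_total(3)
    if round_digits is not None:
        y = np.round(y, round_digits)
    L, J = y.shape
    mask = np.isfinite(y)
    if not mask.any():
        raise ValueError("no observed cells")

    # long format: response, array index, probe index, treatment indicator
    probe_idx, array_idx = np.nonzero(mask)
    resp = y[probe_idx, array_idx]
    idx0, _ = design.level_columns()
    treat = np.isin(array_idx, idx0, invert=True).astype(float)

    # fixed effects: intercept + treatment + probe dummies + interaction
    X_cols = [np.ones_like(resp), treat]
    for l in range(1, L):
        d = (probe_idx == l).astype(float)
        X_cols.append(d)
        X_cols.append(d * treat)
    X = np.column_stack(X_cols)
    Z = np.zeros((len(resp), J))
    Z[np.arange(len(resp)), array_idx] = 1.0

    def neg_restricted_ll(params):
        log_vs, log_ve = params
        vs, ve = math.exp(log_vs), math.exp(log_ve)
        V = vs * (Z @ Z.T) + ve * np.eye(len(resp))
        try:
            c, low = np.linalg.cholesky(V), True
        except np.linalg.LinAlgError:
            return 1e12
        logdet_V = 2.0 * np.log(np.diag(c)).sum()
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtViX, Vi_X.T @ resp)
        r = resp - X @ beta
        quad = r @ np.linalg.solve(V, r)
        return 0.5 * (logdet_V + logdet_XtViX + quad)

    from scipy.optimize import minimize

    var0 = max(float(np.var(resp)), 1e-6)
    best = None
    for start in ([math.log(var0 / 2)] * 2, [math.log(var0), math.log(var0 / 10)]):
        res = minimize(neg_restricted_ll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    vs, ve = math.exp(best.x[0]), math.exp(best.x[1])

    V = vs * (Z @ Z.T) + ve * np.eye(len(resp))
    Vi_X = np.linalg.solve(V, X)
    XtViX_inv = np.linalg.inv(X.T @ Vi_X)
    beta = XtViX_inv @ (Vi_X.T @ resp)
    # average treatment difference: beta_treat + mean of interaction terms
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    for k in range(1, L):
        c[1 + 2 * k] = 1.0 / L
    est = c @ beta
    se2 = c @ XtViX_inv @ c
    f = float(est * est / se2)
    df_num, df_den = f_theoretical_df(design)
    return NFMResult(
        f_statistic=f,
        df_num=df_num,
        df_den=df_den,
        var_subject=float(vs),
        var_resid=float(ve),
        engine="reml",
        converged=bool(best.success),
        single_probe=(L == 1),
    )


def stabilize_rounding(m: ProbeIntensityMatrix, digits: int = 5) -> ProbeIntensityMatrix:
    """Round log2 intensities half-to-even to ``digits`` decimals.

    Applied before iterative REML fitting, where trivial rounding of the
    log-scale data removes occasional non-convergence.
    """
    if digits < 0:
        raise ValueError("digits must be non-negative")
    if m.scale is not Scale.LOG2:
        raise ValueError("stabilize_rounding expects log2-scale data")
    return m.with_values(np.round(m.values, digits))


def f_theoretical_df(design: SampleDesign) -> tuple[int, int]:
    """Degrees of freedom (g - 1, sum(n_i) - g) of the theoretical null F."""
    return design.g - 1, design.n_arrays - design.g


def f_quantile_diagnostic(
    f_values: np.ndarray, df: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (theoretical, empirical) quantiles of observed F statistics.

    Probabilities are ``(i - 0.5) / n``.  A near-identity relationship
    supports using the theoretical F as the null reference; systematic
    curvature signals short or long tails, motivating the pooled
    permutation null instead.
    """
    f_values = np.asarray(f_values, dtype=float)
    f_values = f_values[np.isfinite(f_values)]
    n = len(f_values)
    if n < 10:
        raise ValueError("need at least 10 finite statistics")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theoretical = stats.f.ppf(probs, df[0], df[1])
    empirical = np.sort(f_values)
    return theoretical, empirical


def fit_all_genes(
    m: ProbeIntensityMatrix,
    design: SampleDesign,
    *,
    engine: str = "closed_form",
    round_digits: int | None = 5,
) -> dict[str, NFMResult]:
    """Per-gene nested-factorial F over every probeset of ``m``."""
    return {
        ps: nested_f_statistic(block, design, engine=engine, round_digits=round_digits)
        for ps, block in m.iter_genes()
    }
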