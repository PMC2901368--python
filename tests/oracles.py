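"""Independent oracles used by the test suite.

Each oracle recomputes a quantity from first principles, by a route
different from the package implementation: sums of squares directly from
group means, mixed-model F statistics via R's nlme REML fit, AUC by
rectangle summation, and a literal step-by-step robust-MANOVA evaluation.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np


def brute_force_nested_ss(y: np.ndarray, n1: int) -> dict[str, float]:
    """Nested-factorial sums of squares straight from the definitions.

    Enumerates every cell and accumulates squared deviations of the
    relevant group means; no shortcut formulas shared with the package.
    """
    y = np.asarray(y, dtype=float)
    L, N = y.shape
    levels = [list(range(n1)), list(range(n1, N))]
    grand = y.mean()

    ss = {k: 0.0 for k in ("treatment", "subject", "probe", "interaction", "residual")}
    for l in range(L):
        for j in range(N):
            i = 0 if j < n1 else 1
            cols = levels[i]
            m_trt = y[:, cols].mean()
            m_arr = y[:, j].mean()
            m_probe = y[l, :].mean()
            m_cell = y[l, cols].mean()
            ss["treatment"] += (m_trt - grand) ** 2
            ss["subject"] += (m_arr - m_trt) ** 2
            ss["probe"] += (m_probe - grand) ** 2
            ss["interaction"] += (m_cell - m_trt - m_probe + grand) ** 2
            ss["residual"] += (y[l, j] - m_arr - m_cell + m_trt) ** 2
    return ss


_R_SCRIPT = r"""
suppressMessages(library(nlme))
args <- commandArgs(trailingOnly = TRUE)
d <- read.table(args[1], header = TRUE, sep = "\t")
out <- NULL
for (inst in unique(d$instance)) {
  di <- d[d$instance == inst, ]
  di$probe <- factor(di$probe)
  di$array <- factor(di$array)
  di$trt <- factor(di$trt)
  ctrl <- lmeControl(tolerance = 1e-12, msTol = 1e-12, niterEM = 100,
                     msMaxIter = 200)
  if (nlevels(di$probe) > 1) {
    fit <- lme(Y ~ trt * probe, random = ~1 | array, data = di,
               method = "REML", control = ctrl)
  } else {
    fit <- lme(Y ~ trt, random = ~1 | array, data = di,
               method = "REML", control = ctrl)
  }
  f <- anova(fit)["trt", "F-value"]
  out <- rbind(out, data.frame(instance = inst, F = f))
}
write.table(out, args[2], sep = "\t", row.names = FALSE, quote = FALSE)
"""


def reml_f_via_nlme(instances: list[tuple[np.ndarray, int]]) -> np.ndarray:
    """Treatment F for each (probe x array block, n1) via R nlme, batched.

    This is the reference mixed-model engine for the nested design;
    the balanced-data closed form must agree with it.
    """
    rows = []
    for idx, (y, n1) in enumerate(instances):
        y = np.asarray(y, dtype=float)
        L, N = y.shape
        for l in range(L):
            for j in range(N):
                rows.append(
                    (idx, y[l, j], l, j, "c" if j < n1 else "t")
                )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_path = tmp / "data.tsv"
        with open(data_path, "w") as fh:
            fh.write("instance\tY\tprobe\tarray\ttrt\n")
            for r in rows:
                fh.write(f"{r[0]}\t{r[1]:.12g}\t{r[2]}\t{r[3]}\t{r[4]}\n")
        script = tmp / "oracle.R"
        script.write_text(_R_SCRIPT)
        out_path = tmp / "out.tsv"
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data_path), str(out_path)],
            check=True,
            capture_output=True,
        )
        lines = out_path.read_text().strip().splitlines()[1:]
        result = np.full(len(instances), np.nan)
        for line in lines:
            inst, f = line.split("\t")
            result[int(inst)] = float(f)
    return result


def rectangle_auc(fpr: np.ndarray, tpr: np.ndarray, n_rect: int = 200_000) -> float:
    """Riemann-sum area under the staircase traced by the ROC points."""
    order = np.lexsort((tpr, fpr))
    x, y = np.asarray(fpr)[order], np.asarray(tpr)[order]
    grid = (np.arange(n_rect) + 0.5) / n_rect
    # height at each grid abscissa: linear interpolation along the path
    heights = np.interp(grid, x, y)
    return float(heights.mean())


def literal_rmanova(y: np.ndarray, n1: int) -> tuple[float, float]:
    """Step-by-step robust MANOVA evaluation with explicit loops."""
    y = np.asarray(y, dtype=float)
    L, N = y.shape
    groups = [list(range(n1)), list(range(n1, N))]
    mu = np.array([np.median(y[l, :]) for l in range(L)])
    mu_i = [
        np.array([np.median(y[l, g]) for l in range(L)]) for g in groups
    ]
    W = np.zeros((L, L))
    B = np.zeros((L, L))
    for i, g in enumerate(groups):
        for j in g:
            dev = y[:, j] - mu_i[i]
            for a in range(L):
                for b in range(L):
                    W[a, b] += dev[a] * dev[b]
        d = mu_i[i] - mu
        for a in range(L):
            for b in range(L):
                B[a, b] += len(g) * d[a] * d[b]
    tr_w = sum(W[l, l] for l in range(L))
    tr_b = sum(B[l, l] for l in range(L))
    stat1 = tr_b / tr_w
    stat2 = float(np.median([B[l, l] / W[l, l] for l in range(L)]))
    return stat1, stat2


def bh_qvalues_reference(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up via statsmodels (independent of the package)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
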