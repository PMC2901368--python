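"""Spike-in benchmarking: iterative-removal ROC curves, AUC, subset
averaging, and method rank comparison.

The ROC procedure sorts the absolute test statistics increasingly and
repeatedly discards the smallest one; after each removal the retained set
is scored against the known spike-in truth:

    TPR = retained spiked / total spiked
    FPR = retained non-spiked / total non-spiked

giving one (FPR, TPR) point per retained-set size from all genes down to
one, plus a terminal (0, 0) for the empty set so a perfectly separating
ranking integrates to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GeneStatTable

__all__ = [
    "TruthTable",
    "ROCCurve",
    "make_truth_table",
    "tpr_fpr_curve",
    "roc_auc",
    "average_roc_over_subsets",
    "method_rank_distances",
]


@dataclass(frozen=True)
class TruthTable:
    """Known spike-in status (and optional log2 fold change) per probeset."""

    spiked: dict[str, bool]
    fold_change: dict[str, float]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        fc = {}
        if "log2_fold_change" in df.columns:
            fc = {
                ps: float(v)
                for ps, v in zip(df["probeset_id"], df["log2_fold_change"])
                if np.isfinite(v)
            }
        return cls(
            spiked=dict(zip(df["probeset_id"], df["spiked"].astype(bool))),
            fold_change=fc,
        )

    def restrict_to_fold_change(self, fc: float, tol: float = 1e-9) -> "TruthTable":
        """Truth over {spiked at this fold change} union {non-spiked}.

        Parameterizes per-fold-change ROC curves: genes spiked at other
        fold-change levels are excluded from the universe.
        """
        keep = {
            ps: sp
            for ps, sp in self.spiked.items()
            if not sp or abs(self.fold_change.get(ps, np.nan) - fc) <= tol
        }
        return TruthTable(
            spiked=keep, fold_change={ps: v for ps, v in self.fold_change.items() if ps in keep}
        )


def make_truth_table(
    probeset_ids: Sequence[str],
    spiked_ids: Sequence[str],
    fold_changes: dict[str, float] | None = None,
) -> TruthTable:
    spiked_set = set(spiked_ids)
    return TruthTable(
        spiked={ps: ps in spiked_set for ps in probeset_ids},
        fold_change=dict(fold_changes or {}),
    )


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points of the iterative-removal procedure."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1:
            raise ValueError("fpr and tpr must be matching 1-D vectors")
        if np.any(np.diff(fpr) > 1e-12) or np.any(np.diff(tpr) > 1e-12):
            raise ValueError("FPR and TPR must be non-increasing along the curve")
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    @property
    def auc(self) -> float:
        return roc_auc(self)

    @property
    def n_points(self) -> int:
        return len(self.fpr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": np.arange(self.n_points), "fpr": self.fpr, "tpr": self.tpr}
        )


def tpr_fpr_curve(
    statistics: Sequence[float],
    probeset_ids: Sequence[str],
    truth: TruthTable,
) -> ROCCurve:
    """Iterative-removal ROC curve of one method's statistics.

    Absolute statistics are removed from smallest to largest (ties broken
    by stable input order); each retained set contributes one (FPR, TPR)
    point, followed by the terminal (0, 0).  The first point is (1, 1).
    """
    stats = np.abs(np.asarray(statistics, dtype=float))
    ids = list(probeset_ids)
    if len(stats) != len(ids):
        raise ValueError("statistics and probeset_ids length mismatch")
    missing = [ps for ps in ids if ps not in truth.spiked]
    if missing:
        raise ValueError(f"genes without truth entry: {missing[:5]}")
    is_spiked = np.array([truth.spiked[ps] for ps in ids], dtype=bool)
    n_pos = int(is_spiked.sum())
    n_neg = int((~is_spiked).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one spiked and one non-spiked gene")

    removal_order = np.argsort(stats, kind="stable")  # ascending, stable ties
    spiked_in_order = is_spiked[removal_order]
    # retained counts before each removal step (full set first)
    pos_removed = np.concatenate([[0], np.cumsum(spiked_in_order)[:-1]])
    neg_removed = np.concatenate([[0], np.cumsum(~spiked_in_order)[:-1]])
    tpr = (n_pos - pos_removed) / n_pos
    fpr = (n_neg - neg_removed) / n_neg
    return ROCCurve(fpr=np.append(fpr, 0.0), tpr=np.append(tpr, 0.0))


def roc_auc(curve: ROCCurve) -> float:
    """Area under the removal staircase by the trapezoidal rule.

    Points are traversed in (FPR, TPR)-ascending order; vertical runs at
    equal FPR contribute zero width, so the integral follows the staircase
    path.  Without ties this equals the rank-based (Mann-Whitney) AUC.
    """
    order = np.lexsort((curve.tpr, curve.fpr))
    x = curve.fpr[order]
    y = curve.tpr[order]
    return float(np.trapezoid(y, x))


def average_roc_over_subsets(curves: Sequence[ROCCurve]) -> ROCCurve:
    """Pointwise mean of ROC curves aligned by removal-step index.

    All curves must share the gene universe (equal point counts), as is
    the case for sub-design comparisons of one dataset.
    """
    if not curves:
        raise ValueError("no curves to average")
    n = curves[0].n_points
    if any(c.n_points != n for c in curves):
        raise ValueError("curves have unequal point counts")
    fpr = np.mean([c.fpr for c in curves], axis=0)
    tpr = np.mean([c.tpr for c in curves], axis=0)
    return ROCCurve(fpr=fpr, tpr=tpr)


def method_rank_distances(
    tables: Sequence[GeneStatTable], top_n: int = 500
) -> pd.DataFrame:
    """Manhattan distances between methods' rank vectors on their top genes.

    Takes the union of each method's ``top_n`` genes by absolute statistic,
    ranks that union within each method (rank 1 = largest |statistic|), and
    returns the pairwise Manhattan distance matrix between the methods'
    rank vectors — a scale-free comparison of how the methods order genes.
    """
    if len(tables) < 2:
        raise ValueError("need at least two methods")
    universe = tables[0].probeset_ids
    for t in tables[1:]:
        if t.probeset_ids != universe:
            raise ValueError("all methods must cover the same gene universe")
    if top_n > len(universe):
        raise ValueError("top_n exceeds the gene universe")

    union: dict[str, None] = {}
    abs_stats = {}
    for t in tables:
        s = np.abs(t.statistics)
        abs_stats[t.frame["method"].iloc[0]] = dict(zip(universe, s))
        top = np.argsort(-s, kind="stable")[:top_n]
        for i in top:
            union.setdefault(universe[i], None)
    union_ids = list(union)

    methods = list(abs_stats)
    ranks = {}
    for m in methods:
        vals = np.array([abs_stats[m][ps] for ps in union_ids])
        order = np.argsort(-vals, kind="stable")
        r = np.empty(len(union_ids))
        r[order] = np.arange(1, len(union_ids) + 1)
        ranks[m] = r
    dist = pd.DataFrame(0.0, index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for mj in methods[i + 1 :]:
            d = float(np.abs(ranks[mi] - ranks[mj]).sum())
            dist.loc[mi, mj] = dist.loc[mj, mi] = d
    return dist
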