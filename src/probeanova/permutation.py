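"""Treatment-label permutation inference with a pooled cross-gene null.

With very small designs a per-gene permutation null cannot produce small
p-values: a 3 vs 3 comparison has only C(6,3) = 20 labelings (10 unique up
to swapping the two level names), so the smallest per-gene p-value is 1/10.
The pooled approach instead concatenates the test statistics of *all* genes
under *all* label permutations into one flat null collection of size G * K;
each gene's p-value is the proportion of that collection at least as large
as the gene's observed statistic, so p can be as small as 1/(G * K).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .containers import ProbeIntensityMatrix, SampleDesign

__all__ = [
    "LabelPermutationSet",
    "PooledNullDistribution",
    "enumerate_label_permutations",
    "build_pooled_null",
    "pooled_pvalues",
    "per_gene_pvalues",
    "storey_qvalues",
    "estimate_pi0",
]

#: Refuse exhaustive enumeration beyond this many labelings.
MAX_LABELINGS = 10_000


@dataclass(frozen=True)
class LabelPermutationSet:
    """All distinct two-level labelings of the arrays with group sizes fixed."""

    labelings: tuple[tuple[str, ...], ...]
    reduced: bool

    @property
    def n_total(self) -> int:
        return len(self.labelings)

    def __iter__(self):
        return iter(self.labelings)


def enumerate_label_permutations(
    design: SampleDesign, reduce: bool = True
) -> LabelPermutationSet:
    """Enumerate treatment-label permutations of a two-group design.

    All ``C(N, n1)`` assignments of arrays to the two levels with group
    sizes fixed, identity labeling first, remainder in lexicographic order
    of the level-1 index set.  A sign-free statistic such as the nested-
    factorial F is unchanged by swapping the two level names, so for equal
    group sizes ``reduce=True`` keeps one representative per swap pair (the
    member that gives the first array its original label), halving the count.
    """
    n1, n2 = design.n_per_level
    N = design.n_arrays
    total = math.comb(N, n1)
    effective = total // 2 if (reduce and n1 == n2) else total
    if effective > MAX_LABELINGS:
        raise ValueError(
            f"{effective} labelings exceed the exhaustive-enumeration cap "
            f"({MAX_LABELINGS})"
        )
    control, treatment = design.levels
    identity = design.labels
    first_label = identity[0]

    labelings: list[tuple[str, ...]] = []
    for combo in itertools.combinations(range(N), n1):
        members = set(combo)
        labels = tuple(
            control if j in members else treatment for j in range(N)
        )
        if reduce and n1 == n2 and labels[0] != first_label:
            continue  # swap-pair representative keeps the first array's label
        labelings.append(labels)
    labelings.sort(key=lambda lab: lab != identity)  # identity first, stable
    return LabelPermutationSet(labelings=tuple(labelings), reduced=reduce and n1 == n2)


@dataclass(frozen=True)
class PooledNullDistribution:
    """Flat sorted collection of statistics: all genes x all labelings."""

    stats: np.ndarray  # sorted ascending; may contain +inf sentinels
    n_genes: int
    n_perms: int
    engine: str = "closed_form"

    def __post_init__(self) -> None:
        stats = np.sort(np.asarray(self.stats, dtype=float))
        if np.isnan(stats).any():
            raise ValueError("null statistics must not be NaN")
        if len(stats) != self.n_genes * self.n_perms:
            raise ValueError("pool size must equal n_genes * n_perms")
        object.__setattr__(self, "stats", stats)

    @property
    def size(self) -> int:
        return len(self.stats)

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / self.size


def build_pooled_null(
    m: ProbeIntensityMatrix,
    design: SampleDesign,
    statistic: Callable[[np.ndarray, SampleDesign], float],
    perms: LabelPermutationSet,
) -> PooledNullDistribution:
    """Compute ``statistic`` for every gene under every labeling and pool.

    ``statistic(block, design)`` must be sign-free (larger = more extreme).
    The identity labeling is part of ``perms``, so every gene's observed
    statistic is contained in the pool and pooled p-values are strictly
    positive.  Degenerate genes contribute their sentinel values (0 or
    ``+inf``), which participate in exceedance counting.
    """
    genes = list(m.iter_genes())
    pool = np.empty(len(genes) * perms.n_total, dtype=float)
    k = 0
    for labels in perms:
        d = design.relabelled(labels)
        for _, block in genes:
            pool[k] = statistic(block, d)
            k += 1
    return PooledNullDistribution(
        stats=pool, n_genes=len(genes), n_perms=perms.n_total
    )


def pooled_pvalues(
    observed: Sequence[float], null: PooledNullDistribution
) -> np.ndarray:
    """p = (# null entries >= observed) / (G * K), per gene.

    Ties count as extreme ("at least as extreme"); statistics are compared
    exactly as computed, with no tolerance fuzzing.  Because each observed
    statistic is itself in the pool, every p is >= 1/(G * K).
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) != null.n_genes:
        raise ValueError(
            f"{len(observed)} observed statistics for {null.n_genes} pooled genes"
        )
    n_less = np.searchsorted(null.stats, observed, side="left")
    return (null.size - n_less) / null.size


def per_gene_pvalues(
    m: ProbeIntensityMatrix,
    design: SampleDesign,
    statistic: Callable[[np.ndarray, SampleDesign], float],
    perms: LabelPermutationSet,
) -> np.ndarray:
    """Classical per-gene permutation p-values (comparison utility).

    Each gene is compared only against its own K permutation statistics, so
    p >= 1/K: with small designs no gene can reach small p-values, which is
    the motivation for the pooled null.
    """
    genes = list(m.iter_genes())
    designs = [design.relabelled(labels) for labels in perms]
    pvals = np.empty(len(genes))
    for gi, (_, block) in enumerate(genes):
        stats_g = np.array([statistic(block, d) for d in designs])
        obs = stats_g[0]  # identity labeling is first
        pvals[gi] = float(np.mean(stats_g >= obs))
    return pvals


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from a p-value vector.

    Computes ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` on the grid
    lambda = 0.05, 0.10, ..., 0.95, smooths the sequence with a
    least-squares cubic fit, and evaluates the smooth at the largest
    lambda; the result is clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(p: Sequence[float], pi0_mode: str = "storey_spline") -> np.ndarray:
    """Convert p-values to q-values for false-discovery-rate control.

    ``q_i = pi0 * min over p_(j) >= p_i of (p_(j) * m / j)``.  With
    ``pi0_mode="fixed_one"`` this is exactly the Benjamini-Hochberg
    step-up; ``"storey_spline"`` scales by the estimated null proportion
    (always <= 1, so never more conservative than BH).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0_mode == "fixed_one":
        pi0 = 1.0
    elif pi0_mode == "storey_spline":
        pi0 = estimate_pi0(p)
    else:
        raise ValueError(f"unknown pi0_mode {pi0_mode!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q
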