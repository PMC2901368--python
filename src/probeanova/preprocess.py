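"""Preprocessing utilities: quantile normalization, probeset summarization,
non-specific filtering, and subset-comparison enumeration.

Background correction is out of scope: the toolkit accepts input that is
already background corrected (raw scale) or background corrected and
log2 transformed.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .containers import (
    ProbeIntensityMatrix,
    ProbesetExpressionMatrix,
    SampleDesign,
    Scale,
)

__all__ = [
    "quantile_normalize",
    "summarize_probesets",
    "nonspecific_filter",
    "enumerate_subsets",
    "count_subsets",
    "subset_probe_matrix",
]


def quantile_normalize(m: ProbeIntensityMatrix) -> ProbeIntensityMatrix:
    """Quantile-normalize the arrays of a probe intensity matrix.

    Every output column carries the identical sorted value multiset: the
    reference vector of per-rank means of the sorted input columns.  Tied
    values within a column receive the mean of the reference values at
    their tied ranks, so the operation is idempotent.
    """
    if m.n_arrays < 2:
        raise ValueError("quantile normalization needs at least two arrays")
    x = m.values
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = reference.copy()
        # average reference values over runs of tied input values
        sorted_col = col[order]
        start = 0
        for stop in range(1, len(col) + 1):
            if stop == len(col) or sorted_col[stop] != sorted_col[start]:
                if stop - start > 1:
                    mapped[start:stop] = mapped[start:stop].mean()
                start = stop
        out[order, j] = mapped
    return m.with_values(out)


def summarize_probesets(m: ProbeIntensityMatrix) -> ProbesetExpressionMatrix:
    """Summarize a log2 probe matrix to one expression row per probeset.

    The summary is the plain mean over the probeset's probes of the log2
    intensities on each array — an explicit, simple stand-in for model-based
    summarization methods, adequate for the probeset-level statistics here.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("summarization requires log2-scale input")
    probesets = m.probeset_ids
    values = np.empty((len(probesets), m.n_arrays), dtype=float)
    for i, ps in enumerate(probesets):
        values[i, :] = m.gene_submatrix(ps).mean(axis=0)
    return ProbesetExpressionMatrix(
        values=values, probeset_ids=probesets, array_ids=m.array_ids
    )


def nonspecific_filter(
    e: ProbesetExpressionMatrix,
    threshold: float = 20.0,
    min_arrays: int = 2,
    *,
    threshold_scale: str = "antilog",
) -> list[str]:
    """Probesets whose expression exceeds ``threshold`` on >= ``min_arrays`` arrays.

    The threshold is compared on the anti-log (natural intensity, ``2**value``)
    scale by default, since log2 expression summaries rarely exceed ~14;
    pass ``threshold_scale="log2"`` to compare on the stored scale.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not (1 <= min_arrays <= len(e.array_ids)):
        raise ValueError("min_arrays out of range")
    if threshold_scale not in ("antilog", "log2"):
        raise ValueError("threshold_scale must be 'antilog' or 'log2'")
    x = np.power(2.0, e.values) if threshold_scale == "antilog" else e.values
    keep = (x > threshold).sum(axis=1) >= min_arrays
    return [ps for ps, k in zip(e.probeset_ids, keep) if k]


def count_subsets(n1: int, n2: int, k: int) -> int:
    """Closed-form number of k-vs-k sub-designs: C(n1, k) * C(n2, k)."""
    return math.comb(n1, k) * math.comb(n2, k)


def enumerate_subsets(design: SampleDesign, k: int) -> list[SampleDesign]:
    """All sub-designs keeping ``k`` arrays per treatment level.

    Returns ``C(n1, k) * C(n2, k)`` designs in deterministic lexicographic
    order (by array position within each level, level-1 combinations outer).
    Each sub-design preserves original array order and labels.
    """
    n1, n2 = design.n_per_level
    if not (2 <= k <= min(n1, n2)):
        raise ValueError(f"k={k} out of range [2, {min(n1, n2)}]")
    idx0, idx1 = design.level_columns()
    out: list[SampleDesign] = []
    for combo0 in itertools.combinations(idx0.tolist(), k):
        for combo1 in itertools.combinations(idx1.tolist(), k):
            cols = sorted(combo0 + combo1)
            arrays = tuple(design.array_ids[c] for c in cols)
            out.append(
                SampleDesign(
                    array_ids=arrays,
                    treatment_of_array={
                        a: design.treatment_of_array[a] for a in arrays
                    },
                    levels=design.levels,
                )
            )
    return out


def subset_probe_matrix(
    m: ProbeIntensityMatrix, design: SampleDesign
) -> ProbeIntensityMatrix:
    """Restrict a probe matrix to the arrays of ``design`` (in design order)."""
    cols = [m.array_ids.index(a) for a in design.array_ids]
    return ProbeIntensityMatrix(
        values=m.values[:, cols],
        scale=m.scale,
        probe_ids=m.probe_ids,
        probeset_of_probe=dict(m.probeset_of_probe),
        array_ids=design.array_ids,
    )
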