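"""Core data containers for probe-level expression analysis.

The toolkit works on two matrix layouts: a probe-level intensity matrix
(rows = perfect-match probes, each annotated with the probeset it belongs
to; columns = arrays) and a probeset-level expression matrix (rows =
probesets).  A :class:`SampleDesign` maps arrays to one of two treatment
levels.  All containers validate on construction and are immutable in
spirit: operations return new objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ProbeIntensityMatrix",
    "SampleDesign",
    "ProbesetExpressionMatrix",
    "GeneStatTable",
]


class Scale(str, Enum):
    """Measurement scale of an intensity matrix."""

    RAW = "raw"
    LOG2 = "log2"


@dataclass(frozen=True)
class ProbeIntensityMatrix:
    """Probe x array intensity matrix with a probe -> probeset mapping.

    Parameters
    ----------
    values
        2-D float array, one row per probe, one column per array.
    scale
        ``Scale.RAW`` (strictly positive intensities) or ``Scale.LOG2``.
    probe_ids
        Unique probe identifiers, one per row.
    probeset_of_probe
        Mapping from probe id to its (single) probeset id.
    array_ids
        Unique array identifiers, one per column, in column order.
    """

    values: np.ndarray
    scale: Scale
    probe_ids: tuple[str, ...]
    probeset_of_probe: dict[str, str]
    array_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "array_ids", tuple(self.array_ids))
        object.__setattr__(self, "scale", Scale(self.scale))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.probe_ids) != values.shape[0]:
            raise ValueError("probe_ids length must match row count")
        if len(self.array_ids) != values.shape[1]:
            raise ValueError("array_ids length must match column count")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe_id")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValueError("duplicate array_id")
        if not np.all(np.isfinite(values)):
            raise ValueError("all intensities must be finite")
        if self.scale is Scale.RAW and np.any(values <= 0):
            raise ValueError("raw-scale intensities must be strictly positive")
        missing = [p for p in self.probe_ids if p not in self.probeset_of_probe]
        if missing:
            raise ValueError(f"probes without probeset: {missing[:5]}")
        empty = [p for p in self.probe_ids if not str(self.probeset_of_probe[p])]
        if empty:
            raise ValueError(f"probe with empty probeset_id: {empty[:5]}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def probeset_ids(self) -> tuple[str, ...]:
        """Probeset ids in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.probe_ids:
            seen.setdefault(self.probeset_of_probe[p], None)
        return tuple(seen)

    def probe_rows_of(self, probeset_id: str) -> np.ndarray:
        """Row indices of the probes belonging to ``probeset_id``."""
        idx = [
            i
            for i, p in enumerate(self.probe_ids)
            if self.probeset_of_probe[p] == probeset_id
        ]
        if not idx:
            raise KeyError(probeset_id)
        return np.asarray(idx, dtype=int)

    def gene_submatrix(self, probeset_id: str) -> np.ndarray:
        """The probe x array block for one probeset."""
        return self.values[self.probe_rows_of(probeset_id), :]

    def iter_genes(self):
        """Yield ``(probeset_id, probe x array block)`` in first-appearance order."""
        for ps in self.probeset_ids:
            yield ps, self.gene_submatrix(ps)

    def with_values(self, values: np.ndarray, scale: Scale | None = None) -> "ProbeIntensityMatrix":
        return ProbeIntensityMatrix(
            values=np.asarray(values, dtype=float),
            scale=self.scale if scale is None else scale,
            probe_ids=self.probe_ids,
            probeset_of_probe=dict(self.probeset_of_probe),
            array_ids=self.array_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.array_ids))
        df.insert(0, "probe_id", list(self.probe_ids))
        df.insert(0, "probeset_id", [self.probeset_of_probe[p] for p in self.probe_ids])
        return df


@dataclass(frozen=True)
class SampleDesign:
    """Two-group treatment assignment of arrays.

    ``levels`` is the ordered pair ``(control, treatment)``.  ``g`` is the
    number of treatment levels (always 2 here) and ``n_per_level`` the
    per-level array counts ``n_i``.
    """

    array_ids: tuple[str, ...]
    treatment_of_array: dict[str, str]
    levels: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "array_ids", tuple(self.array_ids))
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) != 2 or self.levels[0] == self.levels[1]:
            raise ValueError("exactly two distinct treatment levels required")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValueError("duplicate array_id in design")
        for a in self.array_ids:
            if a not in self.treatment_of_array:
                raise ValueError(f"array {a!r} has no treatment label")
            if self.treatment_of_array[a] not in self.levels:
                raise ValueError(
                    f"array {a!r} labelled {self.treatment_of_array[a]!r}, "
                    f"not one of {self.levels}"
                )
        if min(self.n_per_level) < 1:
            raise ValueError("each treatment level needs at least one array")

    @property
    def g(self) -> int:
        return 2

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def n_per_level(self) -> tuple[int, int]:
        labels = [self.treatment_of_array[a] for a in self.array_ids]
        return (labels.count(self.levels[0]), labels.count(self.levels[1]))

    @property
    def labels(self) -> tuple[str, ...]:
        """Treatment label per array, in array order."""
        return tuple(self.treatment_of_array[a] for a in self.array_ids)

    def level_columns(self, arrays: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Column indices (into ``array_ids``) of each level, in array order."""
        ids = self.array_ids if arrays is None else tuple(arrays)
        idx0 = [i for i, a in enumerate(ids) if self.treatment_of_array[a] == self.levels[0]]
        idx1 = [i for i, a in enumerate(ids) if self.treatment_of_array[a] == self.levels[1]]
        return np.asarray(idx0, dtype=int), np.asarray(idx1, dtype=int)

    def relabelled(self, labels: Sequence[str]) -> "SampleDesign":
        """A design with the same arrays but new treatment labels (array order)."""
        return SampleDesign(
            array_ids=self.array_ids,
            treatment_of_array=dict(zip(self.array_ids, labels)),
            levels=self.levels,
        )

    def require_min_total(self, minimum: int = 3) -> None:
        if self.n_arrays < minimum:
            raise ValueError(
                f"design has {self.n_arrays} arrays; at least {minimum} required "
                "(denominator degrees of freedom would vanish)"
            )


@dataclass(frozen=True)
class ProbesetExpressionMatrix:
    """Probeset x array log2 expression matrix."""

    values: np.ndarray
    probeset_ids: tuple[str, ...]
    array_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probeset_ids", tuple(self.probeset_ids))
        object.__setattr__(self, "array_ids", tuple(self.array_ids))
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.probeset_ids) != values.shape[0]:
            raise ValueError("probeset_ids length must match row count")
        if len(self.array_ids) != values.shape[1]:
            raise ValueError("array_ids length must match column count")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("duplicate probeset_id")
        if not np.all(np.isfinite(values)):
            raise ValueError("all expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.array_ids))
        df.insert(0, "probeset_id", list(self.probeset_ids))
        return df


@dataclass
class GeneStatTable:
    """Per-gene output of one test-statistic method.

    A thin wrapper over a DataFrame with the canonical columns
    ``probeset_id, method, statistic, df_num, df_den, p_value, q_value,
    degenerate``.  Missing quantities are NaN (columns are always present).
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = (
        "probeset_id",
        "method",
        "statistic",
        "df_num",
        "df_den",
        "p_value",
        "q_value",
        "degenerate",
    )

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                if col == "degenerate":
                    df[col] = False
                elif col in ("probeset_id", "method"):
                    raise ValueError(f"missing required column {col!r}")
                else:
                    df[col] = np.nan
        df = df[list(self.COLUMNS)]
        for col in ("p_value", "q_value"):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise ValueError(f"{col} outside [0, 1]")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_stats(
        cls,
        probeset_ids: Sequence[str],
        method: str,
        statistic: Sequence[float],
        *,
        df_num=None,
        df_den=None,
        p_value=None,
        q_value=None,
        degenerate=None,
    ) -> "GeneStatTable":
        n = len(probeset_ids)

        def col(x, fill):
            if x is None:
                return np.full(n, fill)
            return np.broadcast_to(np.asarray(x), (n,)).copy()

        return cls(
            pd.DataFrame(
                {
                    "probeset_id": list(probeset_ids),
                    "method": method,
                    "statistic": np.asarray(statistic, dtype=float),
                    "df_num": col(df_num, np.nan),
                    "df_den": col(df_den, np.nan),
                    "p_value": col(p_value, np.nan),
                    "q_value": col(q_value, np.nan),
                    "degenerate": col(degenerate, False).astype(bool),
                }
            )
        )

    @property
    def statistics(self) -> np.ndarray:
        return self.frame["statistic"].to_numpy(dtype=float)

    @property
    def probeset_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["probeset_id"])
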