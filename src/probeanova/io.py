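"""TSV readers and writers.

Dialect: tab-separated, UTF-8, header row required, ``.`` decimal point,
no quoting; writers emit 10 significant digits so read/write round-trips
are bit-identical.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    GeneStatTable,
    ProbeIntensityMatrix,
    ProbesetExpressionMatrix,
    SampleDesign,
    Scale,
)

__all__ = [
    "read_probe_matrix",
    "write_probe_matrix",
    "read_design",
    "write_design",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_truth_table",
    "write_truth_table",
    "read_stat_table",
    "write_stat_table",
]

_FLOAT_FMT = "%.10g"


def _read_tsv(path: os.PathLike | str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_numeric_block(df: pd.DataFrame, value_cols: Sequence[str], path) -> np.ndarray:
    """Parse string cells to floats, naming the offending cell on failure."""
    out = np.empty((len(df), len(value_cols)), dtype=float)
    for j, col in enumerate(value_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & ~df[col].str.lower().isin(["nan"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in data row {row + 1}, array column {col!r}"
            )
        out[:, j] = parsed.to_numpy(dtype=float)
    return out


def read_probe_matrix(path, scale: Scale | str = Scale.LOG2) -> ProbeIntensityMatrix:
    """Read a probe-level matrix TSV.

    Expected header: ``probeset_id<TAB>probe_id<TAB><array1>...<arrayN>``.
    """
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["probeset_id", "probe_id"]:
        raise ValueError(
            f"{path}: header must start with 'probeset_id\\tprobe_id', "
            f"got {list(df.columns[:2])}"
        )
    array_cols = list(df.columns[2:])
    if not array_cols:
        raise ValueError(f"{path}: no array columns")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r}")
    if (df["probeset_id"].str.len() == 0).any():
        row = int(np.flatnonzero((df["probeset_id"].str.len() == 0).to_numpy())[0])
        raise ValueError(f"{path}: empty probeset_id in data row {row + 1}")
    values = _parse_numeric_block(df, array_cols, path)
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ValueError(
            f"{path}: non-finite value in data row {i + 1}, array column {array_cols[j]!r}"
        )
    return ProbeIntensityMatrix(
        values=values,
        scale=Scale(scale),
        probe_ids=tuple(df["probe_id"]),
        probeset_of_probe=dict(zip(df["probe_id"], df["probeset_id"])),
        array_ids=tuple(array_cols),
    )


def write_probe_matrix(m: ProbeIntensityMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_design(path, control_label: str | None = None) -> SampleDesign:
    """Read an ``array_id<TAB>treatment`` design TSV.

    The first treatment value encountered is the control level unless
    ``control_label`` overrides it.
    """
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["array_id", "treatment"]:
        raise ValueError(f"{path}: header must be 'array_id\\ttreatment'")
    labels = list(dict.fromkeys(df["treatment"]))
    if len(labels) != 2:
        raise ValueError(f"{path}: need exactly two treatment values, got {labels}")
    if control_label is not None:
        if control_label not in labels:
            raise ValueError(f"{path}: control label {control_label!r} not present")
        labels = [control_label] + [x for x in labels if x != control_label]
    return SampleDesign(
        array_ids=tuple(df["array_id"]),
        treatment_of_array=dict(zip(df["array_id"], df["treatment"])),
        levels=(labels[0], labels[1]),
    )


def write_design(design: SampleDesign, path) -> None:
    pd.DataFrame(
        {"array_id": list(design.array_ids), "treatment": list(design.labels)}
    ).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> ProbesetExpressionMatrix:
    """Read a ``probeset_id<TAB><array1>...`` probeset expression TSV (log2)."""
    df = _read_tsv(path)
    if df.columns[0] != "probeset_id":
        raise ValueError(f"{path}: first column must be 'probeset_id'")
    array_cols = list(df.columns[1:])
    values = _parse_numeric_block(df, array_cols, path)
    return ProbesetExpressionMatrix(
        values=values,
        probeset_ids=tuple(df["probeset_id"]),
        array_ids=tuple(array_cols),
    )


def write_expression_matrix(e: ProbesetExpressionMatrix, path) -> None:
    e.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_truth_table(path) -> pd.DataFrame:
    """Read a ``probeset_id<TAB>spiked<TAB>log2_fold_change`` truth TSV."""
    df = _read_tsv(path)
    need = ["probeset_id", "spiked"]
    if list(df.columns[: len(need)]) != need:
        raise ValueError(f"{path}: header must start with {need}")
    out = pd.DataFrame({"probeset_id": df["probeset_id"]})
    out["spiked"] = df["spiked"].str.lower().isin(["1", "true", "yes"])
    if "log2_fold_change" in df.columns:
        out["log2_fold_change"] = pd.to_numeric(df["log2_fold_change"], errors="coerce")
    else:
        out["log2_fold_change"] = np.nan
    return out


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_stat_table(path) -> GeneStatTable:
    df = pd.read_csv(path, sep="\t")
    df["degenerate"] = df["degenerate"].astype(bool)
    return GeneStatTable(df)


def write_stat_table(table: GeneStatTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
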