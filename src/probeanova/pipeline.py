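"""End-to-end pipeline: (simulate | ingest) -> normalize -> statistics ->
pooled permutation inference -> ROC, with a JSON artifact manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .comparators import block_statistic
from .containers import GeneStatTable, ProbeIntensityMatrix, SampleDesign
from .evaluation import TruthTable, tpr_fpr_curve
from .nested_anova import f_theoretical_df
from .permutation import (
    build_pooled_null,
    enumerate_label_permutations,
    pooled_pvalues,
    storey_qvalues,
)
from .preprocess import quantile_normalize
from .simulate import SimulationConfig, simulate_probe_dataset

__all__ = ["RunConfig", "run_end_to_end"]

log = logging.getLogger("probeanova")

#: Methods that can be driven through the common per-gene block interface.
PIPELINE_METHODS = ("nfm", "fc", "rmanova1", "rmanova2", "firstp")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: Path
    probe_matrix_path: Path | None = None
    design_path: Path | None = None
    truth_path: Path | None = None
    simulation: SimulationConfig | None = None
    methods: tuple[str, ...] = ("nfm",)
    normalize: bool = True
    reduce_permutations: bool = True
    pi0_mode: str = "storey_spline"
    control_label: str | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        bad = [m for m in self.methods if m not in PIPELINE_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {PIPELINE_METHODS}")
        if self.simulation is None and (
            self.probe_matrix_path is None or self.design_path is None
        ):
            raise ValueError("either a simulation config or input paths are required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class _Manifest:
    artifacts: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        self.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the artifact manifest."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest()
    t_start = time.monotonic()

    # --- ingest / simulate -------------------------------------------------
    stage = "ingest"
    try:
        truth = None
        if cfg.simulation is not None:
            sim = simulate_probe_dataset(cfg.simulation)
            matrix, design, truth = sim.probe_matrix, sim.design, sim.truth
            pio.write_probe_matrix(matrix, cfg.out_dir / "probe_matrix.tsv")
            pio.write_design(design, cfg.out_dir / "design.tsv")
            pio.write_truth_table(sim.truth_frame, cfg.out_dir / "truth.tsv")
            (cfg.out_dir / "simulation_metadata.json").write_text(
                json.dumps(sim.metadata, indent=2, default=str) + "\n"
            )
            for name in ("probe_matrix.tsv", "design.tsv", "truth.tsv",
                         "simulation_metadata.json"):
                manifest.add(name, cfg.out_dir / name)
        else:
            matrix = pio.read_probe_matrix(cfg.probe_matrix_path)
            design = pio.read_design(cfg.design_path, control_label=cfg.control_label)
            if cfg.truth_path is not None:
                truth = TruthTable.from_frame(pio.read_truth_table(cfg.truth_path))
        _log_stage(stage, t_start)

        # --- normalize -----------------------------------------------------
        stage = "normalize"
        if cfg.normalize:
            matrix = quantile_normalize(matrix)
            pio.write_probe_matrix(matrix, cfg.out_dir / "normalized_matrix.tsv")
            manifest.add("normalized_matrix.tsv", cfg.out_dir / "normalized_matrix.tsv")
        _log_stage(stage, t_start)

        # --- statistics + permutation inference ----------------------------
        stage = "statistics"
        perms = enumerate_label_permutations(design, reduce=cfg.reduce_permutations)
        probesets = list(matrix.probeset_ids)
        df_num, df_den = f_theoretical_df(design)
        for method in cfg.methods:
            stat_fn = block_statistic(method)
            observed = np.array(
                [stat_fn(block, design) for _, block in matrix.iter_genes()]
            )
            null = build_pooled_null(matrix, design, stat_fn, perms)
            p = pooled_pvalues(observed, null)
            q = storey_qvalues(p, pi0_mode=cfg.pi0_mode)
            table = GeneStatTable.from_stats(
                probesets,
                method,
                observed,
                df_num=df_num if method == "nfm" else None,
                df_den=df_den if method == "nfm" else None,
                p_value=p,
                q_value=q,
                degenerate=~np.isfinite(observed),
            )
            out = cfg.out_dir / f"stats_{method}.tsv"
            pio.write_stat_table(table, out)
            manifest.add(out.name, out)
            log.info(
                "method=%s G=%d K=%d pool=%d min_p=%.3g",
                method, null.n_genes, null.n_perms, null.size, null.min_attainable_p,
            )

            # --- ROC -------------------------------------------------------
            if truth is not None:
                curve = tpr_fpr_curve(observed, probesets, truth)
                out = cfg.out_dir / f"roc_{method}.tsv"
                curve.to_frame().to_csv(out, sep="\t", index=False, float_format="%.10g")
                manifest.add(out.name, out)
                log.info("method=%s auc=%.4f", method, curve.auc)
        _log_stage(stage, t_start)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = cfg.out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.artifacts, indent=2) + "\n")
    return manifest.artifacts


def _log_stage(stage: str, t_start: float) -> None:
    log.info("stage=%s elapsed=%.2fs", stage, time.monotonic() - t_start)
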