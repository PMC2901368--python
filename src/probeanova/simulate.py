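"""Generative probe-level spike-in simulator.

Emulates the structure of Affymetrix-style spike-in experiments: each gene
is a probeset of 11-20 probes measured on a small number of arrays split
between two treatment levels, with additive variance components

    Y_ijl = mu_g + T_i + S_j(i) + P_l + (TP)_il + eps_ijl

where ``S_j(i)`` is the per-array (subject) effect nested within treatment,
``P_l`` the probe affinity, ``(TP)_il`` an optional treatment x probe
interaction, and ``eps`` residual noise, all independent zero-mean
Gaussians.  A configurable fraction of genes is "spiked": their treatment
term encodes a known log2 fold change delta (symmetric -delta/2 / +delta/2
by default, or all-up in one level), recorded in the emitted truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ProbeIntensityMatrix, SampleDesign, Scale
from .evaluation import TruthTable

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_probe_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated spike-in experiment.

    Defaults mirror a small two-group GeneChip comparison: probesets of
    11-20 probes, three arrays per level, moderate array-to-array and
    residual noise (log2 scale), a dominant probe-affinity spread, 10% of
    genes spiked at a 1.5 log2 fold change.
    """

    n_genes: int = 500
    probes_per_gene: int | tuple[int, int] = (11, 20)
    n1: int = 3
    n2: int = 3
    mu_range: tuple[float, float] = (4.0, 12.0)
    sigma_subject: float = 0.3
    sigma_probe: float = 1.0
    sigma_interaction: float = 0.0
    sigma_resid: float = 0.3
    spike_fraction: float = 0.10
    log2_fold_change: float | Sequence[float] = 1.5
    all_up: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 arrays per level")
        if not (0.0 <= self.spike_fraction < 1.0):
            raise ValueError("spike_fraction must be in [0, 1)")
        for name in ("sigma_subject", "sigma_probe", "sigma_interaction", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self._probe_range()
        if lo < 1 or hi < lo:
            raise ValueError("invalid probes_per_gene")

    def _probe_range(self) -> tuple[int, int]:
        if isinstance(self.probes_per_gene, int):
            return self.probes_per_gene, self.probes_per_gene
        lo, hi = self.probes_per_gene
        return int(lo), int(hi)


@dataclass(frozen=True)
class SimulatedDataset:
    """Probe matrix, design, and spike-in truth of one simulated experiment."""

    probe_matrix: ProbeIntensityMatrix
    design: SampleDesign
    truth: TruthTable
    truth_frame: pd.DataFrame = field(repr=False)
    config: SimulationConfig

    @property
    def metadata(self) -> dict:
        meta = asdict(self.config)
        meta["generator"] = "numpy.random.default_rng(PCG64)"
        return meta


def simulate_probe_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under the nested variance-component model.

    Deterministic given ``cfg.seed``.  Spiked genes receive a treatment
    shift of +-delta/2 per level (or 0 / +delta with ``all_up``); all other
    terms are shared between spiked and non-spiked genes.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg._probe_range()
    N = cfg.n1 + cfg.n2

    array_ids = tuple(
        [f"ctl_{j + 1}" for j in range(cfg.n1)] + [f"trt_{j + 1}" for j in range(cfg.n2)]
    )
    labels = ("control",) * cfg.n1 + ("treatment",) * cfg.n2
    design = SampleDesign(
        array_ids=array_ids,
        treatment_of_array=dict(zip(array_ids, labels)),
        levels=("control", "treatment"),
    )
    level_of_col = np.array([0] * cfg.n1 + [1] * cfg.n2)

    n_spiked = round(cfg.n_genes * cfg.spike_fraction)
    spiked_idx = rng.choice(cfg.n_genes, size=n_spiked, replace=False)
    spiked_mask = np.zeros(cfg.n_genes, dtype=bool)
    spiked_mask[spiked_idx] = True
    if np.ndim(cfg.log2_fold_change) == 0:
        deltas_spiked = np.full(n_spiked, float(cfg.log2_fold_change))
    else:
        fc_levels = np.asarray(cfg.log2_fold_change, dtype=float)
        deltas_spiked = fc_levels[rng.integers(0, len(fc_levels), size=n_spiked)]
    delta = np.zeros(cfg.n_genes)
    delta[spiked_idx] = deltas_spiked

    probe_counts = rng.integers(lo, hi + 1, size=cfg.n_genes)
    mus = rng.uniform(*cfg.mu_range, size=cfg.n_genes)

    rows_values = []
    probe_ids: list[str] = []
    probeset_of_probe: dict[str, str] = {}
    probeset_ids = [f"ps{str(g + 1).zfill(len(str(cfg.n_genes)))}" for g in range(cfg.n_genes)]

    for g in range(cfg.n_genes):
        L = int(probe_counts[g])
        if cfg.all_up:
            t_levels = np.array([0.0, delta[g]])
        else:
            t_levels = np.array([-delta[g] / 2.0, delta[g] / 2.0])
        subj = rng.normal(0.0, cfg.sigma_subject, size=N)
        probe_eff = rng.normal(0.0, cfg.sigma_probe, size=L)
        interact = rng.normal(0.0, cfg.sigma_interaction, size=(2, L))
        eps = rng.normal(0.0, cfg.sigma_resid, size=(L, N))
        y = (
            mus[g]
            + t_levels[level_of_col][None, :]
            + subj[None, :]
            + probe_eff[:, None]
            + interact[level_of_col, :].T
            + eps
        )
        rows_values.append(y)
        for l in range(L):
            pid = f"{probeset_ids[g]}_p{l + 1}"
            probe_ids.append(pid)
            probeset_of_probe[pid] = probeset_ids[g]

    matrix = ProbeIntensityMatrix(
        values=np.vstack(rows_values),
        scale=Scale.LOG2,
        probe_ids=tuple(probe_ids),
        probeset_of_probe=probeset_of_probe,
        array_ids=array_ids,
    )
    truth_frame = pd.DataFrame(
        {
            "probeset_id": probeset_ids,
            "spiked": spiked_mask,
            "log2_fold_change": np.where(spiked_mask, delta, np.nan),
        }
    )
    truth = TruthTable(
        spiked=dict(zip(probeset_ids, spiked_mask.tolist())),
        fold_change={
            ps: float(d)
            for ps, d, sp in zip(probeset_ids, delta, spiked_mask)
            if sp
        },
    )
    return SimulatedDataset(
        probe_matrix=matrix,
        design=design,
        truth=truth,
        truth_frame=truth_frame,
        config=cfg,
    )
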