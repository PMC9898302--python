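"""Multistage gene-expression matrix simulation with known cluster labels.

Each cluster follows a distinct stage profile on the log2 scale (monotone
up, monotone down, flat, then steeper variants when more clusters are
requested), plus log-normal noise. Values are emitted on an FPKM-like linear
scale so the analysis side can apply its own log2(x+1) normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import SimCohortDesign


@dataclass
class ExpressionSim:
    matrix: pd.DataFrame          # genes x samples, linear scale
    labels: np.ndarray            # true cluster index per gene
    sample_stages: pd.Series      # stage label per sample column


def _cluster_profiles(k: int, n_stages: int) -> list[np.ndarray]:
    """Distinct stage profiles on the log2 scale.

    Order: monotone up, monotone down, peak, valley, then steeper monotone
    pairs. A flat profile is deliberately not used: per-gene standardization
    (applied before clustering) maps a flat-plus-noise profile to pure noise,
    which no clustering can recover.
    """
    t = np.arange(n_stages, dtype=float)
    tent = np.minimum(t, n_stages - 1 - t) * 1.5
    base = [t, -t, tent, -tent]
    step = 2.0
    while len(base) < k:
        base.extend([step * t, -step * t])
        step += 1.0
    return base[:k]


def simulate_expression_matrix(
    genes: int,
    design: SimCohortDesign,
    trend_clusters: int,
    noise_sd: float = 0.3,
    base_log2: float = 6.0,
    rng_seed: Optional[int] = None,
) -> ExpressionSim:
    if trend_clusters < 2:
        raise ValueError("trend_clusters must be >= 2")
    if genes < trend_clusters:
        raise ValueError(
            f"genes ({genes}) must be >= trend_clusters ({trend_clusters})"
        )
    rng = np.random.default_rng(
        design.rng_seed if rng_seed is None else rng_seed
    )
    stages = design.stages
    n_stages = len(stages)
    sample_ids = [
        f"{s}_{k:02d}" for s in stages for k in range(design.samples_per_stage)
    ]
    stage_idx = np.repeat(np.arange(n_stages), design.samples_per_stage)

    labels = np.arange(genes) % trend_clusters
    shapes = _cluster_profiles(trend_clusters, n_stages)

    log2_vals = np.empty((genes, len(sample_ids)))
    for g in range(genes):
        profile = base_log2 + shapes[labels[g]][stage_idx]
        noise = rng.normal(0.0, noise_sd, size=len(sample_ids)) if noise_sd > 0 else 0.0
        log2_vals[g] = profile + noise
    matrix = pd.DataFrame(
        np.exp2(log2_vals) - 1.0,
        index=[f"gene_{g:04d}" for g in range(genes)],
        columns=sample_ids,
    )
    sample_stages = pd.Series(
        [stages[i] for i in stage_idx], index=sample_ids, name="stage"
    )
    return ExpressionSim(matrix=matrix, labels=labels, sample_stages=sample_stages)
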