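"""Cohort-level container: samples x sites editing levels plus metadata.

Site keys are ``(mirna_id, mature_position)`` tuples; ``mature_position`` is
1-based along the mature strand and 0 for sites inside a hairpin but outside
any mature arm. Missing editing values (site uncovered in a sample) are NaN
and are excluded from all means and rank statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SiteKey = tuple[str, int]


@dataclass
class CohortEditingMatrix:
    editing: pd.DataFrame       # index: site keys, columns: sample ids
    site_meta: pd.DataFrame     # index: site keys; contig, pos, in_seed
    samples: pd.DataFrame       # index: sample ids; stage, group
    tpm: pd.DataFrame           # index: mirna_id; columns: sample ids
    stage_order: tuple[str, ...]

    def __post_init__(self):
        unknown = set(self.samples["stage"]) - set(self.stage_order)
        if unknown:
            raise ValueError(f"samples carry undeclared stages: {sorted(unknown)}")

    @property
    def site_keys(self) -> list[SiteKey]:
        return list(self.editing.index)

    def values_for(self, site: SiteKey) -> pd.Series:
        # the index holds tuples as opaque objects (not a MultiIndex)
        return self.editing.iloc[self.editing.index.get_loc(site)]

    def mean_editing(self, site: SiteKey) -> float:
        """Mean editing level over covered samples only."""
        vals = self.values_for(site)
        return float(vals.mean()) if vals.notna().any() else float("nan")

    def n_samples_at(self, site: SiteKey, threshold: float) -> int:
        vals = self.values_for(site)
        return int((vals >= threshold).sum())

    def host_mean_tpm(self, mirna_id: str) -> float:
        if mirna_id not in self.tpm.index:
            return 0.0
        return float(self.tpm.loc[mirna_id].mean())

    def stage_means(self, site: SiteKey) -> dict[str, float]:
        vals = self.values_for(site)
        out = {}
        for stage in self.stage_order:
            sids = self.samples.index[self.samples["stage"] == stage]
            sub = vals.loc[[s for s in sids if s in vals.index]]
            out[stage] = float(sub.mean()) if sub.notna().any() else float("nan")
        return out

    # ------------------------------------------------------------------ I/O
    def write(self, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flat = self.editing.copy()
        flat.index = [f"{m}:{p}" for m, p in flat.index]
        paths = {
            "editing": outdir / f"{prefix}_editing.tsv",
            "samples": outdir / f"{prefix}_samples.tsv",
            "tpm": outdir / f"{prefix}_tpm.tsv",
        }
        flat.to_csv(paths["editing"], sep="\t")
        self.samples.to_csv(paths["samples"], sep="\t")
        self.tpm.to_csv(paths["tpm"], sep="\t")
        return paths
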