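"""Seed-hotspot candidate selection and cross-cohort intersection.

Cohort rule "catholic": editing rises with disease stage (nondecreasing
stage means, minimum total rise, positive rank correlation). Cohort rule
"tcga": editing elevated in the tumor group versus the normal group
(two-sided rank-sum test plus a mean direction check). Both operate on a
CohortEditingMatrix restricted to seed-region sites (mature positions 2-8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SEED_END, SEED_START
from .cohort import CohortEditingMatrix, SiteKey


@dataclass(frozen=True)
class SelectConfig:
    trend_delta: float = 0.01       # minimum rise from first to last stage mean
    require_positive_rho: bool = True
    alpha_two_group: float = 0.05
    tumor_group: str = "tumor"
    normal_group: str = "normal"


@dataclass
class TrendReport:
    stage_means: dict[str, float]
    rho: float
    p_value: float
    monotone: bool


@dataclass
class TwoGroupReport:
    mean_tumor: float
    mean_normal: float
    p_value: float
    direction: str  # 'increased', 'decreased', or 'none'


@dataclass(frozen=True)
class CandidateMiRNA:
    mirna_id: str
    mature_position: int
    stage_means: tuple[tuple[str, float], ...]
    statistic: float
    p_value: float
    cohort: str

    @property
    def key(self) -> SiteKey:
        return (self.mirna_id, self.mature_position)


def annotate_seed_sites(site_keys: Sequence[SiteKey]) -> list[SiteKey]:
    """Project onto sites at mature positions 2-8 (idempotent)."""
    out = []
    for key in site_keys:
        pos = key[1]
        if pos is None or pos == 0:
            warnings.warn(f"site {key} lacks a mature mapping; excluded")
            continue
        if SEED_START <= pos <= SEED_END:
            out.append(key)
    return out


def stage_trend(
    matrix: CohortEditingMatrix,
    site: SiteKey,
    delta: float = 0.01,
) -> TrendReport:
    """Per-stage means plus Spearman rho of editing vs ordinal stage."""
    means = matrix.stage_means(site)
    covered_stages = [s for s, m in means.items() if not np.isnan(m)]
    if len(covered_stages) < 2:
        raise ValueError("stage trend requires >= 2 stages with covered samples")
    vals = matrix.values_for(site)
    ordinal = {s: i for i, s in enumerate(matrix.stage_order)}
    xs, ys = [], []
    for sid, v in vals.items():
        if not np.isnan(v):
            xs.append(ordinal[matrix.samples.loc[sid, "stage"]])
            ys.append(v)
    if len(set(ys)) < 2 or len(set(xs)) < 2:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(xs, ys)
    seq = [means[s] for s in matrix.stage_order if not np.isnan(means[s])]
    nondecreasing = all(b >= a for a, b in zip(seq, seq[1:]))
    monotone = nondecreasing and (seq[-1] - seq[0] >= delta)
    return TrendReport(stage_means=means, rho=float(rho), p_value=float(p),
                       monotone=monotone)


def tumor_vs_normal(
    matrix: CohortEditingMatrix,
    site: SiteKey,
    alpha: float = 0.05,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
) -> TwoGroupReport:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected)."""
    vals = matrix.values_for(site)
    groups = matrix.samples["group"]
    tum = vals[[s for s in vals.index if groups.get(s) == tumor_group]].dropna()
    nor = vals[[s for s in vals.index if groups.get(s) == normal_group]].dropna()
    if len(tum) == 0 or len(nor) == 0:
        raise ValueError("both groups must be non-empty")
    if tum.nunique() == 1 and nor.nunique() == 1 and tum.iloc[0] == nor.iloc[0]:
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(tum, nor, alternative="two-sided",
                                  method="asymptotic")
    mean_t, mean_n = float(tum.mean()), float(nor.mean())
    if p < alpha and mean_t > mean_n:
        direction = "increased"
    elif p < alpha and mean_t < mean_n:
        direction = "decreased"
    else:
        direction = "none"
    return TwoGroupReport(mean_tumor=mean_t, mean_normal=mean_n,
                          p_value=float(p), direction=direction)


def select_candidates(
    matrix: CohortEditingMatrix,
    rule: str,
    config: SelectConfig = SelectConfig(),
    site_keys: Optional[Sequence[SiteKey]] = None,
) -> tuple[list[CandidateMiRNA], dict]:
    """Apply the per-cohort selection rule to seed-restricted sites.

    Returns (candidates, log) where log maps rejected site keys to the
    reason ('NON_SEED', 'NO_STAGE_TREND' or 'NOT_INCREASED_IN_TUMOR').
    """
    if rule not in ("catholic", "tcga"):
        raise ValueError(f"unknown selection rule {rule!r}")
    keys = list(site_keys) if site_keys is not None else matrix.site_keys
    log: dict = {}
    seed_keys = []
    for key in keys:
        if key[1] and SEED_START <= key[1] <= SEED_END:
            seed_keys.append(key)
        else:
            log[key] = "NON_SEED"
    candidates = []
    for key in seed_keys:
        means = matrix.stage_means(key)
        if rule == "catholic":
            rep = stage_trend(matrix, key, delta=config.trend_delta)
            ok = rep.monotone and (not config.require_positive_rho or rep.rho > 0)
            if ok:
                candidates.append(
                    CandidateMiRNA(key[0], key[1], tuple(means.items()),
                                   rep.rho, rep.p_value, "catholic")
                )
            else:
                log[key] = "NO_STAGE_TREND"
        else:
            rep = tumor_vs_normal(
                matrix, key, alpha=config.alpha_two_group,
                tumor_group=config.tumor_group, normal_group=config.normal_group,
            )
            if rep.direction == "increased":
                candidates.append(
                    CandidateMiRNA(key[0], key[1], tuple(means.items()),
                                   rep.mean_tumor - rep.mean_normal,
                                   rep.p_value, "tcga")
                )
            else:
                log[key] = "NOT_INCREASED_IN_TUMOR"
    return candidates, log


def intersect_cohorts(
    candidates_a: Sequence[CandidateMiRNA],
    candidates_b: Sequence[CandidateMiRNA],
) -> list[tuple[CandidateMiRNA, CandidateMiRNA]]:
    """Candidates present in both cohorts, keyed by (mirna_id, position)."""
    by_key_b = {c.key: c for c in candidates_b}
    out = []
    for ca in candidates_a:
        cb = by_key_b.get(ca.key)
        if cb is not None:
            out.append((ca, cb))
    return out


def candidates_to_frame(pairs_or_candidates) -> pd.DataFrame:
    rows = []
    for item in pairs_or_candidates:
        cs = item if isinstance(item, tuple) else (item,)
        for c in cs:
            rows.append(
                dict(mirna_id=c.mirna_id, mature_position=c.mature_position,
                     cohort=c.cohort, statistic=c.statistic, p_value=c.p_value,
                     **{f"mean_{s}": m for s, m in c.stage_means})
            )
    return pd.DataFrame(rows)
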