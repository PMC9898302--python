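"""Cohort-level statistics: ROC/AUC, 2x2 mutual exclusivity, copy-number
call summaries, and rank correlation.

Survival analysis (Kaplan-Meier / log-rank) is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COPY_NUMBER_CATEGORIES = ("deletion", "none", "gain", "amplification")
ALTERED_CATEGORIES = ("gain", "amplification")


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame  # threshold, sensitivity, specificity


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties.

    The 95% CI uses the Hanley-McNeil variance formula. Curve points are
    emitted at every distinct threshold ("score >= threshold" is positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))

    rows = []
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        rows.append(dict(threshold=float(thr), sensitivity=tp / n1,
                         specificity=tn / n0))
    curve = pd.DataFrame(rows)
    return RocResult(auc=float(auc), ci_low=float(max(0.0, auc - half)),
                     ci_high=float(min(1.0, auc + half)), curve=curve)


@dataclass
class MutexResult:
    counts: np.ndarray       # [[both, a_only], [b_only, neither]]
    chi2: float
    p_value: float
    odds_ratio: float
    direction: str           # 'mutually_exclusive', 'co_occurring', 'none'
    warning: Optional[str] = None


def mutual_exclusivity(
    event_a: Sequence[bool],
    event_b: Sequence[bool],
    continuity_correction: bool = False,
    method: str = "chisq",
) -> MutexResult:
    """Two-sided association test on a 2x2 presence/absence table.

    Default is the chi-square test without continuity correction; Fisher's
    exact test is available via ``method='fisher'``. The odds ratio uses the
    Haldane half-count correction when any cell is zero; OR < 1 is read as
    mutual exclusivity.
    """
    a = np.asarray(event_a, dtype=bool)
    b = np.asarray(event_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need equal-length, non-empty event vectors")
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    table = np.array([[n11, n10], [n01, n00]], dtype=float)

    warning = None
    degenerate = (a.all() or (~a).all() or b.all() or (~b).all())
    if degenerate:
        warning = "degenerate margin: an event never or always occurs; p undefined"
        chi2 = float("nan")
        p = float("nan")
    elif method == "fisher":
        chi2 = float("nan")
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif method == "chisq":
        chi2, p, _, _ = stats.chi2_contingency(
            table, correction=continuity_correction
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    cells = table.copy()
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    if odds < 1:
        direction = "mutually_exclusive"
    elif odds > 1:
        direction = "co_occurring"
    else:
        direction = "none"
    if warning:
        warnings.warn(warning)
    return MutexResult(counts=table.astype(int), chi2=float(chi2),
                       p_value=float(p), odds_ratio=float(odds),
                       direction=direction, warning=warning)


@dataclass
class CopyNumberSummary:
    counts: dict[str, int]
    n: int
    percent_altered_raw: float
    percent_altered: int     # rounded to the nearest integer


def copy_number_summary(calls: Sequence[str]) -> CopyNumberSummary:
    """Counts per category and percent altered (gain + amplification)."""
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one call")
    unknown = set(calls) - set(COPY_NUMBER_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown copy-number categories: {sorted(unknown)}")
    counts = {c: calls.count(c) for c in COPY_NUMBER_CATEGORIES}
    n = len(calls)
    altered = sum(counts[c] for c in ALTERED_CATEGORIES)
    raw = 100.0 * altered / n
    return CopyNumberSummary(counts=counts, n=n, percent_altered_raw=raw,
                             percent_altered=int(round(raw)))


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman rho with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input: rank correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
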