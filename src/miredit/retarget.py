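"""Edited-miRNA derivation, seed-match target scanning, target deltas, and
fuzzy c-means expression-pattern shortlisting.

Seed-match site types follow the canonical conventions: with the seed being
mature positions 2-8, a UTR window (5'->3') matches as

* ``8mer``      reverse complement of positions 2-8, followed by an A
* ``7mer-m8``   reverse complement of positions 2-8
* ``7mer-A1``   reverse complement of positions 2-7, followed by an A
* ``6mer``      reverse complement of positions 2-7

Each window start is assigned its single highest-priority matching type
(8mer > 7mer-m8 > 7mer-A1 > 6mer); overlapping windows are all reported.
Only site typing is implemented — no context scoring or conservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp, to_dna, to_rna, validate_alphabet

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SITE_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}


# ------------------------------------------------------------------ editing


@dataclass(frozen=True)
class EditedMirna:
    mirna_id: str
    canonical: str       # RNA alphabet
    edit_position: int   # 1-based
    edited: str

    @property
    def canonical_seed(self) -> str:
        return self.canonical[1:8]

    @property
    def edited_seed(self) -> str:
        return self.edited[1:8]


def apply_edit(
    mature_sequence: str,
    position: int,
    from_base: str = "A",
    to_base: str = "G",
    mirna_id: str = "miRNA",
) -> EditedMirna:
    """Substitute one base of a mature sequence (1-based position)."""
    rna = to_rna(mature_sequence)
    validate_alphabet(rna, what="mature sequence")
    if len(rna) < 8:
        raise ValueError("mature sequence must span at least positions 1-8")
    if not (1 <= position <= len(rna)):
        raise ValueError(f"position {position} outside 1..{len(rna)}")
    found = rna[position - 1]
    if found != to_rna(from_base):
        raise ValueError(
            f"expected {from_base} at position {position}, found {found}"
        )
    edited = rna[:position - 1] + to_rna(to_base) + rna[position:]
    return EditedMirna(mirna_id=mirna_id, canonical=rna,
                       edit_position=position, edited=edited)


# ------------------------------------------------------------- seed matches


@dataclass(frozen=True)
class SeedMatchSite:
    gene: Optional[str]
    start: int          # 0-based UTR coordinate of the match
    site_type: str
    form: str           # 'canonical' or 'edited'


def site_motifs(seed: str) -> dict[str, str]:
    """UTR match motifs (DNA, 5'->3') for a 7-nt seed (positions 2-8)."""
    seed = to_dna(seed)
    if len(seed) != 7:
        raise ValueError("seed must be the 7-mer of mature positions 2-8")
    core28 = revcomp(seed)        # complement to positions 2-8
    core27 = revcomp(seed[:6])    # complement to positions 2-7
    return {
        "8mer": core28 + "A",
        "7mer-m8": core28,
        "7mer-A1": core27 + "A",
        "6mer": core27,
    }


def _seed_of(mirna: str) -> str:
    seq = to_dna(mirna)
    if len(seq) == 7:
        return seq
    if len(seq) >= 8:
        return seq[1:8]
    raise ValueError("need a 7-mer seed or a mature sequence of >= 8 nt")


def scan_utr(mirna_form: str, utr_sequence: str, form: str = "canonical") -> list[SeedMatchSite]:
    """All seed-match sites of one miRNA form in one UTR.

    ``mirna_form`` may be a full mature sequence (seed extracted from
    positions 2-8) or the 7-mer seed itself; RNA and DNA alphabets are
    accepted. N never matches.
    """
    utr = to_dna(utr_sequence)
    validate_alphabet(utr, what="UTR sequence")
    motifs = site_motifs(_seed_of(mirna_form))
    ordered = [(t, motifs[t]) for t in SITE_TYPES]
    out: list[SeedMatchSite] = []
    for i in range(len(utr)):
        for site_type, motif in ordered:
            if utr.startswith(motif, i) and i + len(motif) <= len(utr):
                out.append(SeedMatchSite(None, i, site_type, form))
                break
    return out


def predict_targets(edit: EditedMirna, utrs: Mapping[str, str]) -> pd.DataFrame:
    """Scan every UTR with both miRNA forms; returns a flat site table."""
    rows = []
    for gene, utr in utrs.items():
        for form, seq in (("canonical", edit.canonical), ("edited", edit.edited)):
            for s in scan_utr(seq, utr, form=form):
                rows.append(dict(gene=gene, form=form, site_type=s.site_type,
                                 start=s.start))
    return pd.DataFrame(rows, columns=["gene", "form", "site_type", "start"])


@dataclass
class TargetDelta:
    lost: list[str]      # canonical-only targets, best-site ranked
    gained: list[str]    # edited-only targets
    shared: list[str]


def _rank_genes(site_map: Mapping[str, list[SeedMatchSite]], genes) -> list[str]:
    def score(g):
        sites = site_map[g]
        best = min(_SITE_PRIORITY[s.site_type] for s in sites)
        return (best, -len(sites), g)

    return sorted(genes, key=score)


def target_delta(
    canonical_sites: Mapping[str, Sequence[SeedMatchSite]],
    edited_sites: Mapping[str, Sequence[SeedMatchSite]],
) -> TargetDelta:
    """Partition genes into lost / gained / shared target sets."""
    canon = {g: list(v) for g, v in canonical_sites.items() if v}
    edited = {g: list(v) for g, v in edited_sites.items() if v}
    lost = set(canon) - set(edited)
    gained = set(edited) - set(canon)
    shared = set(canon) & set(edited)
    return TargetDelta(
        lost=_rank_genes(canon, lost),
        gained=_rank_genes(edited, gained),
        shared=_rank_genes({**edited, **canon}, shared),
    )


def sites_by_gene(frame: pd.DataFrame, form: str) -> dict[str, list[SeedMatchSite]]:
    out: dict[str, list[SeedMatchSite]] = {}
    sub = frame[frame["form"] == form]
    for _, row in sub.iterrows():
        out.setdefault(row["gene"], []).append(
            SeedMatchSite(row["gene"], int(row["start"]), row["site_type"], form)
        )
    return out


# ---------------------------------------------------------------- clustering


@dataclass
class FuzzyClustering:
    membership: pd.DataFrame   # genes x clusters, rows sum to 1
    centers: pd.DataFrame      # clusters x features (stages)
    fuzzifier: float
    objective_history: list[float]
    n_iter: int

    def dominant_cluster(self, gene: str) -> tuple[int, float]:
        row = self.membership.loc[gene]
        c = int(np.argmax(row.values))
        return c, float(row.iloc[c])


def prepare_profiles(
    expression: pd.DataFrame,
    sample_stages: pd.Series,
    stage_order: Sequence[str],
) -> pd.DataFrame:
    """log2(x+1), collapse to per-stage means, standardize per gene.

    Zero-variance genes are excluded with a warning.
    """
    log = np.log2(expression + 1.0)
    by_stage = pd.DataFrame(
        {s: log.loc[:, sample_stages[sample_stages == s].index].mean(axis=1)
         for s in stage_order}
    )
    sd = by_stage.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} zero-variance gene(s) from clustering"
        )
        by_stage = by_stage.loc[~flat]
        sd = sd.loc[~flat]
    return by_stage.sub(by_stage.mean(axis=1), axis=0).div(sd, axis=0)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    rng_seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means on per-gene standardized profiles.

    Alternates membership updates u_ij = 1 / sum_k (d_ij/d_kj)^(2/(m-1))
    and membership^m-weighted center updates until the largest center shift
    drops below ``tol`` or ``max_iter`` is reached. Centers are initialized
    from a seeded random selection of distinct genes.
    """
    if c < 2:
        raise ValueError("cluster count c must be >= 2")
    if c > len(profiles):
        raise ValueError("more clusters than genes")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = profiles.to_numpy(dtype=float)
    n, _ = x.shape
    rng = np.random.default_rng(rng_seed)
    centers = x[rng.choice(n, size=c, replace=False)].copy()
    exponent = 2.0 / (m - 1.0)
    history: list[float] = []
    u = np.full((n, c), 1.0 / c)
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        # u_ij proportional to d_ij^(-2/(m-1)); points sitting on a center
        # get full membership there
        u = np.zeros_like(d2)
        np.power(d2, -(exponent / 2.0), out=u, where=~zero)
        row_zero = zero.any(axis=1)
        u[row_zero] = zero[row_zero].astype(float)
        u /= u.sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        history.append(float((um * d2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    membership = pd.DataFrame(u, index=profiles.index,
                              columns=[f"cluster_{k}" for k in range(c)])
    center_df = pd.DataFrame(centers, index=[f"cluster_{k}" for k in range(c)],
                             columns=profiles.columns)
    return FuzzyClustering(membership=membership, centers=center_df,
                           fuzzifier=m, objective_history=history, n_iter=it)


def _monotone(center: np.ndarray, direction: str, tol: float, min_span: float) -> bool:
    diffs = np.diff(center)
    span = center[-1] - center[0]
    if direction == "up":
        return bool((diffs >= -tol).all() and span >= min_span)
    return bool((diffs <= tol).all() and -span >= min_span)


def shortlist_by_pattern(
    delta: TargetDelta,
    clustering: FuzzyClustering,
    membership_threshold: float = 0.5,
    monotone_tol: float = 0.05,
    min_span: float = 0.5,
) -> dict[str, list[str]]:
    """Filter target sets by their dominant cluster's stage profile.

    Lost (canonical-only) targets are kept when their dominant cluster's
    center is stage-monotone increasing — consistent with target
    re-expression as editing rises; gained (edited-only) targets when it is
    monotone decreasing. Genes absent from the clustering are skipped with
    a warning.
    """
    out = {"lost": [], "gained": []}
    for label, genes, direction in (
        ("lost", delta.lost, "up"), ("gained", delta.gained, "down")
    ):
        for gene in genes:
            if gene not in clustering.membership.index:
                warnings.warn(f"gene {gene} absent from clustering; skipped")
                continue
            k, grade = clustering.dominant_cluster(gene)
            if grade < membership_threshold:
                continue
            center = clustering.centers.iloc[k].to_numpy()
            if _monotone(center, direction, monotone_tol, min_span):
                out[label].append(gene)
    return out
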