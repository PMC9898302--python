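"""Strand-aware pileup, per-site A->G editing calls, and site/cohort filters.

The editing signature is always reported on the miRNA strand: for
minus-strand hairpins, base counts and the reference base are complemented
so editing evidence is A->G everywhere downstream. The per-site null is an
exact upper-tail binomial test at a per-base A->G error rate of
``error_rate / 3`` (uniform substitution spectrum), with Bonferroni control
over the sites tested in the same sample.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import complement, encode
from .annotation import MirnaAnnotation, SEED_END, SEED_START
from .smallrna_align import AlignmentRecord

ERROR_RATE_FLOOR = 1e-6

_COMP_ORDER = [3, 2, 1, 0]  # complement permutation of A,C,G,T counts

AlnInput = Union[Sequence[AlignmentRecord], dict]


@dataclass(frozen=True)
class SitePileup:
    contig: str
    pos: int                       # genomic, 0-based
    ref_base: str                  # miRNA-strand reference base
    counts: tuple[int, int, int, int]  # A, C, G, T on the miRNA strand
    mirna_id: Optional[str]        # hairpin id, None outside pre-miRNAs
    mature_position: int           # 1-based; 0 if outside any mature arm
    mito: bool = False

    @property
    def coverage(self) -> int:
        return sum(self.counts)

    @property
    def in_seed(self) -> bool:
        return SEED_START <= self.mature_position <= SEED_END

    def count(self, base: str) -> int:
        return self.counts["ACGT".index(base)]


@dataclass
class EditingSite:
    site: SitePileup
    editing_level: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    filter_flags: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int]:
        """(miRNA id, mature position); genomic fallback keys keep non-mature
        and intergenic sites distinct."""
        if self.site.mirna_id is None:
            return (f"{self.site.contig}:{self.site.pos}", 0)
        if self.site.mature_position == 0:
            return (f"{self.site.mirna_id}@{self.site.pos}", 0)
        return (self.site.mirna_id, self.site.mature_position)


@dataclass(frozen=True)
class CallConfig:
    alpha_bonferroni: float = 0.1
    min_coverage: int = 10
    error_rate: Union[float, str] = "AUTO"
    min_mean_editing: float = 0.05
    min_tpm: float = 1.0
    min_samples_at_threshold: int = 10

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        for name in ("alpha_bonferroni", "min_mean_editing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.error_rate != "AUTO" and not (0.0 <= float(self.error_rate) <= 1.0):
            raise ValueError("error_rate must be AUTO or a probability")


def collapse_alignments(records: Iterable[AlignmentRecord]) -> Counter:
    """Collapse mapped records to (contig, start, seq) -> count."""
    c: Counter = Counter()
    for r in records:
        if r.mapped:
            c[(r.contig, r.start, r.seq)] += 1
    return c


def _as_counter(alignments: AlnInput) -> Counter:
    if isinstance(alignments, (dict, Counter)):
        return Counter(alignments)
    return collapse_alignments(alignments)


def pileup(
    alignments: AlnInput,
    annotation: MirnaAnnotation,
    reference: dict[str, str],
    include_outside: bool = False,
) -> list[SitePileup]:
    """Per-site base tallies in miRNA-strand space.

    Positions outside annotated pre-miRNA intervals are suppressed unless
    ``include_outside`` is set (they are then emitted in genomic '+' space
    so the downstream NOT_PREMIRNA filter can see and flag them).
    """
    counter = _as_counter(alignments)
    known = set(reference)
    arrays: dict[str, np.ndarray] = {}
    for (contig, start, seq), n in counter.items():
        if contig not in known:
            raise ValueError(f"alignment on unknown contig {contig!r}")
        arr = arrays.get(contig)
        if arr is None:
            arr = arrays[contig] = np.zeros((4, len(reference[contig])), dtype=np.int64)
        codes = encode(seq)
        pos = np.arange(start, start + len(seq))
        ok = codes < 4
        np.add.at(arr, (codes[ok], pos[ok]), n)

    out: list[SitePileup] = []
    for contig, arr in arrays.items():
        covered = np.nonzero(arr.sum(axis=0) > 0)[0]
        for pos in covered:
            pre, mature, matpos = annotation.locate(contig, int(pos))
            if pre is None and not include_outside:
                continue
            counts = tuple(int(arr[b, pos]) for b in range(4))
            ref = reference[contig][pos]
            if pre is not None and pre.strand == "-":
                counts = tuple(counts[i] for i in _COMP_ORDER)
                ref = complement(ref)
            out.append(
                SitePileup(
                    contig=contig, pos=int(pos), ref_base=ref, counts=counts,
                    mirna_id=pre.id if pre else None,
                    mature_position=matpos if matpos else 0,
                    mito=pre.mito if pre else False,
                )
            )
    out.sort(key=lambda s: (s.contig, s.pos))
    return out


def estimate_error_rate(pileups: Sequence[SitePileup], min_coverage: int = 10) -> float:
    """Pooled non-(A->G) mismatch rate; the editing signature is excluded."""
    mismatches = 0
    total = 0
    for s in pileups:
        if s.coverage < min_coverage:
            continue
        total += s.coverage
        if s.ref_base == "A":
            mismatches += s.count("C") + s.count("T")
        elif s.ref_base in "CGT":
            mismatches += s.coverage - s.count(s.ref_base)
    if total == 0:
        raise ValueError(
            "no site with sufficient coverage to estimate the error rate; "
            "set error_rate explicitly"
        )
    return max(mismatches / total, ERROR_RATE_FLOOR)


def binomial_p_raw(g: int, n: int, per_base_rate: float) -> float:
    """Exact upper-tail P(X >= g) for X ~ Binomial(n, per_base_rate)."""
    if n == 0 or g == 0:
        return 1.0
    return float(stats.binom.sf(g - 1, n, per_base_rate))


def call_editing_sites(
    pileups: Sequence[SitePileup],
    config: CallConfig = CallConfig(),
) -> list[EditingSite]:
    """Test every A-reference site meeting the coverage floor.

    The Bonferroni family is the number of sites tested in this call (one
    sample's eligible A sites).
    """
    if config.error_rate == "AUTO":
        error_rate = estimate_error_rate(pileups, config.min_coverage)
    else:
        error_rate = float(config.error_rate)
    per_base = error_rate / 3.0
    eligible = [
        s for s in pileups
        if s.ref_base == "A" and s.coverage >= config.min_coverage
    ]
    n_tests = len(eligible)
    out: list[EditingSite] = []
    for s in eligible:
        a, g = s.count("A"), s.count("G")
        denom = a + g
        level = g / denom if denom else 0.0
        p_raw = binomial_p_raw(g, denom, per_base)
        p_bonf = min(1.0, p_raw * n_tests)
        out.append(
            EditingSite(
                site=s, editing_level=level, p_raw=p_raw, p_bonferroni=p_bonf,
                significant=p_bonf <= config.alpha_bonferroni,
            )
        )
    return out


def load_variant_positions(source) -> set[tuple[str, int]]:
    """Known-variant positions as (contig, 0-based pos), ref-length expanded."""
    if isinstance(source, set):
        return source
    if isinstance(source, (str, Path)):
        import pysam

        out: set[tuple[str, int]] = set()
        with pysam.VariantFile(str(source)) as vf:
            for rec in vf:
                for off in range(len(rec.ref or "N")):
                    out.add((rec.contig, rec.start + off))
        return out
    # iterable of VariantRecord-like objects
    out = set()
    for v in source:
        for off in range(len(v.ref)):
            out.add((v.contig, v.pos + off))
    return out


def filter_sites(
    sites: Sequence[EditingSite],
    annotation: MirnaAnnotation,
    known_variants,
) -> tuple[list[EditingSite], list[EditingSite]]:
    """Apply the positional exclusion rules; returns (kept, flagged).

    A site is dropped iff it lies outside every pre-miRNA, on a
    mitochondrial hairpin, or overlaps any known-variant record regardless
    of allele. Flags are ordered NOT_PREMIRNA > MITOCHONDRIAL > KNOWN_SNP.
    """
    variant_pos = load_variant_positions(known_variants)
    kept, flagged = [], []
    for es in sites:
        s = es.site
        flags = []
        if s.mirna_id is None:
            flags.append("NOT_PREMIRNA")
        elif s.mito:
            flags.append("MITOCHONDRIAL")
        if (s.contig, s.pos) in variant_pos:
            flags.append("KNOWN_SNP")
        es.filter_flags = set(flags)
        (flagged if flags else kept).append(es)
    return kept, flagged


def quantify_expression(alignments: AlnInput, annotation: MirnaAnnotation) -> pd.DataFrame:
    """Per-mature-miRNA counts and TPM.

    A read counts toward a mature arm when its alignment midpoint falls in
    the mature interval. TPM = (count/length_kb) / sum(count/length_kb) * 1e6.
    """
    counter = _as_counter(alignments)
    rows = []
    for pre, mature in annotation.matures():
        rows.append(dict(mature_id=mature.id, mirna_id=pre.id,
                         length=mature.length, count=0))
    df = pd.DataFrame(rows).set_index("mature_id")
    intervals = [
        (pre.contig, mature.start, mature.end, mature.id)
        for pre, mature in annotation.matures()
    ]
    for (contig, start, seq), n in counter.items():
        mid = start + len(seq) // 2
        for ctg, mstart, mend, mid_id in intervals:
            if ctg == contig and mstart <= mid < mend:
                df.loc[mid_id, "count"] += n
                break
    rate = df["count"] / (df["length"] / 1000.0)
    total = rate.sum()
    if total == 0:
        warnings.warn("no reads counted toward any mature miRNA; TPM all zero")
        df["tpm"] = 0.0
    else:
        df["tpm"] = rate / total * 1e6
    return df


def apply_cohort_filters(
    matrix,
    rule: str,
    config: CallConfig = CallConfig(),
) -> tuple[list, dict]:
    """Cohort-level retention rules.

    ``MEAN_AND_TPM``: mean editing (over covered samples) >= 5% AND host
    miRNA mean TPM >= 1. ``N_SAMPLES``: editing >= 5% in at least
    ``min_samples_at_threshold`` samples. Returns (retained site keys,
    {dropped site key: [reasons]}).
    """
    if rule not in ("MEAN_AND_TPM", "N_SAMPLES"):
        raise ValueError(f"unknown cohort rule {rule!r}")
    retained = []
    dropped: dict = {}
    for key in matrix.site_keys:
        reasons = []
        if rule == "MEAN_AND_TPM":
            mean = matrix.mean_editing(key)
            if not (mean >= config.min_mean_editing):
                reasons.append("MEAN_EDITING_BELOW_MIN")
            if matrix.host_mean_tpm(key[0]) < config.min_tpm:
                reasons.append("TPM_BELOW_MIN")
        else:
            n_at = matrix.n_samples_at(key, config.min_mean_editing)
            if n_at < config.min_samples_at_threshold:
                reasons.append("TOO_FEW_SAMPLES_AT_THRESHOLD")
        if reasons:
            dropped[key] = reasons
        else:
            retained.append(key)
    return retained, dropped


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    """Flat per-site table matching the TSV output contract."""
    rows = []
    for es in sites:
        s = es.site
        rows.append(
            dict(
                contig=s.contig, pos_1based=s.pos + 1,
                mirna=s.mirna_id or "", mature_pos=s.mature_position,
                in_seed=s.in_seed,
                A=s.counts[0], C=s.counts[1], G=s.counts[2], T=s.counts[3],
                editing_level=es.editing_level, p_raw=es.p_raw,
                p_bonf=es.p_bonferroni, significant=es.significant,
                flags=",".join(sorted(es.filter_flags)),
            )
        )
    return pd.DataFrame(rows)
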