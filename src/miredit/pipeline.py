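"""End-to-end orchestration: reads -> trim -> map -> pileup -> calls ->
filters -> cohort matrix -> candidate selection -> cross-cohort intersection.

Every exclusion is logged so that a planted decoy can be attributed to the
single filter that removed it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import SEED_END, SEED_START
from .candidate_select import (
    CandidateMiRNA, SelectConfig, intersect_cohorts, select_candidates,
)
from .cohort import CohortEditingMatrix, SiteKey
from .editcall import (
    CallConfig, EditingSite, call_editing_sites, filter_sites, pileup,
    quantify_expression,
)
from .smallrna_align import AlignConfig, Mapper, TrimConfig, trim_read
from .synthetic_data.design import DecoyKind
from .synthetic_data.reads import ResolvedDecoy, SimulatedCohort


@dataclass
class CohortRunLog:
    """Per-cohort record of why each site or miRNA was excluded."""

    site_filter: dict = field(default_factory=dict)       # key -> positional flag
    cohort_dropped: dict = field(default_factory=dict)    # key -> [reasons]
    selection_log: dict = field(default_factory=dict)     # key -> reason
    tpm_failed_mirnas: set = field(default_factory=set)
    error_rates: dict = field(default_factory=dict)       # sample -> estimate
    n_sites_tested: dict = field(default_factory=dict)


@dataclass
class CohortResult:
    matrix: CohortEditingMatrix
    candidates: list[CandidateMiRNA]
    log: CohortRunLog


@dataclass
class StudyResult:
    cohort_a: CohortResult
    cohort_b: CohortResult
    final: list[tuple[CandidateMiRNA, CandidateMiRNA]]


def _sample_alignment_counter(
    reads: Sequence[tuple[str, str, str]],
    mapper: Mapper,
    trim_config: Optional[TrimConfig],
) -> Counter:
    """Trim, deduplicate and map one sample's reads into a pileup counter."""
    seq_counts: Counter = Counter()
    for _, seq, qual in reads:
        if trim_config is not None:
            seq, qual, reason = trim_read(seq, qual, trim_config)
            if reason is not None:
                continue
        seq_counts[seq] += 1
    t3 = mapper.config.trim3
    aln: Counter = Counter()
    for seq, n in seq_counts.items():
        eff = seq[:-t3] if t3 else seq
        if not eff:
            continue
        status, contig, start, strand, _ = mapper.align_sequence(eff)
        if status != "mapped":
            continue
        from ._seq import revcomp

        ref_seq = revcomp(eff) if strand == "-" else eff
        aln[(contig, start, ref_seq)] += n
    return aln


def build_cohort_matrix(
    bundle,
    cohort: SimulatedCohort,
    call_config: CallConfig = CallConfig(),
    trim_config: Optional[TrimConfig] = None,
    mapper: Optional[Mapper] = None,
) -> tuple[CohortEditingMatrix, CohortRunLog]:
    """Reads -> calls -> positional filters -> samples x sites matrix.

    A site enters the matrix when it is Bonferroni-significant in at least
    one sample and survives the positional filters; its editing level is
    then reported for every sample where it meets the coverage floor.
    """
    annotation = bundle.annotation
    genome = bundle.genome
    if mapper is None:
        mapper = Mapper(genome, AlignConfig())
    if trim_config is None and (cohort.design.adapter or cohort.design.lowq_tail):
        trim_config = TrimConfig(adapter=cohort.design.adapter)

    log = CohortRunLog()
    level_maps: dict[str, dict[SiteKey, float]] = {}
    meta: dict[SiteKey, dict] = {}
    matrix_keys: set[SiteKey] = set()
    tpm_cols: dict[str, pd.Series] = {}

    for sid in cohort.sample_ids:
        counter = _sample_alignment_counter(cohort.reads_for(sid), mapper, trim_config)
        piles = pileup(counter, annotation, genome, include_outside=True)
        sites = call_editing_sites(piles, call_config)
        log.n_sites_tested[sid] = len(sites)
        levels: dict[SiteKey, float] = {}
        for es in sites:
            levels[es.key] = es.editing_level
            meta.setdefault(es.key, dict(
                contig=es.site.contig, pos=es.site.pos,
                mature_position=es.site.mature_position,
                in_seed=es.site.in_seed,
            ))
        level_maps[sid] = levels
        significant = [es for es in sites if es.significant]
        kept, flagged = filter_sites(significant, annotation, bundle.variants)
        for es in flagged:
            order = ["NOT_PREMIRNA", "MITOCHONDRIAL", "KNOWN_SNP"]
            primary = next(f for f in order if f in es.filter_flags)
            log.site_filter.setdefault(es.key, primary)
        matrix_keys.update(es.key for es in kept)

        expr = quantify_expression(counter, annotation)
        tpm_cols[sid] = expr.groupby("mirna_id")["tpm"].sum()

    keys = sorted(matrix_keys, key=lambda k: (str(k[0]), k[1]))
    editing = pd.DataFrame(
        {sid: [level_maps[sid].get(k, np.nan) for k in keys]
         for sid in cohort.sample_ids},
        index=pd.Index(keys, tupleize_cols=False),
    )
    site_meta = pd.DataFrame(
        [meta[k] for k in keys], index=pd.Index(keys, tupleize_cols=False)
    ) if keys else pd.DataFrame(columns=["contig", "pos", "mature_position", "in_seed"])
    samples = cohort.sample_table.set_index("sample_id")
    tpm = pd.DataFrame(tpm_cols)
    matrix = CohortEditingMatrix(
        editing=editing, site_meta=site_meta, samples=samples, tpm=tpm,
        stage_order=cohort.design.stages,
    )

    for mirna_id in tpm.index:
        if matrix.host_mean_tpm(mirna_id) < call_config.min_tpm:
            log.tpm_failed_mirnas.add(mirna_id)
    return matrix, log


def analyze_cohort(
    bundle,
    cohort: SimulatedCohort,
    rule: str,
    call_config: CallConfig = CallConfig(),
    select_config: SelectConfig = SelectConfig(),
    trim_config: Optional[TrimConfig] = None,
    mapper: Optional[Mapper] = None,
) -> CohortResult:
    """Full per-cohort analysis: matrix building plus candidate selection.

    ``rule`` is 'catholic' (stage trend + MEAN_AND_TPM) or 'tcga'
    (tumor vs normal + N_SAMPLES). A shared ``mapper`` may be passed so its
    alignment cache is reused across cohorts.
    """
    from .editcall import apply_cohort_filters

    matrix, log = build_cohort_matrix(bundle, cohort, call_config,
                                      trim_config, mapper)
    cohort_rule = "MEAN_AND_TPM" if rule == "catholic" else "N_SAMPLES"
    retained, dropped = apply_cohort_filters(matrix, cohort_rule, call_config)
    log.cohort_dropped.update(dropped)

    candidates, sel_log = select_candidates(
        matrix, rule, select_config, site_keys=retained
    )
    log.selection_log.update(sel_log)
    return CohortResult(matrix=matrix, candidates=candidates, log=log)


def run_two_cohort_study(
    study,
    call_config: CallConfig = CallConfig(),
    select_config: SelectConfig = SelectConfig(),
) -> StudyResult:
    mapper = Mapper(study.bundle.genome, AlignConfig())
    res_a = analyze_cohort(study.bundle, study.cohort_a, "catholic",
                           call_config, select_config, mapper=mapper)
    res_b = analyze_cohort(study.bundle, study.cohort_b, "tcga",
                           call_config, select_config, mapper=mapper)
    final = intersect_cohorts(res_a.candidates, res_b.candidates)
    return StudyResult(cohort_a=res_a, cohort_b=res_b, final=final)


_SELECTION_EQUIV = {
    "NO_STAGE_TREND": "NO_STAGE_TREND",
    "NOT_INCREASED_IN_TUMOR": "NO_STAGE_TREND",  # cohort-B flavour of the rule
}


def _decoy_hits(decoy: ResolvedDecoy, log: CohortRunLog) -> list[str]:
    """All filters that excluded this decoy in one cohort's run, in order."""
    hits: list[str] = []
    if decoy.mirna_id is None:
        target = (f"{decoy.contig}:{decoy.genomic_pos}", 0)
    else:
        target = (decoy.mirna_id, decoy.mature_position)
    if target in log.site_filter:
        hits.append(log.site_filter[target])
    if target in log.cohort_dropped:
        hits.extend(log.cohort_dropped[target])
    if target in log.selection_log:
        reason = log.selection_log[target]
        hits.append(_SELECTION_EQUIV.get(reason, reason))
    if decoy.spec.kind is DecoyKind.LOW_EXPRESSION \
            and decoy.mirna_id in log.tpm_failed_mirnas:
        hits.append("TPM_BELOW_MIN")
    return hits


def attribute_decoys(study, result: StudyResult) -> dict[str, list[str]]:
    """Map each decoy kind to the filter(s) that removed it.

    Attribution prefers the multistage cohort's log; the tumor/normal
    cohort is consulted only when the decoy left no trace there (the
    flat-trend decoy fails the cohort-B two-group rule, reported under the
    same NO_STAGE_TREND label).
    """
    out: dict[str, list[str]] = {}
    for decoy in study.cohort_a.resolved_decoys:
        hits = _decoy_hits(decoy, result.cohort_a.log)
        if not hits:
            decoy_b = next(
                d for d in study.cohort_b.resolved_decoys
                if d.spec.kind is decoy.spec.kind
            )
            hits = _decoy_hits(decoy_b, result.cohort_b.log)
        out[decoy.spec.kind.value] = sorted(set(hits))
    return out
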