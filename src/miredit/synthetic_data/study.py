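"""Two-cohort synthetic study assembly for end-to-end runs.

Builds a shared reference, one multistage cohort (stage-trend selection
rule) and one tumor/normal cohort (two-group selection rule), with a single
true seed-position-3 hotspot plus the six documented decoy kinds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .design import DecoyKind, DecoySpec, PlantedEdit, SimCohortDesign
from .reads import SimulatedCohort, rising_fractions
from .reference import ReferenceBundle, make_reference

DEFAULT_STAGES = ("NORMAL", "CH", "CIRRHOSIS", "HCC")
DEFAULT_TREND = (0.02, 0.08, 0.15, 0.25)


@dataclass
class SyntheticStudy:
    bundle: ReferenceBundle
    cohort_a: SimulatedCohort       # multistage, stage-trend rule
    cohort_b: SimulatedCohort       # tumor/normal, two-group rule
    plant: PlantedEdit              # the cohort-A instance of the true hotspot
    decoys: list[DecoySpec]


def default_decoys(bundle: ReferenceBundle, reserved: Sequence[str]) -> list[DecoySpec]:
    """One decoy of each kind, mapped onto distinct hairpins.

    ``reserved`` hairpin ids (e.g. the true plant's host) are never used.
    """
    ann = bundle.annotation
    snp_host = bundle.variant_mature_sites[0][0] if bundle.variant_mature_sites else None
    mito_host = next(p.id for p in ann if p.mito)
    taken = set(reserved) | {snp_host, mito_host}
    free = [p.id for p in ann if p.id not in taken and not p.mito]
    needed = 3  # NON_SEED, FLAT_TREND, LOW_EXPRESSION
    if snp_host is None or len(free) < needed:
        raise ValueError(
            "reference too small for the full decoy set; use >= 7 miRNAs"
        )
    return [
        DecoySpec(DecoyKind.SNP_SITE, mirna_id=snp_host, mature_position=3),
        DecoySpec(DecoyKind.MITO_SITE, mirna_id=mito_host, mature_position=3),
        DecoySpec(DecoyKind.OUTSIDE_PREMIRNA),
        DecoySpec(DecoyKind.LOW_EXPRESSION, mirna_id=free[0], mature_position=3,
                  expression_multiplier=1e-6),
        DecoySpec(DecoyKind.NON_SEED, mirna_id=free[1], mature_position=12),
        DecoySpec(DecoyKind.FLAT_TREND, mirna_id=free[2], mature_position=3),
    ]


def build_synthetic_study(
    seed: int = 0,
    n_mirnas: int = 8,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    trend_fractions: tuple[float, ...] = DEFAULT_TREND,
    samples_per_stage: int = 8,
    tumor_normal_n: int = 15,
    depth_per_mirna: float = 5000.0,
    error_rate: float = 0.01,
    plant_host_index: int = 1,
    with_decoys: bool = True,
) -> SyntheticStudy:
    bundle = make_reference(n_mirnas, rng_seed=seed)
    ann = bundle.annotation
    host = ann.premirnas[plant_host_index]
    if host.mito or (bundle.variant_mature_sites
                     and host.id == bundle.variant_mature_sites[0][0]):
        raise ValueError("plant host collides with a decoy hairpin")

    design_a = SimCohortDesign(
        stages=stages, samples_per_stage=samples_per_stage,
        depth_per_mirna=depth_per_mirna, error_rate=error_rate,
        rng_seed=seed + 1,
    )
    design_b = SimCohortDesign(
        stages=("NORMAL", "TUMOR"), samples_per_stage=tumor_normal_n,
        depth_per_mirna=depth_per_mirna, error_rate=error_rate,
        rng_seed=seed + 2,
    )
    plant_a = PlantedEdit.trend(host.id, 3, stages, trend_fractions)
    plant_b = PlantedEdit(
        host.id, 3,
        {"NORMAL": trend_fractions[0], "TUMOR": trend_fractions[-1]},
    )
    decoys = default_decoys(bundle, reserved=[host.id]) if with_decoys else []
    cohort_a = SimulatedCohort(bundle, design_a, [plant_a], decoys)
    cohort_b = SimulatedCohort(bundle, design_b, [plant_b], decoys)
    return SyntheticStudy(
        bundle=bundle, cohort_a=cohort_a, cohort_b=cohort_b,
        plant=plant_a, decoys=decoys,
    )
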