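"""Study-design dataclasses for the synthetic cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


@dataclass(frozen=True)
class SimCohortDesign:
    """Shape of one simulated cohort.

    ``stages`` is the ordered disease-stage vocabulary (e.g. NORMAL, CH,
    CIRRHOSIS, DN, HCC); every sample belongs to exactly one stage.
    """

    stages: tuple[str, ...]
    samples_per_stage: int
    depth_per_mirna: float
    error_rate: float
    rng_seed: int
    adapter: Optional[str] = None   # appended to reads when set
    lowq_tail: int = 0              # number of Q10 3' bases to append

    def __post_init__(self):
        if len(self.stages) == 0:
            raise ValueError("stages must be non-empty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if self.samples_per_stage < 1:
            raise ValueError("samples_per_stage must be >= 1")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.depth_per_mirna <= 0:
            raise ValueError("depth_per_mirna must be positive")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_samples(self) -> int:
        return len(self.stages) * self.samples_per_stage


@dataclass(frozen=True)
class PlantedEdit:
    """A true A-to-G editing signal planted at a mature-miRNA position."""

    mirna_id: str
    mature_position: int  # 1-based within the mature sequence
    stage_fractions: Mapping[str, float]
    substitution: tuple[str, str] = ("A", "G")

    def __post_init__(self):
        if self.mature_position < 1:
            raise ValueError("mature_position is 1-based and must be >= 1")
        if self.substitution != ("A", "G"):
            raise ValueError("only A->G substitutions are supported")
        for stage, f in self.stage_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"stage fraction for {stage!r} out of [0,1]: {f}"
                )
        object.__setattr__(
            self, "stage_fractions", dict(self.stage_fractions)
        )

    @classmethod
    def trend(cls, mirna_id: str, mature_position: int,
              stages: tuple[str, ...], fractions: tuple[float, ...]) -> "PlantedEdit":
        """A plant whose per-stage means must be nondecreasing."""
        if len(stages) != len(fractions):
            raise ValueError("stages and fractions must align")
        if any(b < a for a, b in zip(fractions, fractions[1:])):
            raise ValueError("trend plant requires nondecreasing stage fractions")
        return cls(mirna_id, mature_position, dict(zip(stages, fractions)))


class DecoyKind(str, Enum):
    SNP_SITE = "SNP_SITE"                 # editing signal at a known-variant position
    MITO_SITE = "MITO_SITE"               # editing signal on the mitochondrial contig
    OUTSIDE_PREMIRNA = "OUTSIDE_PREMIRNA" # mismatch signal outside any hairpin
    LOW_EXPRESSION = "LOW_EXPRESSION"     # host miRNA below the TPM floor
    NON_SEED = "NON_SEED"                 # editing signal outside mature positions 2-8
    FLAT_TREND = "FLAT_TREND"             # real editing with no stage trend


@dataclass(frozen=True)
class DecoySpec:
    """One decoy; each kind is built to violate exactly one pipeline filter."""

    kind: DecoyKind
    mirna_id: Optional[str] = None
    mature_position: Optional[int] = None
    stage_fractions: Optional[Mapping[str, float]] = None
    # OUTSIDE_PREMIRNA placement (genomic, 0-based)
    contig: Optional[str] = None
    window_start: Optional[int] = None
    site_offset: Optional[int] = None
    expression_multiplier: float = 1.0

    #: filter expected to remove this decoy, by kind
    EXPECTED_FILTER = {
        DecoyKind.SNP_SITE: "KNOWN_SNP",
        DecoyKind.MITO_SITE: "MITOCHONDRIAL",
        DecoyKind.OUTSIDE_PREMIRNA: "NOT_PREMIRNA",
        DecoyKind.LOW_EXPRESSION: "TPM_BELOW_MIN",
        DecoyKind.NON_SEED: "NON_SEED",
        DecoyKind.FLAT_TREND: "NO_STAGE_TREND",
    }

    @property
    def expected_filter(self) -> str:
        return self.EXPECTED_FILTER[self.kind]
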