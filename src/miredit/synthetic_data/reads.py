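"""Read-level cohort simulation.

Reads are drawn from mature miRNA sequences in sense orientation, edited
per-site according to each sample's stage fraction, then corrupted with a
uniform substitution error model (no indels). Per-miRNA read counts are
Poisson around ``depth_per_mirna`` times an optional per-miRNA expression
multiplier. Base qualities are constant Q30 with an optional low-quality
3' tail; an optional adapter can be appended to exercise trimming.

Samples are generated lazily and deterministically: sample ``k`` of a design
always yields the same reads for a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .._seq import encode
from .design import DecoyKind, DecoySpec, PlantedEdit, SimCohortDesign
from .reference import ReferenceBundle

_Q30 = "?"   # Phred+33 quality 30
_Q10 = "+"   # Phred+33 quality 10
_CODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class OutsideSource:
    """A non-miRNA genomic read source with a planted mismatch."""

    contig: str
    start: int
    length: int
    site_offset: int         # 0-based within the window
    fraction: float          # mismatch (A->G) fraction, all stages
    depth_multiplier: float = 1.0


@dataclass
class ResolvedDecoy:
    spec: DecoySpec
    mirna_id: Optional[str]
    mature_position: Optional[int]
    contig: Optional[str] = None
    genomic_pos: Optional[int] = None  # 0-based site coordinate


class SimulatedCohort:
    """Lazy, seed-deterministic read cohort plus its truth tables."""

    def __init__(
        self,
        bundle: ReferenceBundle,
        design: SimCohortDesign,
        plants: Sequence[PlantedEdit],
        decoys: Sequence[DecoySpec] = (),
        groups: Optional[Mapping[str, str]] = None,
    ):
        self.bundle = bundle
        self.design = design
        self.decoys = list(decoys)
        self.multipliers: dict[str, float] = {}
        self.outside_sources: list[OutsideSource] = []
        self.resolved_decoys: list[ResolvedDecoy] = []

        all_plants = list(plants)
        for spec in self.decoys:
            all_plants.extend(self._resolve_decoy(spec))
        self.plants = all_plants
        self._validate_plants()

        if groups is None:
            groups = {s: ("normal" if i == 0 else "tumor")
                      for i, s in enumerate(design.stages)}
        rows = []
        for stage in design.stages:
            for k in range(design.samples_per_stage):
                rows.append(
                    dict(sample_id=f"{stage}_{k:02d}", stage=stage,
                         group=groups[stage])
                )
        self.sample_table = pd.DataFrame(rows)

        # sense mature sequences and per-mature plant lists, annotation order
        self._matures = []
        for pre, mature in bundle.annotation.matures():
            seq = bundle.mature_sequence(pre, mature)
            site_plants = [p for p in self.plants if p.mirna_id in (pre.id, mature.id)]
            mult = self.multipliers.get(pre.id, self.multipliers.get(mature.id, 1.0))
            self._matures.append((pre, mature, seq, site_plants, mult))

    # ------------------------------------------------------------ resolution
    def _resolve_decoy(self, spec: DecoySpec) -> list[PlantedEdit]:
        bundle, design = self.bundle, self.design
        stages = design.stages
        fractions = spec.stage_fractions
        plants: list[PlantedEdit] = []
        if spec.kind is DecoyKind.OUTSIDE_PREMIRNA:
            contig, start, length, a_off = (
                (spec.contig, spec.window_start, 22, spec.site_offset)
                if spec.contig is not None else bundle.intergenic_window
            )
            self.outside_sources.append(
                OutsideSource(contig, start, length, a_off, fraction=0.30)
            )
            self.resolved_decoys.append(
                ResolvedDecoy(spec, None, None, contig, start + a_off)
            )
            return plants
        if spec.mirna_id is None:
            raise ValueError(f"decoy {spec.kind} requires a mirna_id")
        pre = bundle.annotation.get(spec.mirna_id)
        pos = spec.mature_position if spec.mature_position is not None else 3
        if spec.kind is DecoyKind.LOW_EXPRESSION:
            self.multipliers[pre.id] = spec.expression_multiplier
        if fractions is None:
            if spec.kind is DecoyKind.FLAT_TREND:
                fractions = {s: 0.15 for s in stages}
            else:
                fractions = dict(zip(stages, rising_fractions(stages)))
        plants.append(PlantedEdit(pre.id, pos, fractions))
        mature = pre.matures[0]
        self.resolved_decoys.append(
            ResolvedDecoy(spec, pre.id, pos, pre.contig,
                          pre.mature_genomic_pos(mature, pos))
        )
        return plants

    def _validate_plants(self) -> None:
        by_id = {}
        for pre, mature, seq, _, _ in self._iter_mature_defs():
            by_id[pre.id] = (mature, seq)
            by_id[mature.id] = (mature, seq)
        for p in self.plants:
            if p.mirna_id not in by_id:
                raise ValueError(f"plant references unknown miRNA {p.mirna_id!r}")
            mature, seq = by_id[p.mirna_id]
            if p.mature_position > len(seq):
                raise ValueError(
                    f"plant {p.mirna_id}:{p.mature_position} beyond mature length {len(seq)}"
                )
            base = seq[p.mature_position - 1]
            if base != "A":
                raise ValueError(
                    f"plant {p.mirna_id}:{p.mature_position} requires reference A, found {base}"
                )

    def _iter_mature_defs(self):
        for pre, mature in self.bundle.annotation.matures():
            yield pre, mature, self.bundle.mature_sequence(pre, mature), None, None

    # ------------------------------------------------------------ generation
    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_table["sample_id"])

    def stage_of(self, sample_id: str) -> str:
        row = self.sample_table.loc[self.sample_table.sample_id == sample_id]
        return str(row["stage"].iloc[0])

    def reads_for(self, sample_id: str) -> list[tuple[str, str, str]]:
        """All reads of one sample as (read_id, sequence, quality)."""
        idx = self.sample_ids.index(sample_id)
        stage = self.stage_of(sample_id)
        rng = np.random.default_rng([self.design.rng_seed, idx])
        design = self.design
        out: list[tuple[str, str, str]] = []
        counter = 0

        def emit(template: str, site_fracs: list[tuple[int, float]], mult: float):
            nonlocal counter
            n = int(rng.poisson(design.depth_per_mirna * mult))
            if n == 0:
                return
            length = len(template)
            mat = np.tile(encode(template), (n, 1))
            for pos0, frac in site_fracs:
                if frac > 0:
                    mask = rng.random(n) < frac
                    mat[mask, pos0] = 2  # G
            if design.error_rate > 0:
                err = rng.random((n, length)) < design.error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum()))
                    mat[err] = (mat[err] + shift) % 4
            qual = _Q30 * length
            if design.lowq_tail:
                qual_tail = _Q10 * design.lowq_tail
            else:
                qual_tail = ""
            adapter = design.adapter or ""
            chars = _CODE_LUT[mat]
            for row in chars:
                seq = row.tobytes().decode("ascii")
                if design.lowq_tail:
                    # low-quality random tail bases
                    tail = "".join(
                        "ACGT"[b] for b in rng.integers(0, 4, design.lowq_tail)
                    )
                    seq = seq + tail
                seq = seq + adapter
                q = qual + qual_tail + _Q30 * len(adapter)
                out.append((f"{sample_id}:r{counter}", seq, q))
                counter += 1

        for pre, mature, seq, site_plants, mult in self._matures:
            fracs = [
                (p.mature_position - 1, p.stage_fractions.get(stage, 0.0))
                for p in site_plants
            ]
            emit(seq, fracs, mult)
        for src in self.outside_sources:
            window = self.bundle.genome[src.contig][src.start:src.start + src.length]
            emit(window, [(src.site_offset, src.fraction)], src.depth_multiplier)
        return out

    # ------------------------------------------------------------ truth I/O
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for _, srow in self.sample_table.iterrows():
            for p in self.plants:
                rows.append(
                    dict(
                        sample_id=srow.sample_id, stage=srow.stage,
                        mirna_id=p.mirna_id, mature_position=p.mature_position,
                        true_fraction=p.stage_fractions.get(srow.stage, 0.0),
                    )
                )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid in self.sample_ids:
            p = outdir / f"{sid}.fastq"
            with p.open("w") as fh:
                for rid, seq, qual in self.reads_for(sid):
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            paths[sid] = p
        truth = outdir / "truth.tsv"
        self.truth_table().to_csv(truth, sep="\t", index=False)
        samples = outdir / "samples.tsv"
        self.sample_table.to_csv(samples, sep="\t", index=False)
        paths["truth"] = truth
        paths["samples"] = samples
        return paths


def rising_fractions(stages: Sequence[str]) -> list[float]:
    """Stage-increasing editing fractions spanning 0.02 -> 0.25."""
    if len(stages) == 1:
        return [0.25]
    return [round(f, 4) for f in np.linspace(0.02, 0.25, len(stages))]


def simulate_reads(
    bundle: ReferenceBundle,
    design: SimCohortDesign,
    plants: Sequence[PlantedEdit],
    decoys: Sequence[DecoySpec] = (),
    outdir: Optional[str | Path] = None,
    groups: Optional[Mapping[str, str]] = None,
) -> SimulatedCohort:
    cohort = SimulatedCohort(bundle, design, plants, decoys, groups=groups)
    if outdir is not None:
        cohort.write(outdir)
    return cohort
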