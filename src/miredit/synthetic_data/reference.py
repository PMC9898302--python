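"""Synthetic reference bundle: genome FASTA, hairpin GFF3, known-variant VCF.

The generated genome has one autosomal contig (``chr1``) and one
mitochondrial contig (``chrM``). Every mature arm carries an adenosine at
mature positions 3 (in-seed) and 12 (non-seed) so editing signals and decoys
can always be planted at comparable places. A declared subset of mature
adenosine positions is covered by VCF records, standing in for dbSNP/gnomAD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..annotation import MatureMirna, MirnaAnnotation, Premirna
from .._seq import revcomp

MITO_CONTIG = "chrM"
AUTO_CONTIG = "chr1"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantRecord:
    """One known variant (0-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    id: str


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    annotation: MirnaAnnotation
    variants: list[VariantRecord]
    #: (mirna_id, mature_position) pairs whose adenosine overlaps a VCF record
    variant_mature_sites: list[tuple[str, int]]
    #: an intergenic window guaranteed outside every hairpin, with the offset
    #: of a forced adenosine inside it (contig, start, length, a_offset)
    intergenic_window: tuple[str, int, int, int]
    mito_contig: str = MITO_CONTIG
    paths: dict = field(default_factory=dict)

    def mature_sequence(self, premirna: Premirna, mature: MatureMirna) -> str:
        """Mature sequence on the miRNA (sense) strand, DNA alphabet."""
        sub = self.genome[premirna.contig][mature.start:mature.end]
        return sub if premirna.strand == "+" else revcomp(sub)

    def variant_positions(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for v in self.variants:
            for off in range(len(v.ref)):
                out.add((v.contig, v.pos + off))
        return out

    # ------------------------------------------------------------------ I/O
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        gff3 = outdir / "mirnas.gff3"
        vcf = outdir / "known_variants.vcf"
        with fasta.open("w") as fh:
            for contig, seq in self.genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        self.annotation.to_gff3(gff3)
        with vcf.open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for contig, seq in self.genome.items():
                fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in self.variants:
                fh.write(
                    f"{v.contig}\t{v.pos + 1}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
                )
        self.paths = {"fasta": fasta, "gff3": gff3, "vcf": vcf}
        return self.paths


def _random_mature(rng: np.random.Generator, length: int) -> str:
    seq = list(rng.choice(_BASES, size=length))
    seq[2] = "A"   # mature position 3 (seed)
    seq[11] = "A"  # mature position 12 (non-seed)
    return "".join(seq)


def _hamming_close(a: str, b: str, max_d: int = 2) -> bool:
    if len(a) != len(b):
        return False
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > max_d:
                return False
    return True


def make_reference(n_mirnas: int, rng_seed: int) -> ReferenceBundle:
    """Generate a deterministic reference bundle.

    Every hairpin is 60-110 nt with one 20-24 nt mature arm; at least one
    hairpin sits on the minus strand and at least one on the mitochondrial
    contig. Known variants cover the seed adenosine of one declared mature
    arm (when n_mirnas >= 3) plus intergenic positions.
    """
    if not isinstance(n_mirnas, (int, np.integer)) or n_mirnas < 1:
        raise ValueError(f"n_mirnas must be a positive integer, got {n_mirnas!r}")
    rng = np.random.default_rng(rng_seed)

    matures: list[str] = []
    for _ in range(n_mirnas):
        length = int(rng.integers(20, 25))
        for _attempt in range(100):
            cand = _random_mature(rng, length)
            if not any(_hamming_close(cand, prev) for prev in matures):
                break
        matures.append(cand)

    premirnas: list[Premirna] = []
    contig_parts: dict[str, list[str]] = {AUTO_CONTIG: [], MITO_CONTIG: []}
    cursors = {AUTO_CONTIG: 0, MITO_CONTIG: 0}

    # leading spacer on chr1 hosting the declared intergenic window
    lead = list(rng.choice(_BASES, size=120))
    win_start, win_len, a_off = 20, 22, 10
    lead[win_start + a_off] = "A"
    contig_parts[AUTO_CONTIG].append("".join(lead))
    cursors[AUTO_CONTIG] = 120
    contig_parts[MITO_CONTIG].append("".join(rng.choice(_BASES, size=60)))
    cursors[MITO_CONTIG] = 60
    intergenic = (AUTO_CONTIG, win_start, win_len, a_off)

    for i, mature_seq in enumerate(matures):
        mito = i == n_mirnas - 1
        strand = "-" if (n_mirnas == 1 or i % 2 == 1) else "+"
        contig = MITO_CONTIG if mito else AUTO_CONTIG
        pre_len = int(rng.integers(60, 111))
        m_len = len(mature_seq)
        offset = int(rng.integers(5, pre_len - m_len - 4))
        pre_sense = (
            "".join(rng.choice(_BASES, size=offset))
            + mature_seq
            + "".join(rng.choice(_BASES, size=pre_len - m_len - offset))
        )
        genomic = pre_sense if strand == "+" else revcomp(pre_sense)
        start = cursors[contig]
        if strand == "+":
            m_start = start + offset
        else:
            m_start = start + pre_len - m_len - offset
        pid = f"pre-mir{i:03d}"
        mid = f"mir{i:03d}-3p"
        premirnas.append(
            Premirna(
                id=pid, contig=contig, start=start, end=start + pre_len,
                strand=strand, mito=mito,
                matures=(MatureMirna(mid, m_start, m_start + m_len),),
            )
        )
        spacer = "".join(rng.choice(_BASES, size=100))
        contig_parts[contig].append(genomic + spacer)
        cursors[contig] += pre_len + 100

    genome = {c: "".join(parts) for c, parts in contig_parts.items()}
    annotation = MirnaAnnotation(premirnas)

    variants: list[VariantRecord] = []
    variant_mature_sites: list[tuple[str, int]] = []
    if n_mirnas >= 3:
        pre = premirnas[2]
        mature = pre.matures[0]
        gpos = pre.mature_genomic_pos(mature, 3)
        ref = genome[pre.contig][gpos]
        alt = "T" if ref != "T" else "C"
        variants.append(VariantRecord(pre.contig, gpos, ref, alt, "rs_sim_seed"))
        variant_mature_sites.append((pre.id, 3))
    for k, pos in enumerate((60, 80)):  # intergenic, clear of the decoy window
        ref = genome[AUTO_CONTIG][pos]
        alt = "G" if ref != "G" else "A"
        variants.append(VariantRecord(AUTO_CONTIG, pos, ref, alt, f"rs_sim_bg{k}"))
    variants.sort(key=lambda v: (v.contig, v.pos))

    return ReferenceBundle(
        genome=genome,
        annotation=annotation,
        variants=variants,
        variant_mature_sites=variant_mature_sites,
        intergenic_window=intergenic,
    )
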