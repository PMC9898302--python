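"""Small-RNA read preprocessing and a bespoke <=1-mismatch ungapped mapper.

Trimming removes the 3' adapter at its best (leftmost, hence longest) exact
match of at least ``min_adapter_overlap`` bases, then quality-trims the 3'
end with the BWA-style partial-sum rule, then gates on length. Mapping
ignores the final ``trim3`` read bases and reports a read iff its best
mismatch stratum (0, then 1) contains exactly one location across both
strands of the whole reference; anything else is unmapped with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pysam
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, revcomp

# --------------------------------------------------------------------- trim


@dataclass(frozen=True)
class TrimConfig:
    adapter: Optional[str] = None
    quality_cutoff: int = 20
    quality_base: int = 33
    min_len: int = 15
    max_len: int = 28
    min_adapter_overlap: int = 3

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.quality_cutoff < 0:
            raise ValueError("quality_cutoff must be >= 0")


@dataclass
class TrimReport:
    kept: int = 0
    too_short: int = 0
    too_long: int = 0

    @property
    def discarded(self) -> int:
        return self.too_short + self.too_long

    @property
    def total(self) -> int:
        return self.kept + self.discarded

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "reason\tcount\nkept\t{0}\ntoo_short\t{1}\ntoo_long\t{2}\n".format(
                self.kept, self.too_short, self.too_long
            )
        )


def _adapter_cut(seq: str, adapter: str, min_overlap: int) -> int:
    """Index at which to cut the adapter off, or len(seq) if no match."""
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        k = min(len(adapter), n - i)
        if k >= min_overlap and seq[i:i + k] == adapter[:k]:
            return i
    return n


def _quality_cut(qual: str, cutoff: int, base: int) -> int:
    """BWA-style 3' quality trim point (index of first trimmed base)."""
    s = 0
    max_s = 0
    cut = len(qual)
    for i in range(len(qual) - 1, -1, -1):
        s += cutoff - (ord(qual[i]) - base)
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return cut


def trim_read(seq: str, qual: str, config: TrimConfig) -> tuple[str, str, Optional[str]]:
    """Trim one read; returns (seq, qual, discard_reason-or-None)."""
    if config.adapter:
        cut = _adapter_cut(seq, config.adapter, config.min_adapter_overlap)
        seq, qual = seq[:cut], qual[:cut]
    if config.quality_cutoff > 0:
        cut = _quality_cut(qual, config.quality_cutoff, config.quality_base)
        seq, qual = seq[:cut], qual[:cut]
    if len(seq) < config.min_len:
        return seq, qual, "too_short"
    if len(seq) > config.max_len:
        return seq, qual, "too_long"
    return seq, qual, None


def parse_fastq(source: Union[str, Path, Iterable[str]]) -> Iterator[tuple[str, str, str]]:
    """Minimal strict FASTQ reader yielding (id, seq, qual)."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).open()
    else:
        lines = iter(source)
    it = iter(lines)
    idx = 0
    while True:
        try:
            header = next(it)
        except StopIteration:
            return
        header = header.rstrip("\n")
        if header == "":
            return
        try:
            seq = next(it).rstrip("\n")
            plus = next(it).rstrip("\n")
            qual = next(it).rstrip("\n")
        except StopIteration:
            raise ValueError(f"truncated FASTQ record at record {idx}")
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"malformed FASTQ record at record {idx}")
        if len(seq) != len(qual):
            raise ValueError(
                f"sequence/quality length mismatch at record {idx}"
            )
        yield header[1:].split()[0], seq, qual
        idx += 1


def trim_reads(
    reads: Union[str, Path, Iterable[tuple[str, str, str]]],
    config: TrimConfig,
    fastq_out: Optional[str | Path] = None,
) -> tuple[list[tuple[str, str, str]], TrimReport]:
    """Trim a FASTQ file or (id, seq, qual) iterable, preserving order."""
    if isinstance(reads, (str, Path)):
        reads = parse_fastq(reads)
    report = TrimReport()
    kept: list[tuple[str, str, str]] = []
    for rid, seq, qual in reads:
        tseq, tqual, reason = trim_read(seq, qual, config)
        if reason == "too_short":
            report.too_short += 1
        elif reason == "too_long":
            report.too_long += 1
        else:
            report.kept += 1
            kept.append((rid, tseq, tqual))
    if fastq_out is not None:
        with Path(fastq_out).open("w") as fh:
            for rid, seq, qual in kept:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return kept, report


# ---------------------------------------------------------------------- map


@dataclass(frozen=True)
class AlignConfig:
    max_mismatches: int = 1
    trim3: int = 2

    def __post_init__(self):
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if self.trim3 < 0:
            raise ValueError("trim3 must be >= 0")


@dataclass(frozen=True)
class AlignmentRecord:
    """One normalized alignment (or unmapped read).

    ``seq``/``quals`` are stored reference-forward; ``start`` is 0-based.
    """

    read_id: str
    contig: Optional[str]
    start: Optional[int]
    strand: Optional[str]
    seq: str
    quals: str
    nm: Optional[int]
    mapped: bool
    reason: Optional[str] = None  # 'no_hit' or 'multimapped' when unmapped


class Mapper:
    """Exhaustive ungapped aligner over a small reference, with caching."""

    def __init__(self, reference: Union[dict[str, str], str, Path],
                 config: AlignConfig = AlignConfig()):
        if isinstance(reference, (str, Path)):
            reference = _read_fasta(reference)
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ValueError("empty reference")
        self.reference = {c: s.upper() for c, s in reference.items()}
        self.config = config
        self._enc = {c: encode(s) for c, s in self.reference.items()}
        self._cache: dict[str, tuple] = {}

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def _hits(self, codes: np.ndarray, max_mm: int) -> list[tuple[str, int, str, int]]:
        """(contig, start, strand, nm) for all placements with nm <= max_mm."""
        out = []
        lr = len(codes)
        # N (code 4) is remapped to 5 so it can never match a reference code
        fwd = codes.copy()
        fwd[fwd == 4] = 5
        rev = fwd[::-1]
        rc = np.full_like(rev, 5)
        valid = rev < 4
        rc[valid] = 3 - rev[valid]
        codes = fwd
        for contig, ref in self._enc.items():
            if len(ref) < lr:
                continue
            windows = sliding_window_view(ref, lr)
            for strand, q in (("+", codes), ("-", rc)):
                mm = (windows != q).sum(axis=1)
                for off in np.nonzero(mm <= max_mm)[0]:
                    out.append((contig, int(off), strand, int(mm[off])))
        return out

    def align_sequence(self, seq: str) -> tuple:
        """Map one (already 3'-trimmed) sequence.

        Returns (status, contig, start, strand, nm) with status in
        {'mapped', 'no_hit', 'multimapped'}.
        """
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        codes = encode(seq)
        hits = self._hits(codes, self.config.max_mismatches)
        best = min((h[3] for h in hits), default=None)
        if best is None:
            result = ("no_hit", None, None, None, None)
        else:
            stratum = [h for h in hits if h[3] == best]
            if len(stratum) == 1:
                contig, start, strand, nm = stratum[0]
                result = ("mapped", contig, start, strand, nm)
            else:
                result = ("multimapped", None, None, None, None)
        self._cache[seq] = result
        return result

    def align_read(self, read_id: str, seq: str, qual: str) -> AlignmentRecord:
        t = self.config.trim3
        eff_seq = seq[:-t] if t else seq
        eff_qual = qual[:-t] if t else qual
        if len(eff_seq) == 0:
            return AlignmentRecord(read_id, None, None, None, seq, qual,
                                   None, False, "no_hit")
        status, contig, start, strand, nm = self.align_sequence(eff_seq)
        if status != "mapped":
            return AlignmentRecord(read_id, None, None, None, eff_seq,
                                   eff_qual, None, False, status)
        if strand == "-":
            eff_seq = revcomp(eff_seq)
            eff_qual = eff_qual[::-1]
        return AlignmentRecord(read_id, contig, start, strand, eff_seq,
                               eff_qual, nm, True)


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def map_reads(
    reads: Union[str, Path, Iterable[tuple[str, str, str]]],
    reference: Union[dict[str, str], str, Path, Mapper],
    config: AlignConfig = AlignConfig(),
    sam_out: Optional[str | Path] = None,
) -> list[AlignmentRecord]:
    """Map trimmed reads; optionally write a SAM v1 file (NM-tagged)."""
    if isinstance(reads, (str, Path)):
        reads = list(parse_fastq(reads))
    mapper = reference if isinstance(reference, Mapper) else Mapper(reference, config)
    records = [mapper.align_read(rid, seq, qual) for rid, seq, qual in reads]
    if sam_out is not None:
        write_sam(records, mapper.contig_lengths(), sam_out)
    return records


def write_sam(records: Sequence[AlignmentRecord], contig_lengths: dict[str, int],
              path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for r in records:
            seq = r.seq or "*"
            qual = r.quals or "*"
            if r.mapped:
                flag = 16 if r.strand == "-" else 0
                fh.write(
                    f"{r.read_id}\t{flag}\t{r.contig}\t{r.start + 1}\t255\t"
                    f"{len(r.seq)}M\t*\t0\t0\t{seq}\t{qual}\tNM:i:{r.nm}\n"
                )
            else:
                fh.write(
                    f"{r.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\t"
                    f"XR:Z:{r.reason}\n"
                )


def read_sam(path: str | Path,
             annotation_contigs: Optional[Sequence[str]] = None) -> list[AlignmentRecord]:
    """Load a SAM file into normalized records.

    Secondary and supplementary alignments are dropped; soft-clipped bases
    are excluded via the query *alignment* sequence. When
    ``annotation_contigs`` is given, mapped records on other contigs raise.
    """
    out: list[AlignmentRecord] = []
    known = set(annotation_contigs) if annotation_contigs is not None else None
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            full_qual = (
                pysam.qualities_to_qualitystring(aln.query_qualities)
                if aln.query_qualities is not None else ""
            )
            if aln.is_unmapped:
                out.append(
                    AlignmentRecord(
                        aln.query_name, None, None, None,
                        aln.query_sequence or "", full_qual, None, False,
                        aln.get_tag("XR") if aln.has_tag("XR") else "no_hit",
                    )
                )
                continue
            contig = aln.reference_name
            if known is not None and contig not in known:
                raise ValueError(f"alignment on unknown contig {contig!r}")
            seq = aln.query_alignment_sequence
            qual = full_qual[aln.query_alignment_start:aln.query_alignment_end]
            nm = int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
            out.append(
                AlignmentRecord(
                    aln.query_name, contig, aln.reference_start,
                    "-" if aln.is_reverse else "+", seq, qual, nm, True,
                )
            )
    return out
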