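"""Pre-miRNA / mature-miRNA annotation model and GFF3 round-trip.

Coordinates are 0-based, half-open internally and 1-based, closed in GFF3,
matching the format specification. Mature coordinates are genomic; position
lookups convert to 1-based positions along the mature (sense) strand.

The GFF3 dialect mirrors miRBase conventions: ``miRNA_primary_transcript``
features for hairpins (with a ``mito=true|false`` attribute) and ``miRNA``
features carrying ``Derives_from``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

SEED_START = 2  # 1-based mature positions 2..8 form the seed
SEED_END = 8


@dataclass(frozen=True)
class MatureMirna:
    """One mature arm, genomic 0-based half-open coordinates."""

    id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Premirna:
    id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mito: bool
    matures: tuple[MatureMirna, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def mature_position(self, mature: MatureMirna, pos: int) -> Optional[int]:
        """1-based position of genomic ``pos`` along the mature sense strand."""
        if not (mature.start <= pos < mature.end):
            return None
        if self.strand == "+":
            return pos - mature.start + 1
        return mature.end - pos

    def mature_genomic_pos(self, mature: MatureMirna, mature_pos: int) -> int:
        """Genomic coordinate (0-based) of 1-based mature position."""
        if not (1 <= mature_pos <= mature.length):
            raise ValueError(f"mature position {mature_pos} outside 1..{mature.length}")
        if self.strand == "+":
            return mature.start + mature_pos - 1
        return mature.end - mature_pos


class MirnaAnnotation:
    """Lookup-friendly container of pre-miRNA records."""

    def __init__(self, premirnas: Iterable[Premirna]):
        self.premirnas: list[Premirna] = list(premirnas)
        self._by_id = {p.id: p for p in self.premirnas}
        self._mature_host = {m.id: p for p in self.premirnas for m in p.matures}

    def __len__(self) -> int:
        return len(self.premirnas)

    def __iter__(self):
        return iter(self.premirnas)

    @property
    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.premirnas:
            seen.setdefault(p.contig, None)
        return list(seen)

    def get(self, premirna_id: str) -> Premirna:
        return self._by_id[premirna_id]

    def host_of(self, mature_id: str) -> Premirna:
        return self._mature_host[mature_id]

    def matures(self) -> list[tuple[Premirna, MatureMirna]]:
        return [(p, m) for p in self.premirnas for m in p.matures]

    def premirna_at(self, contig: str, pos: int) -> Optional[Premirna]:
        for p in self.premirnas:
            if p.contig == contig and p.contains(pos):
                return p
        return None

    def locate(self, contig: str, pos: int):
        """Return (premirna, mature, mature_position) for a genomic site.

        ``mature``/``mature_position`` are None when the site lies in the
        hairpin but outside any mature arm; everything is None outside
        annotated pre-miRNAs.
        """
        pre = self.premirna_at(contig, pos)
        if pre is None:
            return None, None, None
        for m in pre.matures:
            mp = pre.mature_position(m, pos)
            if mp is not None:
                return pre, m, mp
        return pre, None, None

    # ------------------------------------------------------------------ GFF3
    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for p in self.premirnas:
            attrs = f"ID={p.id};Name={p.id};mito={'true' if p.mito else 'false'}"
            lines.append(
                "\t".join(
                    [p.contig, "miredit", "miRNA_primary_transcript",
                     str(p.start + 1), str(p.end), ".", p.strand, ".", attrs]
                )
            )
            for m in p.matures:
                attrs = f"ID={m.id};Name={m.id};Derives_from={p.id}"
                lines.append(
                    "\t".join(
                        [p.contig, "miredit", "miRNA",
                         str(m.start + 1), str(m.end), ".", p.strand, ".", attrs]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "MirnaAnnotation":
        pres: dict[str, dict] = {}
        order: list[str] = []
        matures: list[tuple[str, MatureMirna]] = []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attr_str = fields
            attrs = dict(
                kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv
            )
            if ftype == "miRNA_primary_transcript":
                pid = attrs["ID"]
                pres[pid] = dict(
                    id=pid, contig=contig, start=int(start) - 1, end=int(end),
                    strand=strand, mito=attrs.get("mito", "false") == "true",
                )
                order.append(pid)
            elif ftype == "miRNA":
                matures.append(
                    (attrs["Derives_from"],
                     MatureMirna(attrs["ID"], int(start) - 1, int(end)))
                )
        grouped: dict[str, list[MatureMirna]] = {pid: [] for pid in order}
        for parent, m in matures:
            if parent not in grouped:
                raise ValueError(f"miRNA feature derives from unknown hairpin {parent}")
            grouped[parent].append(m)
        return cls(
            Premirna(matures=tuple(grouped[pid]), **pres[pid]) for pid in order
        )
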