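"""Synthetic 3'UTR generation with planted seed-match sites.

Background sequence is rejection-sampled so that neither the canonical nor
the edited seed has any match site; planted sites are spliced in at recorded
coordinates and re-verified by a full scan after splicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .._seq import to_dna
from ..retarget import site_motifs, scan_utr

_BASES = np.array(list("ACGT"))

PlantSpec = Union[tuple[str, str], Sequence[tuple[str, str]]]


@dataclass
class UtrSim:
    sequences: dict[str, str]     # gene -> UTR (DNA alphabet)
    truth: pd.DataFrame           # gene, form, site_type, start

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gene, seq in self.sequences.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")


def _random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _clean_background(rng, length, forbidden_cores) -> str:
    for _ in range(500):
        seq = _random_utr(rng, length)
        if not any(core in seq for core in forbidden_cores):
            return seq
    raise RuntimeError("could not sample a site-free background UTR")


def simulate_utrs(
    n_genes: int,
    canonical_seed: str,
    edited_seed: str,
    planted: Mapping[str, PlantSpec],
    rng_seed: int,
    utr_length: int = 500,
) -> UtrSim:
    canonical_seed = to_dna(canonical_seed)
    edited_seed = to_dna(edited_seed)
    if len(canonical_seed) != 7 or len(edited_seed) != 7:
        raise ValueError("seeds must be 7-mers (mature positions 2-8)")
    if canonical_seed == edited_seed:
        raise ValueError("canonical and edited seeds must differ at >=1 position")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    motifs = {
        "canonical": site_motifs(canonical_seed),
        "edited": site_motifs(edited_seed),
    }
    # every site type contains the 6mer core, so excluding the cores excludes all
    forbidden = {motifs["canonical"]["6mer"], motifs["edited"]["6mer"]}

    names = [f"gene_{i:04d}" for i in range(n_genes)]
    for key in planted:
        if key not in names:
            names.append(key)

    sequences: dict[str, str] = {}
    truth_rows = []
    for gene in names:
        specs = planted.get(gene, ())
        if specs and isinstance(specs[0], str):
            specs = (specs,)  # single (form, site_type) pair
        ok = False
        for _ in range(100):
            seq = _clean_background(rng, utr_length, forbidden)
            expected = []
            for form, site_type in specs:
                if form not in motifs:
                    raise ValueError(f"unknown miRNA form {form!r}")
                motif = motifs[form][site_type]
                start = int(rng.integers(10, utr_length - len(motif) - 10))
                seq = seq[:start] + motif + seq[start + len(motif):]
                expected.append((form, site_type, start))
            found = {
                form: [(s.site_type, s.start)
                       for s in scan_utr(
                           canonical_seed if form == "canonical" else edited_seed,
                           seq, form=form)]
                for form in motifs
            }
            # an 8mer window embeds a 7mer-A1 at start+1, a 7mer-m8 a 6mer
            derived = {"8mer": ("7mer-A1", 1), "7mer-m8": ("6mer", 1)}
            want: dict[str, list] = {form: [] for form in motifs}
            for f, t, p in expected:
                want[f].append((t, p))
                if t in derived:
                    sub_t, off = derived[t]
                    want[f].append((sub_t, p + off))
            want = {f: sorted(v) for f, v in want.items()}
            if all(sorted(found[f]) == want[f] for f in motifs):
                ok = True
                break
        if not ok:
            raise RuntimeError(f"could not plant sites cleanly for {gene}")
        sequences[gene] = seq
        for form, site_type, start in expected:
            truth_rows.append(
                dict(gene=gene, form=form, site_type=site_type, start=start)
            )
    truth = pd.DataFrame(truth_rows, columns=["gene", "form", "site_type", "start"])
    return UtrSim(sequences=sequences, truth=truth)
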