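# miredit

Detection of A-to-I editing hotspots in miRNA seed regions from small-RNA
sequencing, and prediction of the resulting target switching (targets lost
by the canonical miRNA, targets gained by the edited form). The package is
fully exercisable on synthetic data: a seedable simulator generates the
reference genome, miRBase-style annotation, known-variant VCF, multistage
cohort reads, expression matrices and 3'UTRs with planted ground truth.

## Pipeline stages

| Module | Role |
| --- | --- |
| `miredit.synthetic_data` | reference/reads/expression/UTR simulators with planted edits and six decoy kinds (known-SNP overlap, mitochondrial, outside-hairpin, sub-TPM expression, non-seed position, flat stage trend) |
| `miredit.smallrna_align` | adapter/quality trimming with length gating; exhaustive ungapped ≤1-mismatch mapper with unique-best-stratum reporting; SAM v1 I/O |
| `miredit.editcall` | strand-aware pileup over annotated hairpins, exact binomial editing test against the sequencing-error null with Bonferroni control, positional filters (non-hairpin / mitochondrial / known variant), TPM quantification, cohort retention rules |
| `miredit.candidate_select` | seed-region (positions 2–8) restriction, stage-trend and tumor-vs-normal selection, cross-cohort intersection |
| `miredit.retarget` | edited-miRNA derivation, seed-match site typing (8mer / 7mer-m8 / 7mer-A1 / 6mer), lost/gained target partition, fuzzy c-means expression-pattern shortlisting |
| `miredit.cohort_stats` | ROC/AUC (Hanley–McNeil CI), 2×2 mutual-exclusivity chi-square/Fisher, copy-number call summaries, Spearman rank correlation |
| `miredit.pipeline` | end-to-end orchestration with a run log that attributes every exclusion to a single filter |

## CLI

```bash
miredit simulate --design design.yaml --plants plants.yaml --seed 1 --outdir sim/
miredit trim reads.fastq trimmed.fastq --adapter TGGAATTCTCGGGTGCCAAGG --report trim.tsv
miredit map trimmed.fastq sim/reference.fa aln.sam
miredit call aln.sam sim/reference.fa sim/mirnas.gff3 --vcf sim/known_variants.vcf --out sites.tsv
miredit quantify aln.sam sim/mirnas.gff3 --out expr.tsv
miredit retarget "mir-x:3:A>G" --mature UUACGCCUAGGCUAACCUGAAU --utrs utrs.fa --outdir rt/
miredit stats cn-summary calls.tsv
```

`design.yaml` example:

```yaml
stages: [NORMAL, CH, CIRRHOSIS, DN, HCC]
samples_per_stage: 8
depth_per_mirna: 5000
error_rate: 0.01
```

## Programmatic end-to-end run

```python
from miredit.synthetic_data import build_synthetic_study
from miredit.pipeline import run_two_cohort_study, attribute_decoys

study = build_synthetic_study(seed=1)           # two cohorts, one true hotspot, six decoys
result = run_two_cohort_study(study)
print([a.key for a, _ in result.final])         # the planted (miRNA, seed position 3)
print(attribute_decoys(study, result))          # decoy kind -> excluding filter
```

## Conventions

- Coordinates are 0-based half-open internally, 1-based closed in GFF3/VCF.
- Editing is always reported on the miRNA strand (minus-strand hairpins are
  complemented), so the signature is A→G everywhere downstream.
- Editing level is G/(A+G); other mismatches are treated as errors.
- The binomial null uses a per-base A→G rate of `error_rate / 3`
  (uniform substitution spectrum); the Bonferroni family is the set of
  A-reference sites meeting the coverage floor within one sample.
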