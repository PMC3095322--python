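# mirtarmap

A toolkit for predicting plant miRNA target sites in transcript and genomic
sequences, curating them with a positional mismatch-penalty score, annotating
them against gene models, placing them on the genetic BIN map of the tomato
*Solanum pennellii* introgression-line population, co-locating them with
fruit metabolic (QML) and yield-associated (YAL) QTL, and persisting the
whole relation in an embedded SQLite store.

It is aimed at plant genomicists who want to go from "here are mature miRNAs
and here are my BAC/unigene sequences" to "which putative miRNA-target
interactions fall into introgression-line segments that carry fruit QTL, and
how are those targets expressed during fruit development" — without any
external binaries or downloads.

## The scoring model

A candidate duplex aligns a mature miRNA (5'→3') antisense against a target
subsequence. Each alignment column is classified and penalized:

| column                                   | penalty |
|------------------------------------------|---------|
| Watson-Crick pair (A:U, G:C)             | 0       |
| G:U wobble (not counted as a mismatch)   | 0.5     |
| insertion/deletion (per gapped column)   | 2.0     |
| mismatch at positions 2–7 from the miRNA 5' end (seed) | 1.5 |
| mismatch at any other position           | 1.0     |

Scores are always computed over 20 consecutive miRNA positions; when the
miRNA is longer, every consecutive 20-nt window is summed and the **minimum**
kept, so a defect near either end of a long miRNA can be forgiven by a
window that excludes it. Sites are retained only when the score is
**strictly below 3**.

Around that score the pipeline provides:

- a self-contained antisense duplex **scanner** (banded DP with
  miRanda-like rewards: +5 pair, +2 G:U, −3 mismatch, affine gaps −8/−2),
  scanning BACs on both strands and unigenes sense-only, plus a brute-force
  enumerator used as a test oracle;
- **annotation** of sites as genic "yes"/"no" by ≥1-nt overlap with predicted
  genes from six channels (Augustus with tomato-EST / potato-EST / unigene /
  de-novo hints, GenomeThreader, BLASTX vs Arabidopsis peptides);
- **genetic mapping**: BACs anchored through their molecular markers (both
  the EXPEN1992 and EXPEN2000 tomato maps), unigenes placed by alignment to
  anchored BACs filtered at ≥90% identity and ≥95% query coverage, and
  non-genic sites flagged as putative precursor loci when a precursor-search
  hit passes e-value ≤ 1e-50;
- a **16-table SQLite store** searchable by BIN, miRNA, target or keyword
  (over hit definitions and QTL trait text), exporting CSV or HTML. The
  16-table schema is this toolkit's own reconstruction of such a relational
  layout; see `mirtarmap/store.py` for the DDL.

A seeded fixture **generator** (`mirtarmap simulate`) emulates every input —
miRNAs, BAC/unigene sequences with planted target sites of known mutation
profiles, GFF3 gene models and markers, a marker→BIN table, QTL and
expression tables — with a machine-readable ground-truth manifest, so the
whole pipeline is testable offline.

## Worked example

```
$ mirtarmap simulate --seed 1 --out demo/bundle
wrote fixture bundle with 8 planted sites to demo/bundle

$ mirtarmap run --bundle demo/bundle --out demo/out
annotated_no: 3
annotated_yes: 4
candidate_sites: 12
curated_sites: 7
mirnas: 5
precursor_candidates: 2
sequences_with_bins: 5
sites_with_bins: 6
sites_with_qtl: 6
store: demo/out/sites.sqlite
targets: 6
```

The scanner proposed 12 candidate duplexes; the penalty filter retained the
7 scoring < 3 (the bundle deliberately plants one site scoring exactly 3.0,
which the strict bound rejects). Four retained sites overlap predicted
genes; two of the non-genic ones carry a passing precursor hit and are
flagged as putative precursor loci.

Querying by the keyword `fructose` (a QML trait on BIN 5B in the fixture's
QTL table) surfaces every curated site mapped to that BIN, with its score
and annotation:

```
$ mirtarmap query --db demo/out/sites.sqlite --by keyword --term fructose \
      --fields site_id,mirna_id,target_id,bin_ids,score,hit_definition
[
 {"bin_ids": "5B", "hit_definition": "", "mirna_id": "sly-miR395a",
  "score": 0.0, "site_id": "S00004", "target_id": "BAC0001"},
 {"bin_ids": "5B", "hit_definition": "", "mirna_id": "sly-miR395a",
  "score": 0.5, "site_id": "S00005", "target_id": "BAC0001"},
 {"bin_ids": "5B", "hit_definition": "", "mirna_id": "sly-miR395a",
  "score": 1.0, "site_id": "S00006", "target_id": "BAC0001"},
 {"bin_ids": "5B", "hit_definition": "sulfate adenylyltransferase
  (ATP sulfurylase)", "mirna_id": "sly-miR395a", "score": 1.5,
  "site_id": "S00007", "target_id": "SGN-U0001"}
]
```

The three `BAC0001` rows are the planted precursor-like cluster lying
between markers CT53 and TG432 on BIN 5B; the unigene row is the planted
sulfate-assimilation target. Add `--format csv --out rows.csv` (or
`html`) to export. Individual stages are also available as subcommands
(`scan`, `score`, `annotate`, `map-bins`) reading and writing plain TSV.

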