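# Methods

## Model

A putative miRNA target site is an antisense duplex between a mature miRNA
(19–26 nt, RNA alphabet, T/U equivalent on input) and a subsequence of a
target: either a transcript (unigene) or a genomic clone (BAC). Columns of
the gapped duplex are classified as Watson-Crick pair, G:U wobble, mismatch
or indel, and penalized 0 / 0.5 / (1.5 in miRNA positions 2–7, 1.0
elsewhere) / 2.0 per column. The site score is the minimum of the penalty
sums over every window of 20 consecutive miRNA positions; sites scoring
strictly below 3.0 are retained. The assumption behind the windowed minimum
is that a 20-nt stretch of near-perfect complementarity suffices for
recognition even if a longer miRNA has defects outside it; the assumption
behind the seed surcharge is the disproportionate contribution of positions
2–7 to target recognition in plants.

Position conventions: the seed test uses the *absolute* miRNA position from
the 5' end, not the window-relative one (a `seed_by_window_position` flag
exposes the alternative for sensitivity analysis). Windows slide over miRNA
positions; a window charges every column consuming one of its positions
plus the miRNA-gap (insertion) columns lying strictly between its flanking
columns; each gapped column is charged 2.0 independently, so a 2-nt bulge
costs 4.0. "Positions 2–7" is read as the inclusive range (positions 1 and
8+ carry 1.0): the two penalty clauses are only mutually consistent under
the range reading. The curation bound is strict — a score of exactly 3.0 is
rejected — with a 1e-9 comparison tolerance (scores are sums of multiples
of 0.5, so the tolerance never flips a legitimate comparison).

## Scanner

Finding candidate duplexes is delegated to this package's own banded
antisense DP rather than an external program, so the stage is
self-contained; its defaults (+5 pair, +2 wobble, −3 mismatch, affine gaps
−8 open / −2 extend) are declared, not claimed identical to any external
tool. Working in "alignment space" (the miRNA aligned against the reverse
complement of the scanned strand) makes Watson-Crick pairing an identity
match and turns G:U wobbles into the (G,A)/(U,C) pairs.

Semantics: for every target offset the scanner finds the optimal
full-miRNA-coverage alignment whose first and last columns pair both
strands, whose running target-vs-miRNA shift never exceeds the band
(default 3), and which uses at most band-width gap columns in total.
Optimality is a total order — DP reward score, then fewer gap columns, then
lexicographically earliest operation string — which makes the result
deterministic and lets the production DP and the brute-force enumerator
(`scan_exhaustive`, the test oracle) agree *exactly*, not just in score.
An offset becomes a candidate when its best alignment pairs (Watson-Crick
or wobble) at least `min_mirna_coverage` (default 0.9) of the miRNA
positions; this is the coverage reading that remains meaningful once
alignments are extended to full miRNA length with terminal mismatches.
Overlapping candidates of the same miRNA within 3 nt on one strand are
merged keeping the lowest penalty score; penalty ties are broken by the
higher DP reward before the leftmost start, because a shifted alignment can
park its gap columns between miRNA positions 1 and 2 — outside every
window's column span — and tie the compact duplex's penalty while being the
worse alignment. BACs are scanned on both strands (reported in plus-strand
coordinates), unigenes sense-only, matching the biology of mRNA targeting.
Results are capped at `max_sites_per_pair` (default 20) keeping the best
scores.

Performance: a vectorized prescreen upper-bounds the number of pairable
miRNA positions per offset with a banded numpy DP and discards offsets that
provably cannot reach the coverage floor; surviving offsets (a small
fraction of random sequence) go to the exact per-offset DP. The prescreen
only over-approximates, so it never changes results. miRNAs shorter than
the 20-nt scoring window are skipped with a warning: their sites could
never be scored or curated.

## Annotation, mapping, co-location

A site is genic ("yes") when its interval shares at least one base
(1-based inclusive coordinates, strand-agnostic) with a predicted gene from
any of six channels: Augustus hinted with tomato ESTs, potato ESTs, tomato
unigenes, or de novo; GenomeThreader; BLASTX against Arabidopsis peptides.
All six flags are stored separately so either aggregate reading (Augustus
only vs any channel) remains queryable; the shipped aggregate is the OR of
all six. Hit definitions of overlapping features are concatenated
deduplicated in (start, source) order so exports are diff-stable.

BACs inherit BINs from the molecular markers they carry on either genetic
map (EXPEN1992, EXPEN2000); when maps disagree the union is kept and both
evidence items exposed. Unigenes are placed by their alignments against
anchored BACs, filtered at identity ≥ 90% and query coverage ≥ 95%
(inclusive bounds; coverage = alignment length / unigene length × 100, the
standard convention for placing a transcript on a genome). Sites inherit
the BIN set of their carrying sequence — never computed independently — and
QTL co-location is a join on the BIN label. Alignments are consumed from
standard 12-column BLAST tabular files; the toolkit never executes an
aligner. Sites with no genic annotation can be flagged as putative
precursor loci when a precursor-search hit overlapping the site passes
e-value ≤ 1e-50 (inclusive).

## Store and determinism

All outputs land in one SQLite file with 16 tables (species, mirnas,
sequences, bacs, unigenes, sites, alignments, annotations, gene_features,
markers, bins, bin_assignments, qtl, expression, precursor_hits,
provenance). Foreign keys are validated in an explicit pre-insert pass so a
dangling reference aborts the build listing every offender. Inserts are
sorted and no data table carries timestamps, so identical inputs produce a
byte-identical file; run metadata lives only in the provenance table.
Expression profiles are stored long-format (unigene, stage index, label,
value) to stay agnostic to the number of developmental stages. Exports are
RFC-4180 CSV (CRLF, minimal quoting) and a hand-rendered escaped HTML
table, both byte-stable. The duplex rendering convention is miRNA on top
5'→3', `|` for Watson-Crick, `:` for G:U, space otherwise, target below
read 3'→5'.

## Synthetic data

The generator emulates the full input surface at toy scale: 5 miRNAs
(21–24 nt, two species tags), 2 BACs of 2 kb and 4 unigenes of 600 nt by
default, with eight planted sites specified as mutation profiles. The
default plan mirrors a miR395-flavoured narrative: three clustered
non-genic loci on one BAC between two markers of BIN 5B (precursor
candidates), a sulfate-assimilation unigene target, a genic site on the
second BAC's minus strand, boundary placements at exactly 90.0% identity /
95.0% coverage and at 89.9%, precursor hits at e-values 1e-62/1e-55/1e-40
straddling the cutoff, a site scoring exactly 3.0 that curation must
reject, and a QTL table carrying 19 QML (fructose among them) plus 5 YAL
for BIN 5B.

Each plant's expected score is computed by the generator's own
window-enumeration scorer, deliberately independent of the scoring module
(the tests cross-check the two). Mismatch and insertion bases are chosen so
they cannot pair where they sit, keeping the planted alignment the unique
scanner optimum. After planting, background complementarity is suppressed:
an exhaustive ungapped window scan over every miRNA × strand re-draws any
background locus scoring below 3.5 (threshold + 0.5 margin) outside the
planted neighbourhoods, iterating to convergence. Gapped spurious sites are
not explicitly excluded — a gapped duplex under the threshold would need
≥ 18 paired positions by chance, which at these sequence lengths is
vanishingly unlikely — and the end-to-end tests verify zero spurious
recoveries on the default bundle. Identical seeds yield byte-identical
bundles.

What the generator does **not** emulate: realistic base composition or
repeat structure, polycistronic precursor transcription, multi-BIN markers,
expression noise models, or real SGN identifiers. Passing the end-to-end
tests therefore demonstrates the pipeline's correctness on its own
contracts (recovery, scoring, inheritance, joins), not calibration against
real tomato data.

## Problem sizes

Default toy scale (2 × 2 kb BACs, 4 × 600 nt unigenes, 5 miRNAs) runs the
full pipeline in about a second. The scanner-vs-enumerator equivalence
suite uses 100 seeded fixtures of 40–80 nt at band widths 1–3 because the
enumerator's cost grows combinatorially with band width; the windowed-score
brute-force comparison uses 1000 random gapped duplexes. These sizes were
chosen to exercise every code path (both strands, both target kinds, gap
placements, merge clusters) while keeping the oracle side cheap.

## Known limitations

- No thermodynamics: duplex stability (ΔG), accessibility and conservation
  are out of scope; the penalty score is the only curation signal.
- The scanner reports at most one optimal alignment per offset; ties deeper
  than the documented total order (identical score, gaps and operation
  string) cannot occur, but biologically near-equivalent suboptimal gap
  placements are not enumerated.
- 19-nt miRNAs load but cannot be scanned/scored under the 20-nt window
  contract.
- Keyword search is substring-based, not tokenized; "ala" matches
  "alanine".
- The store schema is a reconstruction; column names are this toolkit's
  own.
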