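"""Core domain types and readers/writers for the toolkit's file formats.

The toolkit consumes mature miRNA and target sequences (FASTA), gene-model and
marker annotations (GFF3), precomputed sequence placements (12-column BLAST
tabular) and plain TSV tables for the marker→BIN map, QTL traits and
expression profiles.  Everything is normalized at the boundary: miRNA
sequences to the RNA alphabet (T and U are equivalent on input), targets to
DNA, coordinates kept 1-based inclusive as in GFF3.
"""
from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

GAP = "-"

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: The six gene-prediction channels whose hits flag a target site as genic:
#: Augustus runs hinted with tomato ESTs, potato ESTs, tomato unigenes and
#: de novo, plus GenomeThreader spliced alignments and BLASTX hits against
#: the Arabidopsis peptide set.
ANNOTATION_SOURCES = (
    "AUGUSTUS_TOMATO_EST",
    "AUGUSTUS_POTATO_EST",
    "AUGUSTUS_UNIGENE",
    "AUGUSTUS_DENOVO",
    "GENOMETHREADER",
    "BLASTX_ARATH",
)

GENETIC_MAPS = ("EXPEN1992", "EXPEN2000")

_BIN_PATTERN = re.compile(r"^\d{1,2}[A-Z]$")


class ParseError(ValueError):
    """A file could not be parsed; the message names the file and position."""


def normalize_rna(sequence: str) -> str:
    """Uppercase, strip whitespace and map T→U."""
    return "".join(sequence.split()).upper().replace("T", "U")


def normalize_dna(sequence: str) -> str:
    return "".join(sequence.split()).upper().replace("U", "T")


def revcomp_rna(sequence: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(sequence))


def revcomp_dna(sequence: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(sequence))


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA; the query of every target scan.

    The sequence is stored 5'→3' in the RNA alphabet; the species tag is
    conventionally the id prefix (e.g. ``sly`` in ``sly-miR395a``).
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 19:
            raise ValueError(f"miRNA {self.id!r}: length {len(seq)} < 19")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSequence:
    """A scan subject: either a genomic clone (BAC) or a transcript (UNIGENE).

    The kind decides the strand policy downstream: BACs are scanned on both
    strands, unigenes only on the given (sense) strand.
    """

    id: str
    kind: str
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("BAC", "UNIGENE"):
            raise ValueError(f"target {self.id!r}: kind must be BAC or UNIGENE")
        seq = normalize_dna(self.sequence)
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"target {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A predicted gene interval from one of the six annotation channels."""

    seq_id: str
    source: str
    start: int
    end: int
    strand: str = "+"
    hit_definition: str = ""

    def __post_init__(self) -> None:
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.start > self.end:
            raise ValueError(
                f"feature on {self.seq_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class MarkerRecord:
    """A genetic-map marker anchored on a BAC, placed in a map BIN."""

    name: str
    map_name: str
    seq_id: str
    position: int
    bin_id: str

    def __post_init__(self) -> None:
        if self.map_name and self.map_name not in GENETIC_MAPS:
            raise ValueError(f"marker {self.name!r}: unknown map {self.map_name!r}")
        if self.bin_id and not _BIN_PATTERN.match(self.bin_id):
            raise ValueError(
                f"marker {self.name!r}: bin {self.bin_id!r} does not match "
                "chromosome-number + letter (e.g. '5B')"
            )


@dataclass(frozen=True)
class QTLRecord:
    """A fruit quantitative metabolic locus (QML) or yield-associated locus
    (YAL) keyed to a genetic BIN."""

    trait: str
    qtl_type: str
    bin_id: str
    direction: Optional[str] = None
    magnitude: Optional[float] = None
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.qtl_type not in ("QML", "YAL"):
            raise ValueError(f"QTL {self.trait!r}: type must be QML or YAL")
        if not self.bin_id:
            raise ValueError(f"QTL {self.trait!r}: empty bin_id")


@dataclass(frozen=True)
class ExpressionProfile:
    """Expression of one unigene across ordered fruit-development stages."""

    unigene_id: str
    stage_labels: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.stage_labels) != len(self.values) or len(self.values) < 2:
            raise ValueError(
                f"expression {self.unigene_id!r}: need >= 2 stages with one "
                "value per stage"
            )


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column BLAST tabular output, plus derived query coverage
    (aln_len / query_len × 100) when query lengths are known."""

    query: str
    subject: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    coverage: Optional[float] = None


@dataclass
class SiteAnnotation:
    """The yes/no genic call for a target site across the six channels."""

    site_id: str
    channel_hits: dict[str, bool]
    gene_hit: bool
    hit_definition: str = ""
    precursor_candidate: bool = False

    def __post_init__(self) -> None:
        if self.gene_hit != any(self.channel_hits.values()):
            raise ValueError(
                f"annotation {self.site_id!r}: aggregate gene_hit must equal "
                "the OR of the channel flags"
            )


@dataclass
class TargetSite:
    """A curated miRNA target site, the canonical persisted record."""

    site_id: str
    mirna_id: str
    target_id: str
    target_kind: str
    strand: str
    start: int
    end: int
    score: float
    alignment_text: str = ""
    bin_ids: tuple[str, ...] = ()
    annotation: Optional[SiteAnnotation] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"site {self.site_id!r}: end < start")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read mature miRNAs from FASTA, normalizing to the RNA alphabet.

    Duplicate ids are rejected; non-nucleotide characters raise an error
    naming the offending record.
    """
    path = Path(path)
    records: list[MatureMiRNA] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate miRNA id {rec.id!r}")
        seen.add(rec.id)
        species = rec.id.split("-", 1)[0] if "-" in rec.id else ""
        try:
            records.append(
                MatureMiRNA(id=rec.id, sequence=str(rec.seq), species=species)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def read_target_fasta(path: str | Path, kind: str) -> list[TargetSequence]:
    """Read target sequences (DNA); sequences shorter than the 20-nt scoring
    window are skipped with a warning."""
    path = Path(path)
    out: list[TargetSequence] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate target id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) < 20:
            log.warning(
                "target %s is shorter than the 20-nt scoring window; skipped",
                rec.id,
            )
            continue
        try:
            out.append(TargetSequence(id=rec.id, kind=kind, sequence=str(rec.seq)))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(records: Iterable[MatureMiRNA | TargetSequence], path: str | Path,
                width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_MARKER_TYPES_DEFAULT = ("genetic_marker",)


def read_gff3_features(
    path: str | Path,
    sources_filter: Sequence[str] = ANNOTATION_SOURCES,
    marker_types: Sequence[str] = _MARKER_TYPES_DEFAULT,
    marker_source_substring: str = "marker",
) -> tuple[list[GeneFeature], list[MarkerRecord], Counter]:
    """Read gene-prediction features and marker features from GFF3.

    Marker features are recognized by a configurable type whitelist (default
    ``genetic_marker``) or by ``marker`` appearing in the source column; the
    SGN GFF3 dialect is not fixed, hence the knobs.  Unknown sources are
    counted and skipped, records with end < start are rejected and logged.
    Returns (gene features, markers, skipped-source counter).
    """
    from gffutils.iterators import DataIterator

    path = Path(path)
    features: list[GeneFeature] = []
    markers: list[MarkerRecord] = []
    skipped: Counter = Counter()
    if path.stat().st_size == 0:
        return features, markers, skipped
    for f in DataIterator(str(path)):
        if f.end is not None and f.start is not None and f.end < f.start:
            log.warning("rejected feature on %s: end %s < start %s",
                        f.seqid, f.end, f.start)
            skipped["end_before_start"] += 1
            continue
        attrs = dict(f.attributes)

        def _attr(key: str, default: str = "") -> str:
            vals = attrs.get(key)
            return vals[0] if vals else default

        is_marker = (f.featuretype in marker_types
                     or marker_source_substring in (f.source or "").lower())
        if is_marker:
            name = _attr("Name") or _attr("ID") or f"{f.seqid}:{f.start}"
            markers.append(
                MarkerRecord(
                    name=name,
                    map_name=_attr("map"),
                    seq_id=f.seqid,
                    position=int(f.start),
                    bin_id=_attr("bin"),
                )
            )
        elif f.source in sources_filter:
            features.append(
                GeneFeature(
                    seq_id=f.seqid,
                    source=f.source,
                    start=int(f.start),
                    end=int(f.end),
                    strand=f.strand if f.strand in ("+", "-") else "+",
                    hit_definition=_attr("Note") or _attr("description"),
                )
            )
        else:
            skipped[f.source] += 1
    if skipped:
        log.info("GFF3 %s: skipped sources %s", path.name, dict(skipped))
    return features, markers, skipped


def read_blast_tab(
    path: str | Path,
    query_lengths: Optional[Mapping[str, int]] = None,
) -> list[BlastHit]:
    """Read 12-column BLAST tabular output (-outfmt 6).

    ``query_lengths`` (e.g. from the companion FASTA) enables per-hit query
    coverage = aln_len / query_len × 100.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hit = BlastHit(
                    query=cols[0],
                    subject=cols[1],
                    pct_identity=float(cols[2]),
                    aln_len=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if query_lengths and hit.query in query_lengths:
                qlen = query_lengths[hit.query]
                hit = BlastHit(
                    **{**hit.__dict__, "coverage": hit.aln_len / qlen * 100.0}
                )
            hits.append(hit)
    return hits


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    """TSV with columns: name, map, bac, position, bin."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "map", "bac", "position", "bin"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: marker table missing columns {sorted(missing)}")
    return [
        MarkerRecord(
            name=row["name"],
            map_name=row["map"],
            seq_id=row["bac"],
            position=int(row["position"]),
            bin_id=row["bin"],
        )
        for _, row in df.iterrows()
    ]


def read_qtl_table(path: str | Path) -> list[QTLRecord]:
    """TSV with columns: trait, type, bin and optional direction, magnitude,
    significant."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"trait", "type", "bin"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: QTL table missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        sig = row.get("significant")
        out.append(
            QTLRecord(
                trait=row["trait"],
                qtl_type=row["type"],
                bin_id=row["bin"],
                direction=row.get("direction") if pd.notna(row.get("direction")) else None,
                magnitude=float(row["magnitude"])
                if "magnitude" in df.columns and pd.notna(row.get("magnitude"))
                else None,
                significant=(str(sig).lower() in ("1", "true", "yes"))
                if "significant" in df.columns and pd.notna(sig)
                else None,
            )
        )
    return out


def read_expression_table(path: str | Path) -> list[ExpressionProfile]:
    """Long-format TSV with columns unigene_id, stage, value; stage order is
    order of first appearance per unigene."""
    df = pd.read_csv(path, sep="\t", dtype={"unigene_id": str, "stage": str})
    required = {"unigene_id", "stage", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: expression table missing columns {sorted(missing)}")
    profiles = []
    for uid, grp in df.groupby("unigene_id", sort=True):
        profiles.append(
            ExpressionProfile(
                unigene_id=str(uid),
                stage_labels=tuple(grp["stage"]),
                values=tuple(float(v) for v in grp["value"]),
            )
        )
    return profiles
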