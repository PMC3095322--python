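"""Relational persistence and the query surface.

Everything the pipeline produces — curated sites with their alignments and
annotations, gene features, markers, BIN assignments, QTL and expression
profiles — lands in a single embedded SQLite file with a fixed 16-table
schema, joinable site → sequence → BIN → QTL.  The store is deterministic:
identical inputs produce a byte-identical file (run metadata lives only in
the provenance table).  Queries go by BIN, miRNA, target or free-text
keyword over hit definitions and QTL traits; results export to RFC-4180 CSV
or a static HTML table, both byte-stable.
"""
from __future__ import annotations

import csv
import html as _html
import sqlite3
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .genmap import BinAssignment
from .seqio import (ANNOTATION_SOURCES, BlastHit, ExpressionProfile,
                    GeneFeature, MarkerRecord, MatureMiRNA, QTLRecord,
                    TargetSequence, TargetSite)

QUERY_FIELDS = ("bin", "mirna", "target", "keyword")

#: Default display columns of a query result row.
DISPLAY_FIELDS = (
    "site_id", "mirna_id", "target_id", "target_kind", "strand", "start",
    "end", "score", "bin_ids", "gene_hit", "hit_definition",
    "precursor_candidate", "qtl", "expression", "alignment",
)

_FLAG_COLUMNS = {
    "AUGUSTUS_TOMATO_EST": "aug_tomato_est",
    "AUGUSTUS_POTATO_EST": "aug_potato_est",
    "AUGUSTUS_UNIGENE": "aug_unigene",
    "AUGUSTUS_DENOVO": "aug_denovo",
    "GENOMETHREADER": "genomethreader",
    "BLASTX_ARATH": "blastx_arath",
}

#: The 16 tables of the schema (this enumeration is the toolkit's own
#: reconstruction; see the README).
SCHEMA = """
CREATE TABLE species (
    species_id TEXT PRIMARY KEY
);
CREATE TABLE mirnas (
    mirna_id TEXT PRIMARY KEY,
    species_id TEXT NOT NULL REFERENCES species(species_id),
    sequence TEXT NOT NULL
);
CREATE TABLE sequences (
    seq_id TEXT PRIMARY KEY,
    kind TEXT NOT NULL CHECK (kind IN ('BAC', 'UNIGENE')),
    length INTEGER NOT NULL
);
CREATE TABLE bacs (
    bac_id TEXT PRIMARY KEY REFERENCES sequences(seq_id)
);
CREATE TABLE unigenes (
    unigene_id TEXT PRIMARY KEY REFERENCES sequences(seq_id)
);
CREATE TABLE sites (
    site_id TEXT PRIMARY KEY,
    mirna_id TEXT NOT NULL REFERENCES mirnas(mirna_id),
    seq_id TEXT NOT NULL REFERENCES sequences(seq_id),
    strand TEXT NOT NULL CHECK (strand IN ('+', '-')),
    start INTEGER NOT NULL,
    end INTEGER NOT NULL CHECK (end >= start),
    score REAL NOT NULL
);
CREATE TABLE alignments (
    site_id TEXT PRIMARY KEY REFERENCES sites(site_id),
    mirna_line TEXT NOT NULL,
    pairing_line TEXT NOT NULL,
    target_line TEXT NOT NULL
);
CREATE TABLE annotations (
    site_id TEXT PRIMARY KEY REFERENCES sites(site_id),
    aug_tomato_est INTEGER NOT NULL,
    aug_potato_est INTEGER NOT NULL,
    aug_unigene INTEGER NOT NULL,
    aug_denovo INTEGER NOT NULL,
    genomethreader INTEGER NOT NULL,
    blastx_arath INTEGER NOT NULL,
    gene_hit INTEGER NOT NULL,
    hit_definition TEXT NOT NULL DEFAULT '',
    precursor_candidate INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE gene_features (
    feature_id INTEGER PRIMARY KEY,
    seq_id TEXT NOT NULL REFERENCES sequences(seq_id),
    source TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    hit_definition TEXT NOT NULL DEFAULT ''
);
CREATE TABLE markers (
    name TEXT NOT NULL,
    map_name TEXT NOT NULL,
    seq_id TEXT NOT NULL REFERENCES sequences(seq_id),
    position INTEGER NOT NULL,
    bin_id TEXT NOT NULL REFERENCES bins(bin_id),
    PRIMARY KEY (name, map_name)
);
CREATE TABLE bins (
    bin_id TEXT PRIMARY KEY,
    chromosome TEXT NOT NULL
);
CREATE TABLE bin_assignments (
    seq_id TEXT NOT NULL REFERENCES sequences(seq_id),
    bin_id TEXT NOT NULL REFERENCES bins(bin_id),
    evidence TEXT NOT NULL,
    PRIMARY KEY (seq_id, bin_id)
);
CREATE TABLE qtl (
    qtl_id INTEGER PRIMARY KEY,
    trait TEXT NOT NULL,
    qtl_type TEXT NOT NULL CHECK (qtl_type IN ('QML', 'YAL')),
    bin_id TEXT NOT NULL REFERENCES bins(bin_id),
    direction TEXT,
    magnitude REAL,
    significant INTEGER
);
CREATE TABLE expression (
    unigene_id TEXT NOT NULL REFERENCES unigenes(unigene_id),
    stage_index INTEGER NOT NULL,
    stage_label TEXT NOT NULL,
    value REAL NOT NULL,
    PRIMARY KEY (unigene_id, stage_index)
);
CREATE TABLE precursor_hits (
    site_id TEXT NOT NULL REFERENCES sites(site_id),
    precursor_id TEXT NOT NULL,
    e_value REAL NOT NULL,
    retained INTEGER NOT NULL,
    PRIMARY KEY (site_id, precursor_id)
);
CREATE TABLE provenance (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
"""

TABLE_NAMES = (
    "species", "mirnas", "sequences", "bacs", "unigenes", "sites",
    "alignments", "annotations", "gene_features", "markers", "bins",
    "bin_assignments", "qtl", "expression", "precursor_hits", "provenance",
)


class StoreBuildError(ValueError):
    """Raised when inputs are mutually inconsistent; lists every offender."""


def _bin_chromosome(bin_id: str) -> str:
    return "".join(ch for ch in bin_id if ch.isdigit())


def build_store(
    path: str | Path,
    *,
    mirnas: Sequence[MatureMiRNA] = (),
    targets: Sequence[TargetSequence] = (),
    sites: Sequence[TargetSite] = (),
    gene_features: Sequence[GeneFeature] = (),
    markers: Sequence[MarkerRecord] = (),
    bin_assignments: Sequence[BinAssignment] = (),
    qtl: Sequence[QTLRecord] = (),
    expression: Sequence[ExpressionProfile] = (),
    precursor_hits: Sequence[tuple[str, str, float, bool]] = (),
    provenance: Optional[Mapping[str, str]] = None,
) -> Path:
    """Build the 16-table store file; aborts listing offenders on any
    dangling reference.  Content is deterministic for identical inputs."""
    path = Path(path)
    mirna_ids = {m.id for m in mirnas}
    seq_ids = {t.id for t in targets}
    site_ids = {s.site_id for s in sites}
    unigene_ids = {t.id for t in targets if t.kind == "UNIGENE"}
    problems: list[str] = []
    for s in sites:
        if s.mirna_id not in mirna_ids:
            problems.append(f"site {s.site_id}: unknown miRNA {s.mirna_id!r}")
        if s.target_id not in seq_ids:
            problems.append(f"site {s.site_id}: unknown sequence {s.target_id!r}")
    for f in gene_features:
        if f.seq_id not in seq_ids:
            problems.append(f"gene feature: unknown sequence {f.seq_id!r}")
    for m in markers:
        if m.seq_id not in seq_ids:
            problems.append(f"marker {m.name}: unknown sequence {m.seq_id!r}")
    for a in bin_assignments:
        if a.seq_id not in seq_ids:
            problems.append(f"bin assignment: unknown sequence {a.seq_id!r}")
    for e in expression:
        if e.unigene_id not in unigene_ids:
            problems.append(
                f"expression profile: unknown unigene {e.unigene_id!r}")
    for site_id, prec_id, _, _ in precursor_hits:
        if site_id not in site_ids:
            problems.append(
                f"precursor hit {prec_id}: unknown site {site_id!r}")
    if problems:
        raise StoreBuildError(
            "store build aborted; dangling references:\n  "
            + "\n  ".join(sorted(problems))
        )

    bins = sorted(
        {m.bin_id for m in markers if m.bin_id}
        | {b for a in bin_assignments for b in a.bin_ids}
        | {q.bin_id for q in qtl}
    )
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(SCHEMA)
        con.executemany(
            "INSERT INTO species VALUES (?)",
            [(sp,) for sp in sorted({m.species or "unknown" for m in mirnas})],
        )
        con.executemany(
            "INSERT INTO mirnas VALUES (?,?,?)",
            [(m.id, m.species or "unknown", m.sequence)
             for m in sorted(mirnas, key=lambda m: m.id)],
        )
        con.executemany(
            "INSERT INTO sequences VALUES (?,?,?)",
            [(t.id, t.kind, len(t))
             for t in sorted(targets, key=lambda t: t.id)],
        )
        con.executemany(
            "INSERT INTO bacs VALUES (?)",
            [(t.id,) for t in sorted(targets, key=lambda t: t.id)
             if t.kind == "BAC"],
        )
        con.executemany(
            "INSERT INTO unigenes VALUES (?)",
            [(t.id,) for t in sorted(targets, key=lambda t: t.id)
             if t.kind == "UNIGENE"],
        )
        con.executemany(
            "INSERT INTO bins VALUES (?,?)",
            [(b, _bin_chromosome(b)) for b in bins],
        )
        sorted_sites = sorted(sites, key=lambda s: s.site_id)
        con.executemany(
            "INSERT INTO sites VALUES (?,?,?,?,?,?,?)",
            [(s.site_id, s.mirna_id, s.target_id, s.strand, s.start, s.end,
              s.score) for s in sorted_sites],
        )
        aln_rows = []
        ann_rows = []
        for s in sorted_sites:
            lines = (s.alignment_text or "\n\n").split("\n")
            lines += [""] * (3 - len(lines))
            aln_rows.append((s.site_id, lines[0], lines[1], lines[2]))
            ann = s.annotation
            if ann is not None:
                flags = [int(ann.channel_hits.get(src, False))
                         for src in ANNOTATION_SOURCES]
                ann_rows.append(
                    (s.site_id, *flags, int(ann.gene_hit),
                     ann.hit_definition, int(ann.precursor_candidate))
                )
        con.executemany("INSERT INTO alignments VALUES (?,?,?,?)", aln_rows)
        con.executemany(
            "INSERT INTO annotations VALUES (?,?,?,?,?,?,?,?,?,?)", ann_rows)
        con.executemany(
            "INSERT INTO gene_features VALUES (?,?,?,?,?,?,?)",
            [(i + 1, f.seq_id, f.source, f.start, f.end, f.strand,
              f.hit_definition)
             for i, f in enumerate(sorted(
                 gene_features,
                 key=lambda f: (f.seq_id, f.start, f.end, f.source)))],
        )
        con.executemany(
            "INSERT INTO markers VALUES (?,?,?,?,?)",
            [(m.name, m.map_name, m.seq_id, m.position, m.bin_id)
             for m in sorted(markers, key=lambda m: (m.name, m.map_name))],
        )
        con.executemany(
            "INSERT INTO bin_assignments VALUES (?,?,?)",
            [(a.seq_id, b, repr(a.evidence))
             for a in sorted(bin_assignments, key=lambda a: a.seq_id)
             for b in sorted(a.bin_ids)],
        )
        con.executemany(
            "INSERT INTO qtl VALUES (?,?,?,?,?,?,?)",
            [(i + 1, q.trait, q.qtl_type, q.bin_id, q.direction, q.magnitude,
              None if q.significant is None else int(q.significant))
             for i, q in enumerate(sorted(
                 qtl, key=lambda q: (q.bin_id, q.qtl_type, q.trait)))],
        )
        con.executemany(
            "INSERT INTO expression VALUES (?,?,?,?)",
            [(e.unigene_id, i, lbl, val)
             for e in sorted(expression, key=lambda e: e.unigene_id)
             for i, (lbl, val) in enumerate(zip(e.stage_labels, e.values))],
        )
        con.executemany(
            "INSERT INTO precursor_hits VALUES (?,?,?,?)",
            [(sid, pid, ev, int(ret))
             for sid, pid, ev, ret in sorted(precursor_hits)],
        )
        con.executemany(
            "INSERT INTO provenance VALUES (?,?)",
            sorted((provenance or {}).items()),
        )
        con.commit()
    finally:
        con.close()
    return path


# ---------------------------------------------------------------------------
# querying
# ---------------------------------------------------------------------------

def _load_rows(con: sqlite3.Connection) -> list[dict]:
    con.row_factory = sqlite3.Row
    bins_by_seq: dict[str, list[str]] = {}
    for r in con.execute(
            "SELECT seq_id, bin_id FROM bin_assignments ORDER BY seq_id, bin_id"):
        bins_by_seq.setdefault(r["seq_id"], []).append(r["bin_id"])
    qtl_by_bin: dict[str, list[str]] = {}
    for r in con.execute(
            "SELECT trait, qtl_type, bin_id FROM qtl "
            "ORDER BY bin_id, qtl_type, trait"):
        qtl_by_bin.setdefault(r["bin_id"], []).append(
            f"{r['trait']} [{r['qtl_type']}]")
    expr_by_uni: dict[str, list[str]] = {}
    for r in con.execute(
            "SELECT unigene_id, stage_label, value FROM expression "
            "ORDER BY unigene_id, stage_index"):
        expr_by_uni.setdefault(r["unigene_id"], []).append(
            f"{r['stage_label']}={r['value']:g}")
    rows = []
    for r in con.execute(
            "SELECT s.site_id, s.mirna_id, s.seq_id, q.kind, s.strand, "
            "s.start, s.end, s.score, "
            "a.mirna_line, a.pairing_line, a.target_line, "
            "n.gene_hit, n.hit_definition, n.precursor_candidate "
            "FROM sites s "
            "JOIN sequences q ON q.seq_id = s.seq_id "
            "LEFT JOIN alignments a ON a.site_id = s.site_id "
            "LEFT JOIN annotations n ON n.site_id = s.site_id "
            "ORDER BY s.mirna_id, s.seq_id, s.start, s.strand"):
        site_bins = bins_by_seq.get(r["seq_id"], [])
        qtl_texts: list[str] = []
        for b in site_bins:
            qtl_texts.extend(qtl_by_bin.get(b, []))
        aln = "\n".join(
            x for x in (r["mirna_line"], r["pairing_line"], r["target_line"])
            if x is not None
        )
        rows.append({
            "site_id": r["site_id"],
            "mirna_id": r["mirna_id"],
            "target_id": r["seq_id"],
            "target_kind": r["kind"],
            "strand": r["strand"],
            "start": r["start"],
            "end": r["end"],
            "score": r["score"],
            "bin_ids": ",".join(site_bins),
            "gene_hit": "yes" if r["gene_hit"] else "no",
            "hit_definition": r["hit_definition"] or "",
            "precursor_candidate": "yes" if r["precursor_candidate"] else "no",
            "qtl": "; ".join(qtl_texts),
            "expression": ";".join(expr_by_uni.get(r["seq_id"], [])),
            "alignment": aln,
        })
    return rows


def query(
    store: str | Path,
    by: str,
    term: str,
    fields: Optional[Sequence[str]] = None,
) -> list[dict]:
    """Search the store by BIN, miRNA, target or keyword.

    Keyword search is a case-insensitive substring match over hit
    definitions and the QTL trait text of the site's BINs.  ``fields``
    selects and orders the output columns (default: all display fields).
    """
    if by not in QUERY_FIELDS:
        raise ValueError(
            f"unknown query field {by!r}; choose from {QUERY_FIELDS}"
        )
    if fields:
        unknown = [f for f in fields if f not in DISPLAY_FIELDS]
        if unknown:
            raise ValueError(f"unknown output fields: {unknown}")
    con = sqlite3.connect(store)
    try:
        rows = _load_rows(con)
    finally:
        con.close()
    t = term.lower()
    if by == "bin":
        rows = [r for r in rows if term in r["bin_ids"].split(",")]
    elif by == "mirna":
        rows = [r for r in rows if r["mirna_id"] == term]
    elif by == "target":
        rows = [r for r in rows if r["target_id"] == term]
    else:
        rows = [r for r in rows
                if t in r["hit_definition"].lower() or t in r["qtl"].lower()]
    if fields:
        rows = [{f: r[f] for f in fields} for r in rows]
    return rows


def export(
    rows: Sequence[Mapping],
    format: str,
    path: str | Path,
) -> Path:
    """Write query rows as RFC-4180 CSV (CRLF line ends, fields quoted as
    needed) or as a single static HTML table page; both are byte-stable for
    a fixed input."""
    path = Path(path)
    if format not in ("csv", "html"):
        raise ValueError(f"unknown export format {format!r}")
    header = list(rows[0].keys()) if rows else list(DISPLAY_FIELDS)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\r\n")
            writer.writerow(header)
            for r in rows:
                writer.writerow([r[k] for k in header])
        return path
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset=\"utf-8\">",
        "<title>miRNA target site query results</title></head><body>",
        "<table border=\"1\">",
        "<tr>" + "".join(f"<th>{_html.escape(str(h))}</th>" for h in header)
        + "</tr>",
    ]
    for r in rows:
        cells = "".join(
            "<td><pre>{}</pre></td>".format(_html.escape(str(r[k])))
            if k == "alignment" else
            f"<td>{_html.escape(str(r[k]))}</td>"
            for k in header
        )
        parts.append(f"<tr>{cells}</tr>")
    parts.append("</table></body></html>")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(parts) + "\n")
    return path
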