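"""Stage chaining: scan → score/curate → annotate → map BINs → co-locate →
store, with plain-TSV stage outputs so every stage can be run and inspected
standalone."""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import annotate as _annotate
from . import genmap as _genmap
from . import scanner as _scanner
from . import scoring as _scoring
from . import store as _store
from .seqio import (ANNOTATION_SOURCES, SiteAnnotation, TargetSite,
                    read_blast_tab, read_expression_table, read_gff3_features,
                    read_marker_table, read_mirna_fasta, read_qtl_table,
                    read_target_fasta)

log = logging.getLogger(__name__)

__version__ = "0.1.0"

BUNDLE_FILES = {
    "mirnas": "mirnas.fasta",
    "bacs": "bacs.fasta",
    "unigenes": "unigenes.fasta",
    "gff3": "features.gff3",
    "markers": "markers.tsv",
    "qtl": "qtl.tsv",
    "expression": "expression.tsv",
    "placements": "unigene_placements.tsv",
    "precursors": "precursor_hits.tsv",
}


@dataclass
class RunConfig:
    """Paths and parameter overrides for one pipeline run."""

    mirnas: Path
    out_dir: Path
    bacs: Optional[Path] = None
    unigenes: Optional[Path] = None
    gff3: Optional[Path] = None
    markers: Optional[Path] = None
    qtl: Optional[Path] = None
    expression: Optional[Path] = None
    placements: Optional[Path] = None
    precursors: Optional[Path] = None
    store_name: str = "sites.sqlite"
    scan_params: _scanner.ScanParams = field(
        default_factory=_scanner.ScanParams)
    scoring_params: _scoring.ScoringParams = field(
        default_factory=_scoring.ScoringParams)
    mapping_params: _genmap.MappingParams = field(
        default_factory=_genmap.MappingParams)

    @classmethod
    def from_bundle_dir(cls, bundle_dir: str | Path, out_dir: str | Path,
                        **overrides) -> "RunConfig":
        bundle_dir = Path(bundle_dir)
        kwargs = {
            key: bundle_dir / name
            for key, name in BUNDLE_FILES.items()
            if (bundle_dir / name).exists()
        }
        if "mirnas" not in kwargs:
            raise FileNotFoundError(
                f"{bundle_dir / BUNDLE_FILES['mirnas']}: missing input")
        kwargs.update(overrides)
        return cls(out_dir=Path(out_dir), **kwargs)


def apply_config_overrides(cfg: RunConfig, flat: dict) -> RunConfig:
    """Apply a flat key→value mapping (e.g. from a YAML config file) onto the
    three parameter dataclasses; unknown keys raise."""
    groups = {
        "scan_params": cfg.scan_params,
        "scoring_params": cfg.scoring_params,
        "mapping_params": cfg.mapping_params,
    }
    remaining = dict(flat)
    for attr, params in groups.items():
        hits = {k: remaining.pop(k) for k in list(remaining)
                if k in params.__dataclass_fields__}
        if hits:
            setattr(cfg, attr, replace(params, **hits))
    if remaining:
        raise ValueError(f"unknown config keys: {sorted(remaining)}")
    return cfg


# ---------------------------------------------------------------------------
# stage TSV round-trip
# ---------------------------------------------------------------------------

SITE_TSV_COLUMNS = (
    "site_id", "mirna_id", "target_id", "target_kind", "strand", "start",
    "end", "mirna_gapped", "target_gapped", "score", "gene_hit",
    "hit_definition", "precursor_candidate", "bin_ids",
) + ANNOTATION_SOURCES


def write_sites_tsv(rows: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SITE_TSV_COLUMNS,
                                delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in SITE_TSV_COLUMNS})
    return path


def read_sites_tsv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            for key in ("start", "end"):
                row[key] = int(row[key])
            if row.get("score"):
                row["score"] = float(row["score"])
            rows.append(row)
    return rows


def site_row(aln: _scanner.DuplexAlignment, kind: str, **extra) -> dict:
    row = {
        "mirna_id": aln.mirna_id,
        "target_id": aln.target_id,
        "target_kind": kind,
        "strand": aln.strand,
        "start": aln.target_start,
        "end": aln.target_end,
        "mirna_gapped": aln.mirna_gapped,
        "target_gapped": aln.target_gapped,
    }
    row.update(extra)
    return row


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _require(path: Optional[Path], label: str) -> None:
    if path is not None and not Path(path).exists():
        raise FileNotFoundError(f"{label} input not found: {path}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and build the store; returns the run report
    (counts per stage).  Raises FileNotFoundError for missing inputs."""
    for label in ("mirnas", "bacs", "unigenes", "gff3", "markers", "qtl",
                  "expression", "placements", "precursors"):
        _require(getattr(cfg, label), label)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mirnas = read_mirna_fasta(cfg.mirnas)
    targets = []
    if cfg.bacs:
        targets += read_target_fasta(cfg.bacs, "BAC")
    if cfg.unigenes:
        targets += read_target_fasta(cfg.unigenes, "UNIGENE")
    if not targets:
        raise ValueError("no target sequences given (need --bacs and/or "
                         "--unigenes)")

    # stage 1: scan
    candidates: list[tuple[_scanner.DuplexAlignment, str]] = []
    for mirna in mirnas:
        for target in targets:
            for aln in _scanner.scan(mirna, target, cfg.scan_params,
                                     cfg.scoring_params):
                candidates.append((aln, target.kind))
    log.info("scan: %d candidate duplexes", len(candidates))

    # stage 2: score + curate
    scored = [(aln, _scoring.score_duplex(aln, cfg.scoring_params), kind)
              for aln, kind in candidates]
    curated = _scoring.curate([(a, s) for a, s, _ in scored],
                              cfg.scoring_params)
    kind_of = {id(a): k for a, _, k in scored}
    curated.sort(key=lambda p: (p[0].mirna_id, p[0].target_id,
                                p[0].target_start, p[0].strand))
    sites: list[TargetSite] = []
    for idx, (aln, score) in enumerate(curated, start=1):
        sites.append(TargetSite(
            site_id=f"S{idx:05d}",
            mirna_id=aln.mirna_id,
            target_id=aln.target_id,
            target_kind=kind_of[id(aln)],
            strand=aln.strand,
            start=aln.target_start,
            end=aln.target_end,
            score=score.score,
            alignment_text=_scanner.render_alignment(aln),
        ))
    log.info("curation: %d of %d candidates retained (< %g)",
             len(sites), len(candidates), cfg.scoring_params.threshold)

    # stage 3: annotate
    gene_features, gff_markers, _ = (
        read_gff3_features(cfg.gff3) if cfg.gff3 else ([], [], None))
    _annotate.annotate_sites(sites, gene_features)
    yes = sum(1 for s in sites if s.annotation.gene_hit)

    # stage 4: precursor curation for non-genic sites
    precursor_hits = read_blast_tab(cfg.precursors) if cfg.precursors else []
    prec_rows: list[tuple[str, str, float, bool]] = []
    for site in sites:
        if site.annotation.gene_hit:
            continue
        matching = [h for h in precursor_hits
                    if h.query == site.target_id
                    and h.q_start <= site.end and site.start <= h.q_end]
        retained = _genmap.curate_precursor_hits(matching, cfg.mapping_params)
        retained_ids = {h.subject for h in retained}
        for h in matching:
            prec_rows.append((site.site_id, h.subject, h.e_value,
                              h.subject in retained_ids))
        if retained:
            site.annotation.precursor_candidate = True

    # stage 5: genetic mapping
    markers = read_marker_table(cfg.markers) if cfg.markers else []
    bac_assignments = {
        t.id: _genmap.assign_bac_bins(t.id, markers)
        for t in targets if t.kind == "BAC"
    }
    qlens = {t.id: len(t) for t in targets if t.kind == "UNIGENE"}
    placements = (read_blast_tab(cfg.placements, query_lengths=qlens)
                  if cfg.placements else [])
    uni_assignments = {
        t.id: _genmap.place_unigene(t.id, placements, bac_assignments,
                                    cfg.mapping_params)
        for t in targets if t.kind == "UNIGENE"
    }
    assignments = {**bac_assignments, **uni_assignments}
    for site in sites:
        a = assignments.get(site.target_id)
        site.bin_ids = tuple(sorted(a.bin_ids)) if a else ()

    # stage 6: co-locate and persist
    qtl = read_qtl_table(cfg.qtl) if cfg.qtl else []
    expression = read_expression_table(cfg.expression) if cfg.expression else []
    qtl_bins = {q.bin_id for q in qtl}
    store_path = out_dir / cfg.store_name
    _store.build_store(
        store_path,
        mirnas=mirnas,
        targets=targets,
        sites=sites,
        gene_features=gene_features,
        markers=markers,
        bin_assignments=[a for a in assignments.values() if a.bin_ids],
        qtl=qtl,
        expression=expression,
        precursor_hits=prec_rows,
        provenance={
            "toolkit": f"mirtarmap {__version__}",
            "threshold": repr(cfg.scoring_params.threshold),
            "min_identity": repr(cfg.mapping_params.min_identity),
            "min_coverage": repr(cfg.mapping_params.min_coverage),
            "precursor_evalue_cutoff": repr(
                cfg.mapping_params.precursor_evalue_cutoff),
        },
    )

    report = {
        "mirnas": len(mirnas),
        "targets": len(targets),
        "candidate_sites": len(candidates),
        "curated_sites": len(sites),
        "annotated_yes": yes,
        "annotated_no": len(sites) - yes,
        "precursor_candidates": sum(
            1 for s in sites if s.annotation.precursor_candidate),
        "sequences_with_bins": sum(
            1 for a in assignments.values() if a.bin_ids),
        "sites_with_bins": sum(1 for s in sites if s.bin_ids),
        "sites_with_qtl": sum(
            1 for s in sites if any(b in qtl_bins for b in s.bin_ids)),
        "store": str(store_path),
    }
    rows = []
    for s in sites:
        ann = s.annotation
        rows.append({
            "site_id": s.site_id,
            "mirna_id": s.mirna_id,
            "target_id": s.target_id,
            "target_kind": s.target_kind,
            "strand": s.strand,
            "start": s.start,
            "end": s.end,
            "mirna_gapped": s.alignment_text.split("\n")[0][3:-3],
            "target_gapped": s.alignment_text.split("\n")[2][3:-3],
            "score": s.score,
            "gene_hit": "yes" if ann.gene_hit else "no",
            "hit_definition": ann.hit_definition,
            "precursor_candidate": "yes" if ann.precursor_candidate else "no",
            "bin_ids": ",".join(s.bin_ids),
            **{src: int(ann.channel_hits.get(src, False))
               for src in ANNOTATION_SOURCES},
        })
    write_sites_tsv(rows, out_dir / "sites.tsv")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
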