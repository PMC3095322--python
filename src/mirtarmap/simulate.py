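"""Seeded synthetic-data generator.

Produces a complete toy dataset — mature miRNAs, BAC and unigene sequences
with planted antisense target sites, GFF3 gene models and markers, a
marker→BIN table, QTL and expression tables, unigene placements and
precursor-search hits — together with a machine-readable ground-truth
manifest, so every pipeline stage is testable without any download.

Planted sites are specified as mutation profiles (wobble / mismatch /
insertion / deletion edits at given miRNA positions); the generator computes
each plant's expected penalty score with its own small window-enumeration
scorer, kept deliberately independent of the scoring module so the two can
be cross-checked.  Background sequence is random with miRNA complementarity
suppressed: after planting, an exhaustive ungapped window scan re-draws any
background locus that would score below the curation threshold (with a
safety margin), so the manifest lists every recoverable site.

The default plan mirrors a miR395-flavoured proof of concept: three
clustered precursor-like loci on one BAC lying between two markers of BIN
5B, a sulfate-assimilation unigene target, and a QTL table carrying 19 QML
plus 5 YAL for that BIN (fructose among them).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import normalize_rna, revcomp_dna

log = logging.getLogger(__name__)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOB = {"G": "U", "U": "G"}
_BASES = "ACGU"

EDITS = ("wobble", "mismatch", "insertion", "deletion")

#: fruit development / ripening stages used for the expression profiles
STAGES = ("anthesis", "10dpa", "20dpa", "30dpa", "mature_green", "breaker",
          "ripe", "overripe")

QML_TRAITS_5B = (
    "fructose", "glucose", "sucrose", "citrate", "malate", "succinate",
    "glutamate", "aspartate", "alanine", "valine", "leucine", "glycine",
    "serine", "phenylalanine", "GABA", "myo-inositol", "phosphate",
    "palmitate", "stearate",
)
YAL_TRAITS_5B = ("fruit length", "plant weight", "brix", "harvest index",
                 "seeds per plant")


@dataclass(frozen=True)
class PlantSpec:
    """One planted target site: where it goes and how it deviates from
    perfect complementarity."""

    mirna_id: str
    target_id: str
    position: int  # 1-based start on the plus strand of the target
    strand: str
    profile: tuple[tuple[int, str], ...] = ()
    expected_score: Optional[float] = None

    def __post_init__(self) -> None:
        for pos, edit in self.profile:
            if edit not in EDITS:
                raise ValueError(f"unknown edit {edit!r}")
            if pos < 1:
                raise ValueError("edit positions are 1-based")


class GenerationError(ValueError):
    pass


def profile_expected_score(
    mirna_len: int,
    profile: Sequence[tuple[int, str]],
    window_len: int = 20,
    seed_start: int = 2,
    seed_end: int = 7,
) -> float:
    """Window-minimum penalty of a mutation profile, by direct enumeration.

    Intentionally independent of the scoring module: it never builds an
    alignment, it just walks every consecutive window and adds up the edit
    penalties that fall inside it (an insertion after position p belongs to
    windows containing both p and p+1).
    """
    if mirna_len < window_len:
        raise GenerationError(
            f"miRNA of {mirna_len} nt cannot carry a {window_len}-nt window"
        )
    best = None
    for w in range(1, mirna_len - window_len + 2):
        hi = w + window_len - 1
        total = 0.0
        for pos, edit in profile:
            if edit == "wobble" and w <= pos <= hi:
                total += 0.5
            elif edit == "mismatch" and w <= pos <= hi:
                total += 1.5 if seed_start <= pos <= seed_end else 1.0
            elif edit == "deletion" and w <= pos <= hi:
                total += 2.0
            elif edit == "insertion" and w <= pos <= hi - 1:
                total += 2.0
        if best is None or total < best:
            best = total
    return best


def build_site_sequence(
    mirna_seq: str,
    profile: Sequence[tuple[int, str]],
    rng: np.random.Generator,
) -> str:
    """Transcript-sense (5'→3') site sequence pairing the miRNA under the
    given mutation profile.

    Mismatch and insertion bases are chosen so they cannot pair (Watson-Crick
    or wobble) where they sit, keeping the planted alignment the unique
    optimum.
    """
    q = normalize_rna(mirna_seq)
    m = len(q)
    paired = [_COMP[b] for b in q]
    inserts: dict[int, str] = {}
    deletions: set[int] = set()
    for pos, edit in profile:
        if edit == "insertion":
            if not 1 <= pos <= m - 1:
                raise GenerationError(
                    f"insertion after position {pos} outside miRNA of {m} nt")
        elif not 1 <= pos <= m:
            raise GenerationError(
                f"edit position {pos} outside miRNA of {m} nt")
        if edit == "wobble":
            partner = _WOB.get(q[pos - 1])
            if partner is None:
                raise GenerationError(
                    f"no G:U wobble possible at position {pos} "
                    f"(miRNA base {q[pos - 1]})")
            paired[pos - 1] = partner
        elif edit == "mismatch":
            banned = {_COMP[q[pos - 1]], _WOB.get(q[pos - 1])}
            choices = [b for b in _BASES if b not in banned]
            paired[pos - 1] = choices[rng.integers(len(choices))]
        elif edit == "deletion":
            deletions.add(pos)
        elif edit == "insertion":
            banned = {_COMP[q[pos - 1]], _WOB.get(q[pos - 1]),
                      _COMP[q[pos]], _WOB.get(q[pos])}
            choices = [b for b in _BASES if b not in banned]
            if not choices:  # only Watson-Crick partners need excluding
                choices = [b for b in _BASES
                           if b not in (_COMP[q[pos - 1]], _COMP[q[pos]])]
            inserts[pos] = choices[rng.integers(len(choices))]
    in_mirna_order: list[str] = []
    for pos in range(1, m + 1):
        if pos not in deletions:
            in_mirna_order.append(paired[pos - 1])
        if pos in inserts:
            in_mirna_order.append(inserts[pos])
    return "".join(reversed(in_mirna_order))


def _rand_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _rand_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# background suppression
# ---------------------------------------------------------------------------

def _penalty_profile(q: str) -> np.ndarray:
    """pen[i, b]: penalty of miRNA position i+1 facing transcript base b."""
    m = len(q)
    pen = np.empty((m, 4))
    for i, qb in enumerate(q):
        seed = 2 <= i + 1 <= 7
        for bi, tb in enumerate(_BASES):
            if _COMP[qb] == tb:
                pen[i, bi] = 0.0
            elif _WOB.get(qb) == tb:
                pen[i, bi] = 0.5
            else:
                pen[i, bi] = 1.5 if seed else 1.0
    return pen


def _ungapped_window_scores(q: str, transcript_enc: np.ndarray) -> np.ndarray:
    """Best 20-window penalty of the ungapped duplex at every transcript
    offset (offset = position of the site's 3'-most base pairing miRNA
    position 1, 0-based on the transcript read 3'→5').

    ``transcript_enc`` must be the transcript encoded 3'→5' so that offset o,
    miRNA position i pairs transcript_enc[o + i - 1].
    """
    m = len(q)
    n = len(transcript_enc)
    if n < m:
        return np.empty(0)
    pen = _penalty_profile(q)
    n_off = n - m + 1
    cols = np.empty((m, n_off))
    for i in range(m):
        cols[i] = pen[i, transcript_enc[i:i + n_off]]
    csum = np.vstack([np.zeros(n_off), np.cumsum(cols, axis=0)])
    window = 20
    wins = [csum[w + window] - csum[w] for w in range(m - window + 1)]
    return np.min(np.stack(wins), axis=0)


def _suppress_background(
    rng: np.random.Generator,
    q_list: Sequence[tuple[str, str]],  # (mirna_id, sequence)
    seq: str,
    protected: Sequence[tuple[int, int]],
    kind: str,
    margin: float = 0.5,
    threshold: float = 3.0,
    max_rounds: int = 40,
) -> str:
    """Re-draw background bases until no ungapped duplex outside the
    protected intervals scores below threshold + margin, for any miRNA on
    any scanned strand."""
    arr = np.array(list(seq))
    enc_map = {b: i for i, b in enumerate("ACGT")}
    L = len(seq)

    def protected_mask() -> np.ndarray:
        mask = np.zeros(L, dtype=bool)
        for s, e in protected:
            lo = max(0, s - 1 - 4)
            hi = min(L, e + 4)
            mask[lo:hi] = True
        return mask

    prot = protected_mask()
    strands = ("+", "-") if kind == "BAC" else ("+",)
    for round_no in range(max_rounds):
        dirty = np.zeros(L, dtype=bool)
        dna = "".join(arr)
        for _, qseq in q_list:
            m = len(qseq)
            if m > L:
                continue
            for strand in strands:
                # transcript read 3'→5': for '+' the transcript is the plus
                # strand, read 3'→5' == reversed; for '-' it is the revcomp,
                # read 3'→5' == complement of the plus strand left-to-right.
                if strand == "+":
                    t35 = dna.replace("T", "U")[::-1]
                    # offset o covers plus positions [L-o-m+1 .. L-o] 1-based
                    def span(o: int) -> tuple[int, int]:
                        return L - o - m + 1, L - o
                else:
                    t35 = "".join(_COMP[b] for b in dna.replace("T", "U"))
                    def span(o: int) -> tuple[int, int]:
                        return o + 1, o + m
                enc = np.fromiter((enc_map["T" if c == "U" else c]
                                   for c in t35), dtype=np.int64, count=L)
                # re-encode in RNA base order ACGU == ACGT indices, same
                scores = _ungapped_window_scores(qseq, enc)
                for o in np.nonzero(scores < threshold + margin)[0]:
                    s1, e1 = span(int(o))
                    idx = slice(s1 - 1, e1)
                    if prot[idx].any():
                        continue
                    dirty[idx] = True
        dirty &= ~prot
        if not dirty.any():
            return "".join(arr)
        redraw = np.nonzero(dirty)[0]
        arr[redraw] = [_rand_dna(rng, 1) for _ in redraw]
    raise GenerationError("background suppression did not converge")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    out_dir: Path
    files: dict[str, Path]
    manifest: dict


def _default_mirnas(rng: np.random.Generator) -> list[tuple[str, str]]:
    specs = [
        ("sly-miR395a", 21),
        ("sly-miR0002", 21),
        ("sly-miR0003", 24),
        ("sly-miR0004", 22),
        ("ath-miR0005", 21),
    ]
    out = []
    for name, length in specs:
        seq = _rand_rna(rng, length)
        # guarantee wobble-capable bases in and out of the seed zone
        if not any(b in "GU" for b in seq[1:7]):
            seq = seq[:3] + "G" + seq[4:]
        if not any(b in "GU" for b in seq[9:15]):
            seq = seq[:10] + "U" + seq[11:]
        out.append((name, seq))
    return out


def _default_plants(mirnas: dict[str, str]) -> list[PlantSpec]:
    def wob_pos(mid: str, lo: int, hi: int) -> int:
        seq = mirnas[mid]
        for p in range(lo, hi + 1):
            if seq[p - 1] in "GU":
                return p
        raise GenerationError(f"no wobble-capable position in {mid}")

    return [
        # precursor-like cluster on BAC0001 (BIN 5B), no gene models there
        PlantSpec("sly-miR395a", "BAC0001", 800, "+", ()),
        PlantSpec("sly-miR395a", "BAC0001", 1000, "+",
                  ((wob_pos("sly-miR395a", 8, 21), "wobble"),)),
        PlantSpec("sly-miR395a", "BAC0001", 1200, "-",
                  ((12, "mismatch"),)),
        # expressed targets on unigenes
        PlantSpec("sly-miR395a", "SGN-U0001", 150, "+", ((4, "mismatch"),)),
        PlantSpec("sly-miR0002", "SGN-U0002", 200, "+", ((10, "insertion"),)),
        PlantSpec("sly-miR0003", "SGN-U0003", 120, "+", ((22, "mismatch"),)),
        # genic site on the second BAC, minus strand
        PlantSpec("sly-miR0004", "BAC0002", 600, "-",
                  ((2, "mismatch"), (9, "mismatch"))),
        # boundary case: scores exactly 3.0, must be curated away
        PlantSpec("ath-miR0005", "SGN-U0004", 180, "+",
                  ((4, "mismatch"), (6, "mismatch"))),
    ]


def generate(
    out_dir: str | Path,
    seed: int,
    n_bacs: int = 2,
    n_unigenes: int = 4,
    bac_length: int = 2000,
    unigene_length: int = 600,
    plants: Optional[Sequence[PlantSpec]] = None,
) -> FixtureBundle:
    """Write a complete fixture bundle plus ground-truth manifest.

    Identical seeds produce byte-identical bundles.  The default plan plants
    eight sites (one scoring exactly 3.0, which curation must reject) across
    two BACs and four unigenes, anchors BAC0001 to BIN 5B via markers CT53
    and TG432, and ships a 19-QML + 5-YAL QTL table for that BIN.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    mirna_list = _default_mirnas(rng)
    mirnas = dict(mirna_list)

    bac_ids = [f"BAC{i + 1:04d}" for i in range(n_bacs)]
    uni_ids = [f"SGN-U{i + 1:04d}" for i in range(n_unigenes)]
    seqs: dict[str, str] = {}
    kinds: dict[str, str] = {}
    for bid in bac_ids:
        seqs[bid] = _rand_dna(rng, bac_length)
        kinds[bid] = "BAC"
    for uid in uni_ids:
        seqs[uid] = _rand_dna(rng, unigene_length)
        kinds[uid] = "UNIGENE"

    plant_list = list(plants) if plants is not None else _default_plants(mirnas)

    # embed planted sites
    manifest_sites = []
    protected: dict[str, list[tuple[int, int]]] = {sid: [] for sid in seqs}
    for spec in plant_list:
        if spec.target_id not in seqs:
            raise GenerationError(f"unknown plant target {spec.target_id!r}")
        if spec.mirna_id not in mirnas:
            raise GenerationError(f"unknown plant miRNA {spec.mirna_id!r}")
        if kinds[spec.target_id] == "UNIGENE" and spec.strand != "+":
            raise GenerationError(
                "unigenes are scanned sense-strand only; plant on '+'")
        qseq = mirnas[spec.mirna_id]
        site_rna = build_site_sequence(qseq, spec.profile, rng)
        site_dna = site_rna.replace("U", "T")
        if spec.strand == "-":
            site_dna = revcomp_dna(site_dna)
        start = spec.position
        end = start + len(site_dna) - 1
        if not (1 <= start and end <= len(seqs[spec.target_id])):
            raise GenerationError(
                f"plant at {spec.target_id}:{start}-{end} out of bounds")
        for s0, e0 in protected[spec.target_id]:
            if start <= e0 + 10 and s0 <= end + 10:
                raise GenerationError(
                    f"plants overlap near {spec.target_id}:{start}")
        seq = seqs[spec.target_id]
        seqs[spec.target_id] = seq[:start - 1] + site_dna + seq[end:]
        protected[spec.target_id].append((start, end))
        expected = profile_expected_score(len(qseq), spec.profile)
        if spec.expected_score is not None and \
                abs(spec.expected_score - expected) > 1e-9:
            raise GenerationError(
                f"plant {spec.mirna_id}→{spec.target_id}: declared score "
                f"{spec.expected_score} != computed {expected}")
        manifest_sites.append({
            "mirna_id": spec.mirna_id,
            "target_id": spec.target_id,
            "target_kind": kinds[spec.target_id],
            "strand": spec.strand,
            "start": start,
            "end": end,
            "profile": [list(p) for p in spec.profile],
            "expected_score": expected,
            "curated": expected < 3.0 - 1e-9,
        })

    # suppress accidental background complementarity
    for sid in sorted(seqs):
        seqs[sid] = _suppress_background(
            rng, mirna_list, seqs[sid], protected[sid], kinds[sid])

    # gene features: the unigene targets are genic; the precursor cluster on
    # BAC0001 deliberately is not; BAC0002's site sits inside a de novo gene
    gff_rows: list[tuple] = []
    gene_truth: dict[int, dict] = {}
    uni_defs = {
        "SGN-U0001": ("AUGUSTUS_UNIGENE",
                      "sulfate adenylyltransferase (ATP sulfurylase)"),
        "SGN-U0002": ("GENOMETHREADER", "phosphate transporter"),
        "SGN-U0003": ("BLASTX_ARATH", "TCP family transcription factor"),
        "SGN-U0004": ("AUGUSTUS_TOMATO_EST", "lipoxygenase"),
    }
    for uid in uni_ids:
        src, definition = uni_defs.get(
            uid, ("AUGUSTUS_UNIGENE", "hypothetical protein"))
        gff_rows.append((uid, src, "gene", 1, len(seqs[uid]), "+",
                         f"ID={uid}.g1;Note={definition}"))
    # BAC0002 gene spanning its planted site
    gff_rows.append(("BAC0002", "AUGUSTUS_DENOVO", "gene", 520, 760, "-",
                     "ID=BAC0002.g1;Note=serine carboxypeptidase"))
    gff_rows.append(("BAC0002", "AUGUSTUS_POTATO_EST", "gene", 1400, 1700, "+",
                     "ID=BAC0002.g2;Note=cell wall invertase"))
    # background gene on BAC0001 far from the cluster
    gff_rows.append(("BAC0001", "AUGUSTUS_TOMATO_EST", "gene", 100, 340, "+",
                     "ID=BAC0001.g1;Note=pectinesterase"))
    # markers flanking the cluster on BAC0001 (BIN 5B) and one on BAC0002
    marker_rows = [
        ("CT53", "EXPEN2000", "BAC0001", 700, "5B"),
        ("CT53", "EXPEN1992", "BAC0001", 700, "5B"),
        ("TG432", "EXPEN2000", "BAC0001", 1320, "5B"),
        ("TG154", "EXPEN2000", "BAC0002", 900, "2C"),
    ]
    for name, map_name, bac, pos, bin_id in marker_rows:
        gff_rows.append((bac, "SGN_marker", "genetic_marker", pos, pos + 5,
                         "+", f"Name={name};map={map_name};bin={bin_id}"))

    gene_by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for row in gff_rows:
        if row[2] == "gene":
            gene_by_seq.setdefault(row[0], []).append((row[3], row[4], row[1]))
    bac_bin_truth = {"BAC0001": ["5B"], "BAC0002": ["2C"]}

    # unigene placements (12-column BLAST tabular), with threshold boundaries
    placements = []
    def _placement(uid, bac, ident, cov_frac):
        qlen = len(seqs[uid])
        alen = int(round(cov_frac * qlen))
        return (uid, bac, f"{ident:.1f}", alen, max(0, int(alen * (1 - ident / 100))),
                0, 1, alen, 101, 100 + alen, "1e-100", f"{alen * 1.8:.1f}")
    placements.append(_placement("SGN-U0001", "BAC0001", 98.5, 0.99))
    placements.append(_placement("SGN-U0002", "BAC0002", 90.0, 0.95))
    placements.append(_placement("SGN-U0003", "BAC0001", 89.9, 0.99))
    placements.append(_placement("SGN-U0004", "BAC0002", 96.2, 0.98))
    uni_bin_truth = {
        "SGN-U0001": ["5B"],
        "SGN-U0002": ["2C"],
        "SGN-U0003": [],
        "SGN-U0004": ["2C"],
    }

    # precursor-search hits for the gene-free cluster sites on BAC0001
    precursor_rows = []
    cluster = [s for s in manifest_sites if s["target_id"] == "BAC0001"]
    prec_evalues = ["1e-62", "1e-55", "1e-40"]
    prec_names = ["ath-MIR395a-prec", "ath-MIR395b-prec", "ath-MIR395c-prec"]
    for site, ev, pname in zip(cluster, prec_evalues, prec_names):
        span = site["end"] - site["start"] + 1
        precursor_rows.append(
            ("BAC0001", pname, "96.0", span, 1, 0, site["start"], site["end"],
             10, 9 + span, ev, "80.0"))
    prec_truth = {
        (s["target_id"], s["start"], s["end"]): float(ev) <= 1e-50 * (1 + 1e-9)
        for s, ev in zip(cluster, prec_evalues)
    }

    # expression profiles
    expr_rows = []
    for uid in uni_ids:
        values = np.round(rng.lognormal(2.0, 0.6, size=len(STAGES)), 2)
        for stage, val in zip(STAGES, values):
            expr_rows.append((uid, stage, f"{val:.2f}"))

    # QTL: 19 QML + 5 YAL on BIN 5B, a couple elsewhere
    qtl_rows = [(t, "QML", "5B") for t in QML_TRAITS_5B]
    qtl_rows += [(t, "YAL", "5B") for t in YAL_TRAITS_5B]
    qtl_rows += [("starch", "QML", "2C"), ("threonine", "QML", "2C")]

    # ground truth per site: gene hit, bins, co-located QTL
    for site in manifest_sites:
        genes = gene_by_seq.get(site["target_id"], [])
        hit_channels = sorted({
            src for (gs, ge, src) in genes
            if gs <= site["end"] and site["start"] <= ge
        })
        site["gene_hit"] = bool(hit_channels)
        site["gene_channels"] = hit_channels
        bins = (bac_bin_truth.get(site["target_id"])
                or uni_bin_truth.get(site["target_id"]) or [])
        site["bin_ids"] = sorted(bins)
        site["qtl_count"] = sum(1 for (_, _, b) in qtl_rows if b in bins)
        key = (site["target_id"], site["start"], site["end"])
        site["precursor_candidate"] = bool(
            not site["gene_hit"] and prec_truth.get(key, False))

    # ---------------- write files (fixed order => byte determinism) -------
    files: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        p = out_dir / name
        with open(p, "w", newline="") as fh:
            fh.write(text)
        files[name] = p

    fasta = []
    for mid, seq in mirna_list:
        fasta.append(f">{mid}\n{seq}\n")
    _write("mirnas.fasta", "".join(fasta))
    for name, ids in (("bacs.fasta", bac_ids), ("unigenes.fasta", uni_ids)):
        chunks = []
        for sid in ids:
            s = seqs[sid]
            body = "\n".join(s[i:i + 70] for i in range(0, len(s), 70))
            chunks.append(f">{sid}\n{body}\n")
        _write(name, "".join(chunks))
    gff_lines = ["##gff-version 3"]
    for seqid, src, ftype, start, end, strand, attrs in sorted(gff_rows):
        gff_lines.append(
            f"{seqid}\t{src}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
    _write("features.gff3", "\n".join(gff_lines) + "\n")
    _write("markers.tsv", "name\tmap\tbac\tposition\tbin\n" + "".join(
        f"{n}\t{m}\t{b}\t{p}\t{bi}\n" for n, m, b, p, bi in marker_rows))
    _write("qtl.tsv", "trait\ttype\tbin\n" + "".join(
        f"{t}\t{ty}\t{b}\n" for t, ty, b in qtl_rows))
    _write("expression.tsv", "unigene_id\tstage\tvalue\n" + "".join(
        f"{u}\t{s}\t{v}\n" for u, s, v in expr_rows))
    _write("unigene_placements.tsv", "".join(
        "\t".join(str(c) for c in row) + "\n" for row in placements))
    _write("precursor_hits.tsv", "".join(
        "\t".join(str(c) for c in row) + "\n" for row in precursor_rows))

    manifest = {
        "seed": seed,
        "n_mirnas": len(mirna_list),
        "n_bacs": n_bacs,
        "n_unigenes": n_unigenes,
        "sites": sorted(manifest_sites,
                        key=lambda s: (s["mirna_id"], s["target_id"],
                                       s["start"])),
        "bac_bins": bac_bin_truth,
        "unigene_bins": uni_bin_truth,
        "qtl_per_bin": {
            "5B": {"QML": len(QML_TRAITS_5B), "YAL": len(YAL_TRAITS_5B)},
            "2C": {"QML": 2, "YAL": 0},
        },
        "counts": {
            "planted": len(manifest_sites),
            "curatable": sum(1 for s in manifest_sites if s["curated"]),
            "gene_hit_yes": sum(
                1 for s in manifest_sites if s["curated"] and s["gene_hit"]),
            "precursor_candidates": sum(
                1 for s in manifest_sites
                if s["curated"] and s["precursor_candidate"]),
        },
    }
    with open(out_dir / "manifest.json", "w", newline="") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files["manifest.json"] = out_dir / "manifest.json"
    return FixtureBundle(out_dir=out_dir, files=files, manifest=manifest)
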