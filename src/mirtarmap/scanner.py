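"""Antisense duplex scanner: find candidate miRNA:target sites as gapped
alignments ready for penalty scoring.

The scanner aligns the miRNA 5'→3' against the antisense of the target, so a
sequence-identity match in alignment space is a Watson-Crick pair in duplex
space and the pairs (G,A)/(U,C) in alignment space are the G:U wobbles.  For
each target offset it finds the optimal full-miRNA-coverage banded alignment
under miRanda-like rewards (+5 pair, +2 wobble, -3 mismatch, affine gaps
-8/-2); offsets whose best alignment pairs at least ``min_mirna_coverage`` of
the miRNA positions become candidates, and overlapping candidates of the
same miRNA within 3 nt are merged keeping the one with the lowest downstream
penalty score.  BACs are scanned on both strands, unigenes sense-only.

``scan`` prunes offsets with a vectorized upper-bound pass before running the
exact per-offset DP; ``scan_exhaustive`` enumerates every gap placement
explicitly and is the test oracle — both optimize the same total order
(reward score, then fewer gap columns, then lexicographically earliest
operations) so their outputs are identical.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import scoring as _scoring
from .seqio import (GAP, MatureMiRNA, TargetSequence, normalize_rna,
                    revcomp_rna)

log = logging.getLogger(__name__)

_NEG = float("-inf")
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
# alignment-space wobbles: miRNA G pairs target U (revcomp A), miRNA U pairs
# target G (revcomp C)
_WOBBLE_ALN = {("G", "A"), ("U", "C")}

_EXHAUSTIVE_GUARD = 10_000


@dataclass(frozen=True)
class ScanParams:
    """Scanner defaults (this toolkit's own; the duplex-finding stage has no
    published parameterization beyond 'defaults')."""

    pair_reward: float = 5.0
    wobble_reward: float = 2.0
    mismatch_penalty: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    min_mirna_coverage: float = 0.9
    max_sites_per_pair: int = 20
    band_width: int = 3

    def __post_init__(self) -> None:
        if not (self.pair_reward > 0 and self.wobble_reward > 0):
            raise ValueError("rewards must be positive")
        if not (self.mismatch_penalty < 0 and self.gap_open < 0
                and self.gap_extend < 0):
            raise ValueError("penalties must be negative")
        if not 0 < self.min_mirna_coverage <= 1:
            raise ValueError("min_mirna_coverage must be in (0, 1]")
        if self.band_width < 0:
            raise ValueError("band_width must be >= 0")


@dataclass(frozen=True)
class DuplexAlignment:
    """One gapped antisense alignment between a miRNA and a target site.

    Columns are ordered 5'→3' along the miRNA; the target base of a column is
    the transcript-sense base the miRNA base faces, so reading the target
    bases in column order traverses the site 3'→5'.  Coordinates are 1-based
    inclusive on the plus strand of the target sequence; strand '-' means the
    duplex is formed with the reverse complement.  ``mirna_positions`` gives,
    per column, the 1-based miRNA position consumed (None for columns where
    the miRNA has a gap).
    """

    mirna_id: str
    target_id: str
    target_start: int
    target_end: int
    strand: str
    columns: tuple[tuple[str, str], ...]
    mirna_positions: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.target_end < self.target_start:
            raise ValueError("target_end < target_start")
        if len(self.columns) != len(self.mirna_positions):
            raise ValueError("columns and mirna_positions lengths differ")
        for (mb, tb), pos in zip(self.columns, self.mirna_positions):
            if mb == GAP and tb == GAP:
                raise ValueError("column with a gap on both sides")
            if (mb == GAP) != (pos is None):
                raise ValueError("mirna_positions inconsistent with gaps")

    @property
    def mirna_gapped(self) -> str:
        return "".join(mb for mb, _ in self.columns)

    @property
    def target_gapped(self) -> str:
        return "".join(tb for _, tb in self.columns)


def render_alignment(aln: DuplexAlignment) -> str:
    """Three-line duplex rendering: miRNA on top 5'→3', pairing bars ('|'
    Watson-Crick, ':' G:U wobble, space otherwise), target bottom 3'→5'."""
    bars = []
    for mb, tb in aln.columns:
        cls = _scoring.classify_column(mb, tb) if GAP not in (mb, tb) else None
        if cls is _scoring.PairClass.MATCH:
            bars.append("|")
        elif cls is _scoring.PairClass.WOBBLE:
            bars.append(":")
        else:
            bars.append(" ")
    return "\n".join([
        f"5' {aln.mirna_gapped} 3'",
        f"   {''.join(bars)}   ",
        f"3' {aln.target_gapped} 5'",
    ])


def duplex_from_gapped(
    mirna_id: str,
    target_id: str,
    mirna_gapped: str,
    target_gapped: str,
    target_start: int,
    target_end: int,
    strand: str = "+",
) -> DuplexAlignment:
    """Rebuild a DuplexAlignment from its two gapped strings (used by the
    stage TSV round-trip and by direct duplex construction in tests)."""
    if len(mirna_gapped) != len(target_gapped):
        raise ValueError("gapped strings must have equal length")
    def _norm(ch: str) -> str:
        ch = ch.upper()
        return GAP if ch == GAP else ("U" if ch == "T" else ch)

    columns = []
    positions: list[Optional[int]] = []
    pos = 0
    for mb, tb in zip((_norm(c) for c in mirna_gapped),
                      (_norm(c) for c in target_gapped)):
        columns.append((mb, tb))
        if mb != GAP:
            pos += 1
            positions.append(pos)
        else:
            positions.append(None)
    return DuplexAlignment(
        mirna_id=mirna_id,
        target_id=target_id,
        target_start=target_start,
        target_end=target_end,
        strand=strand,
        columns=tuple(columns),
        mirna_positions=tuple(positions),
    )


# ---------------------------------------------------------------------------
# alignment search
# ---------------------------------------------------------------------------

def _col_score(qb: str, rb: str, params: ScanParams) -> float:
    if qb == rb:
        return params.pair_reward
    if (qb, rb) in _WOBBLE_ALN:
        return params.wobble_reward
    return params.mismatch_penalty


def _required_paired(m: int, params: ScanParams) -> int:
    return int(math.ceil(params.min_mirna_coverage * m - 1e-9))


def _best_at_offset(q: str, R: str, s: int, params: ScanParams):
    """Optimal full-miRNA alignment starting at target offset ``s`` (0-based
    in alignment space): the first and last columns consume both sequences,
    at every prefix the target-vs-miRNA shift stays within the band, and at
    most ``band_width`` gap columns are allowed in total.

    Returns (score, n_gap_columns, ops) where ops is a string over 'A' (both
    consumed), 'B' (miRNA base vs target gap) and 'C' (miRNA gap vs target
    base), or None when no alignment fits.  Optimum under the total order
    (score desc, gaps asc, ops lexicographic asc).
    """
    m, n, band = len(q), len(R), params.band_width
    if s >= n:
        return None
    # layered DP keyed by column count; state (i, shift, gaps, last_op)
    first = _col_score(q[0], R[s], params)
    layers: dict[int, dict] = {1: {(1, 0, 0, "A"): (first, "A")}}
    finals: list[tuple[float, int, str]] = []
    for c in range(1, m + band + 1):
        layer = layers.pop(c, None)
        if not layer:
            continue
        for (i, sh, g, last), (sc, ops) in layer.items():
            if i == m:
                if last == "A":
                    finals.append((sc, g, ops))
                continue
            tpos = s + i + sh  # 0-based index of the next target base
            nxt = layers.setdefault(c + 1, {})

            def push(key, val):
                cur = nxt.get(key)
                # same state => same prefix length; higher score wins, then
                # lexicographically earlier ops
                if cur is None or (-cur[0], cur[1]) > (-val[0], val[1]):
                    nxt[key] = val

            if tpos < n:
                push((i + 1, sh, g, "A"),
                     (sc + _col_score(q[i], R[tpos], params), ops + "A"))
            if g < band:
                if abs(sh - 1) <= band:
                    cost = params.gap_extend if last == "B" else params.gap_open
                    push((i + 1, sh - 1, g + 1, "B"), (sc + cost, ops + "B"))
                if abs(sh + 1) <= band and tpos < n:
                    cost = params.gap_extend if last == "C" else params.gap_open
                    push((i, sh + 1, g + 1, "C"), (sc + cost, ops + "C"))
    if not finals:
        return None
    return min(finals, key=lambda t: (-t[0], t[1], t[2]))


def _enum_best_at_offset(q: str, R: str, s: int, params: ScanParams):
    """Brute-force counterpart of :func:`_best_at_offset`: recursively
    enumerates every operation string within the band and gap budget and
    keeps the optimum under the same total order."""
    m, n, band = len(q), len(R), params.band_width
    if s >= n:
        return None
    best: list = [None]

    def consider(score: float, g: int, ops: str) -> None:
        cand = (score, g, ops)
        cur = best[0]
        if cur is None or (-cand[0], cand[1], cand[2]) < (-cur[0], cur[1], cur[2]):
            best[0] = cand

    def rec(i: int, t: int, sh: int, g: int, last: str,
            score: float, ops: str) -> None:
        if i == m:
            if last == "A":
                consider(score, g, ops)
            return
        if t < n:
            rec(i + 1, t + 1, sh, g, "A",
                score + _col_score(q[i], R[t], params), ops + "A")
        if g < band:
            if abs(sh - 1) <= band:
                cost = params.gap_extend if last == "B" else params.gap_open
                rec(i + 1, t, sh - 1, g + 1, "B", score + cost, ops + "B")
            if abs(sh + 1) <= band and t < n:
                cost = params.gap_extend if last == "C" else params.gap_open
                rec(i, t + 1, sh + 1, g + 1, "C", score + cost, ops + "C")

    rec(1, s + 1, 0, 0, "A", _col_score(q[0], R[s], params), "A")
    return best[0]


def _prescreen(qe: np.ndarray, Re: np.ndarray, params: ScanParams,
               required: int) -> np.ndarray:
    """Vectorized upper bound on the paired-column count per start offset.

    A banded DP maximizing the number of paired (Watson-Crick or wobble)
    columns reachable with at most ``band_width`` gap columns; offsets whose
    bound falls below the coverage requirement provably cannot host a
    candidate and are pruned.  Over-approximates the exact search (no
    terminal-column constraint, gap placement unrestricted within the
    budget).
    """
    m, n, band = len(qe), len(Re), params.band_width
    P = np.zeros((4, 4), dtype=np.int16)
    np.fill_diagonal(P, 1)
    P[_CODE["G"], _CODE["A"]] = 1
    P[_CODE["U"], _CODE["C"]] = 1
    CP = P[qe[:, None], Re[None, :]]  # (m, n) paired indicator
    W = 2 * band + 1
    G = band + 1
    NEG = -1
    base = np.arange(n)
    # cur[shi, g, s]: max paired count after consuming i miRNA bases
    cur = np.full((W, G, n), NEG, dtype=np.int16)
    cur[band, 0, :] = 0
    for i in range(1, m + 1):
        nxt = np.full((W, G, n), NEG, dtype=np.int16)
        for shi in range(W):
            sh = shi - band
            t_idx = base + (i - 1) + sh
            valid = (t_idx >= 0) & (t_idx < n)
            for g in range(G):
                a = np.full(n, NEG, dtype=np.int16)
                if valid.any():
                    prev = cur[shi, g, valid]
                    a[valid] = np.where(prev >= 0,
                                        prev + CP[i - 1, t_idx[valid]], NEG)
                if shi + 1 < W and g > 0:  # B: miRNA base vs target gap
                    prev = cur[shi + 1, g - 1, :]
                    a = np.maximum(a, prev)
                nxt[shi, g] = a
        for shi in range(1, W):  # C: miRNA gap vs target base
            for g in range(1, G):
                np.maximum(nxt[shi, g], nxt[shi - 1, g - 1],
                           out=nxt[shi, g])
        cur = nxt
    ub = cur.max(axis=(0, 1))
    return np.nonzero(ub >= required)[0]


def _paired_count(q: str, R: str, s: int, ops: str) -> int:
    paired = 0
    qi, t = 0, s
    for op in ops:
        if op == "A":
            if q[qi] == R[t] or (q[qi], R[t]) in _WOBBLE_ALN:
                paired += 1
            qi += 1
            t += 1
        elif op == "B":
            qi += 1
        else:
            t += 1
    return paired


def _alignment_from_ops(
    mirna: MatureMiRNA, target_id: str, target_len: int, strand: str,
    R: str, s: int, ops: str,
) -> DuplexAlignment:
    q = mirna.sequence
    columns: list[tuple[str, str]] = []
    positions: list[Optional[int]] = []
    qi, t = 0, s
    for op in ops:
        if op == "A":
            columns.append((q[qi], _COMP[R[t]]))
            positions.append(qi + 1)
            qi += 1
            t += 1
        elif op == "B":
            columns.append((q[qi], GAP))
            positions.append(qi + 1)
            qi += 1
        else:
            columns.append((GAP, _COMP[R[t]]))
            positions.append(None)
            t += 1
    # alignment space interval [s+1, t] 1-based; map back to plus strand
    if strand == "+":
        start, end = target_len - t + 1, target_len - s
    else:
        start, end = s + 1, t
    return DuplexAlignment(
        mirna_id=mirna.id,
        target_id=target_id,
        target_start=start,
        target_end=end,
        strand=strand,
        columns=tuple(columns),
        mirna_positions=tuple(positions),
    )


def _dp_reward(aln: DuplexAlignment, params: ScanParams) -> float:
    """Reward score of an alignment under the scanner's DP objective
    (re-derived from the duplex columns)."""
    total = 0.0
    prev_op = "A"
    for mb, tb in aln.columns:
        if tb == GAP:
            op = "B"
        elif mb == GAP:
            op = "C"
        else:
            op = "A"
        if op == "A":
            pair = (mb, tb)
            if pair in _scoring.WATSON_CRICK:
                total += params.pair_reward
            elif pair in _scoring.WOBBLE_PAIRS:
                total += params.wobble_reward
            else:
                total += params.mismatch_penalty
        else:
            total += params.gap_extend if op == prev_op else params.gap_open
        prev_op = op
    return total


def _merge(
    candidates: Sequence[DuplexAlignment],
    params: ScanParams,
    scoring_params: _scoring.ScoringParams,
) -> list[DuplexAlignment]:
    """Merge overlapping candidates of the same miRNA within 3 nt on the same
    strand, keeping the one with the lowest penalty score (penalty ties go to
    the higher DP reward — gap placements that merely dodge the scoring
    windows lose to the compact duplex — then leftmost start, then fewer
    columns); cap at max_sites_per_pair keeping the best scores."""
    if not candidates:
        return []
    scored = {
        id(a): (_scoring.score_duplex(a, scoring_params).score,
                -_dp_reward(a, params))
        for a in candidates
    }
    kept: list[DuplexAlignment] = []
    for strand in ("+", "-"):
        group = sorted(
            (a for a in candidates if a.strand == strand),
            key=lambda a: (a.target_start, a.target_end),
        )
        cluster: list[DuplexAlignment] = []
        cluster_end = None
        for aln in group:
            if cluster and aln.target_start > cluster_end + 3:
                kept.append(_pick_best(cluster, scored))
                cluster = []
                cluster_end = None
            cluster.append(aln)
            cluster_end = aln.target_end if cluster_end is None else max(
                cluster_end, aln.target_end)
        if cluster:
            kept.append(_pick_best(cluster, scored))
    kept.sort(key=lambda a: (a.target_start, a.target_end, a.strand))
    if len(kept) > params.max_sites_per_pair:
        kept = sorted(kept, key=lambda a: (scored[id(a)], a.target_start,
                                           a.target_end, a.strand))
        kept = sorted(kept[:params.max_sites_per_pair],
                      key=lambda a: (a.target_start, a.target_end, a.strand))
    return kept


def _pick_best(cluster, scored):
    return min(cluster, key=lambda a: (scored[id(a)], a.target_start,
                                       len(a.columns), a.target_end))


def _strands_for(target: TargetSequence) -> tuple[str, ...]:
    return ("+", "-") if target.kind == "BAC" else ("+",)


def _scan_common(mirna, target, params, scoring_params, offset_fn, solver):
    q = mirna.sequence
    m = len(q)
    if len(target) < 20:
        log.warning("target %s shorter than 20 nt; no scan", target.id)
        return []
    if m < scoring_params.window_len:
        log.warning(
            "miRNA %s (%d nt) is shorter than the %d-nt scoring window; "
            "its sites cannot be scored — skipped",
            mirna.id, m, scoring_params.window_len,
        )
        return []
    required = _required_paired(m, params)
    rna = normalize_rna(target.sequence)
    candidates: list[DuplexAlignment] = []
    for strand in _strands_for(target):
        R = revcomp_rna(rna) if strand == "+" else rna
        for s in offset_fn(q, R):
            res = solver(q, R, int(s), params)
            if res is None:
                continue
            _, _, ops = res
            if _paired_count(q, R, int(s), ops) < required:
                continue
            candidates.append(
                _alignment_from_ops(mirna, target.id, len(target), strand,
                                    R, int(s), ops)
            )
    return _merge(candidates, params, scoring_params)


def scan(
    mirna: MatureMiRNA,
    target: TargetSequence,
    params: ScanParams | None = None,
    scoring_params: _scoring.ScoringParams | None = None,
) -> list[DuplexAlignment]:
    """Find candidate antisense duplexes of ``mirna`` in ``target``.

    Returns merged, coordinate-sorted gapped alignments (unscored; penalty
    scoring and curation are downstream).  Targets shorter than 20 nt yield
    an empty result with a warning.
    """
    params = params or ScanParams()
    scoring_params = scoring_params or _scoring.ScoringParams()

    def offsets(q: str, R: str):
        required = _required_paired(len(q), params)
        qe = np.fromiter((_CODE[c] for c in q), dtype=np.int64, count=len(q))
        Re = np.fromiter((_CODE[c] for c in R), dtype=np.int64, count=len(R))
        return _prescreen(qe, Re, params, required)

    return _scan_common(mirna, target, params, scoring_params, offsets,
                        _best_at_offset)


def scan_exhaustive(
    mirna: MatureMiRNA,
    target: TargetSequence,
    params: ScanParams | None = None,
    scoring_params: _scoring.ScoringParams | None = None,
) -> list[DuplexAlignment]:
    """Brute-force scanner: enumerates every offset and every gap placement
    within the band.  Test oracle only; guarded to targets <= 10 kb."""
    params = params or ScanParams()
    scoring_params = scoring_params or _scoring.ScoringParams()
    if len(target) > _EXHAUSTIVE_GUARD:
        raise ValueError(
            f"scan_exhaustive refuses targets longer than {_EXHAUSTIVE_GUARD} nt"
        )
    return _scan_common(mirna, target, params, scoring_params,
                        lambda q, R: range(len(R)), _enum_best_at_offset)
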