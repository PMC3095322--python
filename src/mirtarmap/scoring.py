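"""Positional mismatch-penalty scoring and curation of miRNA:target duplexes.

Each duplex column is classified as a Watson-Crick pair, a G:U wobble, a
mismatch or an indel.  Penalties are position-aware: a G:U wobble costs 0.5
anywhere (it is not treated as a mismatch), an indel 2.0, a mismatch 1.5 when
it falls in the seed region (miRNA positions 2-7 from the 5' end) and 1.0
elsewhere.  Scores are always computed over 20 consecutive miRNA positions;
for longer miRNAs every consecutive 20-nt window is evaluated and the minimum
kept.  Curation retains sites scoring strictly below the threshold (default
3.0).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .seqio import GAP

_EPS = 1e-9

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})


class PairClass(Enum):
    MATCH = "match"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"
    INDEL = "indel"


@dataclass(frozen=True)
class ScoringParams:
    """Penalty constants of the curation score.

    Defaults are the published values; ``seed_by_window_position`` switches
    the 2-7 seed test from absolute miRNA positions to window-relative ones
    (sensitivity analysis only; absolute is the default and the documented
    behaviour).
    """

    wobble_penalty: float = 0.5
    indel_penalty: float = 2.0
    mismatch_seed_penalty: float = 1.5
    mismatch_other_penalty: float = 1.0
    seed_start: int = 2
    seed_end: int = 7
    window_len: int = 20
    threshold: float = 3.0
    seed_by_window_position: bool = False

    def __post_init__(self) -> None:
        for name in ("wobble_penalty", "indel_penalty",
                     "mismatch_seed_penalty", "mismatch_other_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 1 <= self.seed_start <= self.seed_end:
            raise ValueError("seed region bounds must satisfy 1 <= start <= end")


@dataclass(frozen=True)
class SiteScore:
    """Windowed penalty score of one duplex: the minimum over all consecutive
    20-position windows, plus the full per-window breakdown."""

    score: float
    best_window_start: int
    per_window_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.score - min(self.per_window_scores)) > _EPS:
            raise ValueError("score must equal min(per_window_scores)")
        if self.score < -_EPS:
            raise ValueError("score must be >= 0")


def _norm_base(base: str) -> str:
    return "U" if base == "T" else base


def classify_column(mirna_base: str, target_base: str) -> PairClass:
    """Classify one aligned duplex column.

    Bases are given in duplex orientation: the miRNA base and the target base
    it faces, so complementary bases (A:U, G:C) are MATCHes and G:U / U:G are
    WOBBLEs.  Exactly one side may be a gap (INDEL); both sides gapped is an
    error.
    """
    if mirna_base == GAP and target_base == GAP:
        raise ValueError("column with a gap on both sides")
    if mirna_base == GAP or target_base == GAP:
        return PairClass.INDEL
    pair = (_norm_base(mirna_base.upper()), _norm_base(target_base.upper()))
    if pair in WATSON_CRICK:
        return PairClass.MATCH
    if pair in WOBBLE_PAIRS:
        return PairClass.WOBBLE
    return PairClass.MISMATCH


def column_penalty(
    pair_class: PairClass,
    mirna_position: Optional[int],
    params: ScoringParams | None = None,
) -> float:
    """Penalty of one column: MATCH 0, WOBBLE 0.5 anywhere, INDEL 2.0
    anywhere, MISMATCH 1.5 in the seed zone (positions 2-7 from the miRNA
    5' end) and 1.0 elsewhere."""
    params = params or ScoringParams()
    if pair_class is PairClass.MATCH:
        return 0.0
    if pair_class is PairClass.WOBBLE:
        return params.wobble_penalty
    if pair_class is PairClass.INDEL:
        return params.indel_penalty
    if mirna_position is None or mirna_position < 1:
        raise ValueError("mismatch column needs a 1-based miRNA position")
    if params.seed_start <= mirna_position <= params.seed_end:
        return params.mismatch_seed_penalty
    return params.mismatch_other_penalty


def score_duplex(aln, params: ScoringParams | None = None) -> SiteScore:
    """Windowed penalty score of a gapped duplex alignment.

    Windows slide over miRNA positions (an L-nt fully covered miRNA has
    L - 19 windows of 20).  A window charges every column consuming one of
    its positions, plus the miRNA-gap (insertion) columns lying between the
    first and last such column.  The seed-zone test for mismatches uses the
    absolute miRNA position unless ``seed_by_window_position`` is set.
    Alignments covering fewer than ``window_len`` miRNA positions cannot be
    scored and raise ``ValueError``.
    """
    params = params or ScoringParams()
    positions = aln.mirna_positions
    columns = aln.columns
    covered = sorted({p for p in positions if p is not None})
    if len(covered) < params.window_len:
        raise ValueError(
            f"alignment covers {len(covered)} miRNA positions; "
            f"at least {params.window_len} are required for scoring"
        )
    classes = [classify_column(mb, tb) for mb, tb in columns]
    lo, hi = covered[0], covered[-1]
    window_starts = range(lo, hi - params.window_len + 2)
    per_window: list[float] = []
    for w in window_starts:
        w_hi = w + params.window_len - 1
        idxs = [k for k, p in enumerate(positions)
                if p is not None and w <= p <= w_hi]
        total = 0.0
        for k in idxs:
            pos = positions[k]
            eff = pos - w + 1 if params.seed_by_window_position else pos
            total += column_penalty(classes[k], eff, params)
        # miRNA-gap columns between the window's flanking columns are
        # charged to the window; each gapped column costs the indel penalty
        # independently.
        for k in range(idxs[0], idxs[-1] + 1):
            if positions[k] is None:
                total += params.indel_penalty
        per_window.append(total)
    best = min(per_window)
    best_start = window_starts[per_window.index(best)]
    return SiteScore(
        score=best,
        best_window_start=best_start,
        per_window_scores=tuple(per_window),
    )


def curate(
    sites: Sequence[tuple[object, SiteScore]],
    params: ScoringParams | None = None,
) -> list[tuple[object, SiteScore]]:
    """Retain exactly the (alignment, score) pairs scoring strictly below the
    threshold; input order is preserved.  The comparison is strict: a score
    of exactly 3.0 is rejected under the default threshold."""
    params = params or ScoringParams()
    return [pair for pair in sites if pair[1].score < params.threshold - _EPS]
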