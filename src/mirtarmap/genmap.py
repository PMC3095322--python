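"""Placement of sequences onto genetic BINs of the introgression-line map,
and curation of putative precursor hits.

BACs are anchored directly through the molecular markers they carry (both
the EXPEN1992 and EXPEN2000 maps; BIN sets are unioned when the maps
disagree).  Unigenes are placed indirectly: alignments against anchored BACs
are filtered at >=90% identity and >=95% query coverage (inclusive bounds)
and the unigene inherits the BINs of every passing BAC.  Target sites with no
genic annotation can be flagged as putative precursor loci when a hit against
a known precursor passes the e-value cutoff (<= 1e-50)."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .seqio import BlastHit, MarkerRecord

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class MappingParams:
    min_identity: float = 90.0
    min_coverage: float = 95.0
    precursor_evalue_cutoff: float = 1e-50

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100 and 0 < self.min_coverage <= 100):
            raise ValueError("identity/coverage thresholds must be in (0, 100]")
        if self.precursor_evalue_cutoff <= 0:
            raise ValueError("e-value cutoff must be > 0")


@dataclass(frozen=True)
class BinAssignment:
    """Placement of one sequence onto genetic BINs.

    Evidence is a tuple of (marker name, map, bin) triples for BACs, or of
    (bac id, identity, coverage, bins) tuples for unigenes.  bin_ids is
    non-empty iff evidence is non-empty.
    """

    seq_id: str
    bin_ids: frozenset[str]
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if bool(self.bin_ids) != bool(self.evidence):
            raise ValueError(
                f"{self.seq_id}: bin_ids must be non-empty iff evidence is"
            )


def assign_bac_bins(
    bac_id: str,
    markers: Sequence[MarkerRecord],
) -> BinAssignment:
    """Union of BINs over every marker of this BAC, from both genetic maps.

    Multi-BIN BACs are allowed; a BAC with no markers is left unassigned
    (logged)."""
    own = [m for m in markers if m.seq_id == bac_id and m.bin_id]
    bins = frozenset(m.bin_id for m in own)
    if not bins:
        log.info("BAC %s carries no mapped markers; unassigned", bac_id)
        return BinAssignment(seq_id=bac_id, bin_ids=frozenset(), evidence=())
    evidence = tuple(sorted((m.name, m.map_name, m.bin_id) for m in own))
    return BinAssignment(seq_id=bac_id, bin_ids=bins, evidence=evidence)


def place_unigene(
    unigene_id: str,
    hits: Sequence[BlastHit],
    bac_bins: Mapping[str, BinAssignment],
    params: MappingParams | None = None,
) -> BinAssignment:
    """Place a unigene by its alignments against anchored BACs.

    Hits passing identity >= min_identity AND coverage >= min_coverage
    (inclusive, per the ">=" thresholds) transfer the BINs of the subject
    BAC.  Coverage is query coverage (aln_len / unigene length × 100), the
    standard reading for placing a transcript on a genome; hits without a
    computed coverage are ignored with a warning."""
    params = params or MappingParams()
    bins: set[str] = set()
    evidence = []
    for h in hits:
        if h.query != unigene_id:
            continue
        if h.coverage is None:
            log.warning(
                "placement %s→%s has no coverage (query length unknown); "
                "ignored", h.query, h.subject,
            )
            continue
        if (h.pct_identity >= params.min_identity - _EPS
                and h.coverage >= params.min_coverage - _EPS):
            assignment = bac_bins.get(h.subject)
            if assignment is None or not assignment.bin_ids:
                log.info(
                    "unigene %s aligns to unanchored BAC %s; no BIN "
                    "inherited", unigene_id, h.subject,
                )
                continue
            bins.update(assignment.bin_ids)
            evidence.append(
                (h.subject, h.pct_identity, round(h.coverage, 6),
                 tuple(sorted(assignment.bin_ids)))
            )
    return BinAssignment(
        seq_id=unigene_id,
        bin_ids=frozenset(bins),
        evidence=tuple(sorted(evidence)),
    )


def curate_precursor_hits(
    hits: Sequence[BlastHit],
    params: MappingParams | None = None,
) -> list[BlastHit]:
    """Retain precursor-search hits with e-value <= cutoff (inclusive).

    Applies only to sites whose gene annotation came back negative; the
    caller enforces that precondition."""
    params = params or MappingParams()
    cutoff = params.precursor_evalue_cutoff * (1 + _EPS)
    return [h for h in hits if h.e_value <= cutoff]
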