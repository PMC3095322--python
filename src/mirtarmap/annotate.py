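"""Label curated target sites as genic ("yes") or not ("no") by overlap with
predicted genes from the six annotation channels, and assemble the site's
hit definition text."""
from __future__ import annotations

from typing import Iterable, Sequence

from .seqio import ANNOTATION_SOURCES, GeneFeature, SiteAnnotation, TargetSite


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # 1-based inclusive intervals; >= 1 shared base
    return a_start <= b_end and b_start <= a_end


def annotate_site(
    site: TargetSite,
    features: Sequence[GeneFeature],
) -> SiteAnnotation:
    """Per-channel genic flags for one site.

    A channel flag is true iff the site interval shares at least one base
    with a feature of that channel (strand-agnostic: a miRNA site on either
    strand of a gene locus is reportable).  The hit definition concatenates
    the definitions of all overlapping features, deduplicated, in a stable
    (start, source) order.  All features must live on the site's sequence.
    """
    for f in features:
        if f.seq_id != site.target_id:
            raise ValueError(
                f"feature on {f.seq_id!r} passed for site on "
                f"{site.target_id!r}: coordinate frames differ"
            )
    overlapping = [
        f for f in features
        if _overlaps(site.start, site.end, f.start, f.end)
    ]
    channel_hits = {
        src: any(f.source == src for f in overlapping)
        for src in ANNOTATION_SOURCES
    }
    seen: set[str] = set()
    defs: list[str] = []
    for f in sorted(overlapping, key=lambda f: (f.start, f.source)):
        if f.hit_definition and f.hit_definition not in seen:
            seen.add(f.hit_definition)
            defs.append(f.hit_definition)
    return SiteAnnotation(
        site_id=site.site_id,
        channel_hits=channel_hits,
        gene_hit=any(channel_hits.values()),
        hit_definition="; ".join(defs),
    )


def annotate_sites(
    sites: Iterable[TargetSite],
    features: Sequence[GeneFeature],
) -> list[SiteAnnotation]:
    """Annotate many sites, grouping features by sequence id."""
    by_seq: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_seq.setdefault(f.seq_id, []).append(f)
    out = []
    for site in sites:
        ann = annotate_site(site, by_seq.get(site.target_id, []))
        site.annotation = ann
        out.append(ann)
    return out
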