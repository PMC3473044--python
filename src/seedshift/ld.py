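"""Join altered target sites with germline SNPs and association-study markers.

A hit requires three independent predicates on one altered site:

1. a germline SNP falls inside the seed-match site (inclusive span);
2. an association-study marker lies within a radius (default 100 kb) of the
   site on the same chromosome;
3. some LD block contains both the full site span and the marker position.

LD blocks and marker-SNP R-squared values are consumed as inputs (they come
from external haplotype tools); they are never inferred here.  Distances are
in bp between 1-based positions; a marker inside the site span has distance 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .classify import AlterationEvent
from .io import GermlineSnp, LdBlock, MarkerRecord

log = logging.getLogger(__name__)

DEFAULT_MARKER_RADIUS_BP = 100_000


def site_span_of(event: AlterationEvent) -> tuple | None:
    """Genomic span of the altered site.

    Uses whichever sequence contains the site (reference for disrupted,
    mutant for created); for modified events the union of the two spans.
    Returns None if the event carries no genomic spans (bare-sequence scan).
    """
    spans = [s for s in (event.ref_span, event.mut_span) if s is not None]
    if not spans:
        return None
    chrom = spans[0][0]
    strand = spans[0][3]
    return (chrom, min(s[1] for s in spans), max(s[2] for s in spans), strand)


def _same_chrom(a: str, b: str) -> bool:
    return a.lower() == b.lower()


def germline_in_site(events, snps) -> list[tuple[AlterationEvent, GermlineSnp]]:
    """(event, SNP) pairs where the SNP position lies inside the site span."""
    pairs = []
    for ev in events:
        span = site_span_of(ev)
        if span is None:
            continue
        chrom, start, end, _ = span
        for snp in snps:
            if _same_chrom(snp.chrom, chrom) and start <= snp.pos <= end:
                pairs.append((ev, snp))
    return pairs


def distance_to_span(pos: int, span: tuple) -> int:
    """bp distance from a position to a genomic span (0 when inside)."""
    _, start, end, _ = span
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def markers_near(span: tuple, markers,
                 radius: int = DEFAULT_MARKER_RADIUS_BP) -> list[MarkerRecord]:
    """Markers on the span's chromosome within ``radius`` bp of the span."""
    chrom = span[0]
    return [m for m in markers
            if _same_chrom(m.chrom, chrom) and distance_to_span(m.pos, span) <= radius]


def site_in_block(span: tuple, marker: MarkerRecord,
                  blocks) -> tuple[bool, LdBlock | None]:
    """Whether some LD block contains both the full site span and the marker.

    With overlapping candidate blocks the smallest containing block is
    chosen and the ambiguity logged.
    """
    chrom, start, end, _ = span
    containing = [b for b in blocks
                  if _same_chrom(b.chrom, chrom)
                  and b.start <= start and end <= b.end
                  and b.start <= marker.pos <= b.end]
    if not containing:
        return False, None
    if len(containing) > 1:
        containing.sort(key=lambda b: (len(b), b.start))
        log.warning("site %s:%d-%d and marker %s contained in %d overlapping LD "
                    "blocks; using the smallest", chrom, start, end,
                    marker.marker_id, len(containing))
    return True, min(containing, key=lambda b: (len(b), b.start))


@dataclass(frozen=True)
class IntegrationHit:
    """An altered site with a germline SNP in the site and an LD-linked marker."""

    event: AlterationEvent
    site_span: tuple
    germline: GermlineSnp
    germline_to_somatic_bp: int
    marker: MarkerRecord
    marker_distance_bp: int
    marker_in_block: bool
    block: LdBlock
    r2: float | None = None  # input-supplied; None when not available


def integrate(events, snps, markers, blocks, r2_table=None,
              radius: int = DEFAULT_MARKER_RADIUS_BP) -> list[IntegrationHit]:
    """Intersect the three membership predicates over all altered sites.

    ``r2_table`` maps (marker_id, rsid) -> R-squared; SNPs absent from the
    reference panels simply have no entry and the hit carries ``r2=None``.
    The output is sorted, so it is stable under permutation of the input
    row order.
    """
    r2_table = r2_table or {}
    hits = []
    for ev, snp in germline_in_site(events, snps):
        span = site_span_of(ev)
        for marker in markers_near(span, markers, radius=radius):
            in_block, block = site_in_block(span, marker, blocks)
            if not in_block:
                continue
            hits.append(IntegrationHit(
                event=ev, site_span=span, germline=snp,
                germline_to_somatic_bp=abs(snp.pos - ev.mutation.pos),
                marker=marker,
                marker_distance_bp=distance_to_span(marker.pos, span),
                marker_in_block=True, block=block,
                r2=r2_table.get((marker.marker_id, snp.rsid))))
    hits.sort(key=lambda h: (h.site_span[0], h.site_span[1], h.germline.rsid,
                             h.marker.marker_id, h.event.mirna_name,
                             h.event.mutation.hgvs_g))
    return hits
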