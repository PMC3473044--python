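"""Compare seed matches around a mutation and emit created / disrupted /
modified events per miRNA.

An event compares the reference and mutant sequence of one UTR:

* a site present only in the reference sequence was **disrupted**;
* a site present only in the mutant sequence was **created**;
* the same locus matching with a different maximal seed class in the two
  sequences was **modified** (e.g. a 6merB match extended into a 7merB match).

"Same locus" is decided by site-interval overlap.  Because a substitution can
shorten or extend a site by one end, the surviving site in one sequence need
not itself contain the mutated base (an m8 site whose final base is mutated
leaves an intact m7b one base shorter); candidate matches are therefore those
overlapping the mutated span plus, from the other sequence, matches that
overlap one of those.  The rule is symmetric under swapping the alleles,
which exchanges created and disrupted and reverses modified transitions.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .errors import ReferenceMismatchError, ValidationError
from .io import MirnaRecord, SomaticMutation, UtrRecord
from .mutate import SequencePair, make_pair, utrs_containing
from .seeds import SeedMatch, scan_sites

log = logging.getLogger(__name__)

EVENT_TYPES = ("created", "disrupted", "modified")

#: Rendered arrow for modified transitions, matching the m6b→m7b style.
ARROW = "→"


@dataclass(frozen=True)
class AlterationEvent:
    """A mutation x miRNA locus labelled created / disrupted / modified."""

    mutation: SomaticMutation
    gene_symbol: str
    mirna_name: str
    event_type: str
    ref_class: str | None = None
    mut_class: str | None = None
    ref_offset: int | None = None
    mut_offset: int | None = None
    ref_span: tuple | None = None
    mut_span: tuple | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.event_type == "created" and not (self.ref_class is None and self.mut_class):
            raise ValidationError("created event must have only mut_class set")
        if self.event_type == "disrupted" and not (self.ref_class and self.mut_class is None):
            raise ValidationError("disrupted event must have only ref_class set")
        if self.event_type == "modified" and not (
                self.ref_class and self.mut_class and self.ref_class != self.mut_class):
            raise ValidationError("modified event needs two distinct classes")

    @property
    def transition(self) -> str | None:
        """``m6b→m7b``-style rendering for modified events, else None."""
        if self.event_type != "modified":
            return None
        return f"{self.ref_class}{ARROW}{self.mut_class}"


def overlapping_matches(matches, span: tuple[int, int]) -> list[SeedMatch]:
    """Matches whose half-open site interval intersects ``span``."""
    lo, hi = span
    return [m for m in matches if m.utr_offset < hi and lo < m.utr_offset + m.site_length]


def _interval_overlap(a: SeedMatch, b: SeedMatch) -> int:
    lo = max(a.utr_offset, b.utr_offset)
    hi = min(a.utr_offset + a.site_length, b.utr_offset + b.site_length)
    return max(0, hi - lo)


def _pair_matches(ref_cand, mut_cand):
    """Greedy one-to-one pairing of ref/mut matches by maximal interval overlap.

    Ties resolved leftmost; the sort key is symmetric in the two roles so the
    pairing commutes with an allele swap.
    """
    pairs = []
    for r in ref_cand:
        for u in mut_cand:
            ov = _interval_overlap(r, u)
            if ov > 0:
                pairs.append((ov, r, u))
    pairs.sort(key=lambda t: (
        -t[0],
        min(t[1].utr_offset, t[2].utr_offset),
        max(t[1].utr_offset, t[2].utr_offset),
        -max(t[1].site_length, t[2].site_length)))
    used_r, used_u, chosen = set(), set(), []
    for _ov, r, u in pairs:
        if id(r) in used_r or id(u) in used_u:
            continue
        used_r.add(id(r))
        used_u.add(id(u))
        chosen.append((r, u))
    return chosen


def classify(pair: SequencePair, mirna: MirnaRecord, scan=scan_sites) -> list[AlterationEvent]:
    """Classify one mutation against one miRNA.

    ``scan`` is injectable so the same pairing semantics can be driven by an
    independent scanner (used when planting synthetic truth labels).
    """
    utr = pair.utr
    ref_matches = scan(pair.ref_seq, [mirna], utr=utr)
    mut_matches = scan(pair.mut_seq, [mirna], utr=utr)
    span = pair.affected_span
    ref_hit = overlapping_matches(ref_matches, span)
    mut_hit = overlapping_matches(mut_matches, span)
    # Pull in matches from the other sequence that overlap a span-overlapping
    # match: a one-base extension/truncation keeps the partner site outside
    # the span but it is still the same locus.
    ref_ids = {id(m) for m in ref_hit}
    mut_ids = {id(m) for m in mut_hit}
    ref_cand = ref_hit + [m for m in ref_matches if id(m) not in ref_ids
                          and any(_interval_overlap(m, x) for x in mut_hit)]
    mut_cand = mut_hit + [m for m in mut_matches if id(m) not in mut_ids
                          and any(_interval_overlap(m, x) for x in ref_hit)]

    events: list[AlterationEvent] = []

    def _event(event_type, r: SeedMatch | None, u: SeedMatch | None):
        return AlterationEvent(
            mutation=pair.mutation, gene_symbol=utr.gene_symbol,
            mirna_name=mirna.name, event_type=event_type,
            ref_class=r.seed_class if r else None,
            mut_class=u.seed_class if u else None,
            ref_offset=r.utr_offset if r else None,
            mut_offset=u.utr_offset if u else None,
            ref_span=r.genomic_span if r else None,
            mut_span=u.genomic_span if u else None)

    paired = _pair_matches(ref_cand, mut_cand)
    paired_r = {id(r) for r, _ in paired}
    paired_u = {id(u) for _, u in paired}
    for r, u in paired:
        if r.seed_class != u.seed_class:
            events.append(_event("modified", r, u))
        # identical class (same or shifted anchor): the site survives -> no event
    for r in ref_hit:
        if id(r) not in paired_r:
            events.append(_event("disrupted", r, None))
    for u in mut_hit:
        if id(u) not in paired_u:
            events.append(_event("created", None, u))
    events.sort(key=lambda e: (e.ref_offset if e.ref_offset is not None else e.mut_offset,
                               e.event_type))
    return events


@dataclass
class ClassificationResult:
    """Events plus per-mutation bookkeeping from a full classification run."""

    events: list[AlterationEvent]
    altered_any: dict[tuple, bool]
    skipped: list[tuple[SomaticMutation, str]] = field(default_factory=list)

    @property
    def n_mutations(self) -> int:
        return len(self.altered_any)

    @property
    def n_altered_any(self) -> int:
        return sum(self.altered_any.values())

    def counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in EVENT_TYPES}
        for ev in self.events:
            out[ev.event_type] += 1
        return out


def classify_all(mutations, utrs, mirnas, scan=scan_sites) -> ClassificationResult:
    """Classify every (mutation, containing UTR, miRNA) triple.

    Indels are excluded (substitution analysis only).  A mutation contained
    in several transcripts is processed once per distinct (gene, UTR
    sequence) to avoid double-counting identical isoforms.  A reference
    mismatch against the stored UTR sequence is reported and skipped; the
    run continues.
    """
    by_chrom: dict[str, list[UtrRecord]] = defaultdict(list)
    for u in utrs:
        by_chrom[u.chrom.lower()].append(u)

    events: list[AlterationEvent] = []
    altered: dict[tuple, bool] = {}
    skipped: list[tuple[SomaticMutation, str]] = []
    for mut in mutations:
        altered.setdefault(mut.key, False)
        if mut.is_indel:
            skipped.append((mut, "indel"))
            continue
        seen: set[tuple[str, str]] = set()
        for utr in utrs_containing(mut, by_chrom.get(mut.chrom.lower(), ())):
            dedupe_key = (utr.gene_symbol, utr.sequence)
            if dedupe_key in seen:
                continue
            seen.add(dedupe_key)
            try:
                pair = make_pair(mut, utr)
            except ReferenceMismatchError as exc:
                log.warning("skipping %s in %s: %s", mut.hgvs_g, utr.transcript_id, exc)
                skipped.append((mut, str(exc)))
                continue
            for mirna in mirnas:
                evs = classify(pair, mirna, scan=scan)
                if evs:
                    events.extend(evs)
                    altered[mut.key] = True
    return ClassificationResult(events=events, altered_any=altered, skipped=skipped)
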