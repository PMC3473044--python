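"""Reference brute-force seed-match scanner.

A deliberately naive implementation of the scanning semantics, written
independently of :mod:`seedshift.seeds`: it enumerates every occurrence of
all six class motifs at all offsets by explicit character comparison, picks
the highest-priority class per anchor, and suppresses interval-contained
matches.  It exists to validate the production scanner (equivalence is
asserted over seeded random trials) and to verify planted truth labels in
the synthetic-data generator.
"""
from __future__ import annotations

from .seeds import CLASS_PRIORITY, SeedMatch, genomic_span, site_motif

_PRIORITY_INDEX = {label: i for i, label in enumerate(CLASS_PRIORITY)}


def _occurs_at(sequence: str, motif: str, offset: int) -> bool:
    if offset + len(motif) > len(sequence):
        return False
    for i, ch in enumerate(motif):
        if sequence[offset + i] != ch:
            return False
    return True


def bruteforce_scan(sequence: str, mirnas, utr=None) -> list[SeedMatch]:
    """All maximal seed matches, by exhaustive motif x offset enumeration."""
    out: list[SeedMatch] = []
    for mirna in mirnas:
        motifs = [(label, site_motif(mirna.mature_sequence, label))
                  for label in CLASS_PRIORITY]
        # every (offset -> matching labels)
        by_offset: dict[int, list[str]] = {}
        for label, motif in motifs:
            for off in range(len(sequence)):
                if _occurs_at(sequence, motif, off):
                    by_offset.setdefault(off, []).append(label)
        # maximal class per anchor
        anchored: list[tuple[int, int]] = []  # (offset, end) with label
        chosen: dict[int, str] = {}
        for off, labels in by_offset.items():
            best = min(labels, key=_PRIORITY_INDEX.get)
            chosen[off] = best
            anchored.append((off, off + len(dict(motifs)[best])))
        # drop intervals contained in another anchor's interval
        for off in sorted(chosen):
            label = chosen[off]
            length = len(dict(motifs)[label])
            lo, hi = off, off + length
            if any((o2, e2) != (lo, hi) and o2 <= lo and hi <= e2
                   for (o2, e2) in anchored):
                continue
            out.append(SeedMatch(
                mirna_name=mirna.name, seed_class=label, utr_offset=off,
                site_length=length,
                genomic_span=genomic_span(utr, off, length) if utr is not None else None))
    return out
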