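"""Seed classes, target-site motifs, and the seed-match scanner.

A target site is a stretch of 3'UTR with perfect Watson-Crick complementarity
to a block of 5' bases of a mature miRNA.  Six seed classes are recognised,
named by which miRNA bases (1-based, from the 5' end) must be complemented:

    m8  : bases 1-8     m7a : bases 1-7     m7b : bases 2-8
    m6a : bases 1-6     m6b : bases 2-7     m6c : bases 3-8

The site motif of a class is the reverse complement of that miRNA block,
written 5'->3' in the DNA alphabet, so scanning is plain substring matching.
Wobble (G:U) pairs, 3'-compensatory pairing, and site accessibility are out
of scope: only exact complementarity counts.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .io import MirnaRecord, UtrRecord

#: miRNA base ranges per class, 1-based inclusive.
SEED_CLASS_RANGES: dict[str, tuple[int, int]] = {
    "m8": (1, 8), "m7a": (1, 7), "m7b": (2, 8),
    "m6a": (1, 6), "m6b": (2, 7), "m6c": (3, 8),
}

#: Priority for the maximal class at one anchor: longest first; within equal
#: length, classes anchored on miRNA bases 2-8 (the seed proper) first.
CLASS_PRIORITY: tuple[str, ...] = ("m8", "m7b", "m7a", "m6b", "m6a", "m6c")

#: Site length per class (length of the complemented miRNA block).
CLASS_LENGTH = {label: hi - lo + 1 for label, (lo, hi) in SEED_CLASS_RANGES.items()}

_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")


@dataclass(frozen=True)
class SeedMatch:
    """One (miRNA, seed class, position) seed-match occurrence in a UTR.

    ``utr_offset`` is 0-based and marks the 5'-most UTR base of the site
    motif on the transcript strand.  ``genomic_span`` is
    ``(chrom, start, end, strand)`` with 1-based inclusive coordinates, or
    None when the scan was done on a bare sequence.
    """

    mirna_name: str
    seed_class: str
    utr_offset: int
    site_length: int
    genomic_span: tuple | None = None

    @property
    def interval(self) -> tuple[int, int]:
        """Half-open [offset, offset + length) interval in UTR coordinates."""
        return (self.utr_offset, self.utr_offset + self.site_length)


def site_motif(mature_sequence: str, seed_class: str) -> str:
    """DNA motif whose presence in a UTR is a perfect match for ``seed_class``.

    Returns the reverse complement of the class's miRNA base block, 5'->3' in
    DNA (U<->A, G<->C).  For let-7a (UGAGGUAGUAGGUUGUAUAGUU) the m8 motif is
    ``CTACCTCA``.
    """
    if seed_class not in SEED_CLASS_RANGES:
        raise ValidationError(f"unknown seed class {seed_class!r}")
    seq = mature_sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValidationError("mature miRNA sequence shorter than 8 nt")
    lo, hi = SEED_CLASS_RANGES[seed_class]
    block = seq[lo - 1:hi]
    return block.translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


def motif_table(mirna: MirnaRecord) -> dict[str, str]:
    """All six class motifs for one miRNA, in priority order."""
    return {c: site_motif(mirna.mature_sequence, c) for c in CLASS_PRIORITY}


def maximal_class_at(sequence: str, offset: int, mirna: MirnaRecord,
                     motifs: dict[str, str] | None = None) -> str | None:
    """Highest-priority seed class whose motif starts at ``offset``, or None.

    N and lower-case (masked) bases never match because comparison is exact
    against the upper-case ACGT motif.
    """
    if not 0 <= offset < len(sequence):
        raise ValidationError(f"offset {offset} outside sequence of length {len(sequence)}")
    if motifs is None:
        motifs = motif_table(mirna)
    for label in CLASS_PRIORITY:
        m = motifs[label]
        if offset + len(m) <= len(sequence) and sequence.startswith(m, offset):
            return label
    return None


def genomic_span(utr: UtrRecord, offset: int, length: int) -> tuple:
    """Genomic (chrom, start, end, strand) of a site at a UTR offset.

    On the minus strand the transcript-strand offset counts down from the
    genomic end of the interval.
    """
    if utr.strand == "+":
        start = utr.start + offset
        return (utr.chrom, start, start + length - 1, "+")
    end = utr.end - offset
    return (utr.chrom, end - length + 1, end, "-")


def scan_sites(sequence: str, mirnas, utr: UtrRecord | None = None) -> list[SeedMatch]:
    """Scan a transcript-strand sequence for maximal seed matches.

    For each miRNA, every anchor offset reports at most the single maximal
    (longest, then priority-ordered) class whose motif occurs there; matches
    whose site interval is contained within another reported match of the
    same miRNA are then suppressed, so an m8 site is reported once rather
    than together with its nested 7mer/6mer sub-matches.  Overlapping but
    non-nested matches at different offsets are all reported.

    Output order is deterministic: miRNAs in input order, then ascending
    offset.
    """
    out: list[SeedMatch] = []
    n = len(sequence)
    for mirna in mirnas:
        motifs = motif_table(mirna)
        candidates: list[tuple[int, str, int]] = []  # (offset, label, length)
        for off in range(n):
            for label in CLASS_PRIORITY:
                m = motifs[label]
                if off + len(m) <= n and sequence.startswith(m, off):
                    candidates.append((off, label, len(m)))
                    break
        kept = []
        for i, (o1, lab1, l1) in enumerate(candidates):
            contained = any(
                j != i and o2 <= o1 and o1 + l1 <= o2 + l2
                for j, (o2, _lab2, l2) in enumerate(candidates))
            if not contained:
                kept.append((o1, lab1, l1))
        for off, label, length in kept:
            out.append(SeedMatch(
                mirna_name=mirna.name, seed_class=label, utr_offset=off,
                site_length=length,
                genomic_span=genomic_span(utr, off, length) if utr is not None else None))
    return out
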