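"""Map genomic mutations into UTR coordinates and build ref/mut sequence pairs.

All genomic coordinates are 1-based inclusive; UTR offsets are 0-based on the
transcript strand.  For minus-strand UTRs the mapping reflects the coordinate
(offset counts from the genomic end) and reverse-complements the alleles, so
downstream scanning always sees the mRNA 5'->3'.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ReferenceMismatchError, ValidationError
from .io import SomaticMutation, UtrRecord, revcomp_dna


@dataclass(frozen=True)
class SequencePair:
    """Reference and mutant UTR sequence for one mutation.

    ``affected_span`` is the 0-based half-open interval of changed bases in
    UTR (transcript-strand) coordinates.
    """

    utr: UtrRecord
    mutation: SomaticMutation
    ref_seq: str
    mut_seq: str
    affected_span: tuple[int, int]

    def __post_init__(self):
        if self.ref_seq != self.utr.sequence:
            raise ValidationError("ref_seq must equal the UTR sequence")
        lo, hi = self.affected_span
        if not (0 <= lo < hi <= len(self.ref_seq)):
            raise ValidationError(f"affected_span {self.affected_span} out of bounds")
        if len(self.ref_seq) != len(self.mut_seq):
            raise ValidationError("substitution pair must preserve length")
        if self.ref_seq[:lo] != self.mut_seq[:lo] or self.ref_seq[hi:] != self.mut_seq[hi:]:
            raise ValidationError("sequences differ outside the affected span")
        if self.ref_seq[lo:hi] == self.mut_seq[lo:hi]:
            raise ValidationError("sequences identical on the affected span")


def utrs_containing(mutation: SomaticMutation, utrs) -> list[UtrRecord]:
    """UTRs on the mutation's chromosome containing every mutated base.

    Containment (not mere overlap) is required: a multi-base substitution
    hanging off the end of a UTR is not "in" that UTR.
    """
    chrom = mutation.chrom.lower()
    return [u for u in utrs
            if u.chrom.lower() == chrom
            and u.start <= mutation.pos and mutation.end <= u.end]


def map_to_utr(mutation: SomaticMutation, utr: UtrRecord) -> tuple[int, str, str]:
    """Transcript-strand (offset, ref, alt) of a mutation inside a UTR.

    Plus strand: offset = pos - utr.start, alleles unchanged.  Minus strand:
    the offset is reflected from the genomic end and both alleles are
    reverse-complemented.  A disagreement between the mapped reference allele
    and the stored UTR sequence is a hard error naming the transcript.
    """
    if not (utr.start <= mutation.pos and mutation.end <= utr.end):
        raise ValidationError(
            f"mutation {mutation.hgvs_g} not contained in {utr.transcript_id}")
    if mutation.is_indel:
        raise ValidationError(
            f"mutation {mutation.hgvs_g} is length-changing; only substitutions "
            f"can be mapped onto a fixed-length UTR sequence")
    if utr.strand == "+":
        offset = mutation.pos - utr.start
        ref_t, alt_t = mutation.ref_allele, mutation.alt_allele
    else:
        offset = utr.end - mutation.end
        ref_t = revcomp_dna(mutation.ref_allele)
        alt_t = revcomp_dna(mutation.alt_allele)
    found = utr.sequence[offset:offset + len(ref_t)]
    if found != ref_t:
        raise ReferenceMismatchError(
            f"{utr.transcript_id} at {mutation.chrom}:{mutation.pos}: expected "
            f"reference allele {ref_t!r} on transcript strand, found {found!r}")
    return offset, ref_t, alt_t


def make_pair(mutation: SomaticMutation, utr: UtrRecord) -> SequencePair:
    """Build the reference/mutant sequence pair for one mutation in one UTR."""
    offset, ref_t, alt_t = map_to_utr(mutation, utr)
    ref_seq = utr.sequence
    mut_seq = ref_seq[:offset] + alt_t + ref_seq[offset + len(ref_t):]
    return SequencePair(utr=utr, mutation=mutation, ref_seq=ref_seq,
                        mut_seq=mut_seq,
                        affected_span=(offset, offset + len(ref_t)))
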