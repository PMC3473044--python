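"""Descriptive statistics of somatic mutations in 3'UTRs.

Covers the collapsed six-class substitution spectrum, the rolling-window
positional distribution along the UTR, removal of mutations shared between
genes with different UTRs, and site-level recurrence across samples.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ValidationError
from .io import SomaticMutation, UtrRecord
from .mutate import map_to_utr, utrs_containing

#: The six collapsed substitution classes: a substitution and its
#: reverse-complement partner count as one class.
SUBSTITUTION_CLASSES = ("G>A/C>T", "G>T/C>A", "G>C/C>G",
                        "A>G/T>C", "A>T/T>A", "A>C/T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def round_half_up(value, ndigits: int = 2) -> float:
    """Round with ties away from zero (how the source tables print percents)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def substitution_class(ref: str, alt: str) -> str:
    """Collapsed class of a single-base substitution.

    Purine/pyrimidine complement pairs collapse: (C,T) and (G,A) are both
    ``G>A/C>T``.  Multi-base input is an error; callers must pre-filter to
    single-base substitutions.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMP or alt not in _COMP:
        raise ValidationError(f"substitution_class needs single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError("ref and alt are identical")
    if ref in "CT":  # canonicalise onto the purine-reference representative
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}/{_COMP[ref]}>{_COMP[alt]}"


@dataclass
class SubstitutionSpectrum:
    """Counts and percentage frequencies over the six collapsed classes."""

    counts: dict[str, int]
    total: int
    n_excluded: int = 0  # indels / multi-base events not counted

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def frequencies(self) -> dict[str, float]:
        """Percentages summing to 100 (all zero, flagged ``empty``, if no data)."""
        if self.empty:
            return {c: 0.0 for c in SUBSTITUTION_CLASSES}
        return {c: 100.0 * self.counts[c] / self.total for c in SUBSTITUTION_CLASSES}


def spectrum(mutations) -> SubstitutionSpectrum:
    """Substitution spectrum of the single-base substitutions in a mutation set.

    Indels and multi-nucleotide substitutions are excluded and counted
    separately in ``n_excluded``.
    """
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    total = 0
    excluded = 0
    for m in mutations:
        if not m.is_snv:
            excluded += 1
            continue
        counts[substitution_class(m.ref_allele, m.alt_allele)] += 1
        total += 1
    return SubstitutionSpectrum(counts=counts, total=total, n_excluded=excluded)


def spectrum_by_type(mutations) -> dict[str, SubstitutionSpectrum]:
    """Per-cancer-type spectra (for side-by-side comparison of mutation sets)."""
    groups: dict[str, list[SomaticMutation]] = defaultdict(list)
    for m in mutations:
        groups[m.cancer_type].append(m)
    return {ct: spectrum(ms) for ct, ms in sorted(groups.items())}


def relative_position(mutation: SomaticMutation, utr: UtrRecord) -> float:
    """Fractional distance of a mutation from the 5' end of the 3'UTR.

    The 5' end of the 3'UTR is the base following the final coding exon, so
    the measure is strand-aware: on the minus strand the highest genomic
    coordinate is position 0.  Returns offset / UTR length in [0, 1).
    """
    if len(utr) == 0:
        raise ValidationError(f"{utr.transcript_id}: zero-length UTR")
    offset, _, _ = map_to_utr(mutation, utr)
    return offset / len(utr)


def dedupe_multi_utr(mutations, utrs) -> list[SomaticMutation]:
    """Drop mutations located in UTRs of two or more genes with different UTRs.

    A mutation shared by several transcripts of one gene, or by genes whose
    UTR sequences are identical, is kept; only genuinely ambiguous positions
    (distinct genes, distinct UTR sequences) are removed.  Used for the
    positional analysis only.
    """
    kept = []
    for m in mutations:
        containing = utrs_containing(m, utrs)
        genes = {u.gene_symbol for u in containing}
        sequences = {u.sequence for u in containing}
        if len(genes) >= 2 and len(sequences) >= 2:
            continue
        kept.append(m)
    return kept


@dataclass
class PositionalDistribution:
    """Rolling-window counts of relative mutation positions along the UTR."""

    window_width: float
    step: float
    centers: list[float] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)


def rolling_counts(positions, width: float = 0.05, step: float = 0.01) -> PositionalDistribution:
    """Count relative positions in rolling windows along [0, 1].

    Window i covers ``[center - width/2, center + width/2)``, clipped to
    [0, 1]; a window whose upper edge is exactly 1 includes 1.  With
    ``step == width`` this degenerates to a plain histogram.
    """
    if width <= 0:
        raise ValidationError(f"window width must be positive, got {width}")
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    positions = list(positions)
    for p in positions:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"relative position {p} outside [0, 1]")
    centers = [round(c, 10) for c in
               np.arange(width / 2, 1 - width / 2 + 1e-12, step)]
    counts = []
    for c in centers:
        lo = max(0.0, c - width / 2)
        hi = min(1.0, c + width / 2)
        if hi >= 1.0:
            n = sum(lo <= p <= 1.0 for p in positions)
        else:
            n = sum(lo <= p < hi for p in positions)
        counts.append(n)
    return PositionalDistribution(window_width=width, step=step,
                                  centers=centers, counts=counts)


@dataclass
class RecurrenceStats:
    """Site-level recurrence of mutations across samples."""

    n_recurrent: int
    n_total: int
    percent: float | None  # None when no sites (undefined)


def recurrence_stats(mutations) -> RecurrenceStats:
    """Fraction of mutation sites observed in two or more distinct samples.

    A site is the exact (chrom, pos, ref, alt) tuple; the percentage is
    rounded half-up to two decimals (1 of 152 prints as 0.66%).
    """
    samples_by_site: dict[tuple, set[str]] = defaultdict(set)
    for m in mutations:
        samples_by_site[m.key].add(m.sample_id)
    n_total = len(samples_by_site)
    n_recurrent = sum(len(s) >= 2 for s in samples_by_site.values())
    if n_total == 0:
        return RecurrenceStats(0, 0, None)
    # exact rational before rounding, so 1/152 prints 0.66 and not 0.65
    percent = round_half_up(Decimal(100 * n_recurrent) / Decimal(n_total), 2)
    return RecurrenceStats(n_recurrent, n_total, percent)
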