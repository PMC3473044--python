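"""Readers, writers, and domain record types for every external format.

All tables are tab-separated with a mandatory header row; lines starting with
``#`` are treated as comments (outputs use them to carry run metadata).
Genomic coordinates are 1-based inclusive on the plus strand, matching the
HGVS ``g.`` convention used for mutation tokens such as ``Chr4:g.96075969G>T``.
UTR sequences are stored on the transcript strand (5'->3' of the mRNA) and are
never reverse-complemented silently by a reader.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

#: Recognised cancer-type labels; anything else is stored as "other".
CANCER_TYPES = ("lung", "SCLC", "melanoma", "prostate", "other")

_CANCER_LOOKUP = {"lung": "lung", "sclc": "SCLC", "melanoma": "melanoma",
                  "prostate": "prostate", "other": "other"}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def normalize_chrom(chrom: str) -> str:
    """Normalise chromosome naming to lower-case with a ``chr`` prefix.

    The source tables mix styles ("Chr4", "chr4", "4"); internal comparisons
    are all done on this canonical form.
    """
    s = str(chrom).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise ParseError(f"empty chromosome name in {chrom!r}")
    return "chr" + s.lower()


def normalize_cancer_type(value: str) -> str:
    """Map a free-text cancer type onto the recognised vocabulary.

    Unknown labels are stored as ``other`` with a warning, so a pipeline run
    never aborts on an unexpected study name.
    """
    key = str(value).strip().lower()
    if key in _CANCER_LOOKUP:
        return _CANCER_LOOKUP[key]
    log.warning("unknown cancer_type %r stored as 'other'", value)
    return "other"


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaticMutation:
    """A genomic substitution (possibly multi-nucleotide), plus-strand alleles.

    ``pos`` is the 1-based genomic coordinate of the first changed base.
    Length-changing variants are representable but flagged via :attr:`is_indel`
    and excluded from substitution analyses by the callers that require equal
    allele lengths.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    cancer_type: str = "other"
    sample_id: str = ""

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValidationError(f"empty allele in mutation at {self.chrom}:{self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"reference and alternate alleles are identical "
                f"({self.chrom}:g.{self.pos}{self.ref_allele}>{self.alt_allele})")
        if self.pos < 1:
            raise ValidationError(f"genomic position must be >= 1, got {self.pos}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def end(self) -> int:
        """1-based inclusive genomic coordinate of the last reference base."""
        return self.pos + len(self.ref_allele) - 1

    @property
    def key(self) -> tuple:
        """Site identity used for recurrence and score joins."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def hgvs_g(self) -> str:
        return format_hgvs_g(self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class UtrRecord:
    """One gene's 3'UTR: genomic interval plus transcript-strand sequence."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise ValidationError(f"{self.transcript_id}: end ({self.end}) < start ({self.start})")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} does not match "
                f"interval length {self.end - self.start + 1}")
        if set(self.sequence) - set("ACGTN"):
            raise ValidationError(
                f"{self.transcript_id}: sequence contains characters outside ACGTN")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA, 5'->3' in the RNA alphabet."""

    name: str
    mature_sequence: str

    def __post_init__(self):
        if len(self.mature_sequence) < 8:
            raise ValidationError(f"{self.name}: mature sequence shorter than 8 nt")
        if set(self.mature_sequence) - set("ACGU"):
            raise ValidationError(f"{self.name}: sequence contains characters outside ACGU")


@dataclass(frozen=True)
class MarkerRecord:
    """An association-study marker (rsID, position, phenotype, p-value)."""

    marker_id: str
    chrom: str
    pos: int
    phenotype: str = ""
    p_value: float = 1.0
    source: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"{self.marker_id}: pos must be >= 1")
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"{self.marker_id}: p_value must be in (0, 1]")


@dataclass(frozen=True)
class LdBlock:
    """A linkage-disequilibrium block interval (externally inferred)."""

    chrom: str
    start: int
    end: int
    population: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"LD block end ({self.end}) < start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GermlineSnp:
    """A germline variant (dbSNP-style) used for seed-match co-occurrence."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos must be >= 1")


# ---------------------------------------------------------------------------
# HGVS-style genomic substitution tokens
# ---------------------------------------------------------------------------

_HGVS_RE = re.compile(
    r"^\s*(?P<chrom>[A-Za-z0-9_.]+):g\.(?P<pos>\d+)"
    r"(?P<ref>[ACGTNacgtn]+)>(?P<alt>[ACGTNacgtn]+)\s*$")


def parse_hgvs_g(token: str) -> tuple[str, int, str, str]:
    """Parse ``<chrom>:g.<pos><REF>><ALT>`` into (chrom, pos, ref, alt).

    The chromosome is normalised (``Chr4`` -> ``chr4``), the position is an
    integer, and alleles are upper-cased.  ``REF == ALT`` is a validation
    error; anything that does not match the grammar is a parse error naming
    the token.
    """
    m = _HGVS_RE.match(token)
    if not m:
        raise ParseError(f"malformed HGVS g. token: {token!r}")
    ref = m.group("ref").upper()
    alt = m.group("alt").upper()
    if ref == alt:
        raise ValidationError(f"REF equals ALT in HGVS token: {token!r}")
    return normalize_chrom(m.group("chrom")), int(m.group("pos")), ref, alt


def format_hgvs_g(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Render a substitution in the ``chr4:g.96075969G>T`` style."""
    return f"{normalize_chrom(chrom)}:g.{pos}{ref}>{alt}"


# ---------------------------------------------------------------------------
# Table / FASTA readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                           keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_utr_table(path, fasta_path=None) -> list[UtrRecord]:
    """Read a 3'UTR annotation table.

    Required columns: ``gene, transcript, chrom, start, end, strand`` and
    either a ``sequence`` column or a companion FASTA keyed by transcript id.
    Duplicate transcript ids are rejected; every record must satisfy the
    :class:`UtrRecord` invariants (notably interval length == sequence length).
    """
    df = _read_tsv(path)
    if df.empty and not len(df.columns):
        return []
    _require_columns(df, ["gene", "transcript", "chrom", "start", "end", "strand"], path)
    seqs: Mapping[str, str] | None = None
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    elif "sequence" not in df.columns:
        raise ParseError(f"{path}: no 'sequence' column and no companion FASTA given")

    records: list[UtrRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        tx = row.transcript
        if tx in seen:
            raise ValidationError(f"{path}: duplicate transcript id {tx!r}")
        seen.add(tx)
        if seqs is not None:
            if tx not in seqs:
                raise ValidationError(f"{path}: transcript {tx!r} missing from FASTA")
            seq = seqs[tx]
        else:
            seq = row.sequence.upper()
        records.append(UtrRecord(
            gene_symbol=row.gene, transcript_id=tx,
            chrom=normalize_chrom(row.chrom), start=int(row.start),
            end=int(row.end), strand=row.strand, sequence=seq))
    return records


def read_mutation_table(path) -> list[SomaticMutation]:
    """Read a somatic-mutation table.

    Accepts either an ``hgvs_g`` column or explicit ``chrom/pos/ref/alt``
    columns, plus ``cancer_type`` and ``sample_id``.  Length-changing rows are
    kept but carry :attr:`SomaticMutation.is_indel`; substitution analyses
    filter on that flag.
    """
    df = _read_tsv(path)
    if df.empty:
        return []
    if "hgvs_g" in df.columns:
        parsed = [parse_hgvs_g(t) for t in df["hgvs_g"]]
    else:
        _require_columns(df, ["chrom", "pos", "ref", "alt"], path)
        parsed = [(normalize_chrom(r.chrom), int(r.pos), r.ref.upper(), r.alt.upper())
                  for r in df.itertuples(index=False)]
    cancers = df["cancer_type"] if "cancer_type" in df.columns else ["other"] * len(df)
    samples = df["sample_id"] if "sample_id" in df.columns else [""] * len(df)
    out = []
    for (chrom, pos, ref, alt), cancer, sample in zip(parsed, cancers, samples):
        out.append(SomaticMutation(chrom, pos, ref, alt,
                                   normalize_cancer_type(cancer), str(sample)))
    n_indels = sum(m.is_indel for m in out)
    if n_indels:
        log.warning("%s: %d length-changing variant(s) flagged as indels; "
                    "they are excluded from substitution analyses", path, n_indels)
    return out


def read_mirna_fasta(path) -> list[MirnaRecord]:
    """Read mature miRNA sequences from FASTA.

    DNA-alphabet entries are converted to RNA (T -> U).  Entries shorter than
    8 nt cannot carry a full seed and are skipped with a warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if len(seq) < 8:
            log.warning("%s: miRNA %s shorter than 8 nt, skipped", path, rec.id)
            continue
        records.append(MirnaRecord(name=rec.id, mature_sequence=seq))
    return records


def read_marker_table(path) -> list[MarkerRecord]:
    """Association-study markers: ``marker_id, chrom, pos, phenotype, p_value[, source]``."""
    df = _read_tsv(path)
    if df.empty:
        return []
    _require_columns(df, ["marker_id", "chrom", "pos"], path)
    out = []
    for row in df.itertuples(index=False):
        out.append(MarkerRecord(
            marker_id=row.marker_id, chrom=normalize_chrom(row.chrom),
            pos=int(row.pos),
            phenotype=getattr(row, "phenotype", ""),
            p_value=float(getattr(row, "p_value", 1.0) or 1.0),
            source=getattr(row, "source", "")))
    return out


def read_block_table(path) -> list[LdBlock]:
    """LD blocks: ``chrom, start, end[, population]``.

    Rows with ``end < start`` (a malformed boundary) are rejected with a
    warning rather than silently reinterpreted.
    """
    df = _read_tsv(path)
    if df.empty:
        return []
    _require_columns(df, ["chrom", "start", "end"], path)
    out = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            log.warning("%s: rejecting LD block with end < start: %s:%d-%d",
                        path, row.chrom, start, end)
            continue
        out.append(LdBlock(chrom=normalize_chrom(row.chrom), start=start, end=end,
                           population=getattr(row, "population", "")))
    return out


def read_snp_table(path) -> list[GermlineSnp]:
    """Germline SNPs: ``rsid, chrom, pos[, ref, alt]``."""
    df = _read_tsv(path)
    if df.empty:
        return []
    _require_columns(df, ["rsid", "chrom", "pos"], path)
    return [GermlineSnp(rsid=row.rsid, chrom=normalize_chrom(row.chrom),
                        pos=int(row.pos),
                        ref_allele=getattr(row, "ref", ""),
                        alt_allele=getattr(row, "alt", ""))
            for row in df.itertuples(index=False)]


def read_expression_table(path) -> dict[str, int]:
    """Mature-miRNA read counts: ``mirna, reads`` -> dict keyed by miRNA name."""
    df = _read_tsv(path)
    if df.empty:
        return {}
    _require_columns(df, ["mirna", "reads"], path)
    return {row.mirna: int(row.reads) for row in df.itertuples(index=False)}


def read_score_table(path) -> dict[tuple, float]:
    """Precomputed context+ score deltas keyed by (mutation key, miRNA name).

    Columns: ``hgvs_g, mirna`` plus either a ``delta`` column or
    ``ref_score``/``mut_score`` (delta = mut - ref).  Duplicate keys are an
    error: the join in the prioritization cascade must be unambiguous.
    """
    df = _read_tsv(path)
    if df.empty:
        return {}
    _require_columns(df, ["hgvs_g", "mirna"], path)
    has_delta = "delta" in df.columns
    if not has_delta:
        _require_columns(df, ["ref_score", "mut_score"], path)
    out: dict[tuple, float] = {}
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt = parse_hgvs_g(row.hgvs_g)
        key = ((chrom, pos, ref, alt), row.mirna)
        if key in out:
            raise ValidationError(f"{path}: duplicate score row for {row.hgvs_g} x {row.mirna}")
        delta = float(row.delta) if has_delta else float(row.mut_score) - float(row.ref_score)
        out[key] = delta
    return out


def read_gene_annotation_table(path) -> dict[str, str]:
    """Cancer-gene list: ``gene[, direction]`` with direction in
    {overexpressed, underexpressed, unknown}."""
    df = _read_tsv(path)
    if df.empty:
        return {}
    _require_columns(df, ["gene"], path)
    valid = {"overexpressed", "underexpressed", "unknown"}
    out = {}
    for row in df.itertuples(index=False):
        direction = getattr(row, "direction", "unknown") or "unknown"
        if direction not in valid:
            raise ValidationError(f"{path}: unknown direction {direction!r} for {row.gene}")
        out[row.gene] = direction
    return out


def read_mirna_annotation_table(path) -> set[str]:
    """Cancer-associated miRNA list: single ``mirna`` column -> set of names."""
    df = _read_tsv(path)
    if df.empty:
        return set()
    _require_columns(df, ["mirna"], path)
    return set(df["mirna"])


def read_r2_table(path) -> dict[tuple[str, str], float]:
    """Marker-to-SNP LD correlations: ``marker_id, rsid, r2`` (input-supplied)."""
    df = _read_tsv(path)
    if df.empty:
        return {}
    _require_columns(df, ["marker_id", "rsid", "r2"], path)
    return {(row.marker_id, row.rsid): float(row.r2) for row in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, metadata: Mapping[str, str] | None = None) -> None:
    """Write a TSV with optional ``#key=value`` metadata comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


_SPAN_NONE = "."


def _span_to_text(span) -> str:
    if span is None:
        return _SPAN_NONE
    chrom, start, end, strand = span
    return f"{chrom}:{start}-{end}:{strand}"


def _span_from_text(text: str):
    if text == _SPAN_NONE or text == "":
        return None
    chrom, interval, strand = text.rsplit(":", 2)
    start, end = interval.split("-")
    return (chrom, int(start), int(end), strand)


EVENT_COLUMNS = ["hgvs_g", "cancer_type", "sample_id", "gene", "mirna",
                 "event_type", "ref_class", "mut_class", "transition",
                 "ref_offset", "mut_offset", "ref_span", "mut_span"]


def write_events_table(events, path, metadata: Mapping[str, str] | None = None) -> None:
    """Write alteration events as TSV, one row per mutation x miRNA event.

    The transition column renders modified events in the ``m6b->m7b`` style
    (an actual unicode arrow, as the table formatting of the source datasets
    uses).  The file is re-readable losslessly by :func:`read_events_table`.
    """
    rows = []
    for ev in events:
        rows.append({
            "hgvs_g": ev.mutation.hgvs_g,
            "cancer_type": ev.mutation.cancer_type,
            "sample_id": ev.mutation.sample_id,
            "gene": ev.gene_symbol,
            "mirna": ev.mirna_name,
            "event_type": ev.event_type,
            "ref_class": ev.ref_class or _SPAN_NONE,
            "mut_class": ev.mut_class or _SPAN_NONE,
            "transition": ev.transition or _SPAN_NONE,
            "ref_offset": _SPAN_NONE if ev.ref_offset is None else ev.ref_offset,
            "mut_offset": _SPAN_NONE if ev.mut_offset is None else ev.mut_offset,
            "ref_span": _span_to_text(ev.ref_span),
            "mut_span": _span_to_text(ev.mut_span),
        })
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    write_table(df, path, metadata)


def read_events_table(path):
    """Read back an events TSV written by :func:`write_events_table`."""
    from .classify import AlterationEvent  # deferred: classify imports io

    df = _read_tsv(path)
    if df.empty:
        return []
    _require_columns(df, EVENT_COLUMNS[:-1], path)
    events = []
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt = parse_hgvs_g(row.hgvs_g)
        mut = SomaticMutation(chrom, pos, ref, alt, row.cancer_type, row.sample_id)
        events.append(AlterationEvent(
            mutation=mut, gene_symbol=row.gene, mirna_name=row.mirna,
            event_type=row.event_type,
            ref_class=None if row.ref_class == _SPAN_NONE else row.ref_class,
            mut_class=None if row.mut_class == _SPAN_NONE else row.mut_class,
            ref_offset=None if str(row.ref_offset) == _SPAN_NONE else int(row.ref_offset),
            mut_offset=None if str(row.mut_offset) == _SPAN_NONE else int(row.mut_offset),
            ref_span=_span_from_text(row.ref_span),
            mut_span=_span_from_text(row.mut_span)))
    return events
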