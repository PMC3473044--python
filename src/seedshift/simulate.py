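"""Reproducible synthetic datasets with planted, verified truth labels.

The generator emulates the statistical structure of the study inputs without
any downloads: 3'UTRs of realistic length and GC content on both strands,
mature miRNAs with distinct seeds, somatic mutations planted so that the
real pipeline must recover a known created / disrupted / modified label,
per-cancer substitution-class mixtures, sidecar score / expression /
annotation tables that exercise every filter boundary, and LD scenarios with
planted positives and single-violation negatives.

Planting is verified at construction time with the brute-force scanner
(:mod:`seedshift.bruteforce`): a candidate mutation is accepted only if the
classification semantics yield exactly the intended event, and the local
background is redrawn when accidental extra seed matches interfere.  Truth
is therefore exact, not probabilistic.  Everything is deterministic given
``rng_seed``.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bruteforce import bruteforce_scan
from .classify import ARROW, classify
from .errors import SeedshiftError, ValidationError
from .io import (GermlineSnp, LdBlock, MarkerRecord, MirnaRecord, SomaticMutation,
                 UtrRecord, format_hgvs_g, revcomp_dna, write_table)
from .ld import site_span_of
from .mutate import make_pair
from .seeds import CLASS_PRIORITY

CANCER_CYCLE = ("lung", "SCLC", "melanoma", "prostate")

#: Default per-cancer substitution-class mixtures.  Qualitative shapes follow
#: the known mutational etiologies: UV damage makes melanoma G>A/C>T-dominant,
#: tobacco carcinogens make lung and SCLC G>T/C>A-dominant, prostate is
#: comparatively flat.
DEFAULT_MIXTURES = {
    "melanoma": {"G>A/C>T": 0.64, "G>T/C>A": 0.09, "G>C/C>G": 0.06,
                 "A>G/T>C": 0.10, "A>T/T>A": 0.06, "A>C/T>G": 0.05},
    "lung":     {"G>A/C>T": 0.22, "G>T/C>A": 0.36, "G>C/C>G": 0.12,
                 "A>G/T>C": 0.14, "A>T/T>A": 0.09, "A>C/T>G": 0.07},
    "SCLC":     {"G>A/C>T": 0.24, "G>T/C>A": 0.34, "G>C/C>G": 0.11,
                 "A>G/T>C": 0.15, "A>T/T>A": 0.09, "A>C/T>G": 0.07},
    "prostate": {"G>A/C>T": 0.30, "G>T/C>A": 0.16, "G>C/C>G": 0.13,
                 "A>G/T>C": 0.21, "A>T/T>A": 0.11, "A>C/T>G": 0.09},
}

DEFAULT_TRANSITIONS = (f"m6b{ARROW}m7b", f"m7b{ARROW}m6b", f"m6c{ARROW}m7b",
                       f"m8{ARROW}m7b", f"m7b{ARROW}m8", f"m7a{ARROW}m6a")


@dataclass
class SimConfig:
    """Parameters of a synthetic dataset.

    Defaults describe the standard study conditions used throughout the test
    suite: 150 planted events (50 per type) in AT-rich UTRs of 150-1500 nt,
    a panel of 20 miRNAs with distinct seeds, and a 3-positive /
    3-single-violation-negative LD scenario.
    """

    rng_seed: int = 0
    n_utrs: int | None = None  # default: one per planted event
    utr_length_range: tuple[int, int] = (150, 1500)
    gc_content: float = 0.40
    n_mirnas: int = 20
    planted_counts: dict = field(default_factory=lambda: {
        "created": 50, "disrupted": 50, "modified": 50})
    modified_transitions: tuple = DEFAULT_TRANSITIONS
    substitution_mixtures: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURES))
    n_ld_positives: int = 3
    n_ld_negatives: int = 3

    def __post_init__(self):
        if self.utr_length_range[0] < 30:
            raise ValidationError("UTR lengths must be >= 30 nt")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValidationError("gc_content must be in [0, 1]")
        total = sum(self.planted_counts.values())
        if self.n_utrs is None:
            self.n_utrs = total
        if self.n_utrs < total:
            raise ValidationError(
                f"cannot plant {total} events in {self.n_utrs} UTRs (one per UTR)")


@dataclass
class TruthRecord:
    """Ground truth for one planted event."""

    hgvs_g: str
    mirna_name: str
    event_type: str
    ref_class: str | None
    mut_class: str | None
    site_span: tuple
    expected_integration: bool = False
    expected_prioritized: bool | None = None

    @property
    def transition(self) -> str | None:
        if self.event_type != "modified":
            return None
        return f"{self.ref_class}{ARROW}{self.mut_class}"

    @property
    def key(self) -> tuple:
        return (self.hgvs_g, self.mirna_name)


@dataclass
class LdScenario:
    snps: list[GermlineSnp]
    markers: list[MarkerRecord]
    blocks: list[LdBlock]
    r2: dict[tuple[str, str], float]


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its truth table and sidecars."""

    config: SimConfig
    utrs: list[UtrRecord]
    mirnas: list[MirnaRecord]
    mutations: list[SomaticMutation]
    truth: list[TruthRecord]
    scores: dict[tuple, float]
    expression: dict[str, int]
    cancer_mirnas: set[str]
    cancer_genes: dict[str, str]
    ld: LdScenario

    def write(self, outdir) -> dict:
        """Emit every table in the exact formats the readers consume.

        Returns the manifest (also written as ``manifest.json``).  Output is
        byte-identical across reruns with the same config.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"rng_seed": str(self.config.rng_seed), "generator": "seedshift.simulate"}

        write_table(pd.DataFrame(
            [{"gene": u.gene_symbol, "transcript": u.transcript_id, "chrom": u.chrom,
              "start": u.start, "end": u.end, "strand": u.strand, "sequence": u.sequence}
             for u in self.utrs]), outdir / "utrs.tsv", meta)
        write_table(pd.DataFrame(
            [{"hgvs_g": m.hgvs_g, "cancer_type": m.cancer_type, "sample_id": m.sample_id}
             for m in self.mutations]), outdir / "mutations.tsv", meta)
        with open(outdir / "mirnas.fa", "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.name}\n{m.mature_sequence}\n")
        write_table(pd.DataFrame(
            [{"hgvs_g": format_hgvs_g(*k[0]), "mirna": k[1], "delta": v}
             for k, v in self.scores.items()]),
            outdir / "scores.tsv", meta)
        write_table(pd.DataFrame(
            [{"mirna": k, "reads": v} for k, v in self.expression.items()]),
            outdir / "expression.tsv", meta)
        write_table(pd.DataFrame(
            [{"gene": g, "direction": d} for g, d in sorted(self.cancer_genes.items())]),
            outdir / "cancer_genes.tsv", meta)
        write_table(pd.DataFrame(
            [{"mirna": m} for m in sorted(self.cancer_mirnas)]),
            outdir / "cancer_mirnas.tsv", meta)
        write_table(pd.DataFrame(
            [{"rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
              "ref": s.ref_allele, "alt": s.alt_allele} for s in self.ld.snps]),
            outdir / "snps.tsv", meta)
        write_table(pd.DataFrame(
            [{"marker_id": m.marker_id, "chrom": m.chrom, "pos": m.pos,
              "phenotype": m.phenotype, "p_value": m.p_value, "source": m.source}
             for m in self.ld.markers]), outdir / "markers.tsv", meta)
        write_table(pd.DataFrame(
            [{"chrom": b.chrom, "start": b.start, "end": b.end,
              "population": b.population} for b in self.ld.blocks]),
            outdir / "blocks.tsv", meta)
        write_table(pd.DataFrame(
            [{"marker_id": k[0], "rsid": k[1], "r2": v}
             for k, v in sorted(self.ld.r2.items())]), outdir / "r2.tsv", meta)
        write_table(pd.DataFrame(
            [{"hgvs_g": t.hgvs_g, "mirna": t.mirna_name, "event_type": t.event_type,
              "ref_class": t.ref_class or ".", "mut_class": t.mut_class or ".",
              "site_span": f"{t.site_span[0]}:{t.site_span[1]}-{t.site_span[2]}:{t.site_span[3]}",
              "expected_integration": int(t.expected_integration),
              "expected_prioritized": "." if t.expected_prioritized is None
                                      else int(t.expected_prioritized)}
             for t in self.truth]), outdir / "truth.tsv", meta)
        manifest = {
            "rng_seed": self.config.rng_seed,
            "n_utrs": len(self.utrs),
            "n_mirnas": len(self.mirnas),
            "n_mutations": len(self.mutations),
            "n_truth": len(self.truth),
            "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


# ---------------------------------------------------------------------------
# Sequence-level generators
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. DNA with the given GC content (gc=0 gives A/T-only)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=p))


def generate_mirnas(rng: np.random.Generator, n: int, length: int = 22) -> list[MirnaRecord]:
    """Random mature miRNAs with pairwise-distinct 8-base seed prefixes."""
    bases = np.array(["A", "C", "G", "U"])
    out: list[MirnaRecord] = []
    seen_seeds: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise SeedshiftError("could not generate distinct miRNA seeds")
        seq = "".join(rng.choice(bases, size=length))
        if seq[:8] in seen_seeds:
            continue
        seen_seeds.add(seq[:8])
        out.append(MirnaRecord(name=f"syn-miR-{len(out) + 1}", mature_sequence=seq))
    return out


def generate_utrs(config: SimConfig, rng: np.random.Generator) -> list[UtrRecord]:
    """Random UTRs on both strands, spaced widely so LD scenarios never collide."""
    lo, hi = config.utr_length_range
    utrs = []
    cursor: dict[str, int] = {}
    for i in range(config.n_utrs):
        chrom = f"chr{(i % 22) + 1}"
        length = int(rng.integers(lo, hi + 1))
        start = cursor.get(chrom, 1_000_000)
        cursor[chrom] = start + length + 600_000
        strand = "+" if i % 2 == 0 else "-"
        seq = random_dna(rng, length, config.gc_content)
        utrs.append(UtrRecord(
            gene_symbol=f"GENE{i:04d}", transcript_id=f"TX{i:04d}",
            chrom=chrom, start=start, end=start + length - 1,
            strand=strand, sequence=seq))
    return utrs


def mutation_at(utr: UtrRecord, offset: int, ref_t: str, alt_t: str,
                cancer_type: str = "other", sample_id: str = "") -> SomaticMutation:
    """Build the genomic mutation whose transcript-strand effect is
    ``sequence[offset] : ref_t -> alt_t``."""
    if utr.strand == "+":
        pos = utr.start + offset
        ref_g, alt_g = ref_t, alt_t
    else:
        pos = utr.end - offset - (len(ref_t) - 1)
        ref_g, alt_g = revcomp_dna(ref_t), revcomp_dna(alt_t)
    return SomaticMutation(utr.chrom, pos, ref_g, alt_g, cancer_type, sample_id)


def _parse_transition(transition: str) -> tuple[str, str]:
    for sep in (ARROW, "->"):
        if sep in transition:
            a, b = transition.split(sep)
            break
    else:
        raise ValidationError(f"cannot parse transition {transition!r}")
    a, b = a.strip(), b.strip()
    for lab in (a, b):
        if lab not in CLASS_PRIORITY:
            raise ValidationError(f"unknown seed class {lab!r} in transition")
    if a == b:
        raise ValidationError("modified transition needs two distinct classes")
    return a, b


@dataclass
class PlantResult:
    utr: UtrRecord          # the UTR with the planted reference sequence
    mutation: SomaticMutation
    truth: TruthRecord


def _verify_candidate(utr: UtrRecord, mutation: SomaticMutation, mirna: MirnaRecord,
                      want_type: str, want_ref: str | None, want_mut: str | None):
    """Run the classification semantics with the brute-force scanner; return
    the single expected event, or None if the candidate does not plant cleanly."""
    pair = make_pair(mutation, utr)
    events = classify(pair, mirna, scan=bruteforce_scan)
    if len(events) != 1:
        return None
    ev = events[0]
    if (ev.event_type, ev.ref_class, ev.mut_class) != (want_type, want_ref, want_mut):
        return None
    return ev


def plant_event(utr: UtrRecord, mirna: MirnaRecord, event_type: str,
                transition: str | None = None, rng: np.random.Generator | None = None,
                gc: float = 0.40, cancer_type: str = "other", sample_id: str = "",
                max_tries: int = 60) -> PlantResult:
    """Plant one labelled event into a UTR and verify it end to end.

    Embeds a seed-match site, then searches single-base substitutions around
    it until the brute-force classification of the (reference, mutant) pair
    yields exactly the intended event; accidental extra matches trigger a
    redraw of the background sequence.  ``created`` events are planted as the
    allele swap of a disruption, so the reference sequence carries the broken
    site and the mutation restores it.
    """
    rng = rng or np.random.default_rng(0)
    from .seeds import site_motif  # local alias; motifs drive the embedding

    if event_type == "modified":
        if transition is None:
            raise ValidationError("modified planting needs a transition")
        ref_class, mut_class = _parse_transition(transition)
    elif event_type in ("created", "disrupted"):
        target_class = transition or str(rng.choice(CLASS_PRIORITY))
        if target_class not in CLASS_PRIORITY:
            raise ValidationError(f"unknown seed class {target_class!r}")
        ref_class, mut_class = (None, target_class) if event_type == "created" \
            else (target_class, None)
    else:
        raise ValidationError(f"unknown event type {event_type!r}")

    # The embedded motif lives in whichever sequence should contain the site;
    # for created events we plant a disruption and swap alleles afterwards.
    plant_as_created = event_type == "created"
    embed_class = ref_class if not plant_as_created else mut_class

    L = len(utr.sequence)
    if L < 30:
        raise ValidationError(f"{utr.transcript_id}: UTR too short for planting")

    for _attempt in range(max_tries):
        background = random_dna(rng, L, gc)
        motif = site_motif(mirna.mature_sequence, embed_class)
        a = int(rng.integers(4, L - len(motif) - 4))
        seq = background[:a] + motif + background[a + len(motif):]
        utr_ref = dataclasses.replace(utr, sequence=seq)

        if event_type == "modified":
            q_range = range(max(0, a - 2), min(L, a + len(motif) + 2))
        else:
            q_range = range(a, a + len(motif))
        candidates = [(q, b) for q in q_range for b in "ACGT" if b != seq[q]]
        order = rng.permutation(len(candidates))

        for idx in order:
            q, b = candidates[idx]
            mut = mutation_at(utr_ref, q, seq[q], b, cancer_type, sample_id)
            if plant_as_created:
                # reference carries the broken site; the mutation restores it
                broken = seq[:q] + b + seq[q + 1:]
                utr_broken = dataclasses.replace(utr, sequence=broken)
                mut_restore = mutation_at(utr_broken, q, b, seq[q], cancer_type, sample_id)
                ev = _verify_candidate(utr_broken, mut_restore, mirna,
                                       "created", None, mut_class)
                if ev is None:
                    continue
                truth = TruthRecord(mut_restore.hgvs_g, mirna.name, "created",
                                    None, mut_class, site_span_of(ev))
                return PlantResult(utr_broken, mut_restore, truth)
            want = (event_type, ref_class, mut_class)
            ev = _verify_candidate(utr_ref, mut, mirna, *want)
            if ev is None:
                continue
            truth = TruthRecord(mut.hgvs_g, mirna.name, event_type,
                                ref_class, mut_class, site_span_of(ev))
            return PlantResult(utr_ref, mut, truth)
    raise SeedshiftError(
        f"planting {event_type} ({transition}) for {mirna.name} in "
        f"{utr.transcript_id} failed after {max_tries} redraws")


# ---------------------------------------------------------------------------
# Dataset-level generators
# ---------------------------------------------------------------------------

def generate_ld_scenario(truth: list[TruthRecord], config: SimConfig,
                         rng: np.random.Generator) -> LdScenario:
    """Planted LD positives plus negatives that each violate one predicate.

    Positive: a germline SNP inside the altered site, a marker within 100 kb,
    and a block containing both.  Negatives cycle through the three
    violations: SNP outside the site; marker beyond the radius; block that
    excludes the marker.
    """
    n_pos, n_neg = config.n_ld_positives, config.n_ld_negatives
    if n_pos + n_neg > len(truth):
        raise ValidationError("not enough planted events for the LD scenario")
    snps, markers, blocks = [], [], []
    r2: dict[tuple[str, str], float] = {}
    for i in range(n_pos + n_neg):
        t = truth[i]
        chrom, start, end, _strand = t.site_span
        positive = i < n_pos
        violation = (i - n_pos) % 3 if not positive else None

        if violation == 0:       # SNP outside the site span
            snp_pos = end + 2 + int(rng.integers(0, 5))
        else:
            snp_pos = int(rng.integers(start, end + 1))
        snps.append(GermlineSnp(rsid=f"rs{10000 + i}", chrom=chrom, pos=snp_pos,
                                ref_allele="A", alt_allele="G"))

        if violation == 1:       # marker beyond the 100 kb radius
            marker_pos = end + 100_001 + int(rng.integers(0, 5000))
        else:
            marker_pos = end + int(rng.integers(500, 50_000))
        markers.append(MarkerRecord(marker_id=f"rs{20000 + i}", chrom=chrom,
                                    pos=marker_pos, phenotype="cancer",
                                    p_value=float(10.0 ** -rng.integers(6, 18)),
                                    source="synthetic-gwas"))

        if violation == 2:       # block covers the site but not the marker
            block_end = marker_pos - 1 - int(rng.integers(0, 200))
        else:
            block_end = marker_pos + int(rng.integers(1000, 5000))
        block_start = max(1, start - int(rng.integers(1000, 5000)))
        blocks.append(LdBlock(chrom=chrom, start=block_start, end=max(block_end, end),
                              population="SYN"))

        if positive:
            t.expected_integration = True
            if i % 2 == 0:       # some SNPs lack reference-panel R2
                r2[(f"rs{20000 + i}", f"rs{10000 + i}")] = float(
                    np.round(rng.uniform(0.5, 0.99), 2))
    return LdScenario(snps=snps, markers=markers, blocks=blocks, r2=r2)


def generate_sidecar_tables(truth: list[TruthRecord], mutations: list[SomaticMutation],
                            mirnas: list[MirnaRecord], utr_by_hgvs: dict[str, UtrRecord],
                            config: SimConfig, rng: np.random.Generator):
    """Score / expression / annotation tables exercising every filter boundary.

    Returns (scores, expression, cancer_mirnas, cancer_genes) and sets
    ``expected_prioritized`` on each truth record from the values drawn, so
    the cascade's output can be compared against an independent expectation.
    """
    mut_by_hgvs = {m.hgvs_g: m for m in mutations}

    expression: dict[str, int] = {}
    for j, m in enumerate(mirnas):
        if j == 0:
            expression[m.name] = 100          # boundary: kept
        elif j == 1:
            expression[m.name] = 99           # boundary: dropped
        elif j == 2:
            continue                          # absent from table: dropped
        else:
            expression[m.name] = int(rng.integers(150, 50_000))

    cancer_mirnas = {m.name for j, m in enumerate(mirnas) if j != 3}
    cancer_genes: dict[str, str] = {}
    directions = ("overexpressed", "underexpressed", "unknown")
    for i, t in enumerate(truth):
        gene = utr_by_hgvs[t.hgvs_g].gene_symbol
        cancer_genes.setdefault(gene, directions[i % 3])

    scores: dict[tuple, float] = {}
    for i, t in enumerate(truth):
        mut = mut_by_hgvs[t.hgvs_g]
        key = (mut.hgvs_g, t.mirna_name)
        if i % 7 == 6:
            has_score = False                 # no score row at all
            delta = None
        else:
            has_score = True
            if i % 2 == 0:
                magnitude = float(rng.uniform(0.25, 0.6))
            elif i % 10 == 1:
                magnitude = 0.2               # boundary: dropped (strict >)
            else:
                magnitude = float(rng.uniform(0.01, 0.19))
            sign = -1.0 if t.event_type == "created" else 1.0
            delta = sign * magnitude
            scores[key] = delta
        t.expected_prioritized = bool(
            has_score and delta is not None and abs(delta) > 0.2
            and expression.get(t.mirna_name, 0) >= 100
            and t.mirna_name in cancer_mirnas
            and utr_by_hgvs[t.hgvs_g].gene_symbol in cancer_genes)
    # score table is keyed by mutation key tuples for the library API
    scores_by_key = {}
    for (hgvs, mirna), delta in scores.items():
        scores_by_key[(mut_by_hgvs[hgvs].key, mirna)] = delta
    return scores, scores_by_key, expression, cancer_mirnas, cancer_genes


def generate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the full planted dataset described by ``config``."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.rng_seed)
    mirnas = generate_mirnas(rng, config.n_mirnas)
    utrs = generate_utrs(config, rng)

    plan: list[tuple[str, str | None]] = []
    plan += [("created", None)] * config.planted_counts.get("created", 0)
    plan += [("disrupted", None)] * config.planted_counts.get("disrupted", 0)
    n_mod = config.planted_counts.get("modified", 0)
    plan += [("modified", config.modified_transitions[i % len(config.modified_transitions)])
             for i in range(n_mod)]

    final_utrs = list(utrs)
    mutations: list[SomaticMutation] = []
    truth: list[TruthRecord] = []
    utr_by_hgvs: dict[str, UtrRecord] = {}
    for i, (event_type, transition) in enumerate(plan):
        mirna = mirnas[i % len(mirnas)]
        res = plant_event(utrs[i], mirna, event_type, transition, rng=rng,
                          gc=config.gc_content,
                          cancer_type=CANCER_CYCLE[i % len(CANCER_CYCLE)],
                          sample_id=f"S{i:04d}")
        final_utrs[i] = res.utr
        mutations.append(res.mutation)
        truth.append(res.truth)
        utr_by_hgvs[res.mutation.hgvs_g] = res.utr

    _scores_hgvs, scores, expression, cancer_mirnas, cancer_genes = \
        generate_sidecar_tables(truth, mutations, mirnas, utr_by_hgvs, config, rng)
    ld = generate_ld_scenario(truth, config, rng)
    return SyntheticDataset(config=config, utrs=final_utrs, mirnas=mirnas,
                            mutations=mutations, truth=truth, scores=scores,
                            expression=expression, cancer_mirnas=cancer_mirnas,
                            cancer_genes=cancer_genes, ld=ld)


def allele_swapped(dataset: SyntheticDataset) -> tuple[list[UtrRecord], list[SomaticMutation]]:
    """The allele-swapped twin of a planted dataset.

    Each planted UTR carries exactly one mutation; the twin applies that
    mutation to the reference sequence and swaps ref/alt, so classification
    must exchange created and disrupted and reverse every modified
    transition.
    """
    swapped_utrs: list[UtrRecord] = []
    swapped_muts: list[SomaticMutation] = []
    mut_by_idx = {i: m for i, m in enumerate(dataset.mutations)}
    for i, utr in enumerate(dataset.utrs):
        if i not in mut_by_idx:
            swapped_utrs.append(utr)
            continue
        m = mut_by_idx[i]
        pair = make_pair(m, utr)
        swapped_utrs.append(dataclasses.replace(utr, sequence=pair.mut_seq))
        swapped_muts.append(SomaticMutation(m.chrom, m.pos, m.alt_allele, m.ref_allele,
                                            m.cancer_type, m.sample_id))
    return swapped_utrs, swapped_muts


def generate_recurrence_table(n_sites: int, n_recurrent: int,
                              rng: np.random.Generator | None = None,
                              cancer_type: str = "prostate") -> list[SomaticMutation]:
    """A mutation table with exactly ``n_recurrent`` of ``n_sites`` distinct
    sites observed in two samples (all others in one)."""
    if n_recurrent > n_sites:
        raise ValidationError("cannot have more recurrent sites than sites")
    rng = rng or np.random.default_rng(0)
    bases = np.array(["A", "C", "G", "T"])
    out: list[SomaticMutation] = []
    for i in range(n_sites):
        chrom = f"chr{(i % 22) + 1}"
        pos = 1000 + 10 * i
        ref = str(rng.choice(bases))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        out.append(SomaticMutation(chrom, pos, ref, alt, cancer_type, f"P{i:05d}"))
        if i < n_recurrent:
            out.append(SomaticMutation(chrom, pos, ref, alt, cancer_type, f"Q{i:05d}"))
    return out
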