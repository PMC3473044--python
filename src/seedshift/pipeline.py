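"""End-to-end orchestration: io -> classify -> patterns -> prioritize -> integrate.

A run is described by a :class:`RunConfig` (loadable from a YAML file whose
keys mirror the dataclass fields).  Every stage logs record counts in and
out, writes its table into the output directory, and contributes to a JSON
run summary.  A stage failure raises :class:`~seedshift.errors.PipelineError`
naming the stage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .classify import classify_all
from .errors import PipelineError, ValidationError
from .ld import integrate
from .patterns import (dedupe_multi_utr, recurrence_stats, relative_position,
                       rolling_counts, spectrum, spectrum_by_type)
from .prioritize import PrioritizationConfig, disrupted_created_ratio, prioritize
from .mutate import utrs_containing

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    Only the classification inputs are mandatory; prioritization and LD
    integration run when their input tables are configured.  Thresholds
    default to the study values: |context+ delta| > 0.2, >= 100 reads,
    100 kb marker radius, 5% rolling window with 1% step.
    """

    utr_table: str = ""
    mutation_table: str = ""
    mirna_fasta: str = ""
    out_dir: str = "seedshift_out"
    score_table: str | None = None
    expression_table: str | None = None
    cancer_gene_table: str | None = None
    cancer_mirna_table: str | None = None
    snp_table: str | None = None
    marker_table: str | None = None
    block_table: str | None = None
    r2_table: str | None = None
    delta_threshold: float = 0.2
    min_reads: int = 100
    require_cancer_mirna: bool = True
    require_cancer_gene: bool = True
    marker_radius_bp: int = 100_000
    window_width: float = 0.05
    window_step: float = 0.01
    run_patterns: bool = True
    run_prioritize: bool = True
    run_integrate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        """Check every referenced input path before anything is written."""
        required = {"utr_table": self.utr_table, "mutation_table": self.mutation_table,
                    "mirna_fasta": self.mirna_fasta}
        missing = [name for name, p in required.items() if not p]
        if missing:
            raise ValidationError(f"config missing required input(s): {missing}")
        optional = [self.score_table, self.expression_table, self.cancer_gene_table,
                    self.cancer_mirna_table, self.snp_table, self.marker_table,
                    self.block_table, self.r2_table]
        for p in list(required.values()) + [p for p in optional if p]:
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    @property
    def prioritization(self) -> PrioritizationConfig:
        return PrioritizationConfig(
            delta_threshold=self.delta_threshold, min_reads=self.min_reads,
            require_cancer_mirna=self.require_cancer_mirna,
            require_cancer_gene=self.require_cancer_gene)


def _stage(name):
    """Wrap stage bodies so failures carry the stage name."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("io")
def _load_inputs(config: RunConfig):
    utrs = sio.read_utr_table(config.utr_table)
    mutations = sio.read_mutation_table(config.mutation_table)
    mirnas = sio.read_mirna_fasta(config.mirna_fasta)
    log.info("io: %d UTRs, %d mutations, %d miRNAs",
             len(utrs), len(mutations), len(mirnas))
    return utrs, mutations, mirnas


@_stage("classify")
def _classify(config, utrs, mutations, mirnas, outdir, meta):
    result = classify_all(mutations, utrs, mirnas)
    sio.write_events_table(result.events, outdir / "events.tsv", meta)
    log.info("classify: %d mutations in, %d events out (%d skipped)",
             len(mutations), len(result.events), len(result.skipped))
    return result


@_stage("patterns")
def _patterns(config, utrs, mutations, outdir, meta):
    overall = spectrum(mutations)
    per_type = spectrum_by_type(mutations)
    rows = []
    for label, spec in [("all", overall)] + sorted(per_type.items()):
        for cls, count in spec.counts.items():
            rows.append({"set": label, "substitution_class": cls, "count": count,
                         "percent": spec.frequencies[cls]})
    sio.write_table(pd.DataFrame(rows), outdir / "spectrum.tsv", meta)

    deduped = dedupe_multi_utr(mutations, utrs)
    positions = []
    for m in deduped:
        if m.is_indel:
            continue
        for utr in utrs_containing(m, utrs):
            positions.append(relative_position(m, utr))
            break  # one position per mutation: its first containing UTR
    dist = rolling_counts(positions, width=config.window_width, step=config.window_step)
    sio.write_table(pd.DataFrame({"center": dist.centers, "count": dist.counts}),
                    outdir / "positions.tsv", meta)

    recurrence = {ct: recurrence_stats([m for m in mutations if m.cancer_type == ct])
                  for ct in sorted({m.cancer_type for m in mutations})}
    log.info("patterns: %d substitutions in spectrum, %d positional mutations",
             overall.total, len(positions))
    return overall, recurrence


@_stage("prioritize")
def _prioritize(config, events, outdir, meta):
    scores = sio.read_score_table(config.score_table)
    expression = sio.read_expression_table(config.expression_table) \
        if config.expression_table else {}
    cancer_genes = sio.read_gene_annotation_table(config.cancer_gene_table) \
        if config.cancer_gene_table else {}
    cancer_mirnas = sio.read_mirna_annotation_table(config.cancer_mirna_table) \
        if config.cancer_mirna_table else set()
    hits = prioritize(events, scores, expression, cancer_mirnas, cancer_genes,
                      config.prioritization)
    rows = [{"hgvs_g": h.event.mutation.hgvs_g,
             "cancer_type": h.event.mutation.cancer_type,
             "gene": h.event.gene_symbol, "mirna": h.event.mirna_name,
             "event_type": h.event.event_type,
             "transition": h.event.transition or ".",
             "delta": h.delta, "mirna_reads": h.mirna_reads,
             "gene_direction": h.gene_direction, "concordant": h.concordant}
            for h in hits]
    sio.write_table(pd.DataFrame(rows), outdir / "prioritized.tsv", meta)
    log.info("prioritize: %d events in, %d hits out", len(events), len(hits))
    return hits


@_stage("integrate")
def _integrate(config, events, outdir, meta):
    snps = sio.read_snp_table(config.snp_table)
    markers = sio.read_marker_table(config.marker_table)
    blocks = sio.read_block_table(config.block_table)
    r2 = sio.read_r2_table(config.r2_table) if config.r2_table else {}
    hits = integrate(events, snps, markers, blocks, r2_table=r2,
                     radius=config.marker_radius_bp)
    rows = []
    for h in hits:
        chrom, start, end, strand = h.site_span
        rows.append({"hgvs_g": h.event.mutation.hgvs_g,
                     "cancer_type": h.event.mutation.cancer_type,
                     "gene": h.event.gene_symbol, "mirna": h.event.mirna_name,
                     "site_span": f"{chrom}:{start}-{end}:{strand}",
                     "germline_rsid": h.germline.rsid,
                     "germline_to_somatic_bp": h.germline_to_somatic_bp,
                     "marker_id": h.marker.marker_id,
                     "marker_distance_bp": h.marker_distance_bp,
                     "block": f"{h.block.chrom}:{h.block.start}-{h.block.end}",
                     "r2": "." if h.r2 is None else h.r2})
    sio.write_table(pd.DataFrame(rows), outdir / "integration.tsv", meta)
    log.info("integrate: %d events in, %d hits out", len(events), len(hits))
    return hits


def run(config: RunConfig) -> dict:
    """Execute all enabled stages and return (and write) the run summary."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"tool": "seedshift", "config": json.dumps(asdict(config), sort_keys=True)}

    utrs, mutations, mirnas = _load_inputs(config)
    result = _classify(config, utrs, mutations, mirnas, outdir, meta)

    summary: dict = {
        "n_mutations": result.n_mutations,
        "n_altered_any": result.n_altered_any,
        "n_events": len(result.events),
        "events_by_type": result.counts_by_type(),
        "n_skipped": len(result.skipped),
    }
    summary["disrupted_created_ratio"] = {
        ct: disrupted_created_ratio(result.events, ct)
        for ct in sorted({m.cancer_type for m in mutations})}

    if config.run_patterns:
        overall, recurrence = _patterns(config, utrs, mutations, outdir, meta)
        summary["spectrum_total"] = overall.total
        summary["recurrence"] = {
            ct: {"n_recurrent": r.n_recurrent, "n_total": r.n_total,
                 "percent": r.percent}
            for ct, r in recurrence.items()}

    if config.run_prioritize and config.score_table:
        hits = _prioritize(config, result.events, outdir, meta)
        summary["n_prioritized"] = len(hits)
        summary["n_concordant"] = sum(h.concordant for h in hits)

    if config.run_integrate and config.snp_table and config.marker_table \
            and config.block_table:
        ihits = _integrate(config, result.events, outdir, meta)
        summary["n_integration_hits"] = len(ihits)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
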