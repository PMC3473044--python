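"""Filter cascade for ranking alteration events, and the disrupted:created
ratio summary.

The cascade keeps an event only if (1) the supplied context+ score delta for
the mutation x miRNA pair has magnitude strictly greater than a threshold
(default 0.2; context+ scores are consumed from an input table, never
computed here), (2) the miRNA has at least ``min_reads`` total sequencing
reads (default 100), and (3) the miRNA and/or gene carry cancer annotations.
The three filters are pure intersections, so their order does not change the
final set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .classify import AlterationEvent
from .errors import ValidationError
from .patterns import round_half_up
from .seeds import CLASS_LENGTH

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContextScorePair:
    """A precomputed context+ score for one mutation x miRNA pair.

    More negative scores indicate stronger predicted repression;
    ``delta = mut_score - ref_score``.
    """

    mutation_key: tuple
    mirna_name: str
    ref_score: float
    mut_score: float

    @property
    def delta(self) -> float:
        return self.mut_score - self.ref_score


@dataclass
class PrioritizationConfig:
    """Thresholds of the filter cascade."""

    delta_threshold: float = 0.2
    min_reads: int = 100
    require_cancer_mirna: bool = True
    require_cancer_gene: bool = True

    def __post_init__(self):
        if self.delta_threshold <= 0 or self.min_reads <= 0:
            raise ValidationError("prioritization thresholds must be positive")


@dataclass(frozen=True)
class PrioritizedHit:
    """An event that survived the cascade, with its supporting numbers."""

    event: AlterationEvent
    delta: float | None
    mirna_reads: int
    gene_direction: str  # overexpressed / underexpressed / unknown
    concordant: bool


def _as_delta_map(scores) -> dict[tuple, float]:
    if isinstance(scores, dict):
        return scores
    out: dict[tuple, float] = {}
    for s in scores:
        key = (s.mutation_key, s.mirna_name)
        if key in out:
            raise ValidationError(f"duplicate score rows for {key}")
        out[key] = s.delta
    return out


def filter_delta(events, scores, threshold: float = 0.2) -> list[AlterationEvent]:
    """Keep events whose |context+ delta| is strictly greater than ``threshold``.

    ``scores`` maps (mutation key, miRNA name) -> delta (or is an iterable of
    :class:`ContextScorePair`).  Events with no score row are dropped and the
    count logged: a score table that never saw the pair cannot vouch for it.
    """
    deltas = _as_delta_map(scores)
    kept, missing = [], 0
    for ev in events:
        key = (ev.mutation.key, ev.mirna_name)
        if key not in deltas:
            missing += 1
            continue
        if abs(deltas[key]) > threshold:
            kept.append(ev)
    if missing:
        log.info("filter_delta: %d event(s) had no score row and were dropped", missing)
    return kept


def filter_expression(events, expression, min_reads: int = 100) -> list[AlterationEvent]:
    """Keep events whose miRNA has at least ``min_reads`` total reads.

    A miRNA absent from the expression table counts as 0 reads (dropped with
    a warning): the low-expression filter removes what cannot be shown to be
    expressed.
    """
    kept = []
    missing = set()
    for ev in events:
        reads = expression.get(ev.mirna_name)
        if reads is None:
            missing.add(ev.mirna_name)
            continue
        if reads >= min_reads:
            kept.append(ev)
    for name in sorted(missing):
        log.warning("filter_expression: miRNA %s absent from expression table; "
                    "treated as 0 reads", name)
    return kept


def effect_direction(event: AlterationEvent) -> str:
    """Whether an event strengthens ('gain'), weakens ('loss'), or leaves
    neutral the predicted miRNA binding.

    Created sites and modified events that lengthen the match are gains;
    disrupted sites and shortening modifications are losses; equal-length
    class changes (e.g. m6c -> m6b) are neutral.
    """
    if event.event_type == "created":
        return "gain"
    if event.event_type == "disrupted":
        return "loss"
    ref_len = CLASS_LENGTH[event.ref_class]
    mut_len = CLASS_LENGTH[event.mut_class]
    if mut_len > ref_len:
        return "gain"
    if mut_len < ref_len:
        return "loss"
    return "neutral"


def filter_annotations(events, cancer_mirnas, cancer_genes,
                       config: PrioritizationConfig | None = None,
                       scores=None, expression=None) -> list[PrioritizedHit]:
    """Restrict events to cancer-annotated miRNAs/genes and flag concordance.

    Concordance captures the expression logic of the study design: a gene
    overexpressed in cancer with a weakened site (the lost repression could
    explain the overexpression), or an underexpressed gene with a
    strengthened site.  Genes with unknown direction are retained but marked
    non-concordant.
    """
    config = config or PrioritizationConfig()
    deltas = _as_delta_map(scores) if scores is not None else {}
    expression = expression or {}
    hits = []
    for ev in events:
        if config.require_cancer_mirna and ev.mirna_name not in cancer_mirnas:
            continue
        if config.require_cancer_gene and ev.gene_symbol not in cancer_genes:
            continue
        direction = cancer_genes.get(ev.gene_symbol, "unknown")
        eff = effect_direction(ev)
        concordant = ((direction == "overexpressed" and eff == "loss")
                      or (direction == "underexpressed" and eff == "gain"))
        hits.append(PrioritizedHit(
            event=ev,
            delta=deltas.get((ev.mutation.key, ev.mirna_name)),
            mirna_reads=expression.get(ev.mirna_name, 0),
            gene_direction=direction,
            concordant=concordant))
    return hits


def prioritize(events, scores, expression, cancer_mirnas, cancer_genes,
               config: PrioritizationConfig | None = None) -> list[PrioritizedHit]:
    """Run the full cascade: score delta, expression, then annotations."""
    config = config or PrioritizationConfig()
    kept = filter_delta(events, scores, threshold=config.delta_threshold)
    kept = filter_expression(kept, expression, min_reads=config.min_reads)
    return filter_annotations(kept, cancer_mirnas, cancer_genes, config,
                              scores=scores, expression=expression)


def disrupted_created_ratio(events, cancer_type: str | None = None) -> float | None:
    """Number of disrupted sites divided by number of created sites.

    Modified events are excluded.  Returns None (undefined) when no sites
    were created; otherwise the ratio rounded half-up to two decimals.
    """
    if cancer_type is not None:
        events = [e for e in events if e.mutation.cancer_type == cancer_type]
    n_disrupted = sum(e.event_type == "disrupted" for e in events)
    n_created = sum(e.event_type == "created" for e in events)
    if n_created == 0:
        return None
    return round_half_up(n_disrupted / n_created, 2)
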