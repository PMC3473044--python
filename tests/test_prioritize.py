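import numpy as np
import pytest

from seedshift.classify import AlterationEvent
from seedshift.errors import ValidationError
from seedshift.io import SomaticMutation
from seedshift.prioritize import (ContextScorePair, PrioritizationConfig,
                                  disrupted_created_ratio, effect_direction,
                                  filter_annotations, filter_delta,
                                  filter_expression)


def _event(event_type="disrupted", gene="GENE", mirna="mir-1", pos=100,
           ref_class="m8", mut_class=None, cancer_type="melanoma"):
    if event_type == "created":
        ref_class, mut_class = None, mut_class or "m8"
    elif event_type == "modified":
        ref_class, mut_class = ref_class or "m6b", mut_class or "m7b"
    mut = SomaticMutation("chr1", pos, "A", "G", cancer_type, "S1")
    return AlterationEvent(mut, gene, mirna, event_type,
                           ref_class=ref_class, mut_class=mut_class)


class TestFilterDelta:
    def test_strict_threshold_boundary(self):
        events = [_event(pos=p) for p in (100, 200, 300)]
        scores = {(events[0].mutation.key, "mir-1"): -0.35,
                  (events[1].mutation.key, "mir-1"): 0.2,
                  (events[2].mutation.key, "mir-1"): 0.21}
        kept = filter_delta(events, scores, threshold=0.2)
        assert kept == [events[0], events[2]]  # |−0.35| and 0.21 pass; 0.2 exactly fails

    def test_missing_score_rows_dropped(self):
        events = [_event(pos=100), _event(pos=200)]
        scores = {(events[0].mutation.key, "mir-1"): -0.5}
        assert filter_delta(events, scores) == [events[0]]

    def test_duplicate_score_rows_rejected(self):
        mut_key = ("chr1", 100, "A", "G")
        pairs = [ContextScorePair(mut_key, "mir-1", -0.1, -0.4),
                 ContextScorePair(mut_key, "mir-1", -0.1, -0.5)]
        with pytest.raises(ValidationError):
            filter_delta([_event()], pairs)


class TestFilterExpression:
    def test_boundary_keeps_100_drops_99(self):
        events = [_event(mirna="hi"), _event(mirna="lo"), _event(mirna="absent")]
        expression = {"hi": 100, "lo": 99}
        assert filter_expression(events, expression, min_reads=100) == [events[0]]


class TestConcordance:
    def test_overexpressed_gene_with_disrupted_site(self):
        # e.g. an oncogene overexpressed in leukaemia losing its repressor site
        (hit,) = filter_annotations([_event("disrupted", gene="TAL1")],
                                    {"mir-1"}, {"TAL1": "overexpressed"})
        assert hit.concordant

    def test_underexpressed_gene_with_created_site(self):
        (hit,) = filter_annotations([_event("created", gene="MITF")],
                                    {"mir-1"}, {"MITF": "underexpressed"})
        assert hit.concordant

    def test_unknown_direction_retained_not_concordant(self):
        (hit,) = filter_annotations([_event("disrupted", gene="X")],
                                    {"mir-1"}, {"X": "unknown"})
        assert not hit.concordant

    def test_modified_direction_ranked_by_site_length(self):
        lengthening = _event("modified", ref_class="m6b", mut_class="m7b")
        shortening = _event("modified", ref_class="m7b", mut_class="m6b")
        neutral = _event("modified", ref_class="m6c", mut_class="m6b")
        assert effect_direction(lengthening) == "gain"
        assert effect_direction(shortening) == "loss"
        assert effect_direction(neutral) == "neutral"

    def test_annotation_restriction(self):
        events = [_event(mirna="known"), _event(mirna="novel")]
        hits = filter_annotations(events, {"known"}, {"GENE": "unknown"})
        assert [h.event.mirna_name for h in hits] == ["known"]


class TestRatio:
    def test_hand_computed(self):
        events = ([_event("disrupted", pos=100 + i) for i in range(118)]
                  + [_event("created", pos=5000 + i) for i in range(100)]
                  + [_event("modified", pos=9000 + i) for i in range(7)])
        assert disrupted_created_ratio(events) == 1.18

    def test_zero_disrupted(self):
        events = [_event("created", pos=100 + i) for i in range(5)]
        assert disrupted_created_ratio(events) == 0.0

    def test_zero_created_undefined(self):
        events = [_event("disrupted", pos=100 + i) for i in range(5)]
        assert disrupted_created_ratio(events) is None

    def test_cancer_type_restriction(self):
        events = [_event("disrupted", pos=1, cancer_type="lung"),
                  _event("created", pos=2, cancer_type="lung"),
                  _event("created", pos=3, cancer_type="SCLC")]
        assert disrupted_created_ratio(events, "lung") == 1.0


def test_cascade_order_independence():
    """The filters are pure intersections: any order gives the same set."""
    rng = np.random.default_rng(4)
    events = [_event(mirna=f"mir-{i % 5}", pos=10 * i + 1) for i in range(40)]
    scores = {(e.mutation.key, e.mirna_name): float(rng.uniform(-0.5, 0.5))
              for e in events if rng.random() < 0.8}
    expression = {f"mir-{i}": int(rng.integers(0, 300)) for i in range(4)}

    a = filter_expression(filter_delta(events, scores), expression)
    b = filter_delta(filter_expression(events, expression), scores)
    assert a == b


def test_config_rejects_nonpositive_thresholds():
    with pytest.raises(ValidationError):
        PrioritizationConfig(delta_threshold=0.0)
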