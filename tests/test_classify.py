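from collections import Counter

import pytest

from conftest import events_by_key
from seedshift.classify import (AlterationEvent, classify, classify_all,
                                overlapping_matches)
from seedshift.errors import ValidationError
from seedshift.io import SomaticMutation, UtrRecord
from seedshift.mutate import make_pair
from seedshift.seeds import CLASS_LENGTH, SeedMatch
from seedshift.simulate import allele_swapped


def _match(offset, length=8, cls="m8"):
    return SeedMatch("mir", cls, offset, length)


class TestOverlappingMatches:
    def test_boundary_overlap_included(self):
        assert overlapping_matches([_match(3)], (10, 11)) != []

    def test_half_open_exclusivity(self):
        assert overlapping_matches([_match(3)], (11, 12)) == []

    def test_empty(self):
        assert overlapping_matches([], (0, 1)) == []


class TestClassifySingleMirna:
    """The three canonical single-site outcomes on the toy let-7a UTR."""

    def test_truncation_is_modified(self, let7a, toy_utr):
        # mutating the last site base leaves an intact m7b one base shorter
        m = SomaticMutation("chr1", 111, "A", "G")
        events = classify(make_pair(m, toy_utr), let7a)
        assert [(e.event_type, e.transition) for e in events] == [("modified", "m8→m7b")]

    def test_core_hit_is_disrupted(self, let7a, toy_utr):
        m = SomaticMutation("chr1", 107, "C", "G")
        events = classify(make_pair(m, toy_utr), let7a)
        assert [(e.event_type, e.ref_class, e.mut_class) for e in events] == \
            [("disrupted", "m8", None)]

    def test_reverse_of_disruption_is_created(self, let7a, toy_utr):
        broken = UtrRecord("TOY", "TX_TOY", "chr1", 101, 114, "+", "AAACTAGCTCAAAA")
        m = SomaticMutation("chr1", 107, "G", "C")
        events = classify(make_pair(m, broken), let7a)
        assert [(e.event_type, e.ref_class, e.mut_class) for e in events] == \
            [("created", None, "m8")]

    def test_event_sites_touch_the_mutated_span(self, let7a, toy_utr):
        """No action at a distance: at least one of an event's site intervals
        intersects the affected span."""
        for pos in range(toy_utr.start, toy_utr.end + 1):
            ref_b = toy_utr.sequence[pos - toy_utr.start]
            for alt_b in "ACGT":
                if alt_b == ref_b:
                    continue
                pair = make_pair(SomaticMutation("chr1", pos, ref_b, alt_b), toy_utr)
                lo, hi = pair.affected_span
                for ev in classify(pair, let7a):
                    intervals = []
                    if ev.ref_offset is not None:
                        intervals.append((ev.ref_offset,
                                          ev.ref_offset + CLASS_LENGTH[ev.ref_class]))
                    if ev.mut_offset is not None:
                        intervals.append((ev.mut_offset,
                                          ev.mut_offset + CLASS_LENGTH[ev.mut_class]))
                    assert any(a < hi and lo < b for a, b in intervals)


def test_event_invariants_enforced():
    mut = SomaticMutation("chr1", 5, "A", "G")
    with pytest.raises(ValidationError):
        AlterationEvent(mut, "G", "mir", "created", ref_class="m8", mut_class="m7b")
    with pytest.raises(ValidationError):
        AlterationEvent(mut, "G", "mir", "modified", ref_class="m8", mut_class="m8")


def test_classify_all_no_mirnas(toy_utr):
    m = SomaticMutation("chr1", 107, "C", "G")
    result = classify_all([m], [toy_utr], [])
    assert result.events == []
    assert result.altered_any == {m.key: False}


def test_classify_all_skips_reference_mismatch_and_continues(let7a, toy_utr):
    good = SomaticMutation("chr1", 107, "C", "G", sample_id="S1")
    bad = SomaticMutation("chr1", 108, "G", "A", sample_id="S2")  # ref is C
    result = classify_all([bad, good], [toy_utr], [let7a])
    assert len(result.skipped) == 1 and result.skipped[0][0] == bad
    assert result.altered_any[good.key] is True


def test_identical_utr_isoforms_counted_once(let7a, toy_utr):
    import dataclasses
    iso = dataclasses.replace(toy_utr, transcript_id="TX_TOY2")
    m = SomaticMutation("chr1", 107, "C", "G")
    result = classify_all([m], [toy_utr, iso], [let7a])
    assert len(result.events) == 1


def test_planted_labels_recovered(small_dataset):
    ds = small_dataset
    result = classify_all(ds.mutations, ds.utrs, ds.mirnas)
    grouped = events_by_key(result.events)
    for t in ds.truth:
        labels = [(e.event_type, e.ref_class, e.mut_class) for e in grouped.get(t.key, [])]
        assert labels == [(t.event_type, t.ref_class, t.mut_class)]


def test_allele_swap_exchanges_created_and_disrupted(small_dataset):
    ds = small_dataset
    base = classify_all(ds.mutations, ds.utrs, ds.mirnas)
    utrs2, muts2 = allele_swapped(ds)
    swapped = classify_all(muts2, utrs2, ds.mirnas)
    c1, c2 = base.counts_by_type(), swapped.counts_by_type()
    assert c1["created"] == c2["disrupted"]
    assert c1["disrupted"] == c2["created"]
    assert c1["modified"] == c2["modified"]
    fwd = Counter((e.ref_class, e.mut_class) for e in base.events
                  if e.event_type == "modified")
    rev = Counter((e.mut_class, e.ref_class) for e in swapped.events
                  if e.event_type == "modified")
    assert fwd == rev
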