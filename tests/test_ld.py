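import numpy as np
import pytest

from conftest import events_by_key
from seedshift.classify import AlterationEvent, classify_all
from seedshift.io import (GermlineSnp, LdBlock, MarkerRecord, SomaticMutation,
                          read_block_table)
from seedshift.ld import (distance_to_span, germline_in_site, integrate,
                          markers_near, site_in_block, site_span_of)


def _event(span=("chr4", 96075965, 96075972, "+"), pos=96075969, event_type="disrupted"):
    mut = SomaticMutation(span[0], pos, "G", "T", "lung", "S1")
    return AlterationEvent(mut, "BMPR1B", "miR-125b", event_type,
                           ref_class="m8", ref_offset=10, ref_span=span)


SPAN = ("chr4", 96075965, 96075972, "+")


class TestGermlineInSite:
    def test_snp_inside_span_paired(self):
        snp = GermlineSnp("rs1434536", "chr4", 96075969)
        pairs = germline_in_site([_event()], [snp])
        assert len(pairs) == 1 and pairs[0][1] is snp

    def test_snp_past_span_end_not_paired(self):
        snp = GermlineSnp("rs1", "chr4", 96075973)
        assert germline_in_site([_event()], [snp]) == []

    def test_empty_snp_table(self):
        assert germline_in_site([_event()], []) == []


class TestMarkersNear:
    def test_marker_859_bp_away_included(self):
        marker = MarkerRecord("rs2735839", "chr4", SPAN[2] + 859)
        assert markers_near(SPAN, [marker]) == [marker]

    def test_marker_at_radius_plus_one_excluded(self):
        marker = MarkerRecord("rs_far", "chr4", SPAN[2] + 100_001)
        assert markers_near(SPAN, [marker]) == []

    def test_other_chromosome_excluded(self):
        marker = MarkerRecord("rs_other", "chr5", SPAN[2] + 10)
        assert markers_near(SPAN, [marker]) == []

    def test_marker_inside_span_distance_zero(self):
        assert distance_to_span(96075966, SPAN) == 0


class TestSiteInBlock:
    marker = MarkerRecord("rs11097457", "chr4", 96076831)

    def test_block_containing_both(self):
        block = LdBlock("chr4", 96061509, 96091524)
        ok, chosen = site_in_block(SPAN, self.marker, [block])
        assert ok and chosen == block

    def test_marker_outside_block(self):
        block = LdBlock("chr4", 96075000, 96076000)  # covers site, not marker
        ok, chosen = site_in_block(SPAN, self.marker, [block])
        assert not ok and chosen is None

    def test_no_blocks(self):
        assert site_in_block(SPAN, self.marker, []) == (False, None)

    def test_overlapping_blocks_prefer_smallest(self):
        big = LdBlock("chr4", 96000000, 96100000)
        small = LdBlock("chr4", 96061509, 96091524)
        ok, chosen = site_in_block(SPAN, self.marker, [big, small])
        assert ok and chosen == small


def test_block_reader_rejects_inverted_boundaries(tmp_path):
    path = tmp_path / "blocks.tsv"
    path.write_text("chrom\tstart\tend\tpopulation\n"
                    "chr19\t51361757\t5134623\tCEU\n"     # end < start: rejected
                    "chr4\t96061509\t96091524\tCEU\n")
    blocks = read_block_table(path)
    assert [(b.start, b.end) for b in blocks] == [(96061509, 96091524)]


class TestIntegrate:
    snp = GermlineSnp("rs1434536", "chr4", 96075969)
    marker = MarkerRecord("rs11097457", "chr4", 96076816)
    block = LdBlock("chr4", 96061509, 96091524)

    def test_full_join_with_distances(self):
        event = _event(pos=96075965)
        (hit,) = integrate([event], [self.snp], [self.marker], [self.block],
                           r2_table={("rs11097457", "rs1434536"): 0.82})
        assert hit.germline_to_somatic_bp == 4
        assert hit.marker_distance_bp == 96076816 - SPAN[2]
        assert hit.r2 == 0.82

    def test_adjacent_positions_distance_one(self):
        event = _event(pos=96075968)
        (hit,) = integrate([event], [self.snp], [self.marker], [self.block])
        assert hit.germline_to_somatic_bp == 1

    def test_missing_r2_flagged_none(self):
        (hit,) = integrate([_event()], [self.snp], [self.marker], [self.block])
        assert hit.r2 is None

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(0)
        events = [_event(), _event(pos=96075968)]
        snps = [self.snp, GermlineSnp("rs2", "chr4", 96075966)]
        markers = [self.marker, MarkerRecord("rsB", "chr4", 96080000)]
        blocks = [self.block, LdBlock("chr4", 96070000, 96085000)]
        base = integrate(events, snps, markers, blocks)
        for _ in range(5):
            shuffled = integrate([events[i] for i in rng.permutation(len(events))],
                                 [snps[i] for i in rng.permutation(len(snps))],
                                 [markers[i] for i in rng.permutation(len(markers))],
                                 [blocks[i] for i in rng.permutation(len(blocks))])
            assert shuffled == base


def test_modified_event_span_is_union():
    mut = SomaticMutation("chr1", 1000, "A", "G")
    ev = AlterationEvent(mut, "G", "mir", "modified", ref_class="m6b", mut_class="m7b",
                         ref_offset=5, mut_offset=4,
                         ref_span=("chr1", 1001, 1006, "+"),
                         mut_span=("chr1", 1000, 1006, "+"))
    assert site_span_of(ev) == ("chr1", 1000, 1006, "+")


def test_planted_scenario_recovers_exactly_the_positives(planted_dataset, planted_result):
    """3 planted positives and 3 single-violation negatives: the join returns
    exactly the positives, each re-checkable by brute force."""
    ds = planted_dataset
    grouped = events_by_key(planted_result.events)
    truth_events = [e for t in ds.truth for e in grouped.get(t.key, [])]
    hits = integrate(truth_events, ds.ld.snps, ds.ld.markers, ds.ld.blocks,
                     r2_table=ds.ld.r2)
    expected = {t.key for t in ds.truth if t.expected_integration}
    got = {(h.event.mutation.hgvs_g, h.event.mirna_name) for h in hits}
    assert got == expected and len(hits) == 3
    # brute-force re-check of all three membership predicates
    for h in hits:
        chrom, start, end, _ = h.site_span
        assert h.germline.chrom == chrom and start <= h.germline.pos <= end
        d = min(abs(h.marker.pos - start), abs(h.marker.pos - end)) \
            if not start <= h.marker.pos <= end else 0
        assert d <= 100_000
        b = h.block
        assert b.start <= start and end <= b.end and b.start <= h.marker.pos <= b.end
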