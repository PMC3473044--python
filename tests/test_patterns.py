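import numpy as np
import pytest

from seedshift.errors import ValidationError
from seedshift.io import SomaticMutation, UtrRecord
from seedshift.patterns import (PositionalDistribution, dedupe_multi_utr,
                                recurrence_stats, relative_position, rolling_counts,
                                spectrum, substitution_class)
from seedshift.simulate import generate_recurrence_table

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@pytest.mark.parametrize("ref, alt, expected", [
    ("C", "T", "G>A/C>T"), ("G", "A", "G>A/C>T"),
    ("G", "T", "G>T/C>A"), ("C", "A", "G>T/C>A"),
    ("G", "C", "G>C/C>G"), ("C", "G", "G>C/C>G"),
    ("A", "G", "A>G/T>C"), ("T", "C", "A>G/T>C"),
    ("T", "A", "A>T/T>A"), ("A", "T", "A>T/T>A"),
    ("A", "C", "A>C/T>G"), ("T", "G", "A>C/T>G"),
])
def test_substitution_class_collapsing(ref, alt, expected):
    assert substitution_class(ref, alt) == expected
    # class assignment is invariant under simultaneous complementation
    assert substitution_class(_COMP[ref], _COMP[alt]) == expected


@pytest.mark.parametrize("ref, alt", [("CC", "GT"), ("A", "A"), ("N", "A")])
def test_substitution_class_rejects_invalid(ref, alt):
    with pytest.raises(ValidationError):
        substitution_class(ref, alt)


class TestSpectrum:
    def test_arithmetic(self):
        muts = [SomaticMutation("chr1", i + 1, "C", "T") for i in range(3)]
        muts.append(SomaticMutation("chr1", 10, "G", "T"))
        spec = spectrum(muts)
        assert spec.frequencies["G>A/C>T"] == 75.0
        assert spec.frequencies["G>T/C>A"] == 25.0
        assert abs(sum(spec.frequencies.values()) - 100.0) < 1e-9

    def test_empty_flagged(self):
        spec = spectrum([])
        assert spec.empty and spec.total == 0
        assert all(v == 0.0 for v in spec.frequencies.values())

    def test_complement_pairs_collapse_to_one_class(self):
        muts = [SomaticMutation("chr1", 1, "C", "T"),
                SomaticMutation("chr1", 2, "G", "A")]
        assert spectrum(muts).frequencies["G>A/C>T"] == 100.0

    def test_multibase_excluded_but_counted(self):
        muts = [SomaticMutation("chr1", 1, "C", "T"),
                SomaticMutation("chr1", 5, "CC", "GT")]
        spec = spectrum(muts)
        assert spec.total == 1 and spec.n_excluded == 1


class TestRelativePosition:
    def test_plus_strand(self):
        utr = UtrRecord("G", "T", "chr1", 1, 100, "+", "A" * 100)
        assert relative_position(SomaticMutation("chr1", 1, "A", "G"), utr) == 0.0
        assert relative_position(SomaticMutation("chr1", 51, "A", "G"), utr) == 0.5

    def test_minus_strand_five_prime_end_is_genomic_end(self):
        # on the minus strand the 5' end of the 3'UTR is the highest coordinate
        utr = UtrRecord("G", "T", "chr1", 101, 200, "-", "A" * 100)
        m = SomaticMutation("chr1", 200, "T", "G")
        assert relative_position(m, utr) == 0.0


class TestDedupeMultiUtr:
    u1 = UtrRecord("GENEA", "T1", "chr1", 1, 20, "+", "ACGTACGTACGTACGTACGT")
    u2 = UtrRecord("GENEB", "T2", "chr1", 5, 24, "+", "CGTACGTACGTACGTACGTA")
    u3 = UtrRecord("GENEA", "T3", "chr1", 1, 20, "+", "ACGTACGTACGTACGTACGT")

    def test_single_gene_kept(self):
        m = SomaticMutation("chr1", 2, "C", "A")
        assert dedupe_multi_utr([m], [self.u1]) == [m]

    def test_two_genes_different_utrs_removed(self):
        m = SomaticMutation("chr1", 10, "A", "C")
        assert dedupe_multi_utr([m], [self.u1, self.u2]) == []

    def test_two_transcripts_same_gene_kept(self):
        m = SomaticMutation("chr1", 10, "A", "C")
        assert dedupe_multi_utr([m], [self.u1, self.u3]) == [m]


class TestRollingCounts:
    def test_interval_membership(self):
        dist = rolling_counts([0.0, 0.01, 0.5], width=0.05, step=0.01)
        assert dist.centers[0] == 0.025
        assert dist.counts[0] == 2  # window [0.0, 0.05) holds 0.0 and 0.01

    def test_empty_positions(self):
        dist = rolling_counts([], width=0.05, step=0.01)
        assert all(c == 0 for c in dist.counts)

    def test_all_identical_positions(self):
        dist = rolling_counts([0.5] * 7, width=0.05, step=0.01)
        assert max(dist.counts) == 7
        band = [c for c in dist.counts if c > 0]
        assert all(c == 7 for c in band)

    def test_step_equal_width_is_histogram(self):
        rng = np.random.default_rng(1)
        positions = rng.uniform(0, 1, size=500).tolist()
        dist = rolling_counts(positions, width=0.05, step=0.05)
        assert sum(dist.counts) == 500

    def test_invalid_width(self):
        with pytest.raises(ValidationError):
            rolling_counts([0.5], width=0.0)


class TestRecurrence:
    def test_one_of_152_prints_066(self):
        muts = generate_recurrence_table(152, 1, np.random.default_rng(0))
        stats = recurrence_stats(muts)
        assert (stats.n_recurrent, stats.n_total, stats.percent) == (1, 152, 0.66)

    def test_116_of_28626_prints_041(self):
        muts = generate_recurrence_table(28626, 116, np.random.default_rng(0))
        stats = recurrence_stats(muts)
        assert (stats.n_recurrent, stats.n_total, stats.percent) == (116, 28626, 0.41)

    def test_all_unique(self):
        muts = generate_recurrence_table(10, 0, np.random.default_rng(0))
        stats = recurrence_stats(muts)
        assert (stats.n_recurrent, stats.percent) == (0, 0.0)

    def test_empty_undefined(self):
        stats = recurrence_stats([])
        assert stats.percent is None
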