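"""Variant classification, edit application, offset bookkeeping and liftover."""

import numpy as np
import pandas as pd
import pytest

from proteopolish.homopolymer_correction import (
    ConsistencyError,
    OverlapError,
    apply_corrections,
    cross_check,
    is_homopolymer_indel,
    label_locus_tags,
    liftover,
    reported_position,
    select_homopolymer_variants,
)
from proteopolish.records import (
    CoordinateError,
    CorrectionRecord,
    SuggestionRecord,
)

from conftest import cds, make_genome


def _variants(rows):
    return pd.DataFrame(rows, columns=["position", "ref", "alt"])


class TestHomopolymerClassification:
    def test_insertion_adjacent_to_run(self):
        #            123456789
        g = make_genome("CTAAAAGTC")
        recs = select_homopolymer_variants(_variants([(4, "-", "A")]), g)
        assert recs[0].homopolymer and recs[0].applied and recs[0].offset == 1

    def test_deletion_inside_run(self):
        g = make_genome("CTAAAAGTC")
        recs = select_homopolymer_variants(_variants([(4, "A", "-")]), g)
        assert recs[0].homopolymer and recs[0].offset == -1

    def test_insertion_completing_short_run_counts_itself(self):
        # two adjacent As + the inserted A reach min_run 3
        g = make_genome("CTAAGTCGT")
        recs = select_homopolymer_variants(_variants([(3, "-", "A")]), g)
        assert recs[0].homopolymer

    def test_isolated_insertion_not_homopolymer(self):
        g = make_genome("CTAGCTAGC")
        recs = select_homopolymer_variants(_variants([(4, "-", "A")]), g)
        assert not recs[0].homopolymer and not recs[0].applied

    def test_two_base_deletion_not_homopolymer(self):
        g = make_genome("CTATATGTC")
        recs = select_homopolymer_variants(
            _variants([(3, "AT", "-")]), g, alternate_positions={3}
        )
        assert not recs[0].homopolymer
        assert recs[0].offset == -2 and recs[0].applied  # corroborated -> applied

    def test_substitution_zero_offset(self):
        g = make_genome("CTAGCTAGC")
        recs = select_homopolymer_variants(
            _variants([(4, "G", "A")]), g, alternate_positions={4}
        )
        assert recs[0].offset == 0 and recs[0].is_substitution and recs[0].applied

    def test_uncorroborated_substitution_not_applied(self):
        g = make_genome("CTAGCTAGC")
        recs = select_homopolymer_variants(_variants([(4, "G", "A")]), g)
        assert not recs[0].applied

    def test_ref_mismatch_rejected(self):
        g = make_genome("CTAGCTAGC")
        with pytest.raises(ConsistencyError):
            select_homopolymer_variants(_variants([(4, "T", "A")]), g)

    def test_suggestion_locus_corroborates(self):
        g = make_genome("CTAGCTAGCAAA", [cds("L1", 1, 9)])
        recs = select_homopolymer_variants(
            _variants([(4, "G", "A")]), g, suggestion_loci={"L1"}
        )
        assert recs[0].applied and "suggestion_table" in recs[0].corroborations


class TestApplyCorrections:
    def test_empty_is_identity(self):
        g = make_genome("ACGTACGTAC", [cds("L1", 1, 9)])
        corrected, om = apply_corrections(g, [])
        assert corrected.sequence == g.sequence
        assert om.shift_at(5) == 0

    def test_insertion_deletion_substitution(self):
        g = make_genome("AAACCCGGGTTT")
        edits = [
            CorrectionRecord("a", 3, "-", "A", 1, True),     # AAA -> AAAA
            CorrectionRecord("b", 6, "C", "-", -1, True),    # CCC -> CC
            CorrectionRecord("c", 10, "T", "G", 0, True),    # T -> G
        ]
        corrected, om = apply_corrections(g, edits)
        assert corrected.sequence == "AAAACCGGGGTT"
        assert len(corrected) == len(g) + sum(e.offset for e in edits)
        assert om.shift_at(12) == 0

    def test_length_bookkeeping_random(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        g = make_genome(seq)
        edits = []
        for p in sorted(rng.choice(np.arange(10, 490, 10), size=12, replace=False)):
            kind = rng.integers(0, 3)
            base = seq[p - 1]
            if kind == 0:
                edits.append(CorrectionRecord("e", int(p), "-", "A", 1, True))
            elif kind == 1:
                edits.append(CorrectionRecord("e", int(p), base, "-", -1, True))
            else:
                alt = "A" if base != "A" else "C"
                edits.append(CorrectionRecord("e", int(p), base, alt, 0, True))
        corrected, _ = apply_corrections(g, edits)
        assert len(corrected) == 500 + sum(e.offset for e in edits)

    def test_unapplied_records_ignored(self):
        g = make_genome("ACGTACGTAC")
        rec = CorrectionRecord("a", 3, "G", "A", 0, False)
        corrected, _ = apply_corrections(g, [rec])
        assert corrected.sequence == g.sequence

    def test_overlapping_edits_rejected(self):
        g = make_genome("AAACCCGGGTTT")
        edits = [
            CorrectionRecord("a", 5, "CC", "-", -2, True),
            CorrectionRecord("b", 6, "C", "A", 0, True),
        ]
        with pytest.raises(OverlapError):
            apply_corrections(g, edits)

    def test_allele_mismatch_rejected(self):
        g = make_genome("AAACCCGGGTTT")
        with pytest.raises(ConsistencyError):
            apply_corrections(g, [CorrectionRecord("a", 5, "G", "A", 0, True)])

    def test_generator_round_trip(self, default_truth):
        corrected, _ = apply_corrections(
            default_truth.observed_genome, default_truth.injected_errors
        )
        assert corrected.sequence == default_truth.true_genome.sequence


class TestLiftover:
    def _map(self, sequence, edits):
        g = make_genome(sequence)
        return apply_corrections(g, edits)[1]

    def test_upstream_feature_unchanged(self):
        om = self._map("A" * 100, [CorrectionRecord("e", 50, "-", "C", 1, True)])
        [f] = liftover([cds("L1", 5, 20)], om)
        assert (f.start, f.end) == (5, 20)

    def test_downstream_shifts_by_prefix_sum(self):
        om = self._map("A" * 100, [CorrectionRecord("e", 10, "-", "C", 1, True)])
        [f] = liftover([cds("L1", 40, 60)], om)
        assert (f.start, f.end) == (41, 61)

    def test_feature_spanning_insertion_grows(self):
        om = self._map("A" * 100, [CorrectionRecord("e", 50, "-", "C", 1, True)])
        [f] = liftover([cds("L1", 40, 70)], om)
        assert (f.start, f.end) == (40, 71)

    def test_boundary_in_deleted_block_rejected(self):
        g = make_genome("AAACCTTTGG")
        om = apply_corrections(g, [CorrectionRecord("e", 4, "CC", "-", -2, True)])[1]
        with pytest.raises(CoordinateError, match="L1"):
            liftover([cds("L1", 5, 9)], om)

    def test_feature_sequences_preserved_around_edits(self, default_truth):
        """Lifted features on the corrected genome re-extract to the true
        genome's feature sequences."""
        corrected, om = apply_corrections(
            default_truth.observed_genome, default_truth.injected_errors
        )
        for f in corrected.features:
            tf = default_truth.true_genome.feature(f.locus_tag)
            assert corrected.subsequence(f.start, f.end) == \
                default_truth.true_genome.subsequence(tf.start, tf.end)


class TestReportedPositions:
    def test_table_conventions(self):
        g = make_genome("AAACCCGGGTTT")
        ins = CorrectionRecord("a", 3, "-", "A", 1, True)
        dele = CorrectionRecord("b", 6, "C", "-", -1, True)
        sub = CorrectionRecord("c", 10, "T", "G", 0, True)
        _, om = apply_corrections(g, [ins, dele, sub])
        assert reported_position(ins, om) == 4   # corrected coordinate of inserted base
        assert reported_position(dele, om) == 6  # former position of deleted base
        assert reported_position(sub, om) == 10  # +1 insertion and -1 deletion cancel


class TestCrossCheck:
    def test_suggestion_and_alternate_corroboration(self):
        recs = [
            CorrectionRecord("L1/L2", 100, "-", "A", 1, True),
            CorrectionRecord("L9", 500, "A", "G", 0, False),
        ]
        counts = cross_check(
            recs,
            suggestions=[SuggestionRecord(("L1", "L2"), "join")],
            alternate_positions={500},
        )
        assert "suggestion_table" in recs[0].corroborations
        assert "alternate_genome" in recs[1].corroborations
        assert counts == {"suggestion_table": 1, "alternate_genome": 1, "both": 0, "none": 0}

    def test_empty_suggestions_no_corroboration(self):
        recs = [CorrectionRecord("L1", 100, "-", "A", 1, True)]
        counts = cross_check(recs)
        assert recs[0].corroborations == set()
        assert counts["none"] == 1

    def test_abbreviated_pair_labels(self):
        assert label_locus_tags("Clst_0020/21") == ["Clst_0020", "Clst_0021"]
        assert label_locus_tags("Clst_0899/900") == ["Clst_0899", "Clst_0900"]
        assert label_locus_tags("Clst_1435") == ["Clst_1435"]
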