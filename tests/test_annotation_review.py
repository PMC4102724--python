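"""Pseudogene/join review rules, cluster detection and pathway summaries."""

import numpy as np
import pytest

from proteopolish.annotation_review import (
    detect_clusters,
    load_pathway_roles,
    pathway_presence,
    review_pseudogenes,
    summarize_clusters,
)
from proteopolish.homopolymer_correction import apply_corrections
from proteopolish.io_formats import read_table2
from proteopolish.records import (
    CorrectionRecord,
    GeneFeature,
    SuggestionRecord,
    ValidationError,
)

from conftest import cds, make_genome


def _join_world():
    """A real single ORF split in two by a frameshifting deletion.

    Truth: one 60-codon ORF.  The observed genome lost one base of an A-run
    mid-gene, so the annotation carries two part-genes (J1 upstream of the
    shift, J2 downstream).  The restoring correction is an insertion.
    """
    rng = np.random.default_rng(77)
    sense = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    codons = ["ATG"] + list(rng.choice(sense, size=20)) + ["AAA", "AAA"]
    codons += list(rng.choice(sense, size=36)) + ["TAA"]
    orf = "".join(codons)
    pre = "".join(rng.choice(list("ACGT"), size=60))
    post = "".join(rng.choice(list("ACGT"), size=60))
    true_seq = pre + orf + post
    run_pos = len(pre) + 21 * 3 + 1  # first A of the AAAAAA run
    observed_seq = true_seq[: run_pos - 1] + true_seq[run_pos:]  # drop one A
    split = run_pos + 20
    observed = make_genome(
        observed_seq,
        [
            cds("J1", len(pre) + 1, split, "+"),
            cds("J2", split + 1, len(pre) + len(orf) - 1, "+"),
        ],
    )
    correction = CorrectionRecord("J1/J2", run_pos, "-", "A", 1, True, homopolymer=True)
    return observed, correction


class TestReviewRules:
    def _genome(self):
        return make_genome(
            "A" * 500,
            [
                cds("P1", 10, 99, pseudo=True),
                cds("P2", 120, 299, pseudo=True),
            ],
        )

    def test_pseudogene_confirmed_at_zero_coverage(self):
        g = self._genome()
        [d] = review_pseudogenes(
            [SuggestionRecord(("P1",), "pseudogene")], {"P1": 0}, [], g
        )
        assert d.decision == "pseudogene_confirmed"

    def test_pseudogene_rejected_with_coverage(self):
        g = self._genome()
        [d] = review_pseudogenes(
            [SuggestionRecord(("P2",), "pseudogene")], {"P2": 8}, [], g
        )
        assert d.decision == "pseudogene_rejected"

    def test_join_applied_when_frame_restored(self):
        observed, correction = _join_world()
        corrected, _ = apply_corrections(observed, [correction])
        [d] = review_pseudogenes(
            [SuggestionRecord(("J1", "J2"), "join")],
            {"J1": 19, "J2": 0},
            [correction],
            observed,
            corrected_genome=corrected,
        )
        assert d.decision == "join_applied"
        assert d.frame_intact_after_correction

    def test_join_rejected_without_restoring_correction(self):
        observed, _ = _join_world()
        [d] = review_pseudogenes(
            [SuggestionRecord(("J1", "J2"), "join")],
            {"J1": 19, "J2": 0},
            [],
            observed,
        )
        assert d.decision == "join_rejected"

    def test_join_rejected_without_coverage(self):
        observed, correction = _join_world()
        corrected, _ = apply_corrections(observed, [correction])
        [d] = review_pseudogenes(
            [SuggestionRecord(("J1", "J2"), "join")],
            {"J1": 0, "J2": 0},
            [correction],
            observed,
            corrected_genome=corrected,
        )
        assert d.decision == "join_rejected"

    def test_unknown_locus_rejected(self):
        g = self._genome()
        with pytest.raises(ValidationError, match="NOPE"):
            review_pseudogenes([SuggestionRecord(("NOPE",), "pseudogene")], {}, [], g)

    def test_rules_are_total(self, default_truth):
        truth = default_truth
        cov = {f.locus_tag: 0.0 for f in truth.true_genome.features}
        decisions = review_pseudogenes(
            truth.suggestions, cov, [], truth.true_genome
        )
        assert len(decisions) == len(truth.suggestions)
        assert all(d.decision in (
            "pseudogene_confirmed", "pseudogene_rejected",
            "join_applied", "join_rejected", "no_change",
        ) for d in decisions)


class TestDetectClusters:
    def _genome(self, labels_strands):
        feats, pos = [], 1
        for i, (label, strand) in enumerate(labels_strands):
            feats.append(cds(f"G{i}", pos, pos + 89, strand))
            pos += 120
        return make_genome("A" * pos, feats)

    def test_consecutive_same_strand_one_cluster(self):
        g = self._genome([("cut", "+"), ("cut", "+"), ("cut", "+")])
        clusters = detect_clusters(g, {"G0": "cut", "G1": "cut", "G2": "cut"})
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_isolated_gene_is_singleton(self):
        g = self._genome([(None, "+"), ("cut", "+"), (None, "+")])
        clusters = detect_clusters(g, {"G1": "cut"})
        assert [c.locus_tags for c in clusters] == [["G1"]]

    def test_strand_switch_splits(self):
        g = self._genome([("cut", "+"), ("cut", "-"), ("cut", "-")])
        clusters = detect_clusters(g, {f"G{i}": "cut" for i in range(3)})
        assert [c.size for c in clusters] == [1, 2]

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        spec = [("cut" if rng.random() < 0.4 else None, "+" if rng.random() < 0.5 else "-")
                for _ in range(30)]
        g = self._genome(spec)
        labels = {f"G{i}": c for i, (c, _) in enumerate(spec) if c}
        clusters = detect_clusters(g, labels)
        clustered = [t for c in clusters for t in c.locus_tags]
        assert sorted(clustered) == sorted(labels)  # partition: each exactly once


class TestSummarizeClusters:
    def test_row_order_invariance(self):
        genes = read_table2()
        rng = np.random.default_rng(0)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        assert summarize_clusters(genes) == summarize_clusters(shuffled)

    def test_cut2_membership(self):
        summary = summarize_clusters(read_table2())
        assert summary["cut2_clusters"] == 2 and summary["cut2_genes"] == 8


class TestPathwayPresence:
    def _genome(self, products):
        feats = [cds(f"L{i}", 1 + 100 * i, 90 + 100 * i, product=p)
                 for i, p in enumerate(products)]
        return make_genome("A" * (100 * len(products) + 10), feats)

    def test_missing_transaldolase_flagged(self):
        g = self._genome(["transketolase", "xylose isomerase"])
        m = pathway_presence(g, {"pp": ["trk", "xyi", "tal"]})
        row = m.set_index("role").loc["tal"]
        assert row["missing"] and not row["gene_present"]

    def test_complete_pathway_no_flags(self):
        catalog = load_pathway_roles()
        products = []
        for role, pats in catalog["glycolysis"]:
            products.append(pats[0])
        g = self._genome(products)
        m = pathway_presence(g, {"glycolysis": [r for r, _ in catalog["glycolysis"]]})
        assert not m["missing"].any()

    def test_present_but_unsupported(self):
        g = self._genome(["6-phosphogluconolactonase"])
        m = pathway_presence(g, {"pp": ["pgl"]}, coverage_table={"L0": 0})
        row = m.set_index("role").loc["pgl"]
        assert row["gene_present"] and not row["peptide_support"]

    def test_supported_when_covered(self):
        g = self._genome(["transketolase"])
        m = pathway_presence(g, {"pp": ["trk"]}, coverage_table={"L0": 12})
        assert m.set_index("role").loc["trk", "peptide_support"]

    def test_unknown_role_rejected(self):
        g = self._genome(["enolase"])
        with pytest.raises(ValidationError, match="frobnicase"):
            pathway_presence(g, {"pp": ["frobnicase"]})
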