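"""Peptide-to-genome classification, novelty calling, coverage and RT checks."""

import numpy as np
import pytest

from proteopolish.peptide_mapping import (
    ClassifiedPeptide,
    PeptideHit,
    SixFrameIndex,
    call_alternate_frames_and_extensions,
    call_novel_genes,
    classify_peptides,
    map_peptides,
    predict_hydrophobicity,
    protein_peptide_coverage,
    validate_rt,
)
from proteopolish.proteogenomic_db import translate_frame
from proteopolish.records import GenomeRecord, PeptideID, ValidationError, reverse_complement
from proteopolish.synthetic_data import RT_INTERCEPT, RT_SLOPE, make_retention_times

from conftest import cds, make_genome


def _pid(seq, log_e=-3.0, rt=None):
    return PeptideID(seq, log_e, rt)


def _orf(rng, n_codons):
    codons = ["ATG"]
    sense = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    codons += list(rng.choice(sense, size=n_codons - 1))
    return "".join(codons) + "TAA"


@pytest.fixture(scope="module")
def toy():
    """120-codon ORF embedded mid-genome, forward strand."""
    rng = np.random.default_rng(42)
    pre = "".join(rng.choice(list("ACGT"), size=211))
    orf = _orf(rng, 120)
    post = "".join(rng.choice(list("ACGT"), size=307))
    start = len(pre) + 1
    end = len(pre) + len(orf)
    genome = make_genome(pre + orf + post, [cds("G1", start, end)])
    protein = translate_frame(orf, 1)[:-1]
    return genome, protein


class TestMapPeptides:
    def test_internal_peptide_assigned(self, toy):
        genome, protein = toy
        [cp] = map_peptides([_pid(protein[1:9])], genome)
        assert cp.category == "assigned"
        assert any(h.in_frame_cds and h.locus == "G1" for h in cp.hits)

    def test_absent_peptide_unassigned_no_hits(self, toy):
        genome, _ = toy
        [cp] = map_peptides([_pid("WWWWWWHHHW")], genome)
        assert cp.category == "unassigned" and cp.hits == []

    def test_reverse_strand_assignment(self):
        rng = np.random.default_rng(9)
        orf = _orf(rng, 60)
        pre = "".join(rng.choice(list("ACGT"), size=100))
        post = "".join(rng.choice(list("ACGT"), size=95))
        block = reverse_complement(orf)
        genome = make_genome(
            pre + block + post, [cds("R1", 101, 100 + len(block), strand="-")]
        )
        protein = translate_frame(orf, 1)[:-1]
        [cp] = map_peptides([_pid(protein[3:12])], genome)
        assert cp.category == "assigned"
        assert cp.hits[0].frame < 0

    def test_il_equivalent_mode(self, toy):
        genome, protein = toy
        idx = next(
            i for i in range(1, len(protein) - 9) if set(protein[i : i + 9]) & set("IL")
        )
        pep = protein[idx : idx + 9]
        flipped = pep.translate(str.maketrans("IL", "LI"))
        assert flipped != pep
        [strict] = map_peptides([_pid(flipped)], genome)
        [loose] = map_peptides([_pid(flipped)], genome, il_equivalent=True)
        assert strict.category == "unassigned"
        assert loose.category == "assigned"

    def test_sensitivity_one_on_synthetic_truth(self, default_truth):
        genome = default_truth.true_genome
        peps = [_pid(p) for ps in default_truth.true_peptides.values() for p in ps]
        for cp in map_peptides(peps, genome):
            assert cp.category == "assigned"

    def test_decoys_never_assigned(self, default_truth):
        genome = default_truth.true_genome
        peps = [_pid(p) for p in default_truth.decoy_peptides]
        for cp in map_peptides(peps, genome):
            assert cp.category == "unassigned" and not cp.hits


class TestNovelGeneCalls:
    def _hit_cp(self, seq, start, length_nt, frame=1):
        hit = PeptideHit(start=start, end=start + length_nt - 1, frame=frame, aa_index=0)
        return ClassifiedPeptide(peptide=_pid(seq), hits=[hit], category="unassigned")

    def test_two_nearby_hits_one_call(self):
        genome = make_genome("A" * 20000)
        cps = [self._hit_cp("PEPTIDEK", 1000, 24), self._hit_cp("PEPTIDER", 1300, 24)]
        calls = call_novel_genes(cps, genome)
        assert len(calls) == 1
        assert calls[0].span == (1000, 1323)
        assert all(cp.category == "novel_gene_evidence" for cp in cps)

    def test_distant_hits_no_call(self):
        genome = make_genome("A" * 20000)
        cps = [self._hit_cp("PEPTIDEK", 1000, 24), self._hit_cp("PEPTIDER", 11200, 24)]
        assert call_novel_genes(cps, genome) == []

    def test_single_hit_no_call(self):
        genome = make_genome("A" * 20000)
        assert call_novel_genes([self._hit_cp("PEPTIDEK", 1000, 24)], genome) == []

    def test_annotated_overlap_excluded(self):
        genome = make_genome("A" * 20000, [cds("G1", 900, 2400)])
        cps = [self._hit_cp("PEPTIDEK", 1000, 24), self._hit_cp("PEPTIDER", 1300, 24)]
        assert call_novel_genes(cps, genome) == []


class TestModelCalls:
    def test_planted_novelties_recovered(self, default_truth):
        truth = default_truth
        peps = [
            PeptideID(r.sequence, r.log_e, r.retention_time, int(r.spectra_count))
            for r in truth.peptide_table.itertuples(index=False)
            if r.log_e < -1
        ]
        classified, model_calls, novel_calls = classify_peptides(peps, truth.true_genome)
        nov = dict(truth.planted_novelties)
        assert len(novel_calls) == 1
        assert set(novel_calls[0].peptides) == set(nov["missed_gene"]["peptides"])
        assert (nov["extension"]["locus"], "extension") in model_calls
        assert (nov["alternate_frame"]["locus"], "alternate_frame") in model_calls
        assert len(model_calls) == 2

    def test_upstream_peptide_with_intervening_stop_not_extension(self):
        rng = np.random.default_rng(4)
        orf_a = _orf(rng, 30)  # upstream ORF ends with its own stop codon
        orf_b = _orf(rng, 60)
        # orf_a abuts orf_b: the stop of orf_a separates the two elements
        pre = "".join(rng.choice(list("ACGT"), size=99))  # keeps frame of both at +1
        genome = make_genome(
            pre + orf_a + orf_b,
            [cds("B", len(pre) + len(orf_a) + 1, len(pre) + len(orf_a) + len(orf_b))],
        )
        pep_a = translate_frame(orf_a, 1)[1:10]
        classified = map_peptides([_pid(pep_a)], genome)
        calls = call_alternate_frames_and_extensions(classified, genome)
        assert ("B", "extension") not in calls


class TestProteinCoverage:
    def test_zero_and_partial_coverage(self, toy):
        genome, protein = toy
        classified = map_peptides([_pid(protein[0:10])], genome)
        table = protein_peptide_coverage(classified, genome)
        row = table.set_index("locus_tag").loc["G1"]
        assert row["protein_length"] == 120
        assert row["covered_residues"] == 10
        assert row["percent"] == 8  # 10/120 = 8.33 -> 8

    def test_full_tiling_is_hundred(self, toy):
        genome, protein = toy
        peps = [_pid(protein[i : i + 10]) for i in range(0, 120, 10)]
        table = protein_peptide_coverage(map_peptides(peps, genome), genome)
        assert table.set_index("locus_tag").loc["G1", "percent"] == 100

    def test_no_peptides_zero(self, toy):
        genome, _ = toy
        table = protein_peptide_coverage([], genome)
        assert table.set_index("locus_tag").loc["G1", "percent"] == 0


class TestRetention:
    def test_leucine_beats_glycine(self):
        assert predict_hydrophobicity("LLLL") > predict_hydrophobicity("GGGG")

    def test_unknown_residue_named(self):
        with pytest.raises(ValidationError, match="B"):
            predict_hydrophobicity("AAB", {"A": 1.0})

    def test_noiseless_linear_r2_is_one(self):
        peps = ["GGGGGGK", "AAAAAAK", "LLLLLLK", "FFFFFFK", "VVVVVVK", "SSSSSSK"]
        rts = make_retention_times(peps, noise_sd=0.0)
        ids = [PeptideID(p, -3.0, rt) for p, rt in zip(peps, rts)]
        assert validate_rt(ids) == pytest.approx(1.0, abs=1e-9)

    def test_exact_linear_model(self):
        rts = make_retention_times(["AAAAAAK"], noise_sd=0.0)
        assert rts[0] == pytest.approx(RT_INTERCEPT + RT_SLOPE * predict_hydrophobicity("AAAAAAK"))

    def test_too_few_points_is_zero(self):
        assert validate_rt([PeptideID("AAAAK", -2.0, 10.0)]) == 0.0
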