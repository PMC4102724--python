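"""Synthetic genomes, sequencing errors, depth tracks and peptide tables.

The generator emulates the data situation of a pyrosequencing-era bacterial
genome project polished with transcriptome and proteome evidence:

* a circular genome carrying non-overlapping protein-coding ORFs (ATG..stop,
  stop-free on their strand) and a few RNA genes;
* single-base homopolymer indel errors (the characteristic pyrosequencing
  failure mode) injected into runs of >= ``min_run`` identical bases, plus a
  few substitution miscalls;
* a near-uniform per-base transcript depth track with optional uncovered
  gaps;
* tryptic peptide identifications (<=1 missed cleavage, length >= 7) sampled
  from a detectability-thinned subset of annotated proteins, diluted with a
  configured fraction of residue-shuffled decoys;
* three planted proteogenomic novelties: an unannotated ORF supported by two
  peptides, a gene whose annotated start lies downstream of two peptide
  hits, and an out-of-frame peptide inside an annotated gene.

Everything is drawn from a single seeded random stream, so one integer
reproduces a dataset byte for byte.  Error injection is recorded as the
inverse corrections that restore the true genome exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats
from .homopolymer_correction import apply_corrections, is_homopolymer_indel
from .proteogenomic_db import translate_frame, tryptic_digest, FRAMES
from .records import (
    CorrectionRecord,
    GeneFeature,
    GenomeRecord,
    SuggestionRecord,
    reverse_complement,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_CODON_AA = {c: translate_frame(c, 1) for c in _SENSE_CODONS}


class GenerationError(RuntimeError):
    """The requested synthetic dataset cannot be constructed."""


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Defaults scale the study organism down ~50x (60 kb, 40 genes) while
    keeping the evidence structure: an absolute homopolymer-error count in
    the tens, 68% of proteins detectable, ~4 peptides per detected protein
    and ~4.5% spurious identifications.
    """

    seed: int = 0
    genome_length: int = 60_000
    gene_count: int = 40
    gc_fraction: float = 0.40
    homopolymer_error_rate: float = 0.5  # errors per kb, restricted to runs >= min_run
    min_run: int = 3
    depth_mean: float = 25.0
    uncovered_gap_count: int = 2
    protein_detect_prob: float = 0.68
    peptides_per_detected_protein: float = 4.0
    spurious_peptide_fraction: float = 0.045
    substitution_error_count: int = 2
    spurious_variant_count: int = 3
    pseudo_gene_count: int = 2
    rna_gene_count: int = 4
    protein_len_range: tuple[int, int] = (80, 280)
    rt_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "protein_detect_prob",
            "spurious_peptide_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.homopolymer_error_rate < 0 or self.depth_mean < 1:
            raise ValueError("rates must be non-negative and depth_mean >= 1")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.genome_length < 50 * self.gene_count:
            raise ValueError(
                f"genome_length {self.genome_length} < 50 x gene_count {self.gene_count}"
            )


@dataclass
class SimTruth:
    """Ground truth plus all pipeline inputs for one simulated dataset."""

    config: SimConfig
    true_genome: GenomeRecord
    observed_genome: GenomeRecord
    injected_errors: list[CorrectionRecord]  # inverse edits restoring truth
    detected_loci: set[str]
    planted_novelties: list[tuple[str, dict]]
    peptide_table: pd.DataFrame
    depth_track: pd.DataFrame
    variant_table: pd.DataFrame
    suggestions: list[SuggestionRecord]
    decoy_peptides: list[str]
    true_peptides: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence construction helpers


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=_base_probs(gc)))


def _codon_weights(gc: float, codons: list[str]) -> np.ndarray:
    probs = dict(zip("ACGT", _base_probs(gc)))
    w = np.array([probs[c[0]] * probs[c[1]] * probs[c[2]] for c in codons])
    return w / w.sum()


def _sample_codons(
    rng: np.random.Generator, n: int, gc: float, exclude_residues: str = ""
) -> list[str]:
    codons = [c for c in _SENSE_CODONS if _CODON_AA[c] not in exclude_residues]
    return list(rng.choice(codons, size=n, p=_codon_weights(gc, codons)))


def _codon_for(rng: np.random.Generator, residue: str, gc: float) -> str:
    codons = [c for c in _SENSE_CODONS if _CODON_AA[c] == residue]
    return str(rng.choice(codons, p=_codon_weights(gc, codons)))


def _make_cds(rng: np.random.Generator, n_aa: int, gc: float) -> str:
    """ATG + (n_aa - 1) sense codons + stop: a clean ORF on its strand."""
    codons = ["ATG"] + _sample_codons(rng, n_aa - 1, gc) + [str(rng.choice(STOP_CODONS))]
    return "".join(codons)


def _make_extension_cds(rng: np.random.Generator, n_aa: int, gc: float) -> str:
    """ORF whose first 24 codons yield two clean tryptic peptides.

    Residues: M + 9 x [no K/R/P/M] + K + 10 x [no K/R/P/M] + K + 2 spacers +
    M + the rest.  Annotating the start at codon 24 (the second M) leaves the
    two leading tryptic peptides (residues 0-10 and 11-21) upstream of the
    annotated start, in frame, with no intervening stop.
    """
    plain = "ACDEFGHILNQSTVWY"
    codons = [_codon_for(rng, "M", gc)]
    codons += [_codon_for(rng, str(rng.choice(list(plain))), gc) for _ in range(9)]
    codons += [_codon_for(rng, "K", gc)]
    codons += [_codon_for(rng, str(rng.choice(list(plain))), gc) for _ in range(10)]
    codons += [_codon_for(rng, "K", gc)]
    codons += [_codon_for(rng, str(rng.choice(list(plain))), gc) for _ in range(2)]
    codons += [_codon_for(rng, "M", gc)]
    codons += _sample_codons(rng, n_aa - len(codons), gc)
    codons += [str(rng.choice(STOP_CODONS))]
    return "".join(codons)


EXTENSION_OFFSET_NT = 72  # annotated start sits 24 codons downstream of truth


def _cds_translation(genome: GenomeRecord, f: GeneFeature) -> str:
    nt = genome.subsequence(f.start, f.end)
    if f.strand == "-":
        nt = reverse_complement(nt)
    aa = translate_frame(nt, 1)
    return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# the generator


def simulate(config: SimConfig, outdir: Optional[Path] = None) -> SimTruth:
    """Generate one dataset; deterministic for a fixed ``config.seed``.

    When ``outdir`` is given, all pipeline input files (genome FASTA +
    annotation TSV, depth TSV, variant TSV, peptide TSV, suggestion TSV) and
    a ``truth.json`` are written there.
    """
    rng = np.random.default_rng(config.seed)
    layout = _build_true_genome(rng, config)
    true_genome: GenomeRecord = layout["genome"]

    error_records = _inject_errors(rng, config, true_genome, layout)
    observed_genome, offset_map = apply_corrections(true_genome, error_records)
    observed_genome = GenomeRecord(
        id=true_genome.id,
        sequence=observed_genome.sequence,
        circular=True,
        features=observed_genome.features,
    )
    injected = _inverse_corrections(error_records, offset_map)
    # sanity: the inverse edits must restore the true sequence exactly
    restored, _ = apply_corrections(observed_genome, injected)
    if restored.sequence != true_genome.sequence:
        raise GenerationError("internal error: injected errors are not invertible")

    variant_table = _variant_table(rng, config, observed_genome, injected)
    depth_track = _depth_track(rng, config, observed_genome)
    peptides, truth_extra = _peptide_table(rng, config, true_genome, layout)
    suggestions = _suggestions(layout)

    truth = SimTruth(
        config=config,
        true_genome=true_genome,
        observed_genome=observed_genome,
        injected_errors=injected,
        detected_loci=truth_extra["detected_loci"],
        planted_novelties=layout["novelties"],
        peptide_table=peptides,
        depth_track=depth_track,
        variant_table=variant_table,
        suggestions=suggestions,
        decoy_peptides=truth_extra["decoys"],
        true_peptides=truth_extra["true_peptides"],
    )
    if outdir is not None:
        _write_outputs(truth, Path(outdir))
    return truth


def _build_true_genome(rng: np.random.Generator, config: SimConfig) -> dict:
    gc = config.gc_fraction
    n_genes = config.gene_count
    if n_genes < 3:
        raise GenerationError("need at least 3 genes to plant the novelty scenarios")

    # which gene index gets which special role
    roles = rng.choice(n_genes, size=1 + config.pseudo_gene_count, replace=False)
    extension_idx = int(roles[0])
    pseudo_idx = {int(i) for i in roles[1:]}
    missed_slot = int(rng.integers(0, n_genes))  # ORF inserted before this gene

    # hand out real pathway product names (minus transaldolase, the planted
    # pathway hole) so annotation review has something to match
    from .annotation_review import load_pathway_roles

    product_pool = [
        pats[0]
        for steps in load_pathway_roles().values()
        for role, pats in steps
        if role != "tal"
    ]
    rng.shuffle(product_pool)

    rna_kinds = (["tRNA", "tRNA", "rRNA", "misc_RNA"] * (config.rna_gene_count // 4 + 1))[
        : config.rna_gene_count
    ]
    rna_lengths = {"tRNA": 76, "rRNA": 1500, "misc_RNA": 200}

    parts: list[str] = []
    features: list[GeneFeature] = []
    novelties: list[tuple[str, dict]] = []
    pos = 0  # 0-based length so far

    def intergenic() -> None:
        nonlocal pos
        n = int(rng.integers(120, 400))
        parts.append(_random_bases(rng, n, gc))
        pos += n

    intergenic()
    missed_orf: dict = {}
    extension_gene: dict = {}
    lo, hi = config.protein_len_range
    for gi in range(n_genes):
        if gi == missed_slot:
            # unannotated ORF: present in sequence, absent from annotation
            n_aa = int(rng.integers(100, 160))
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _make_cds(rng, n_aa, gc)
            block = cds if strand == "+" else reverse_complement(cds)
            start, end = pos + 1, pos + len(block)
            parts.append(block)
            pos += len(block)
            missed_orf = {"start": start, "end": end, "strand": strand, "n_aa": n_aa}
            intergenic()
        n_aa = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if gi == extension_idx:
            cds = _make_extension_cds(rng, n_aa, gc)
        else:
            cds = _make_cds(rng, n_aa, gc)
        block = cds if strand == "+" else reverse_complement(cds)
        start, end = pos + 1, pos + len(block)
        parts.append(block)
        pos += len(block)
        tag = f"SYN_{gi + 1:04d}"
        if gi == extension_idx:
            # annotated start is 24 codons downstream of the true start
            if strand == "+":
                feat = GeneFeature(tag, start + EXTENSION_OFFSET_NT, end, strand, "CDS",
                                   "hypothetical protein (short-started)")
            else:
                feat = GeneFeature(tag, start, end - EXTENSION_OFFSET_NT, strand, "CDS",
                                   "hypothetical protein (short-started)")
            extension_gene = {"locus": tag, "true_start": start, "true_end": end,
                              "strand": strand}
        else:
            if gi in pseudo_idx or not product_pool:
                product = "hypothetical protein"
            else:
                product = product_pool.pop()
            feat = GeneFeature(tag, start, end, strand, "CDS", product,
                               pseudo=gi in pseudo_idx)
        features.append(feat)
        intergenic()

    for ri, kind in enumerate(rna_kinds):
        n = rna_lengths[kind]
        start, end = pos + 1, pos + n
        parts.append(_random_bases(rng, n, gc))
        pos += n
        features.append(
            GeneFeature(f"SYNR_{ri + 1:03d}", start, end,
                        "+" if rng.random() < 0.5 else "-", kind, f"synthetic {kind}")
        )
        intergenic()

    if pos > config.genome_length:
        raise GenerationError(
            f"placed features need {pos} bp but genome_length is {config.genome_length}; "
            "increase genome_length or reduce gene_count/protein_len_range"
        )
    parts.append(_random_bases(rng, config.genome_length - pos, gc))
    sequence = "".join(parts)
    genome = GenomeRecord(id="synthetic_chr", sequence=sequence, circular=True,
                          features=features)

    novelties.append(("missed_gene", missed_orf))
    novelties.append(("extension", extension_gene))
    return {
        "genome": genome,
        "novelties": novelties,
        "extension_gene": extension_gene,
        "missed_orf": missed_orf,
        "pseudo_tags": {features_tag.locus_tag for features_tag in features if features_tag.pseudo},
    }


_RUN_RE = re.compile(r"(.)\1{2,}")


def _inject_errors(
    rng: np.random.Generator, config: SimConfig, true_genome: GenomeRecord, layout: dict
) -> list[CorrectionRecord]:
    """Plant homopolymer indels (in runs >= min_run) and substitutions, as
    edits *of the true genome* in true coordinates."""
    seq = true_genome.sequence
    n_err = int(round(config.homopolymer_error_rate * len(seq) / 1000.0))
    runs = [
        (m.start() + 1, m.end(), m.group(1))
        for m in _RUN_RE.finditer(seq)
        if m.end() - m.start() >= config.min_run and m.start() >= 1
    ]
    if n_err > len(runs):
        raise GenerationError(
            f"requested {n_err} homopolymer errors but only {len(runs)} runs of "
            f">= {config.min_run} identical bases exist"
        )
    picked = sorted(rng.choice(len(runs), size=n_err, replace=False))
    records: list[CorrectionRecord] = []
    for ri in picked:
        run_start, run_end, base = runs[ri]
        if rng.random() < 0.5:  # sequencing called one base too many
            records.append(
                CorrectionRecord("err", run_start, "-", base, 1, True, homopolymer=True)
            )
        else:  # one base too few
            records.append(
                CorrectionRecord("err", run_start, base, "-", -1, True, homopolymer=True)
            )

    taken = {p for r in records for p in range(r.position - 1, r.position + 2)}
    n_sub = config.substitution_error_count
    tries = 0
    while n_sub > 0 and tries < 10_000:
        tries += 1
        p = int(rng.integers(2, len(seq)))
        if p in taken:
            continue
        ref = seq[p - 1]
        if seq[p - 2] == ref or seq[p] == ref:  # keep substitutions out of runs
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        records.append(CorrectionRecord("err", p, ref, alt, 0, True, homopolymer=False))
        taken.update(range(p - 1, p + 2))
        n_sub -= 1
    if n_sub > 0:
        raise GenerationError("could not place the requested substitution errors")
    records.sort(key=lambda r: r.position)
    return records


def _inverse_corrections(error_records, offset_map) -> list[CorrectionRecord]:
    """Express the restoring edits in observed-genome coordinates."""
    out = []
    for r in error_records:
        before = offset_map.shift_at(r.position)
        if r.is_insertion:  # error added a base after r.position -> delete it
            out.append(r.inverse(r.position + before + 1))
        elif r.is_deletion:  # error removed the base at r.position -> re-insert
            out.append(
                CorrectionRecord(r.interval_label, r.position - 1 + before, "-", r.original,
                                 1, True, homopolymer=r.homopolymer)
            )
        else:
            out.append(r.inverse(r.position + before))
    out.sort(key=lambda r: r.position)
    return out


def _variant_table(
    rng: np.random.Generator,
    config: SimConfig,
    observed: GenomeRecord,
    injected: list[CorrectionRecord],
) -> pd.DataFrame:
    """The transcript-alignment variant calls: every true correction plus a
    few uncorroborated spurious calls outside homopolymer context."""
    rows = []
    for r in injected:
        rows.append(
            {
                "position": r.position,
                "ref": r.original,
                "alt": r.corrected,
                "alt_genome": "Y" if r.is_substitution else "N",
                "truth": True,
            }
        )
    taken = {r.position + d for r in injected for d in (-2, -1, 0, 1, 2)}
    seq = observed.sequence
    placed, tries = 0, 0
    while placed < config.spurious_variant_count and tries < 20_000:
        tries += 1
        p = int(rng.integers(2, len(seq)))
        if p in taken:
            continue
        if placed % 2 == 0:  # spurious substitution, uncorroborated
            ref = seq[p - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            if is_homopolymer_indel(seq, p, ref, alt, config.min_run):
                continue
            rows.append({"position": p, "ref": ref, "alt": alt, "alt_genome": "N",
                         "truth": False})
        else:  # spurious insertion outside any homopolymer context
            alt = str(rng.choice(list("ACGT")))
            if is_homopolymer_indel(seq, p, "-", alt, config.min_run):
                continue
            rows.append({"position": p, "ref": "-", "alt": alt, "alt_genome": "N",
                         "truth": False})
        taken.update(range(p - 2, p + 3))
        placed += 1
    if placed < config.spurious_variant_count:
        raise GenerationError("could not place the requested spurious variants")
    df = pd.DataFrame(rows).sort_values("position", kind="stable").reset_index(drop=True)
    return df


def _depth_track(
    rng: np.random.Generator, config: SimConfig, observed: GenomeRecord
) -> pd.DataFrame:
    length = len(observed)
    depth = 1 + rng.poisson(max(config.depth_mean - 1, 0), size=length)
    for _ in range(config.uncovered_gap_count):
        gap_len = int(rng.integers(200, 600))
        gap_start = int(rng.integers(0, max(length - gap_len, 1)))
        depth[gap_start : gap_start + gap_len] = 0
    pos = np.nonzero(depth)[0] + 1
    return pd.DataFrame({"position": pos, "depth": depth[pos - 1].astype(float)})


def _peptide_table(
    rng: np.random.Generator, config: SimConfig, true_genome: GenomeRecord, layout: dict
) -> tuple[pd.DataFrame, dict]:
    pseudo_tags = layout["pseudo_tags"]
    cds = [f for f in true_genome.cds_features() if not f.pseudo]
    detected: set[str] = set()
    true_peptides: dict[str, list[str]] = {}
    rows: list[dict] = []

    for f in cds:
        if rng.random() >= config.protein_detect_prob:
            continue
        detected.add(f.locus_tag)
        protein = _cds_translation(true_genome, f)
        # internal fragments only: an N-terminal peptide is not a digest
        # product of the surrounding stop-to-stop element
        frags = sorted(
            {p for p in tryptic_digest(protein) if not protein.startswith(p)}
        )
        if not frags:
            continue
        k = min(len(frags), max(1, int(rng.poisson(config.peptides_per_detected_protein))))
        chosen = sorted(rng.choice(len(frags), size=k, replace=False))
        true_peptides[f.locus_tag] = [frags[i] for i in chosen]
        for pep in true_peptides[f.locus_tag]:
            rows.append(_id_row(rng, pep, decoy=False))

    novelty_peps = _novelty_peptides(rng, true_genome, layout)
    for kind, peps in novelty_peps.items():
        for pep in peps:
            rows.append(_id_row(rng, pep, decoy=False))

    n_true = len(rows)
    n_decoy = int(round(
        config.spurious_peptide_fraction * n_true / max(1 - config.spurious_peptide_fraction, 1e-9)
    ))
    translations = [translate_frame(true_genome.sequence, fr) for fr in FRAMES]
    decoys: list[str] = []
    pool = [r["sequence"] for r in rows] or ["SAMPLEPEPTIDEK"]
    attempts = 0
    while len(decoys) < n_decoy:
        attempts += 1
        if attempts > 50 * (n_decoy + 1):
            raise GenerationError("could not shuffle decoys clear of the genome")
        src = pool[int(rng.integers(0, len(pool)))]
        cand = "".join(rng.permutation(list(src)))
        if cand != src and all(cand not in t for t in translations):
            decoys.append(cand)
            rows.append(_id_row(rng, cand, decoy=True))

    # a few identifications above the reporting cutoff (dropped by the reader)
    for _ in range(3):
        src = pool[int(rng.integers(0, len(pool)))]
        rows.append(_id_row(rng, src, decoy=False, log_e=float(rng.uniform(-0.9, -0.1))))

    decoy_flags = [bool(r.pop("decoy")) for r in rows]
    seqs = [r["sequence"] for r in rows]
    rts = make_retention_times(seqs, config.rt_noise_sd, decoy_flags, rng)
    for r, rt in zip(rows, rts):
        r["retention_time"] = round(rt, 3)
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    layout["novelty_peptides"] = novelty_peps
    for kind, payload in layout["novelties"]:
        payload["peptides"] = novelty_peps.get(kind, [])
    extra = {"detected_loci": detected, "true_peptides": true_peptides, "decoys": decoys}
    return df, extra


def _id_row(rng, sequence: str, decoy: bool, log_e: Optional[float] = None) -> dict:
    return {
        "sequence": sequence,
        "log_e": round(float(rng.uniform(-8.0, -1.5)) if log_e is None else log_e, 2),
        "spectra_count": int(1 + rng.poisson(2)),
        "decoy": decoy,
    }


def _novelty_peptides(
    rng: np.random.Generator, true_genome: GenomeRecord, layout: dict
) -> dict[str, list[str]]:
    """Peptides evidencing the planted missed gene, start extension, and
    alternate reading frame; each checked to map uniquely."""
    from .peptide_mapping import SixFrameIndex  # deferred: avoids import cycle

    index = SixFrameIndex(true_genome)
    out: dict[str, list[str]] = {}

    orf = layout["missed_orf"]
    nt = true_genome.subsequence(orf["start"], orf["end"])
    if orf["strand"] == "-":
        nt = reverse_complement(nt)
    aa = translate_frame(nt, 1).rstrip("*")
    frags = [p for p in tryptic_digest(aa, max_missed=0, min_len=9) if _unique_hit(index, p)]
    if len(frags) < 2:
        raise GenerationError("missed ORF yields fewer than two uniquely mapping peptides")
    out["missed_gene"] = [frags[0], frags[len(frags) // 2 if len(frags) > 2 else 1]]

    ext = layout["extension_gene"]
    if ext["strand"] == "+":
        ext_nt = true_genome.subsequence(ext["true_start"], ext["true_start"] + EXTENSION_OFFSET_NT - 1)
    else:
        ext_nt = reverse_complement(
            true_genome.subsequence(ext["true_end"] - EXTENSION_OFFSET_NT + 1, ext["true_end"])
        )
    ext_aa = translate_frame(ext_nt, 1)  # 24 engineered residues: M..K | ..K | ..
    pep1, pep2 = ext_aa[0:11], ext_aa[11:22]
    for pep in (pep1, pep2):
        if not _unique_hit(index, pep):
            raise GenerationError(f"extension peptide {pep!r} does not map uniquely")
    out["extension"] = [pep1, pep2]

    alt = _alternate_frame_peptide(rng, true_genome, index, layout)
    out["alternate_frame"] = [alt["peptide"]]
    layout["novelties"].append(("alternate_frame", alt))
    return out


def _unique_hit(index, peptide: str) -> bool:
    hits = index.find_peptide(peptide)
    return len(hits) == 1


def _alternate_frame_peptide(rng, true_genome: GenomeRecord, index, layout: dict) -> dict:
    """A stop-free >=10-codon window inside an annotated CDS read in a
    different frame, whose translation maps only there."""
    special = {layout["extension_gene"]["locus"]} | layout["pseudo_tags"]
    candidates = [f for f in true_genome.cds_features() if f.locus_tag not in special]
    order = rng.permutation(len(candidates))
    win = 12
    for ci in order:
        f = candidates[int(ci)]
        cds_frame = index.cds_frames[f.locus_tag][0]
        for frame in FRAMES:
            if frame == cds_frame:
                continue
            aa = index.translations[frame]
            lo_idx, hi_idx = _aa_window_inside(len(true_genome), frame, f.start + 3, f.end - 3)
            for start in range(lo_idx, hi_idx - win + 1):
                window = aa[start : start + win]
                if "*" in window or "X" in window:
                    continue
                hits = index.find_peptide(window)
                if len(hits) == 1 and not hits[0].in_frame_cds:
                    return {
                        "locus": f.locus_tag,
                        "frame": frame,
                        "cds_frame": cds_frame,
                        "peptide": window,
                    }
    raise GenerationError("no alternate-frame window found in any annotated gene")


def _aa_window_inside(length: int, frame: int, nt_lo: int, nt_hi: int) -> tuple[int, int]:
    """Range of 0-based aa indices of `frame` whose codons lie within [nt_lo, nt_hi]."""
    f = abs(frame)
    if frame > 0:
        lo = max(0, -(-(nt_lo - f) // 3))
        hi = (nt_hi - 2 - f) // 3 + 1
    else:
        k_lo, k_hi = length + 1 - nt_hi, length + 1 - nt_lo
        lo = max(0, -(-(k_lo - f) // 3))
        hi = (k_hi - 2 - f) // 3 + 1
    return lo, max(lo, hi)


def _suggestions(layout: dict) -> list[SuggestionRecord]:
    out = [SuggestionRecord((tag,), "pseudogene") for tag in sorted(layout["pseudo_tags"])]
    out.append(SuggestionRecord((layout["extension_gene"]["locus"],), "extend"))
    for kind, payload in layout["novelties"]:
        if kind == "alternate_frame":
            out.append(SuggestionRecord((payload["locus"],), "alternate_frame"))
    return out


# ---------------------------------------------------------------------------
# retention times


RT_INTERCEPT = 8.0  # min
RT_SLOPE = 0.55  # min per hydrophobicity unit


def make_retention_times(
    peptides: list[str],
    noise_sd: float,
    decoy_flags: Optional[list[bool]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[float]:
    """Retention times: linear in predicted hydrophobicity (+ Gaussian noise)
    for genuine peptides; uniform over the elution window for decoys."""
    from .peptide_mapping import predict_hydrophobicity
    from .io_formats import read_retention_coefficients

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    flags = decoy_flags if decoy_flags is not None else [False] * len(peptides)
    coeffs = read_retention_coefficients()
    hydro = [predict_hydrophobicity(p, coeffs) for p in peptides]
    true_rts = [RT_INTERCEPT + RT_SLOPE * h for h, fl in zip(hydro, flags) if not fl]
    lo = min(true_rts) if true_rts else RT_INTERCEPT
    hi = max(true_rts) if true_rts else RT_INTERCEPT + 40.0
    if hi - lo < 1.0:
        hi = lo + 40.0
    out = []
    for h, fl in zip(hydro, flags):
        if fl:
            out.append(float(rng.uniform(lo, hi)))
        else:
            out.append(RT_INTERCEPT + RT_SLOPE * h + float(rng.normal(0.0, noise_sd)))
    return out


# ---------------------------------------------------------------------------
# file emission


def _write_outputs(truth: SimTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_genome(
        truth.observed_genome, outdir / "genome.fasta", outdir / "annotation.tsv"
    )
    io_formats.write_depth_track(truth.depth_track, outdir / "depth.tsv")
    io_formats.write_variants(
        truth.variant_table.drop(columns=["truth"]), outdir / "variants.tsv"
    )
    truth.peptide_table.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
    io_formats.write_suggestions(truth.suggestions, outdir / "suggestions.tsv")
    payload = {
        "config": asdict(truth.config),
        "true_sequence": truth.true_genome.sequence,
        "true_features": [
            [f.locus_tag, f.start, f.end, f.strand, f.kind, f.product, f.pseudo]
            for f in truth.true_genome.features
        ],
        "injected_errors": [
            [r.position, r.original, r.corrected, r.offset, r.homopolymer]
            for r in truth.injected_errors
        ],
        "detected_loci": sorted(truth.detected_loci),
        "planted_novelties": [[k, v] for k, v in truth.planted_novelties],
        "decoy_peptides": truth.decoy_peptides,
        "true_peptides": truth.true_peptides,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=0, sort_keys=True)
        fh.write("\n")
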