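"""Mapping identified peptides onto the genome and classifying the misfits.

Each peptide passing the expectation-value filter is searched exactly
against all six reading-frame translations of the genome.  A peptide with an
in-frame hit inside an annotated CDS is *assigned*.  Unassigned peptides
carry the proteogenomic signal:

* ``alternate_frame`` — the hit lies inside an annotated CDS span but in a
  different reading frame (the gene model's frame is wrong);
* ``extension`` — the hit lies upstream of a CDS start, in the CDS's frame,
  inside the same stop-to-stop element (the annotated start is too far
  downstream);
* ``novel_gene_evidence`` — two or more same-frame peptides with nearby
  coordinates overlapping no annotation (a missed gene);
* ``unassigned`` — no genomic hit at all (decoy or off-genome peptide).

Identification quality is validated globally by correlating an additive
hydrophobicity prediction with observed chromatographic retention time:
genuine assignments correlate strongly, spurious ones do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import read_retention_coefficients
from .proteogenomic_db import FRAMES, frame_aa_to_genome, frame_of_interval, translate_frame
from .records import GeneFeature, GenomeRecord, PeptideID, ValidationError
from .coverage_maps import round_half_up

PROXIMITY_WINDOW = 2000  # bp; "nearby coordinates" for grouping novel-gene evidence

CATEGORIES = ("assigned", "novel_gene_evidence", "alternate_frame", "extension", "unassigned")


@dataclass(frozen=True)
class PeptideHit:
    """One exact occurrence of a peptide in a frame translation."""

    start: int  # forward-strand nt coordinates, 1-based inclusive
    end: int
    frame: int
    aa_index: int  # 0-based residue index within the frame translation
    locus: Optional[str] = None  # an overlapping CDS, if any
    in_frame_cds: bool = False


@dataclass
class ClassifiedPeptide:
    peptide: PeptideID
    hits: list[PeptideHit] = field(default_factory=list)
    category: str = "unassigned"


@dataclass(frozen=True)
class NovelGeneCall:
    """Evidence for an unannotated protein: >=2 same-frame nearby peptides."""

    peptides: tuple[str, ...]
    frame: int
    span: tuple[int, int]
    support_note: str = ""


class SixFrameIndex:
    """Cached six-frame translations of a genome with CDS frame bookkeeping."""

    def __init__(self, genome: GenomeRecord, il_equivalent: bool = False):
        self.genome = genome
        self.il_equivalent = il_equivalent
        self.translations: dict[int, str] = {}
        for frame in FRAMES:
            aa = translate_frame(genome.sequence, frame)
            self.translations[frame] = aa.replace("I", "L") if il_equivalent else aa
        # per-CDS: signed frame, aa index of its first codon, aa index where
        # its stop-to-stop element begins (for extension checks)
        self.cds_frames: dict[str, tuple[int, int, int]] = {}
        for f in genome.cds_features():
            frame = frame_of_interval(len(genome), f.start, f.end, f.strand)
            if f.strand == "+":
                aa_start = (f.start - abs(frame)) // 3
            else:
                aa_start = (len(genome) + 1 - f.end - abs(frame)) // 3
            aa = self.translations[frame]
            el_start = aa_start
            while el_start > 0 and aa[el_start - 1] not in "*X":
                el_start -= 1
            self.cds_frames[f.locus_tag] = (frame, aa_start, el_start)

    def find_peptide(self, sequence: str) -> list[PeptideHit]:
        query = sequence.replace("I", "L") if self.il_equivalent else sequence
        length = len(self.genome)
        hits: list[PeptideHit] = []
        for frame in FRAMES:
            aa = self.translations[frame]
            idx = aa.find(query)
            while idx != -1:
                start, end = frame_aa_to_genome(length, frame, idx, len(query))
                locus, in_frame = self._locate(start, end, frame)
                hits.append(
                    PeptideHit(
                        start=start, end=end, frame=frame, aa_index=idx,
                        locus=locus, in_frame_cds=in_frame,
                    )
                )
                idx = aa.find(query, idx + 1)
        return hits

    def _locate(self, start: int, end: int, frame: int) -> tuple[Optional[str], bool]:
        """Overlapping CDS (preferring an in-frame containment) for a hit."""
        overlap: Optional[str] = None
        for f in self.genome.cds_features():
            if f.start <= end and start <= f.end:
                if (
                    f.start <= start
                    and end <= f.end
                    and self.cds_frames[f.locus_tag][0] == frame
                ):
                    return f.locus_tag, True
                overlap = overlap or f.locus_tag
        return overlap, False

    def overlaps_annotation(self, start: int, end: int) -> bool:
        return any(f.start <= end and start <= f.end for f in self.genome.features)


def map_peptides(
    peptides: Sequence[PeptideID],
    genome: GenomeRecord,
    il_equivalent: bool = False,
    index: Optional[SixFrameIndex] = None,
) -> list[ClassifiedPeptide]:
    """Exact-match each peptide against all six frame translations.

    A peptide is ``assigned`` when at least one hit lies fully inside an
    annotated CDS in that CDS's frame; otherwise it is left ``unassigned``
    here and refined by the novelty callers.  Peptides whose sequence cannot
    be searched are skipped with a warning.
    """
    idx = index or SixFrameIndex(genome, il_equivalent=il_equivalent)
    out: list[ClassifiedPeptide] = []
    for p in peptides:
        try:
            hits = idx.find_peptide(p.sequence)
        except ValidationError as exc:  # defensive; PeptideID already validates
            warnings.warn(f"skipping unsearchable peptide {p.sequence!r}: {exc}", stacklevel=2)
            continue
        category = "assigned" if any(h.in_frame_cds for h in hits) else "unassigned"
        out.append(ClassifiedPeptide(peptide=p, hits=hits, category=category))
    return out


def call_alternate_frames_and_extensions(
    classified: Sequence[ClassifiedPeptide],
    genome: GenomeRecord,
    index: Optional[SixFrameIndex] = None,
) -> list[tuple[str, str]]:
    """Explain unassigned genomic hits against the existing gene models.

    Sets ``category`` to ``alternate_frame`` or ``extension`` on the
    classified peptides it explains and returns unique ``(locus, kind)``
    pairs.  Alternate frame takes precedence when both patterns match.
    """
    idx = index or SixFrameIndex(genome)
    calls: list[tuple[str, str]] = []
    for cp in classified:
        if cp.category != "unassigned" or not cp.hits:
            continue
        for hit in cp.hits:
            alt_locus = _alternate_frame_locus(hit, genome, idx)
            if alt_locus is not None:
                cp.category = "alternate_frame"
                pair = (alt_locus, "alternate_frame")
                if pair not in calls:
                    calls.append(pair)
                break
            ext_locus = _extension_locus(hit, genome, idx)
            if ext_locus is not None:
                cp.category = "extension"
                pair = (ext_locus, "extension")
                if pair not in calls:
                    calls.append(pair)
                break
    return calls


def _alternate_frame_locus(
    hit: PeptideHit, genome: GenomeRecord, idx: SixFrameIndex
) -> Optional[str]:
    for f in genome.cds_features():
        if f.start <= hit.start and hit.end <= f.end:
            if idx.cds_frames[f.locus_tag][0] != hit.frame:
                return f.locus_tag
    return None


def _extension_locus(hit: PeptideHit, genome: GenomeRecord, idx: SixFrameIndex) -> Optional[str]:
    """Nearest downstream CDS sharing the hit's frame and stop-to-stop element."""
    best: Optional[tuple[int, str]] = None
    for f in genome.cds_features():
        frame, cds_aa_start, el_start = idx.cds_frames[f.locus_tag]
        if frame != hit.frame:
            continue
        if el_start <= hit.aa_index < cds_aa_start:
            if best is None or cds_aa_start < best[0]:
                best = (cds_aa_start, f.locus_tag)
    return best[1] if best else None


def call_novel_genes(
    classified: Sequence[ClassifiedPeptide],
    genome: GenomeRecord,
    proximity_window: int = PROXIMITY_WINDOW,
) -> list[NovelGeneCall]:
    """Group residual same-frame hits into missed-gene calls.

    Only peptides still ``unassigned`` after the frame/extension checks are
    eligible, and only hits overlapping no annotated feature.  Same-frame
    hits whose genomic gap is at most ``proximity_window`` are chained;
    chains with at least two distinct peptides become calls and their member
    peptides are re-categorised as ``novel_gene_evidence``.
    """
    candidates: list[tuple[str, PeptideHit, ClassifiedPeptide]] = []
    for cp in classified:
        if cp.category != "unassigned":
            continue
        for hit in cp.hits:
            if not genome.features or not _overlaps_any(hit, genome):
                candidates.append((cp.peptide.sequence, hit, cp))

    calls: list[NovelGeneCall] = []
    by_frame: dict[int, list[tuple[str, PeptideHit, ClassifiedPeptide]]] = {}
    for item in candidates:
        by_frame.setdefault(item[1].frame, []).append(item)
    for frame, items in sorted(by_frame.items()):
        items.sort(key=lambda t: (t[1].start, t[1].end))
        chain: list[tuple[str, PeptideHit, ClassifiedPeptide]] = []
        for item in items:
            if chain and item[1].start - chain[-1][1].end > proximity_window:
                _flush_chain(chain, frame, calls)
                chain = []
            chain.append(item)
        _flush_chain(chain, frame, calls)
    return calls


def _overlaps_any(hit: PeptideHit, genome: GenomeRecord) -> bool:
    return any(f.start <= hit.end and hit.start <= f.end for f in genome.features)


def _flush_chain(chain, frame: int, calls: list[NovelGeneCall]) -> None:
    peptides = tuple(dict.fromkeys(seq for seq, _, _ in chain))
    if len(peptides) < 2:
        return
    span = (min(h.start for _, h, _ in chain), max(h.end for _, h, _ in chain))
    for _, _, cp in chain:
        cp.category = "novel_gene_evidence"
    calls.append(
        NovelGeneCall(
            peptides=peptides,
            frame=frame,
            span=span,
            support_note=f"{len(peptides)} peptides in frame {frame:+d} spanning "
            f"{span[0]}..{span[1]}, no overlapping annotation",
        )
    )


def classify_peptides(
    peptides: Sequence[PeptideID],
    genome: GenomeRecord,
    proximity_window: int = PROXIMITY_WINDOW,
    il_equivalent: bool = False,
) -> tuple[list[ClassifiedPeptide], list[tuple[str, str]], list[NovelGeneCall]]:
    """Full classification pipeline: map, explain against gene models, then
    call missed genes from what remains."""
    index = SixFrameIndex(genome, il_equivalent=il_equivalent)
    classified = map_peptides(peptides, genome, index=index)
    model_calls = call_alternate_frames_and_extensions(classified, genome, index=index)
    novel_calls = call_novel_genes(classified, genome, proximity_window=proximity_window)
    return classified, model_calls, novel_calls


# ---------------------------------------------------------------------------
# per-protein residue coverage


def protein_peptide_coverage(
    classified: Sequence[ClassifiedPeptide], genome: GenomeRecord
) -> pd.DataFrame:
    """Percent of each annotated protein's residues covered by >=1 assigned
    peptide (nearest-integer, half up).  Multi-hit peptides count at every
    in-CDS hit; such peptides are flagged in the ``multi_locus`` column."""
    cds = genome.cds_features()
    lengths = {f.locus_tag: _protein_length(f) for f in cds}
    covered = {f.locus_tag: np.zeros(lengths[f.locus_tag], dtype=bool) for f in cds}
    multi: set[str] = set()
    for cp in classified:
        if cp.category != "assigned":
            continue
        in_cds_hits = [h for h in cp.hits if h.in_frame_cds]
        loci = {h.locus for h in in_cds_hits}
        if len(loci) > 1:
            multi.update(loci)
        for h in in_cds_hits:
            f = genome.feature(h.locus)
            if f.strand == "+":
                aa_from = (h.start - f.start) // 3
            else:
                aa_from = (f.end - h.end) // 3
            aa_to = aa_from + (h.end - h.start + 1) // 3
            covered[h.locus][aa_from : min(aa_to, lengths[h.locus])] = True
    rows = []
    for f in cds:
        arr = covered[f.locus_tag]
        pct = int(round_half_up(100.0 * arr.sum() / arr.size)) if arr.size else 0
        rows.append((f.locus_tag, int(arr.sum()), int(arr.size), pct, f.locus_tag in multi))
    return pd.DataFrame(
        rows, columns=["locus_tag", "covered_residues", "protein_length", "percent", "multi_locus"]
    )


def _protein_length(f: GeneFeature) -> int:
    """Residues encoded by a CDS, excluding the stop codon when present."""
    n = f.length // 3
    return n - 1 if f.length % 3 == 0 and n > 1 else n


# ---------------------------------------------------------------------------
# retention-time validation


def predict_hydrophobicity(
    peptide: str, coefficients: Optional[dict[str, float]] = None
) -> float:
    """First-order additive hydrophobicity with a mild length correction.

    ``H = sum of residue coefficients - 0.30 * max(0, len - 10)``: long
    peptides retain less per residue than the naive sum suggests.  The
    coefficient set ships as package data (see its header for provenance).
    """
    coeffs = coefficients if coefficients is not None else read_retention_coefficients()
    total = 0.0
    for aa in peptide:
        if aa not in coeffs:
            raise ValidationError(f"no retention coefficient for residue {aa!r}")
        total += coeffs[aa]
    return total - 0.30 * max(0, len(peptide) - 10)


def validate_rt(
    peptides_with_rt: Iterable[PeptideID],
    coefficients: Optional[dict[str, float]] = None,
) -> float:
    """R-squared of predicted hydrophobicity vs observed retention time.

    Peptides without a retention time are ignored; fewer than three usable
    peptides (or zero variance on either axis) yields 0.0.
    """
    coeffs = coefficients if coefficients is not None else read_retention_coefficients()
    pairs = [
        (predict_hydrophobicity(p.sequence, coeffs), p.retention_time)
        for p in peptides_with_rt
        if p.retention_time is not None
    ]
    if len(pairs) < 3:
        return 0.0
    x = np.array([h for h, _ in pairs])
    y = np.array([rt for _, rt in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
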