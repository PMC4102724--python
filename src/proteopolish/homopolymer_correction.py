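"""Transcript-supported correction of homopolymer sequencing errors.

Pyrosequencing miscalls homopolymer run lengths, leaving spurious single-base
insertions or deletions inside runs of identical bases.  This module turns a
variant table (position, ref, alt) called from deep transcript alignments
into classified :class:`CorrectionRecord` edits, applies the accepted edits
in a single left-to-right pass over the genome, and lifts annotation
coordinates across the edits via cumulative (prefix-sum) offsets.

Application policy: homopolymer-class indels are applied outright;
substitutions and complex variants are applied only when corroborated by an
annotation-review suggestion or by an independently derived genome sequence.
Everything else is recorded with ``applied=False``.

All edit positions are 1-based in the *original* (uncorrected) coordinate
system; insertions land immediately after their position.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    CoordinateError,
    CorrectionRecord,
    GeneFeature,
    GenomeRecord,
    SuggestionRecord,
    ValidationError,
)


class ConsistencyError(ValidationError):
    """A variant's reference allele disagrees with the genome."""


class OverlapError(ValidationError):
    """Two edits touch the same original bases."""


# ---------------------------------------------------------------------------
# homopolymer context


def run_length_at(seq: str, pos: int) -> int:
    """Length of the run of identical bases containing 1-based position ``pos``."""
    base = seq[pos - 1]
    left = pos - 1
    while left > 1 and seq[left - 2] == base:
        left -= 1
    right = pos
    while right < len(seq) and seq[right] == base:
        right += 1
    return right - left + 1


def is_homopolymer_indel(sequence: str, position: int, ref: str, alt: str, min_run: int = 3) -> bool:
    """Whether a single-base indel sits in a homopolymer context.

    The context counts the indel base itself together with identical adjacent
    genome bases, so the rule is symmetric: the inverse of a homopolymer
    error is again homopolymer-class.  Multi-base indels and substitutions
    are never homopolymer-class.
    """
    ins = ref == "-"
    dele = alt == "-"
    if ins == dele:  # substitution or complex
        return False
    allele = alt if ins else ref
    if len(allele) != 1:
        return False
    base = allele
    if dele:
        return run_length_at(sequence, position) >= min_run
    # insertion after `position`: count identical neighbours on both sides
    count = 1
    i = position  # 1-based index of base to the left of the insertion point
    while i >= 1 and sequence[i - 1] == base:
        count += 1
        i -= 1
    j = position + 1
    while j <= len(sequence) and sequence[j - 1] == base:
        count += 1
        j += 1
    return count >= min_run


# ---------------------------------------------------------------------------
# variant selection


def interval_label_for(genome: GenomeRecord, position: int) -> str:
    """Gene or intergenic label for a position, in the corrections-table style."""
    prev_tag = None
    for f in genome.features:
        if f.start <= position <= f.end:
            return f.locus_tag
        if f.end < position:
            prev_tag = f.locus_tag
        elif f.start > position:
            if prev_tag is None:
                return f"upstream/{f.locus_tag}"
            return f"{prev_tag}/{f.locus_tag}"
    return prev_tag or "intergenic"


def label_locus_tags(label: str) -> list[str]:
    """Expand a label like ``Clst_0020/21`` into full locus tags.

    A short suffix after ``/`` replaces the trailing digits of the first tag
    (``Clst_0899/900`` -> Clst_0899, Clst_0900).
    """
    if "/" not in label:
        return [label]
    head, tail = label.split("/", 1)
    tags = [head]
    if tail.isdigit():
        m = head
        digits = "".join(ch for ch in m[::-1] if ch.isdigit())[::-1]
        if digits and len(tail) <= len(digits):
            tags.append(head[: len(head) - len(tail)] + tail)
        else:
            tags.append(tail)
    else:
        tags.append(tail)
    return tags


def select_homopolymer_variants(
    variants: pd.DataFrame,
    genome: GenomeRecord,
    min_run: int = 3,
    suggestion_loci: Optional[set[str]] = None,
    alternate_positions: Optional[set[int]] = None,
) -> list[CorrectionRecord]:
    """Classify variant calls and decide which are applied.

    ``variants`` needs columns ``position``, ``ref``, ``alt`` (``-`` = empty
    allele); an optional ``alt_genome`` column (Y/N) marks concordance with an
    independent genome and is merged with ``alternate_positions``.
    Homopolymer-class indels (run >= ``min_run``) are applied; substitutions
    and complex variants are applied only when corroborated.  Reference
    alleles are checked against the genome.
    """
    suggestion_loci = suggestion_loci or set()
    alternate_positions = set(alternate_positions or ())
    if "alt_genome" in variants.columns:
        for row in variants.itertuples(index=False):
            if str(row.alt_genome).strip().upper() in ("Y", "YES", "TRUE", "1"):
                alternate_positions.add(int(row.position))

    records: list[CorrectionRecord] = []
    for row in variants.itertuples(index=False):
        pos = int(row.position)
        ref, alt = str(row.ref), str(row.alt)
        if ref != "-":
            observed = genome.subsequence(pos, pos + len(ref) - 1)
            if observed != ref:
                raise ConsistencyError(
                    f"variant at {pos}: ref allele {ref!r} disagrees with genome {observed!r}"
                )
        homopolymer = is_homopolymer_indel(genome.sequence, pos, ref, alt, min_run=min_run)
        label = interval_label_for(genome, pos)
        corroborations = set()
        if pos in alternate_positions:
            corroborations.add("alternate_genome")
        if any(tag in suggestion_loci for tag in label_locus_tags(label)):
            corroborations.add("suggestion_table")
        applied = homopolymer or bool(corroborations)
        records.append(
            CorrectionRecord(
                interval_label=label,
                position=pos,
                original=ref,
                corrected=alt,
                offset=CorrectionRecord.allele_length(alt) - CorrectionRecord.allele_length(ref),
                applied=applied,
                homopolymer=homopolymer,
                corroborations=corroborations,
            )
        )
    return records


# ---------------------------------------------------------------------------
# applying edits and lifting coordinates


@dataclass
class OffsetMap:
    """Cumulative coordinate shifts induced by applied edits.

    ``breakpoints`` holds ``(threshold, cumulative_shift)`` pairs sorted by
    threshold: an original position ``p`` maps to ``p + shift`` where shift is
    the cumulative value of the last breakpoint with ``threshold < p``.
    ``deleted_blocks`` lists original intervals removed by multi-base
    deletions; coordinates inside them cannot be lifted.
    """

    breakpoints: list[tuple[int, int]] = field(default_factory=list)
    deleted_blocks: list[tuple[int, int]] = field(default_factory=list)

    def shift_at(self, original_position: int) -> int:
        thresholds = [b[0] for b in self.breakpoints]
        i = bisect_right(thresholds, original_position - 1)
        return self.breakpoints[i - 1][1] if i else 0

    def map_position(self, original_position: int, context: str = "position") -> int:
        for (ds, de) in self.deleted_blocks:
            if ds <= original_position <= de and de > ds:
                raise CoordinateError(
                    f"{context} {original_position} falls inside deleted block {ds}..{de}"
                )
        return original_position + self.shift_at(original_position)


def _edit_span(c: CorrectionRecord) -> tuple[int, int]:
    """Original-coordinate footprint of an edit (insertions are zero-width)."""
    if c.is_insertion:
        return c.position, c.position  # anchors after `position`
    return c.position, c.position + CorrectionRecord.allele_length(c.original) - 1


def apply_corrections(
    genome: GenomeRecord, corrections: Sequence[CorrectionRecord]
) -> tuple[GenomeRecord, OffsetMap]:
    """Apply the ``applied`` corrections in one left-to-right pass.

    Returns the corrected :class:`GenomeRecord` (features lifted through
    :func:`liftover`) and the :class:`OffsetMap`.  Edits must not overlap;
    reference alleles are re-checked against the genome.
    """
    todo = sorted((c for c in corrections if c.applied), key=lambda c: c.position)
    for a, b in zip(todo, todo[1:]):
        a_start, a_end = _edit_span(a)
        b_start, b_end = _edit_span(b)
        # an insertion anchored at p is compatible with an edit starting at p+1
        a_excl = a_end if not a.is_insertion else a.position
        if b_start <= a_excl and not (a.is_insertion and b.is_insertion and a.position != b.position):
            raise OverlapError(
                f"overlapping edits at {a.interval_label} ({a.position}) and "
                f"{b.interval_label} ({b.position})"
            )

    seq = genome.sequence
    parts: list[str] = []
    cursor = 0  # 0-based index into original sequence, already consumed
    breakpoints: list[tuple[int, int]] = []
    deleted_blocks: list[tuple[int, int]] = []
    shift = 0
    for c in todo:
        ref_len = CorrectionRecord.allele_length(c.original)
        if c.is_insertion:
            parts.append(seq[cursor : c.position])
            parts.append(c.corrected)
            cursor = c.position
            threshold = c.position
        else:
            observed = seq[c.position - 1 : c.position - 1 + ref_len]
            if observed != c.original:
                raise ConsistencyError(
                    f"correction at {c.position}: original allele {c.original!r} "
                    f"disagrees with genome {observed!r}"
                )
            parts.append(seq[cursor : c.position - 1])
            if not c.is_deletion:
                parts.append(c.corrected)
            cursor = c.position - 1 + ref_len
            threshold = c.position + ref_len - 1
            if c.is_deletion:
                deleted_blocks.append((c.position, c.position + ref_len - 1))
        shift += c.offset
        breakpoints.append((threshold, shift))
    parts.append(seq[cursor:])
    new_seq = "".join(parts)

    offset_map = OffsetMap(breakpoints=breakpoints, deleted_blocks=deleted_blocks)
    new_features = liftover(genome.features, offset_map)
    corrected = GenomeRecord(
        id=genome.id, sequence=new_seq, circular=genome.circular, features=new_features
    )
    return corrected, offset_map


def liftover(features: Iterable[GeneFeature], offset_map: OffsetMap) -> list[GeneFeature]:
    """Shift feature coordinates through the cumulative offsets of applied edits.

    Features spanning an applied indel change length accordingly.  A feature
    boundary inside a multi-base deleted block cannot be mapped and raises a
    :class:`CoordinateError` naming the locus.
    """
    out = []
    for f in features:
        new_start = offset_map.map_position(f.start, context=f"feature {f.locus_tag} start")
        new_end = offset_map.map_position(f.end, context=f"feature {f.locus_tag} end")
        out.append(f.shifted(new_start, new_end))
    return out


def reported_position(record: CorrectionRecord, offset_map: OffsetMap) -> int:
    """Position in the study table's convention: corrected-sequence position
    for insertions and substitutions, former (original) position for
    deletions."""
    if record.is_deletion or not record.applied:
        return record.position
    if record.is_insertion:
        return record.position + offset_map.shift_at(record.position + 1)
    return record.position + offset_map.shift_at(record.position)


# ---------------------------------------------------------------------------
# corroboration cross-check


def cross_check(
    corrections: Sequence[CorrectionRecord],
    suggestions: Sequence[SuggestionRecord] = (),
    alternate_positions: Optional[set[int]] = None,
) -> dict[str, int]:
    """Populate corroboration sets in place and tally them.

    A correction is corroborated by the suggestion table when its interval
    label shares a locus tag with any suggestion, and by the alternate genome
    when its position appears in ``alternate_positions``.
    """
    suggestion_tags = {t for s in suggestions for t in s.locus_tags}
    alternate_positions = alternate_positions or set()
    counts = {"suggestion_table": 0, "alternate_genome": 0, "both": 0, "none": 0}
    for c in corrections:
        if any(tag in suggestion_tags for tag in label_locus_tags(c.interval_label)):
            c.corroborations.add("suggestion_table")
        if c.position in alternate_positions:
            c.corroborations.add("alternate_genome")
        has_s = "suggestion_table" in c.corroborations
        has_a = "alternate_genome" in c.corroborations
        if has_s:
            counts["suggestion_table"] += 1
        if has_a:
            counts["alternate_genome"] += 1
        if has_s and has_a:
            counts["both"] += 1
        if not has_s and not has_a:
            counts["none"] += 1
    return counts
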