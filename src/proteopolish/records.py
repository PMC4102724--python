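"""Core record types shared across the pipeline.

All genomic coordinates are 1-based inclusive (GenBank convention).
The GFF boundary is the only place any other convention appears, and it is
converted on read.  Wrap-around (origin-spanning) features on circular
replicons are rejected: every feature must lie within [1, genome length].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

VALID_NUCLEOTIDES = frozenset("ACGTN")
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "misc_RNA")
SUGGESTION_KINDS = ("join", "extend", "split", "missed_gene", "alternate_frame", "pseudogene")


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class CoordinateError(ValidationError):
    """A genomic coordinate is out of bounds or inconsistent."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the single replicon.

    ``start``/``end`` are 1-based inclusive with ``start <= end``; ``strand``
    is ``'+'`` or ``'-'``; ``kind`` is one of ``FEATURE_KINDS``.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"feature {self.locus_tag}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.locus_tag}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"feature {self.locus_tag}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def shifted(self, new_start: int, new_end: int) -> "GeneFeature":
        return replace(self, start=new_start, end=new_end)


@dataclass
class GenomeRecord:
    """A nucleotide sequence plus its ordered annotation.

    The single coordinate authority of the pipeline: every module reports
    positions on this record's forward strand.
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError("genome sequence must be non-empty")
        bad = set(self.sequence) - VALID_NUCLEOTIDES
        if bad:
            raise ValidationError(f"genome contains non-nucleotide characters: {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.locus_tag))
        seen: set[str] = set()
        for f in self.features:
            if f.end > len(self.sequence):
                raise CoordinateError(
                    f"feature {f.locus_tag} ({f.start}..{f.end}) exceeds genome "
                    f"length {len(self.sequence)}"
                )
            if f.locus_tag in seen:
                raise ValidationError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive slice of the forward strand."""
        if start < 1 or end > len(self.sequence) or end < start:
            raise CoordinateError(f"bad interval {start}..{end} on genome of length {len(self)}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class PeptideID:
    """One MS/MS peptide identification.

    ``log_e`` is log10 of the search engine's expectation value; lower is
    more confident.  Retention time is in minutes when present.
    """

    sequence: str
    log_e: float
    retention_time: Optional[float] = None
    spectra_count: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValidationError(
                f"peptide {self.sequence!r} contains non-standard residues: {sorted(bad)}"
            )
        if not (self.log_e == self.log_e and abs(self.log_e) != float("inf")):
            raise ValidationError(f"peptide {self.sequence!r}: log_e must be finite")
        if self.spectra_count < 1:
            raise ValidationError("spectra_count must be >= 1")


@dataclass(frozen=True)
class SuggestionRecord:
    """An annotation-improvement suggestion from an external review pipeline."""

    locus_tags: tuple[str, ...]
    suggestion: str
    source: str = "genepirmp_like"

    def __post_init__(self) -> None:
        if self.suggestion not in SUGGESTION_KINDS:
            raise ValidationError(f"unknown suggestion kind {self.suggestion!r}")
        n = len(self.locus_tags)
        if self.suggestion == "join" and n != 2:
            raise ValidationError("join suggestions need exactly two locus tags")
        if self.suggestion != "join" and n != 1:
            raise ValidationError(f"{self.suggestion} suggestions need exactly one locus tag")


@dataclass
class CorrectionRecord:
    """One genome edit in the style of a corrections table row.

    ``position`` is 1-based in the sequence being corrected (the *original*
    coordinate system).  ``original``/``corrected`` are allele strings with
    ``"-"`` denoting the empty allele, so an insertion has ``original == "-"``
    and a deletion has ``corrected == "-"``.  Insertions are placed
    immediately *after* ``position``; deletions and substitutions start *at*
    ``position``.  ``offset`` is len(corrected) - len(original).
    """

    interval_label: str
    position: int
    original: str
    corrected: str
    offset: int
    applied: bool
    homopolymer: bool = False
    corroborations: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.original == self.corrected:
            raise ValidationError(
                f"correction at {self.position}: original and corrected alleles are equal"
            )
        expected = self.allele_length(self.corrected) - self.allele_length(self.original)
        if self.offset != expected:
            raise ValidationError(
                f"correction at {self.position}: offset {self.offset} inconsistent with "
                f"alleles {self.original!r}->{self.corrected!r} (expected {expected})"
            )

    @staticmethod
    def allele_length(allele: str) -> int:
        return 0 if allele == "-" else len(allele)

    @property
    def is_insertion(self) -> bool:
        return self.original == "-"

    @property
    def is_deletion(self) -> bool:
        return self.corrected == "-"

    @property
    def is_substitution(self) -> bool:
        return not self.is_insertion and not self.is_deletion

    def inverse(self, position_in_new: int) -> "CorrectionRecord":
        """The edit that undoes this one, at its position in the edited sequence."""
        return CorrectionRecord(
            interval_label=self.interval_label,
            position=position_in_new,
            original=self.corrected,
            corrected=self.original,
            offset=-self.offset,
            applied=True,
            homopolymer=self.homopolymer,
        )


@dataclass(frozen=True)
class TransporterGene:
    """One ABC-type carbohydrate-uptake transporter locus from a cluster table."""

    locus_tag: str
    cluster_id: str
    strand: str
    img_subunit: str
    abcdb_subunit: str
    coverage_percent: int
    family: str = "CUT1"

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_percent <= 100:
            raise ValidationError(
                f"{self.locus_tag}: coverage percent {self.coverage_percent} out of range"
            )
        if self.img_subunit not in ("S", "M", "N"):
            raise ValidationError(f"{self.locus_tag}: bad IMG subunit {self.img_subunit!r}")
        if self.abcdb_subunit not in ("S", "M", "N", "X"):
            raise ValidationError(f"{self.locus_tag}: bad ABCdb subunit {self.abcdb_subunit!r}")
        if self.family not in ("CUT1", "CUT2"):
            raise ValidationError(f"{self.locus_tag}: bad family {self.family!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
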