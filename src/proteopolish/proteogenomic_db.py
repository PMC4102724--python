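"""Naive proteogenomic peptide databases from six-frame translation.

Reads (or genome segments) are translated in all six reading frames into
*stop-to-stop elements*: maximal translated segments between stop codons,
requiring no start codon.  Each element is digested in silico with trypsin
(cleave after K/R, not before P, one missed cleavage by default) and the
union of fragments forms a non-redundant peptide database suitable for
searching MS/MS spectra against raw sequence rather than annotated proteins.

Codons containing ``N`` translate to ``X`` and terminate an element — a
conservative choice that never fabricates peptides from ambiguous sequence.

Frame labels: ``+1`` starts at position 1 of the forward strand; ``-1``
starts at the last position (position 1 of the reverse complement).  All
reported genome coordinates are 1-based inclusive on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from .records import reverse_complement

FRAMES = (1, 2, 3, -1, -2, -3)

MIN_PEPTIDE_LEN = 7
MAX_PEPTIDE_LEN = 50

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _table.stop_codons})


def translate_frame(seq: str, frame: int) -> str:
    """Translate one reading frame; stops are ``*`` and N-codons are ``X``."""
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = seq if frame > 0 else reverse_complement(seq)
    f = abs(frame)
    out = []
    for i in range(f - 1, len(s) - 2, 3):
        codon = s[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def frame_aa_to_genome(length: int, frame: int, aa_index: int, aa_len: int = 1) -> tuple[int, int]:
    """Forward-strand coordinates of ``aa_len`` codons starting at 0-based
    ``aa_index`` of the given frame's translation."""
    f = abs(frame)
    first = f + 3 * aa_index  # 1-based on the translated strand
    last = f + 3 * (aa_index + aa_len) - 1
    if frame > 0:
        return first, last
    return length + 1 - last, length + 1 - first


def frame_of_interval(length: int, start: int, end: int, strand: str) -> int:
    """Signed frame label of a codon-aligned interval on the given strand."""
    if strand == "+":
        return (start - 1) % 3 + 1
    return -(((length - end) % 3) + 1)


@dataclass(frozen=True)
class PeptideElement:
    """One maximal stop-free translated segment of a source sequence.

    ``aa_start`` is the 0-based index of the element's first residue within
    the full frame translation of its source.  ``genome_start``/``genome_end``
    are forward-strand nucleotide coordinates of the encoding bases.
    """

    source_id: str
    frame: int
    aa_sequence: str
    aa_start: int
    genome_start: int
    genome_end: int

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError("empty peptide element")
        if self.genome_end - self.genome_start + 1 != 3 * len(self.aa_sequence):
            raise ValueError(
                f"element {self.source_id}|{self.frame}|{self.aa_start}: "
                "coordinates inconsistent with length"
            )


def six_frame_elements(
    nucleotide_sequence: str, source_id: str, min_len: int = MIN_PEPTIDE_LEN
) -> list[PeptideElement]:
    """Extract stop-to-stop elements from all six frames of a sequence.

    Elements are split at stop codons and at ``X`` (N-containing codons);
    segments shorter than ``min_len`` residues are discarded.
    """
    seq = nucleotide_sequence.upper()
    length = len(seq)
    elements: list[PeptideElement] = []
    for frame in FRAMES:
        aa = translate_frame(seq, frame)
        i = 0
        n = len(aa)
        while i < n:
            if aa[i] in "*X":
                i += 1
                continue
            j = i
            while j < n and aa[j] not in "*X":
                j += 1
            if j - i >= min_len:
                start, end = frame_aa_to_genome(length, frame, i, j - i)
                elements.append(
                    PeptideElement(
                        source_id=source_id,
                        frame=frame,
                        aa_sequence=aa[i:j],
                        aa_start=i,
                        genome_start=start,
                        genome_end=end,
                    )
                )
            i = j
    return elements


def tryptic_digest(
    aa_sequence: str,
    max_missed: int = 1,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
    kp_rule: bool = True,
) -> list[str]:
    """In-silico tryptic fragments of a protein or element sequence.

    Trypsin cleaves after K or R; with ``kp_rule`` (the default) a site
    followed by proline is suppressed.  All fragments with up to
    ``max_missed`` internal (uncleaved) sites and length within
    ``[min_len, max_len]`` are returned, in order of their start position.
    """
    s = aa_sequence
    cut_after = [
        i
        for i in range(len(s) - 1)
        if s[i] in "KR" and not (kp_rule and s[i + 1] == "P")
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(s)]
    out: list[str] = []
    for bi in range(len(boundaries) - 1):
        for bj in range(bi + 1, min(bi + 2 + max_missed, len(boundaries))):
            frag = s[boundaries[bi] : boundaries[bj]]
            if min_len <= len(frag) <= max_len:
                out.append(frag)
    return out


@dataclass
class PeptideDB:
    """Non-redundant tryptic peptide database built from stop-to-stop elements.

    ``origin_index`` maps each peptide to every ``(source_id, frame,
    aa_offset)`` it was digested from, where ``aa_offset`` is the 0-based
    residue index of the peptide start within the source's frame translation.
    """

    peptides: set[str] = field(default_factory=set)
    origin_index: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    elements: list[PeptideElement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peptides)


def build_peptide_db(
    sources: Iterable[tuple[str, str]],
    max_missed: int = 1,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
    kp_rule: bool = True,
) -> PeptideDB:
    """Build the peptide database from ``(source_id, nucleotide_sequence)`` pairs.

    The result is a set union over all elements of all sources: duplicate
    peptides appear once, with every origin recorded, so the database is
    invariant to source order.
    """
    db = PeptideDB()
    n_sources = 0
    for source_id, seq in sources:
        n_sources += 1
        for element in six_frame_elements(seq, source_id, min_len=min_len):
            db.elements.append(element)
            frags = tryptic_digest(
                element.aa_sequence,
                max_missed=max_missed,
                min_len=min_len,
                max_len=max_len,
                kp_rule=kp_rule,
            )
            for frag in frags:
                offset = element.aa_start + element.aa_sequence.find(frag)
                db.peptides.add(frag)
                origins = db.origin_index.setdefault(frag, [])
                origin = (source_id, element.frame, offset)
                if origin not in origins:
                    origins.append(origin)
    if n_sources == 0:
        warnings.warn("no input sources; peptide database is empty", stacklevel=2)
    return db


def read_sources(path) -> list[tuple[str, str]]:
    """Read reads or segments from FASTA/FASTQ; quality strings are discarded."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(p), fmt)]


def write_db_fasta(db: PeptideDB, path) -> None:
    """Export the database grouped by source element (``>src|frame|offset``).

    Each record is one stop-to-stop element: a collection of connected
    tryptic peptides standing in for a "protein" during spectrum search.
    """
    with open(path, "w") as fh:
        for el in db.elements:
            fh.write(f">{el.source_id}|{el.frame:+d}|{el.aa_start}\n")
            for i in range(0, len(el.aa_sequence), 70):
                fh.write(el.aa_sequence[i : i + 70] + "\n")
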