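"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA (wrapped at 70 columns, via Biopython), GFF3 or 7-column TSV
annotation tables, TSV peptide-identification tables, per-base depth tracks
(``pos<TAB>value``), TSV correction tables, and the packaged transcriptions
of the study's printed corrections and transporter tables.

Coordinates are 1-based inclusive everywhere; GFF3 input (also 1-based) is
validated at the boundary.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CoordinateError,
    CorrectionRecord,
    GeneFeature,
    GenomeRecord,
    PeptideID,
    SuggestionRecord,
    TransporterGene,
    ValidationError,
)

ANNOTATION_COLUMNS = ["locus_tag", "start", "end", "strand", "kind", "product", "pseudo"]

# GFF3 feature types folded onto the pipeline's four kinds
_GFF_KIND_MAP = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "misc_RNA": "misc_RNA",
    "ncRNA": "misc_RNA",
    "tmRNA": "misc_RNA",
}


# ---------------------------------------------------------------------------
# genome + annotation


def read_genome(fasta_path, annotation_path, circular: bool = True) -> GenomeRecord:
    """Read a genome FASTA plus its annotation table into a :class:`GenomeRecord`.

    The annotation may be a 7-column TSV (``locus_tag  start  end  strand
    kind  product  pseudo``) or a GFF3 file (detected from the header or the
    9-column layout); feature types are mapped onto {CDS, rRNA, tRNA,
    misc_RNA} and unknown types are skipped.
    """
    seq_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seq_records:
        raise ValidationError(f"no FASTA records in {fasta_path}")
    rec = seq_records[0]
    features = _read_annotation(annotation_path)
    return GenomeRecord(
        id=rec.id, sequence=str(rec.seq).upper(), circular=circular, features=features
    )


def _read_annotation(path) -> list[GeneFeature]:
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first.count("\t") >= 8:
        return _read_gff3(path)
    return _read_annotation_tsv(path)


def _read_annotation_tsv(path) -> list[GeneFeature]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation table {path} missing columns: {sorted(missing)}")
    feats = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise CoordinateError(f"feature {row.locus_tag}: end {end} < start {start}")
        feats.append(
            GeneFeature(
                locus_tag=str(row.locus_tag),
                start=start,
                end=end,
                strand=str(row.strand),
                kind=str(row.kind),
                product=str(row.product),
                pseudo=_parse_bool(row.pseudo),
            )
        )
    return feats


def _read_gff3(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValidationError(f"malformed GFF3 line: {line.rstrip()!r}")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in _GFF_KIND_MAP:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.rstrip(";").split(";") if "=" in kv
            )
            locus = attr.get("locus_tag") or attr.get("ID")
            if locus is None:
                raise ValidationError(f"GFF3 feature without locus_tag/ID: {line.rstrip()!r}")
            if int(end) < int(start):
                raise CoordinateError(f"feature {locus}: end {end} < start {start}")
            feats.append(
                GeneFeature(
                    locus_tag=locus,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    kind=_GFF_KIND_MAP[ftype],
                    product=attr.get("product", ""),
                    pseudo=_parse_bool(attr.get("pseudo", "false")),
                )
            )
    return feats


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes", "y")


def write_genome(genome: GenomeRecord, fasta_path, annotation_path) -> None:
    """Write the FASTA (70-column wrap) and 7-column TSV annotation of a genome."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([record], fh, "fasta")
    rows = [
        (f.locus_tag, f.start, f.end, f.strand, f.kind, f.product, str(f.pseudo).lower())
        for f in genome.features
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        annotation_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# peptide identifications


def read_peptide_ids(tsv_path, log_e_cutoff: float = -1.0) -> list[PeptideID]:
    """Read a peptide-identification TSV, keeping rows with ``log_e < cutoff``.

    The strict inequality mirrors the reporting rule of expectation-value
    filtered search results; input order is preserved.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#", keep_default_na=False)
    if "sequence" not in df.columns or "log_e" not in df.columns:
        raise ValidationError(f"peptide table {tsv_path} needs 'sequence' and 'log_e' columns")
    out = []
    for row in df.itertuples(index=False):
        log_e = float(row.log_e)
        if not log_e < log_e_cutoff:
            continue
        rt = getattr(row, "retention_time", None)
        rt = None if rt in (None, "") else float(rt)
        spectra = int(getattr(row, "spectra_count", 1) or 1)
        out.append(
            PeptideID(
                sequence=str(row.sequence),
                log_e=log_e,
                retention_time=rt,
                spectra_count=spectra,
            )
        )
    return out


def write_peptide_ids(peptides: Sequence[PeptideID], tsv_path) -> None:
    rows = [
        (p.sequence, p.log_e, "" if p.retention_time is None else p.retention_time, p.spectra_count)
        for p in peptides
    ]
    pd.DataFrame(
        rows, columns=["sequence", "log_e", "retention_time", "spectra_count"]
    ).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# masked FASTA ("base observed is itself, base not observed is a dash")


def write_masked_fasta(genome: GenomeRecord, covered_mask, path, width: int = 70) -> None:
    """Write the genome with uncovered positions replaced by ``-``.

    ``covered_mask`` is a boolean sequence of the genome's length; the output
    keeps the record id and wraps at ``width`` columns.  This is the atlas
    input format for circular-genome viewers.
    """
    mask = np.asarray(covered_mask, dtype=bool)
    if mask.shape != (len(genome),):
        raise ValidationError(
            f"mask length {mask.size} does not match genome length {len(genome)}"
        )
    chars = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    chars[~mask] = b"-"
    masked = chars.tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(masked), width):
            fh.write(masked[i : i + width] + "\n")


def read_masked_fasta(path) -> tuple[str, str]:
    """Return (record id, masked sequence) of a dash-masked FASTA."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq)


# ---------------------------------------------------------------------------
# depth tracks and variants


def read_depth_track(path) -> pd.DataFrame:
    """Read a two-column per-base depth TSV (``position<TAB>depth``)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    if not {"position", "depth"} <= set(df.columns):
        raise ValidationError(f"depth track {path} needs 'position' and 'depth' columns")
    return df[["position", "depth"]].astype({"position": int, "depth": float})


def write_depth_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    """Read a variant TSV with columns position, ref, alt (``-`` = empty allele).

    An optional boolean-ish ``alt_genome`` column marks concordance with an
    independently derived genome sequence.
    """
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    if not {"position", "ref", "alt"} <= set(df.columns):
        raise ValidationError(f"variant table {path} needs position/ref/alt columns")
    df["position"] = df["position"].astype(int)
    return df


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# suggestion tables


def read_suggestions(path) -> list[SuggestionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    out = []
    for row in df.itertuples(index=False):
        tags = tuple(t for t in str(row.locus_tags).split(",") if t)
        out.append(
            SuggestionRecord(
                locus_tags=tags,
                suggestion=str(row.suggestion),
                source=str(getattr(row, "source", "genepirmp_like") or "genepirmp_like"),
            )
        )
    return out


def write_suggestions(suggestions: Iterable[SuggestionRecord], path) -> None:
    rows = [(",".join(s.locus_tags), s.suggestion, s.source) for s in suggestions]
    pd.DataFrame(rows, columns=["locus_tags", "suggestion", "source"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# packaged study tables


def _packaged(name: str):
    return resources.files("proteopolish.data").joinpath(name)


def read_table1(path=None) -> list[CorrectionRecord]:
    """Parse a corrections table (the packaged study transcription by default).

    One :class:`CorrectionRecord` per row.  The printed offset column carries
    ``NA`` for rows whose change was *not* applied to the final sequence;
    those records get ``applied=False`` with the offset recomputed from the
    alleles.  Corroboration flags are carried in ``corroborations`` as
    ``"alternate_genome"`` / ``"suggestion_table"``.
    """
    src = _packaged("table1_corrections.tsv") if path is None else Path(path)
    df = pd.read_csv(src, sep="\t", comment="#", keep_default_na=False, dtype=str)
    out = []
    for row in df.itertuples(index=False):
        offset_field = str(row.offset).strip()
        applied = offset_field.upper() != "NA"
        original, corrected = str(row.original), str(row.corrected)
        offset = CorrectionRecord.allele_length(corrected) - CorrectionRecord.allele_length(
            original
        )
        if applied:
            try:
                stated = int(offset_field)
            except ValueError as exc:
                raise ValidationError(
                    f"row {row.interval}: malformed offset {offset_field!r}"
                ) from exc
            if stated != offset:
                raise ValidationError(
                    f"row {row.interval}: offset {stated} inconsistent with alleles"
                )
        corroborations = set()
        if _parse_bool(getattr(row, "alt_genome", "N")):
            corroborations.add("alternate_genome")
        if _parse_bool(getattr(row, "review_corroborated", "N")):
            corroborations.add("suggestion_table")
        rec = CorrectionRecord(
            interval_label=str(row.interval),
            position=int(row.position),
            original=original,
            corrected=corrected,
            offset=offset,
            applied=applied,
            corroborations=corroborations,
        )
        out.append(rec)
    return out


_CLUSTER_RE = re.compile(r"(?i)(clst)_(\d+)(?:-(\d+))?$")


def cluster_locus_tags(cluster_label: str) -> list[str]:
    """Expand a cluster label like ``Clst_0059-0061`` into its locus tags."""
    m = _CLUSTER_RE.match(cluster_label.strip())
    if not m:
        raise ValidationError(f"unparseable cluster label {cluster_label!r}")
    prefix, lo, hi = m.group(1), m.group(2), m.group(3)
    width = len(lo)
    first = int(lo)
    last = int(hi) if hi is not None else first
    if last < first:
        raise ValidationError(f"cluster label {cluster_label!r} has descending range")
    return [f"{prefix}_{n:0{width}d}" for n in range(first, last + 1)]


def read_table2(path=None) -> list[TransporterGene]:
    """Parse a transporter-cluster table into one :class:`TransporterGene` per
    coverage entry (the packaged study transcription by default)."""
    src = _packaged("table2_transporters.tsv") if path is None else Path(path)
    df = pd.read_csv(src, sep="\t", comment="#", keep_default_na=False, dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        tags = cluster_locus_tags(row.cluster)
        img = str(row.img_order).split("-")
        abcdb = str(row.abcdb_order).split("-")
        cov = [int(c) for c in str(row.coverage).split("/")]
        if not (len(tags) == len(img) == len(abcdb) == len(cov)):
            raise ValidationError(f"cluster {row.cluster}: column lengths disagree")
        for tag, i, a, c in zip(tags, img, abcdb, cov):
            genes.append(
                TransporterGene(
                    locus_tag=tag,
                    cluster_id=str(row.cluster),
                    strand=str(row.strand),
                    img_subunit=i,
                    abcdb_subunit=a,
                    coverage_percent=c,
                    family=str(row.family),
                )
            )
    return genes


def read_retention_coefficients(path=None) -> dict[str, float]:
    """Load the additive residue retention-coefficient set."""
    src = _packaged("retention_coefficients.tsv") if path is None else Path(path)
    df = pd.read_csv(src, sep="\t", comment="#")
    return dict(zip(df["residue"], df["coefficient"].astype(float)))


def write_corrections(corrections: Sequence[CorrectionRecord], path) -> None:
    """Write corrections in the study table's schema (offset ``NA`` when not applied)."""
    rows = []
    for c in corrections:
        rows.append(
            (
                c.interval_label,
                c.position,
                c.original,
                c.corrected,
                c.offset if c.applied else "NA",
                "Y" if "alternate_genome" in c.corroborations else "N",
                "Y" if "suggestion_table" in c.corroborations else "N",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "interval",
            "position",
            "original",
            "corrected",
            "offset",
            "alt_genome",
            "review_corroborated",
        ],
    ).to_csv(path, sep="\t", index=False)
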