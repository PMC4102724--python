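"""Per-base evidence tracks and gene coverage summaries.

A *base pair map* assigns one numeric evidence value to every genome
position: read depth from a transcript alignment, or peptide evidence
(identification count or spectra-weighted) from mapped MS/MS peptides.
Comparing maps to gene regions yields per-gene coverage percentages and the
genome-level summary statistics reported for such studies (fractions of
genes fully covered by reads, genes with zero peptide coverage, ...).

Coverage is strand-agnostic and positional; a position counts as covered
when its value reaches the threshold (default >= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import CoordinateError, GenomeRecord


@dataclass
class BaseMap:
    """A numeric evidence value per genome position (1-based position ``i``
    lives at ``values[i-1]``)."""

    genome_id: str
    values: np.ndarray
    kind: str = "read_depth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("basemap values must be one-dimensional")
        if (self.values < 0).any():
            raise ValueError("basemap values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GeneCoverage:
    locus_tag: str
    kind: str
    covered_bases: int
    gene_length: int
    percent: int
    fully_covered: bool


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


def format_percent(numerator: int, denominator: int) -> str:
    """Render a count ratio the way genome-summary prose prints it.

    Nearest-integer percent (half up), except one decimal place when the
    value lies within 5 points of 0 or 100, where integer rounding would be
    misleading (97.50% must not read as 98%).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    if pct > 95.0 or pct < 5.0:
        return f"{round_half_up(pct, 1):.1f}"
    return f"{int(round_half_up(pct)):d}"


def depth_to_basemap(depth_track: pd.DataFrame, genome: GenomeRecord) -> BaseMap:
    """Densify a (position, depth) track into a base map (0 where unlisted)."""
    values = np.zeros(len(genome), dtype=float)
    if len(depth_track):
        pos = depth_track["position"].to_numpy(dtype=int)
        depth = depth_track["depth"].to_numpy(dtype=float)
        if pos.min() < 1 or pos.max() > len(genome):
            raise CoordinateError(
                f"depth track positions outside genome of length {len(genome)}"
            )
        values[pos - 1] = depth
    return BaseMap(genome_id=genome.id, values=values, kind="read_depth")


def peptides_to_basemap(
    classified_peptides: Iterable, genome: GenomeRecord, weight: str = "count"
) -> BaseMap:
    """Accumulate peptide-to-genome hits into a peptide evidence map.

    Each hit adds its weight to every encoding nucleotide position:
    ``weight='count'`` adds 1 per hit, ``weight='spectra'`` adds the
    identification's spectra count (the available proxy for ion current).
    """
    if weight not in ("count", "spectra"):
        raise ValueError("weight must be 'count' or 'spectra'")
    values = np.zeros(len(genome), dtype=float)
    for cp in classified_peptides:
        w = 1.0 if weight == "count" else float(cp.peptide.spectra_count)
        for hit in cp.hits:
            if hit.start < 1 or hit.end > len(genome):
                raise CoordinateError(
                    f"peptide hit {hit.start}..{hit.end} outside genome"
                )
            values[hit.start - 1 : hit.end] += w
    return BaseMap(genome_id=genome.id, values=values, kind="peptide_evidence")


def basemap_to_mask(basemap: BaseMap, threshold: float = 1.0) -> np.ndarray:
    """Boolean covered/uncovered mask (feeds the dash-masked FASTA writer)."""
    return basemap.values >= threshold


def gene_coverage(
    basemap: BaseMap, genome: GenomeRecord, threshold: float = 1.0
) -> tuple[list[GeneCoverage], dict]:
    """Per-feature coverage against a base map, plus a genome-level summary.

    Per-gene percent is nearest-integer (half up); summary percentages use
    :func:`format_percent`.  The summary counts fully covered features over
    all features and zero-coverage over protein-coding features, matching how
    such studies report the two numbers.
    """
    if len(basemap) != len(genome):
        raise CoordinateError(
            f"basemap length {len(basemap)} != genome length {len(genome)}"
        )
    covered = basemap.values >= threshold
    per_gene: list[GeneCoverage] = []
    for f in genome.features:
        n_cov = int(covered[f.start - 1 : f.end].sum())
        per_gene.append(
            GeneCoverage(
                locus_tag=f.locus_tag,
                kind=f.kind,
                covered_bases=n_cov,
                gene_length=f.length,
                percent=int(round_half_up(100.0 * n_cov / f.length)),
                fully_covered=n_cov == f.length,
            )
        )
    n_features = len(per_gene)
    n_full = sum(g.fully_covered for g in per_gene)
    cds = [g for g in per_gene if g.kind == "CDS"]
    n_zero_cds = sum(g.covered_bases == 0 for g in cds)
    n_any_cds = len(cds) - n_zero_cds
    summary = {
        "kind": basemap.kind,
        "features": n_features,
        "fully_covered": n_full,
        "fully_covered_percent": format_percent(n_full, n_features) if n_features else "0.0",
        "cds": len(cds),
        "cds_zero_coverage": n_zero_cds,
        "cds_zero_coverage_percent": format_percent(n_zero_cds, len(cds)) if cds else "0.0",
        "cds_any_coverage": n_any_cds,
        "cds_any_coverage_percent": format_percent(n_any_cds, len(cds)) if cds else "0.0",
    }
    return per_gene, summary


def coverage_table(per_gene: Sequence[GeneCoverage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.locus_tag, g.kind, g.covered_bases, g.gene_length, g.percent, g.fully_covered)
            for g in per_gene
        ],
        columns=["locus_tag", "kind", "covered_bases", "gene_length", "percent", "fully_covered"],
    )
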