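#!/usr/bin/env python
"""Per-base evidence maps, gene coverage summaries and masked FASTA atlases.

Builds the read-depth and peptide-evidence base pair maps, computes
per-gene coverage for both, and emits dash-masked FASTA tracks (covered
bases as themselves, uncovered bases as dashes) for circular-genome
visualization.
"""

from pathlib import Path

from proteopolish.coverage_maps import (
    basemap_to_mask,
    coverage_table,
    depth_to_basemap,
    gene_coverage,
    peptides_to_basemap,
)
from proteopolish.io_formats import (
    read_depth_track,
    read_genome,
    read_peptide_ids,
    write_masked_fasta,
)
from proteopolish.peptide_mapping import classify_peptides

RESULTS = Path("results")


def main() -> None:
    observed = read_genome(RESULTS / "sim/genome.fasta", RESULTS / "sim/annotation.tsv")
    corrected = read_genome(RESULTS / "corrected_genome.fasta",
                            RESULTS / "corrected_annotation.tsv")

    depth_map = depth_to_basemap(read_depth_track(RESULTS / "sim/depth.tsv"), observed)
    per_gene_rna, rna_summary = gene_coverage(depth_map, observed)
    coverage_table(per_gene_rna).to_csv(RESULTS / "gene_coverage_reads.tsv",
                                        sep="\t", index=False)
    write_masked_fasta(observed, basemap_to_mask(depth_map),
                       RESULTS / "atlas_reads.fasta")

    peptides = read_peptide_ids(RESULTS / "sim/peptides.tsv", log_e_cutoff=-1)
    classified, _, _ = classify_peptides(peptides, corrected)
    assigned = [c for c in classified if c.category == "assigned"]
    pep_map = peptides_to_basemap(assigned, corrected)
    per_gene_pep, pep_summary = gene_coverage(pep_map, corrected)
    coverage_table(per_gene_pep).to_csv(RESULTS / "gene_coverage_peptides.tsv",
                                        sep="\t", index=False)
    write_masked_fasta(corrected, basemap_to_mask(pep_map),
                       RESULTS / "atlas_peptides.fasta")

    print(f"read depth: {rna_summary['fully_covered']}/{rna_summary['features']} features "
          f"fully covered ({rna_summary['fully_covered_percent']}%)")
    print(f"peptides: {pep_summary['cds_zero_coverage']}/{pep_summary['cds']} CDS with "
          f"zero coverage ({pep_summary['cds_zero_coverage_percent']}%); "
          f"{pep_summary['cds_any_coverage']}/{pep_summary['cds']} with any "
          f"({pep_summary['cds_any_coverage_percent']}%)")
    print("masked FASTA atlases written: atlas_reads.fasta, atlas_peptides.fasta")


if __name__ == "__main__":
    main()
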