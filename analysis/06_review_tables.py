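#!/usr/bin/env python
"""Annotation review: pseudogenes and joins on the synthetic data, plus the
packaged study tables.

Reviews the simulated improvement suggestions against peptide coverage and
applied corrections; summarizes the packaged corrections table (applied vs
not-applied rows) and the transporter cluster table; and reports pathway
completeness of the corrected synthetic annotation.
"""

from pathlib import Path

import pandas as pd

from proteopolish.annotation_review import (
    pathway_presence,
    review_pseudogenes,
    summarize_clusters,
)
from proteopolish.coverage_maps import format_percent
from proteopolish.homopolymer_correction import select_homopolymer_variants, apply_corrections
from proteopolish.io_formats import (
    read_genome,
    read_suggestions,
    read_table1,
    read_table2,
    read_variants,
)

RESULTS = Path("results")


def main() -> None:
    observed = read_genome(RESULTS / "sim/genome.fasta", RESULTS / "sim/annotation.tsv")
    corrected = read_genome(RESULTS / "corrected_genome.fasta",
                            RESULTS / "corrected_annotation.tsv")
    suggestions = read_suggestions(RESULTS / "sim/suggestions.tsv")
    coverage = pd.read_csv(RESULTS / "protein_coverage.tsv", sep="\t")
    records = select_homopolymer_variants(
        read_variants(RESULTS / "sim/variants.tsv"), observed,
        suggestion_loci={t for s in suggestions for t in s.locus_tags},
    )
    applied = [r for r in records if r.applied]

    decisions = review_pseudogenes(suggestions, coverage, applied, observed,
                                   corrected_genome=corrected)
    pd.DataFrame(
        [(",".join(d.locus_tags), d.input_flag,
          "/".join(f"{p:.0f}" for p in d.peptide_coverage),
          d.frame_intact_after_correction, d.decision, d.rationale)
         for d in decisions],
        columns=["locus_tags", "suggestion", "coverage", "frame_intact",
                 "decision", "rationale"],
    ).to_csv(RESULTS / "review_decisions.tsv", sep="\t", index=False)
    print("synthetic suggestion review:")
    for d in decisions:
        print(f"  {','.join(d.locus_tags)} [{d.input_flag}] -> {d.decision}")

    matrix = pathway_presence(corrected, coverage_table=coverage)
    matrix.to_csv(RESULTS / "pathway_matrix.tsv", sep="\t", index=False)
    missing = matrix[matrix["missing"]]
    print(f"pathway steps missing from the corrected annotation: "
          f"{list(missing['role'])} (expected hole: tal)")

    table1 = read_table1()
    print(f"\npackaged corrections table: {len(table1)} rows, "
          f"{sum(r.applied for r in table1)} applied, "
          f"{sum(not r.applied for r in table1)} not applied")

    summary = summarize_clusters(read_table2())
    pd.DataFrame([summary]).to_json(RESULTS / "transporter_summary.json",
                                    orient="records", indent=2)
    print(f"packaged transporter table: {summary['clusters']} clusters, "
          f"{summary['genes']} genes, {summary['img_subunits']['N']} N-subunit loci, "
          f"{summary['covered_genes']} covered genes "
          f"({summary['covered_genes_percent']}%), "
          f"{summary['fully_covered_clusters']} fully covered clusters")

    print("\nprinted-style percentages from printed counts: "
          f"2575/2641 -> {format_percent(2575, 2641)}%, "
          f"815/2580 -> {format_percent(815, 2580)}%, "
          f"1755/2580 -> {format_percent(1755, 2580)}%")


if __name__ == "__main__":
    main()
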