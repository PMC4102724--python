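#!/usr/bin/env python
"""Map identified peptides onto the corrected genome and classify them.

Writes the per-peptide classification, the novelty report (missed genes,
alternate frames, start extensions), per-protein peptide coverage, and the
hydrophobicity/retention-time validation numbers under results/.
"""

from pathlib import Path

import pandas as pd

from proteopolish.io_formats import read_genome, read_peptide_ids
from proteopolish.peptide_mapping import (
    classify_peptides,
    protein_peptide_coverage,
    validate_rt,
)

RESULTS = Path("results")


def main() -> None:
    genome = read_genome(RESULTS / "corrected_genome.fasta",
                         RESULTS / "corrected_annotation.tsv")
    peptides = read_peptide_ids(RESULTS / "sim/peptides.tsv", log_e_cutoff=-1)
    classified, model_calls, novel_calls = classify_peptides(peptides, genome)

    pd.DataFrame(
        [
            (
                c.peptide.sequence,
                c.category,
                ";".join(f"{h.start}-{h.end}@{h.frame:+d}" for h in c.hits),
                ";".join(sorted({h.locus for h in c.hits if h.locus})),
            )
            for c in classified
        ],
        columns=["sequence", "category", "hits", "loci"],
    ).to_csv(RESULTS / "peptide_classification.tsv", sep="\t", index=False)

    novelty_rows = [("novel_gene", f"{c.span[0]}-{c.span[1]}@{c.frame:+d}",
                     ",".join(c.peptides)) for c in novel_calls]
    novelty_rows += [(kind, locus, "") for locus, kind in model_calls]
    pd.DataFrame(novelty_rows, columns=["kind", "where", "peptides"]).to_csv(
        RESULTS / "novelties.tsv", sep="\t", index=False
    )

    coverage = protein_peptide_coverage(classified, genome)
    coverage.to_csv(RESULTS / "protein_coverage.tsv", sep="\t", index=False)

    by_cat = pd.Series([c.category for c in classified]).value_counts()
    assigned = [c.peptide for c in classified if c.category == "assigned"]
    unassigned = [c.peptide for c in classified if c.category == "unassigned"]
    r2_assigned = validate_rt(assigned)
    r2_unassigned = validate_rt(unassigned)
    with open(RESULTS / "rt_validation.txt", "w") as fh:
        fh.write(f"r2_assigned\t{r2_assigned:.4f}\nr2_unassigned\t{r2_unassigned:.4f}\n")

    print("peptide classification:")
    for cat, n in by_cat.items():
        print(f"  {cat}: {n}")
    print(f"novelty calls: {len(novel_calls)} novel gene(s), "
          f"{[f'{k}@{l}' for l, k in model_calls]}")
    print(f"proteins with any peptide coverage: {(coverage['percent'] > 0).sum()}"
          f"/{len(coverage)}")
    print(f"hydrophobicity/RT R^2: assigned {r2_assigned:.3f}, "
          f"unassigned {r2_unassigned:.3f}")


if __name__ == "__main__":
    main()
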