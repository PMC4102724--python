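#!/usr/bin/env python
"""Select and apply transcript-supported genome corrections.

Classifies the variant calls (homopolymer-context indels applied outright,
substitutions only when corroborated), applies the accepted edits in one
pass, lifts the annotation across the offsets, and verifies the corrected
sequence against the simulation ground truth.  Writes the corrected genome,
lifted annotation and a study-style correction table under results/.
"""

import json
from pathlib import Path

from proteopolish.homopolymer_correction import (
    apply_corrections,
    cross_check,
    reported_position,
    select_homopolymer_variants,
)
from proteopolish.io_formats import (
    read_genome,
    read_suggestions,
    read_variants,
    write_corrections,
    write_genome,
)

RESULTS = Path("results")


def main() -> None:
    genome = read_genome(RESULTS / "sim/genome.fasta", RESULTS / "sim/annotation.tsv")
    variants = read_variants(RESULTS / "sim/variants.tsv")
    suggestions = read_suggestions(RESULTS / "sim/suggestions.tsv")

    records = select_homopolymer_variants(
        variants, genome, suggestion_loci={t for s in suggestions for t in s.locus_tags}
    )
    applied = [r for r in records if r.applied]
    corrected, offset_map = apply_corrections(genome, applied)
    counts = cross_check(records, suggestions)

    # report positions in the printed-table convention (corrected coordinate
    # for insertions/substitutions, former coordinate for deletions)
    for r in records:
        r.position = reported_position(r, offset_map)
    write_corrections(records, RESULTS / "corrections.tsv")
    write_genome(corrected, RESULTS / "corrected_genome.fasta",
                 RESULTS / "corrected_annotation.tsv")

    truth = json.loads((RESULTS / "sim/truth.json").read_text())
    exact = corrected.sequence == truth["true_sequence"]
    n_hp = sum(1 for r in applied if r.homopolymer)
    print(f"variant calls: {len(records)}; applied {len(applied)} "
          f"({n_hp} homopolymer indels, {len(applied) - n_hp} corroborated others), "
          f"not applied {len(records) - len(applied)}")
    print(f"corroborations: {counts}")
    print(f"corrected genome length {len(corrected)} "
          f"(offset {len(corrected) - len(genome):+d}); "
          f"restores true sequence exactly: {exact}")


if __name__ == "__main__":
    main()
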