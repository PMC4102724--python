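#!/usr/bin/env python
"""Build the naive proteogenomic peptide database.

Translates the observed genome across all six reading frames into
stop-to-stop elements (no start codon required), digests each element with
trypsin (one missed cleavage), and exports the non-redundant peptide
collection grouped by element to results/peptide_db.fasta.
"""

from pathlib import Path

from proteopolish.io_formats import read_genome
from proteopolish.proteogenomic_db import build_peptide_db, write_db_fasta

RESULTS = Path("results")


def main() -> None:
    genome = read_genome(RESULTS / "sim/genome.fasta", RESULTS / "sim/annotation.tsv")
    db = build_peptide_db([(genome.id, genome.sequence)])
    write_db_fasta(db, RESULTS / "peptide_db.fasta")
    lengths = sorted(len(p) for p in db.peptides)
    print(f"six-frame stop-to-stop elements: {len(db.elements)}")
    print(f"unique tryptic peptides (7-50 aa, <=1 missed cleavage): {len(db.peptides)}")
    print(f"peptide length median {lengths[len(lengths) // 2]} aa; "
          f"database written to {RESULTS / 'peptide_db.fasta'}")


if __name__ == "__main__":
    main()
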