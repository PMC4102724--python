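#!/usr/bin/env python
"""Generate the synthetic study dataset.

Writes the observed (error-bearing) genome and annotation, the transcript
depth track, the variant calls, the peptide identification table, the
improvement suggestions and the ground truth under results/sim/.
"""

import argparse
from pathlib import Path

from proteopolish.synthetic_data import SimConfig, simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = parser.parse_args()

    truth = simulate(SimConfig(seed=args.seed), outdir=args.outdir)
    n_hp = sum(1 for r in truth.injected_errors if r.homopolymer)
    n_sub = len(truth.injected_errors) - n_hp
    print(f"wrote synthetic dataset to {args.outdir}/ (seed {args.seed})")
    print(f"  genome: {len(truth.observed_genome)} bp, "
          f"{len(truth.observed_genome.features)} features "
          f"({len(truth.observed_genome.cds_features())} CDS)")
    print(f"  injected errors: {n_hp} homopolymer indels, {n_sub} substitutions")
    print(f"  detected proteins: {len(truth.detected_loci)}; "
          f"peptide rows: {len(truth.peptide_table)} "
          f"({len(truth.decoy_peptides)} decoys)")
    print(f"  planted novelties: {[k for k, _ in truth.planted_novelties]}")


if __name__ == "__main__":
    main()
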