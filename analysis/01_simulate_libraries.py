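#!/usr/bin/env python
"""Simulate the ground-truth sequencing libraries used by the later steps.

Writes one directory per scenario under results/libraries/ with gzipped
FASTQ pairs, molecule/read truth tables, and the edit-spec config.  The
amplicon scenarios emulate targeted deep sequencing of a point correction
(A-to-G plus synonymous PAM change), an oncogenic point mutation, a 3-bp
codon deletion, and the 32-bp HIV-resistance deletion; the UDiTaS scenario
adds nick-to-nick deletions, large deletions and AAV-integration chimeras.
"""

import argparse
from pathlib import Path

from pequant.synthetic_data import end_to_end_fixture, write_library

SCENARIO_SET = [
    "serpina1_correction",
    "ctnnb1_s45f",
    "ctnnb1_s45del",
    "ccr5_del",
    "uditas_aav",
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2026)
    parser.add_argument("--n-molecules", type=int, default=4000)
    parser.add_argument("--out", type=Path, default=Path("results/libraries"))
    args = parser.parse_args()

    for scenario in SCENARIO_SET:
        config, library = end_to_end_fixture(
            scenario, seed=args.seed, n_molecules=args.n_molecules
        )
        outdir = args.out / scenario
        write_library(library, outdir)
        realized = library.molecule_truth["category"].value_counts(normalize=True)
        print(f"{scenario}: {len(library.r1)} read pairs -> {outdir}")
        for category, fraction in realized.items():
            print(f"    {category:18s} {fraction:.4f}")


if __name__ == "__main__":
    main()
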