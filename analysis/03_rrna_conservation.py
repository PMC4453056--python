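#!/usr/bin/env python
"""WCGU conservation profiles over the simulated rRNA alignment.

Computes the canonical-pair conservation of every interaction site per
sequence group, complements the noncanonical tertiary class, and writes
the ordered profiles (3 groups x 4 site classes = 12 data sets) to
results/conservation_profiles.tsv.
"""
from pathlib import Path

import numpy as np

from mitoparallel.alignments import parse_structure_alignment
from mitoparallel.conservation import conservation_profiles, profiles_to_frame

ROOT = Path(__file__).resolve().parents[1]
ALN = ROOT / "scratch" / "analysis_inputs" / "alignment"
OUT = ROOT / "results" / "conservation_profiles.tsv"


def main() -> None:
    aln = parse_structure_alignment(ALN / "aln.fasta", ALN / "sites.tsv",
                                    ALN / "groups.tsv")
    profiles = conservation_profiles(aln)
    OUT.parent.mkdir(exist_ok=True)
    profiles_to_frame(profiles).to_csv(OUT, sep="\t", index=False)

    print(f"{len(profiles)} ordered profiles -> {OUT.relative_to(ROOT)}")
    for p in profiles:
        print(f"  {p.group:>14s} {p.site_class:<22s} "
              f"n={p.n_sites:3d} mean={np.mean(p.values):5.1f}%")


if __name__ == "__main__":
    main()
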