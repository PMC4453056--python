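#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Writes four input kinds under scratch/analysis_inputs/ with truth
manifests: (1) a ten-genome GenBank set in which two genomes lack atp8 and
one carries a duplicated cox1; (2) a 300-sequence structure-annotated rRNA
alignment with three sequence groups and all four interaction-site
classes; (3) two 722-pair conserved-helix base-pair lists, one G:C-rich
(bacterial-like, 57%) and one A:U-rich (mitoribosome-like, 21%); (4) a
core+accessory protein complex whose accessory chain packs against
designed underwrapped backbone hydrogen bonds.
"""
from pathlib import Path

from mitoparallel.simulate import (
    gen_alignment,
    gen_basepair_list,
    gen_genomes,
    gen_structure,
    make_template_sites,
)

SEED = 20240
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "analysis_inputs"


def main() -> None:
    m = gen_genomes(10, "census_demo", seed=SEED, out_dir=OUT / "genomes")
    print(f"genomes: {m['n']} records, scenario {m['scenario']}")

    sites = make_template_sites({
        "secondary": 30,
        "secondary_A_minor": 10,
        "tertiary_canonical": 10,
        "tertiary_noncanonical": 10,
    })
    m = gen_alignment(
        n_seqs=300,
        sites=sites,
        p_canonical={
            "secondary": 0.95,
            "secondary_A_minor": 0.90,
            "tertiary_canonical": 0.85,
            "tertiary_noncanonical": 0.30,
        },
        p_gap=0.10,
        seed=SEED,
        out_dir=OUT / "alignment",
        group_sizes={"bacterial": 120, "mitochondrial": 120, "plastid": 60},
    )
    print(f"alignment: {m['n_seqs']} sequences x {m['width']} columns, "
          f"{len(m['sites'])} sites")

    for label, frac_gc, frac_au in (("gc_rich", 0.57, 0.38),
                                    ("au_rich", 0.21, 0.74)):
        m = gen_basepair_list(722, frac_gc, frac_au, 0.05,
                              [f"H{i}" for i in range(1, 84)], SEED,
                              OUT / f"pairs_{label}.tsv")
        print(f"pairs_{label}: counts {m['counts']}")

    m = gen_structure("core_plus_accessory", SEED, OUT / "complex.pdb")
    print(f"structure: {m['n_res']} core residues, "
          f"{m['n_bonds_expected']} backbone H-bonds, "
          f"{m['n_wrappers_accessory']} accessory wrapper atoms")


if __name__ == "__main__":
    main()
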