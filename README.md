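# mitoparallel

Comparative analyses of mitochondrial genome and gene reduction, and of the
stability consequences that reduction has for the two big molecular machines
the mitochondrial genome still encodes parts of: the mitoribosome and the
OXPHOS complexes of the inner membrane.

The package is aimed at molecular evolution and structural bioinformatics
researchers who want to quantify, on annotated organellar genome records,
structure-annotated rRNA alignments, base-pair inventories and atomic
coordinates:

1. **Gene-length census** — per genome, the total rRNA length (SSU + LSU +
   5S when present, fragments summed, duplicates resolved to the longest
   copy), the mean tRNA length, and the summed amino-acid lengths of the
   mitochondrially encoded OXPHOS subunits per complex
   (cI = nad1–nad6 + nad4L, cIII = cytb, cIV = cox1–cox3, cV = atp6 + atp8),
   with genomes missing a required gene or carrying OXPHOS duplicates
   excluded from the affected tallies.
2. **rRNA pairing conservation (WCGU)** — for an interaction site (a pair
   of alignment columns), the fraction of sequences carrying a canonical
   pair (Watson:Crick or G:U) among the sequences with nucleotides at both
   columns:

   `WCGU = 100 · #{canonical pairs} / #{rows with 2 nt at the site}`

   Gapped rows never enter the denominator, so the statistic is insensitive
   to rRNA length reduction. Sites are classed as regular secondary,
   secondary-within-A-minor, canonical tertiary, or noncanonical tertiary
   (scored as 100 − WCGU), and profiles are ordered per sequence group.
3. **Helix-core base-pair composition** — G:C / A:U / G:U / other fractions
   over a conserved-helix set, with hydrogen-bond accounting
   (G:C = 3, A:U = G:U = 2 bonds) and bond differentials between cores:
   a pure G:C→A:U swap costs one bond per pair.
4. **Structural deficiency** — the fraction of a structure's backbone
   hydrogen bonds that are *underwrapped* (dehydrons): bonds whose
   desolvation spheres (radius 6.5 Å on the donor and acceptor CA atoms)
   contain fewer than a threshold number ρ of nonpolar carbonaceous groups
   (carbons bonded only to C/H). Comparing a mitochondrially encoded core
   with and without accessory subunit chains as wrappers quantifies how
   much third-party packing stabilizes the core.

A seed-deterministic synthetic-data module generates all four input kinds
(GenBank records, gapped FASTA + site tables, pair TSVs, PDB files) with
JSON truth manifests, so the whole pipeline is testable offline.

## Worked example

The numbered scripts under `analysis/` run the four analyses over the
synthetic study set (inputs land in `scratch/`, tables in `results/`):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_gene_length_census.py
python analysis/03_rrna_conservation.py
python analysis/04_helix_composition.py
python analysis/05_structural_deficiency.py
```

`02` censuses ten genomes, two of which lack atp8 and one of which carries
a duplicated cox1:

```
10 genomes censused -> results/census.tsv
total rRNA range: 1620-2289 nt
rows with a complete OXPHOS total: 7 (atp8-less and duplicate-carrying genomes excluded)
```

`04` contrasts a G:C-rich (bacterial-like) with an A:U-rich
(mitoribosome-like) conserved core of 722 pairs:

```
gc_rich: 722 pairs, 57.1% G:C, 38.0% A:U, 1856 hydrogen bonds
au_rich: 722 pairs, 21.1% G:C, 74.0% A:U, 1596 hydrogen bonds
hydrogen-bond loss of the A:U-rich core: 260
```

i.e. dropping the G:C fraction from 57% to 21% over a fixed-size core costs
260 hydrogen bonds — one per swapped pair.

`05` shows the accessory-subunit effect on five replicate complexes:

```
 -accessory: deficiency 33.37% +/- 2.52 (n=5)
 +accessory: deficiency 21.32% +/- 4.81 (n=5)
accessory chains reduce the underprotected fraction by 12.04 percentage points
```

The H-bond set is fixed by the core, so adding wrapper chains can only
lower the deficiency — the package's central monotonicity property.

The same stages are exposed as a CLI
(`mitoparallel census|conservation|composition|composition-diff|deficiency|simulate|run`)
and as a YAML-configured pipeline (`mitoparallel run --config run.yaml`)
that records a provenance block with every parameter affecting any output.

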