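# Methods

## Scope and data model

The package implements four comparative analyses over organellar data:
a gene-length census of annotated mitochondrial genomes, per-site pairing
conservation of structure-annotated rRNA alignments, base-pair composition
of a conserved helix core with hydrogen-bond accounting, and a
backbone-hydrogen-bond wrapping ("structural deficiency") calculator for
atomic structures. All external formats (GenBank flat files via Biopython,
PDB/mmCIF via gemmi, gapped FASTA plus TSV site tables) are mapped onto a
small set of domain types at the io boundary; every analysis consumes only
those types.

## Gene-length census

Per genome we report total rRNA nucleotides, mean tRNA length and summed
amino-acid lengths of the mitochondrially encoded OXPHOS subunits,
plotted-ready against genome size in kb.

*Summation rules.* rRNA genes (SSU, LSU, 5S when annotated) are summed
after two normalizations: fragments of one gene copy (split or
trans-spliced annotations) are added together, and duplicated copies are
collapsed to the single longest copy. The total is reported absent unless
at least one of SSU/LSU is annotated. tRNA lengths are averaged over *all*
annotated tRNAs, duplicates included — the duplicate exclusion applies to
the rRNA and OXPHOS tallies only. OXPHOS sums per complex are
cI = nad1+nad2+nad3+nad4+nad4L+nad5+nad6, cIII = cytb,
cIV = cox1+cox2+cox3, cV = atp6+atp8; a complex is reported absent when
any of its genes is missing or duplicated, and the grand total requires
all four complexes. Protein lengths come from the `/translation`
qualifier when present, else `length_nt/3 − 1` for in-frame CDS.

*Fragment vs duplicate.* GenBank has no formal marker separating a second
gene copy from a second fragment of one copy. Compound `join()` locations
are always fragment-summed within a feature. Across features we treat a
repeated symbol as a fragment of the previous copy when the feature
carries a `/note` containing "fragment" (the common marking for split
organellar genes) and as a new copy otherwise. The synthetic generator
emits exactly this convention, and the writer round-trips it.

*Filters.* `/pseudo`-flagged and partial features are excluded by default
(eroded pseudogene copies would otherwise deflate length averages).
Parasite exclusion is an explicit taxon-group filter supplied by the
caller, not inferred — there is no computable definition of "parasitic"
in an annotation record.

## WCGU conservation

For an interaction site (columns *i*, *j*) and an optional sequence-group
filter, `wcgu` = 100 × (rows whose bases at *i*, *j* form AU/GC/GU in
either orientation) / (rows with a resolved nucleotide at both columns).
Only A, C, G, U count as resolved; IUPAC ambiguity codes are treated like
gaps because an ambiguous base cannot be scored canonical without
guessing. Rows gapped at either column drop out of the denominator, which
makes the statistic invariant to length reduction: deleting a site's bases
from some sequences changes the sample size but not the expected value.
Noncanonical tertiary sites are scored as 100 − WCGU. Profiles are
produced per (group × site class) — three groups and four classes give
twelve data sets — sorted descending by default (direction configurable),
ties stable by site index.

## Helix composition and hydrogen-bond accounting

Pairs are classified by unordered base pair into GC/AU/GU/other and
restricted to a helix set before counting. The shipped default set lists
83 helix ids as an editable placeholder for a conserved large-subunit core
membership, which is a curation input, not a computation. Hydrogen bonds
are counted with the standard Watson–Crick/wobble weights G:C = 3,
A:U = 2, G:U = 2; the "other" weight defaults to 2 and is configurable —
a differential dominated by proportional G:C↔A:U swapping is insensitive
to it. Fractions are exact rationals internally; the report exposes
percentages. The differential between two equal-weight reports is a plain
integer subtraction of bond totals, so a pure swap of *k* G:C pairs for
A:U pairs across equal-sized cores yields exactly *k*.

By default every annotated pair in the selected helices is counted; a
`canonical_only` switch restricts to GC/AU/GU if the input list mixes in
noncanonical annotations.

## Structural deficiency

*H-bond detection.* Backbone amide-N → carbonyl-O bonds are detected
geometrically: N···O ≤ 3.5 Å and N–H···O ≥ 140°, with the amide hydrogen
taken from the file when present and otherwise rebuilt at 1.01 Å along
the external bisector of CA–N–C(prev). Proline never donates; partners
must be ≥ 2 positions apart within a chain; both must lie in the analysed
subset. Residues with a partially missing backbone are skipped with a
warning; residues with no backbone atoms at all (ligand fragments,
pseudo-atom wrappers) are silently non-peptide. These thresholds are
conventional geometric criteria; they are stamped, together with every
other parameter, into each report.

*Wrapping.* A bond's wrapping number ρ counts nonpolar carbonaceous
groups — carbon atoms whose covalent neighbours are only carbon or
hydrogen — inside the union of two spheres of radius 6.5 Å centred on the
donor and acceptor CA atoms, each wrapper counted once. Membership is
decided from connectivity templates for the 20 standard residues (e.g.
alanine CB qualifies; carbonyl, carboxylate and any carbon bonded to
N/O/S do not); nonstandard residues fall back to distance-based bond
inference at 1.9 Å with a warning. Waters never contribute; hetero
compounds (lipids, hemes) are excluded unless explicitly opted in, since
like-for-like protein comparisons should not hinge on crystallized
cofactor content. The production path uses a k-d tree; an all-pairs scan
serves as the independent oracle in the tests.

*Deficiency and comparisons.* A bond is underprotected when ρ < 19 (a
mean-minus-one-SD convention for soluble folds; configurable, and the
synthetic analyses use the threshold recorded in their manifests).
Deficiency is the percentage of underprotected bonds. The ± accessory
comparison holds the bond set fixed (bonds are detected within the core
chains only) and varies only the wrapper selection, so adding accessory
chains can never raise ρ of any bond — deficiency(+accessory) ≤
deficiency(−accessory) holds structurally, and the tests verify it over
randomized complexes. Replicate structures aggregate as mean and sample
SD (n−1), SD absent for single structures.

*Limitations.* No membrane model is applied: membrane-facing bonds are
"underwrapped" by construction, but comparisons are made between membrane
proteins, so the bias largely cancels. No energy model, dynamics or
side-chain repacking; wrapping is a static count.

## Synthetic data

Generators write standard formats plus a JSON manifest holding every
truth value a test needs, and are byte-deterministic for a fixed seed.

* **Genomes** — 13 OXPHOS CDS with lengths jittered ±10% around typical
  metazoan values, 22 tRNAs of 55–75 nt, SSU/LSU lengths drawn per taxon
  group so that total rRNA spans the observed continuum from roughly
  1,500 nt (derived bilaterians) to 5,500 nt (fungi/plants). Scenarios
  control gene dropout, duplication and rRNA fragmentation; the
  `census_demo` set fixes 10 genomes with 2 atp8-less and 1
  cox1-duplicated. CDS nucleotide sequences are literal back-translations
  of the `/translation` qualifier plus a stop, so lengths are consistent
  by construction.
* **Alignments** — at each site a sequence is gapped at both columns with
  `p_gap`, else canonical with the class's `p_canonical` (uniform over the
  six canonical combinations) or noncanonical (uniform over the other
  ten). Non-site columns are uniform. No tree or substitution model is
  simulated: the analyses only consume per-site pair frequencies, so
  position-independent Bernoulli draws are the appropriate minimal model —
  which also means passing tests say nothing about phylogenetic
  correlation structure in real alignments.
* **Pair lists** — exact per-type counts by largest-remainder rounding,
  randomized order and orientation.
* **Structures** — ideal α-helix backbones (φ = −57°, ψ = −47°, standard
  bond geometry via natural-extension-frame placement; the resulting
  O(i)···N(i+4) distance is 3.09 Å at 166°, giving exactly n − 4 bonds
  for an n-residue helix). Helices are poly-glycine so the backbone
  contributes zero nonpolar carbons and wrapping is fully controlled by
  explicitly placed single-carbon (alanine CB) wrapper residues. Because
  neighbouring bonds' 6.5 Å spheres overlap along a helix, per-bond truth
  is computed post hoc inside the generator by a plain distance scan
  (independent of the production tree-search path) and recorded in the
  manifest. The `core_plus_accessory` scenario wraps the first half of a
  ≥40-residue helix and leaves a long bare tail whose final two bonds the
  accessory chain then protects, guaranteeing a strict deficiency decrease.

## Problem sizes and numerical choices

The shipped analyses and the acceptance script use 10 genomes, a
300 × 130 alignment with 60 sites, 722-pair compositions, and helices of
8–48 residues with ≤ 60 wrapper atoms — sizes chosen so each stage
completes in seconds while every statistic is well away from small-sample
degeneracy. Exact-equality checks (gap invariance, complement identity,
oracle equivalence) are asserted with no tolerance; statistical recovery
checks use two binomial standard errors of their generator parameters.
Degenerate inputs error loudly rather than return silent zeros: empty
genome lists, alignments with no resolved rows at a site (reported
absent), pair lists outside the helix set, and subsets without backbone
bonds all raise with named causes.
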