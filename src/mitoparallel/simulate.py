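"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator writes standard on-disk formats (GenBank, FASTA + TSV, TSV,
PDB) plus a JSON manifest recording the true parameters and derived truth
values, so tests exercise the io layer end to end and can check results
against the manifest rather than against the production code path.

All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .genbank import write_genbank_record
from .types import GeneFeature, OrganelleGenome, SITE_CLASSES

# ---------------------------------------------------------------------------
# genomes

# typical metazoan mitochondrial protein lengths (aa), jittered per genome
_OXPHOS_AA = {
    "nad1": 318, "nad2": 347, "nad3": 115, "nad4": 459, "nad4L": 98,
    "nad5": 603, "nad6": 174, "cytb": 380,
    "cox1": 513, "cox2": 227, "cox3": 261, "atp6": 226, "atp8": 68,
}
_TRNA_AAS = "ACDEFGHIKLMNPQRSTVWY"

# per-taxon rRNA length ranges (nt); the observed continuum spans roughly
# 1,500 nt (derived bilaterians) to 5,500 nt (fungi/plants)
_RRNA_RANGES = {
    "bilateria": ((650, 950), (900, 1600)),
    "early_metazoa": ((1100, 1500), (1700, 2400)),
    "fungi": ((1400, 1900), (2700, 3700)),
    "plants": ((1700, 2000), (3200, 3600)),
    "protists": ((1200, 1800), (2300, 3200)),
}

GENOME_SCENARIOS = (
    "complete13", "missing_atp8", "duplicated_cox1", "fragmented_rrnL",
    "census_demo", "bilateria", "fungi", "mixed",
)


def _norm_scenario(s: str) -> str:
    return s.strip().lower().replace("-", "_")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _one_genome(
    rng: np.random.Generator,
    idx: int,
    taxon_group: str = "bilateria",
    drop_genes: Sequence[str] = (),
    duplicate_genes: Sequence[str] = (),
    fragment_rrnL: bool = False,
) -> tuple[OrganelleGenome, str, dict]:
    """Build one genome, its nucleotide sequence and its truth record."""
    rS_rng, rL_rng = _RRNA_RANGES.get(taxon_group, _RRNA_RANGES["bilateria"])
    feats: list[tuple[GeneFeature, str]] = []

    def add(symbol, kind, length_nt, aa=None, copy=1, frag=1, seq=None):
        f = GeneFeature(symbol=symbol, feature_kind=kind, length_nt=length_nt,
                        protein_length_aa=aa, copy_index=copy, fragment_index=frag)
        feats.append((f, seq if seq is not None else _random_bases(rng, length_nt)))

    rrnS_len = int(rng.integers(*rS_rng))
    rrnL_len = int(rng.integers(*rL_rng))
    if "rrnS" not in drop_genes:
        add("rrnS", "rRNA", rrnS_len)
        if "rrnS" in duplicate_genes:
            add("rrnS", "rRNA", max(100, rrnS_len - int(rng.integers(5, 40))),
                copy=2)
    if "rrnL" not in drop_genes:
        if fragment_rrnL:
            cut = rrnL_len // 2 + int(rng.integers(-50, 50))
            add("rrnL", "rRNA", cut)
            add("rrnL", "rRNA", rrnL_len - cut, frag=2)
        else:
            add("rrnL", "rRNA", rrnL_len)

    for aa in _TRNA_AAS:
        add(f"trn{aa}", "tRNA", int(rng.integers(55, 76)))
    # duplicated leucine and serine tRNAs, as in most animal mt genomes
    for aa in "LS":
        add(f"trn{aa}", "tRNA", int(rng.integers(55, 76)), copy=2)

    for gene, base_aa in _OXPHOS_AA.items():
        if gene in drop_genes:
            continue
        n_copies = 2 if gene in duplicate_genes else 1
        for copy in range(1, n_copies + 1):
            aa = max(30, int(round(base_aa * rng.uniform(0.9, 1.1))))
            nt = "ATG" + "GCT" * (aa - 1) + "TAA"
            add(gene, "CDS", len(nt), aa=aa, copy=copy, seq=nt)

    parts = []
    for _, seq in feats:
        parts.append(seq)
        parts.append(_random_bases(rng, 10))
    parts.append(_random_bases(rng, 200))
    genome_seq = "".join(parts)

    genome = OrganelleGenome(
        organism=f"Synthorg species{idx:03d}",
        taxon_group=taxon_group,
        genome_size_bp=len(genome_seq),
        features=[f for f, _ in feats],
    )

    truth = _census_truth(genome)
    truth.update(
        organism=genome.organism,
        taxon_group=taxon_group,
        genome_size_bp=genome.genome_size_bp,
        genes=[
            {"symbol": f.symbol, "kind": f.feature_kind, "length_nt": f.length_nt,
             "aa": f.protein_length_aa, "copy": f.copy_index,
             "fragment": f.fragment_index}
            for f, _ in feats
        ],
    )
    return genome, genome_seq, truth


def _census_truth(genome: OrganelleGenome) -> dict:
    """Independent arithmetic over the feature list (census-module oracle)."""
    rrna_total = 0
    seen_core = False
    for sym in ("rrnS", "rrnL", "rrn5"):
        per_copy: dict[int, int] = {}
        for f in genome.features:
            if f.feature_kind == "rRNA" and f.symbol == sym:
                per_copy[f.copy_index] = per_copy.get(f.copy_index, 0) + f.length_nt
        if per_copy:
            rrna_total += max(per_copy.values())
            if sym != "rrn5":
                seen_core = True
    trnas = [f.length_nt for f in genome.features if f.feature_kind == "tRNA"]
    complexes = {
        "cI": ("nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"),
        "cIII": ("cytb",), "cIV": ("cox1", "cox2", "cox3"),
        "cV": ("atp6", "atp8"),
    }
    by_sym: dict[str, list[GeneFeature]] = {}
    for f in genome.features:
        if f.feature_kind == "CDS":
            by_sym.setdefault(f.symbol, []).append(f)
    cx_truth: dict[str, Optional[int]] = {}
    for cx, genes in complexes.items():
        total = 0
        ok = True
        for g in genes:
            fs = by_sym.get(g, [])
            if len({f.copy_index for f in fs}) != 1:
                ok = False
                break
            total += sum(f.protein_length_aa or 0 for f in fs)
        cx_truth[cx] = total if ok else None
    all_present = all(v is not None for v in cx_truth.values())
    return {
        "total_rrna_nt": rrna_total if seen_core else None,
        "mean_trna_nt": (sum(trnas) / len(trnas)) if trnas else None,
        "oxphos": cx_truth,
        "total_oxphos_aa": sum(cx_truth.values()) if all_present else None,  # type: ignore[arg-type]
    }


def gen_genomes(
    n: int,
    scenario: str,
    seed: int,
    out_dir: Union[str, Path],
) -> dict:
    """Write ``n`` GenBank records plus a JSON manifest; returns the manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scenario = _norm_scenario(scenario)
    if scenario not in GENOME_SCENARIOS:
        raise ValueError(
            f"unknown genome scenario {scenario!r}; known: {GENOME_SCENARIOS}"
        )
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups_cycle = ["bilateria", "early_metazoa", "fungi", "plants", "protists"]
    records = []
    for i in range(n):
        kwargs: dict = {"taxon_group": "bilateria"}
        if scenario == "missing_atp8":
            kwargs["drop_genes"] = ("atp8",)
        elif scenario == "duplicated_cox1":
            kwargs["duplicate_genes"] = ("cox1",)
        elif scenario == "fragmented_rrnL":
            kwargs["fragment_rrnL"] = True
        elif scenario == "fungi":
            kwargs["taxon_group"] = "fungi"
        elif scenario == "mixed":
            kwargs["taxon_group"] = groups_cycle[i % len(groups_cycle)]
        elif scenario == "census_demo":
            # 10-genome demo: genomes 0-1 miss atp8, genome 2 duplicates cox1
            if i in (0, 1):
                kwargs["drop_genes"] = ("atp8",)
            elif i == 2:
                kwargs["duplicate_genes"] = ("cox1",)
        genome, seq, truth = _one_genome(rng, i, **kwargs)
        path = out_dir / f"genome_{i:03d}.gbk"
        path.write_text(write_genbank_record(genome, seq))
        truth["file"] = path.name
        records.append(truth)

    manifest = {"seed": seed, "scenario": scenario, "n": n, "genomes": records}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# alignments

_CANONICAL_PAIRS = ["AU", "UA", "GC", "CG", "GU", "UG"]
_ALL_PAIRS = [a + b for a in "ACGU" for b in "ACGU"]
_NONCANONICAL_PAIRS = [p for p in _ALL_PAIRS if p not in _CANONICAL_PAIRS]


def make_template_sites(n_per_class: Union[int, dict], spacing: int = 0) -> list[tuple[int, int, str]]:
    """Lay out site column pairs left to right, cycling the four classes."""
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in SITE_CLASSES}
    sites = []
    col = 1
    for cls in SITE_CLASSES:
        for _ in range(n_per_class.get(cls, 0)):
            sites.append((col, col + 1, cls))
            col += 2 + spacing
    return sites


def gen_alignment(
    n_seqs: int,
    sites: Union[list[tuple[int, int, str]], int],
    p_canonical: Union[float, dict],
    p_gap: float,
    seed: int,
    out_dir: Union[str, Path],
    group_sizes: Optional[dict[str, int]] = None,
    extra_columns: int = 10,
) -> dict:
    """Write aln.fasta, sites.tsv, groups.tsv and manifest.json.

    At every interaction site each sequence is independently gapped at both
    columns with probability ``p_gap``; otherwise it carries a canonical
    pair with the class's ``p_canonical`` (uniform over the six canonical
    combinations) or a noncanonical pair. Non-site columns are uniform.
    """
    if isinstance(sites, int):
        sites = make_template_sites({"secondary": sites})
    if isinstance(p_canonical, float) or isinstance(p_canonical, int):
        p_canonical = {c: float(p_canonical) for c in SITE_CLASSES}
    for c, p in p_canonical.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_canonical[{c}]={p} outside [0,1]")
    if not 0.0 <= p_gap <= 1.0:
        raise ValueError(f"p_gap={p_gap} outside [0,1]")

    rng = np.random.default_rng(seed)
    width = max(s[1] for s in sites) + extra_columns
    if group_sizes is None:
        group_sizes = {"mitochondrial": n_seqs}
    if sum(group_sizes.values()) != n_seqs:
        raise ValueError("group sizes must sum to n_seqs")
    groups = [g for g, k in group_sizes.items() for _ in range(k)]

    rows = rng.choice(list("ACGU"), size=(n_seqs, width))
    for col_i, col_j, cls in sites:
        p = p_canonical[cls]
        for s in range(n_seqs):
            u = rng.random()
            if u < p_gap:
                rows[s, col_i - 1] = "-"
                rows[s, col_j - 1] = "-"
            else:
                if rng.random() < p:
                    pair = _CANONICAL_PAIRS[rng.integers(len(_CANONICAL_PAIRS))]
                else:
                    pair = _NONCANONICAL_PAIRS[rng.integers(len(_NONCANONICAL_PAIRS))]
                rows[s, col_i - 1] = pair[0]
                rows[s, col_j - 1] = pair[1]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_ids = [f"seq{i:04d}" for i in range(n_seqs)]
    with open(out_dir / "aln.fasta", "w") as fh:
        for sid, row in zip(seq_ids, rows):
            fh.write(f">{sid}\n{''.join(row)}\n")
    with open(out_dir / "sites.tsv", "w") as fh:
        fh.write("col_i\tcol_j\tsite_class\n")
        for col_i, col_j, cls in sites:
            fh.write(f"{col_i}\t{col_j}\t{cls}\n")
    with open(out_dir / "groups.tsv", "w") as fh:
        fh.write("seq_id\tgroup\n")
        for sid, g in zip(seq_ids, groups):
            fh.write(f"{sid}\t{g}\n")

    manifest = {
        "seed": seed,
        "n_seqs": n_seqs,
        "width": width,
        "p_gap": p_gap,
        "p_canonical": p_canonical,
        "sites": [{"col_i": a, "col_j": b, "site_class": c} for a, b, c in sites],
        "groups": group_sizes,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# base-pair lists

_PAIR_BASES = {"GC": ("G", "C"), "AU": ("A", "U"), "GU": ("G", "U"),
               "other": ("A", "C")}


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer counts summing to n, by the largest-remainder method."""
    quotas = [n * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    shortfall = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (quotas[i] - counts[i], -i),
                   reverse=True)
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def gen_basepair_list(
    n_pairs: int,
    frac_gc: float,
    frac_au: float,
    frac_gu: float,
    helix_labels: Sequence[str],
    seed: int,
    out_path: Union[str, Path],
) -> dict:
    """Write a pair TSV with exact per-type counts; returns the manifest."""
    if frac_gc + frac_au + frac_gu > 1.0 + 1e-9:
        raise ValueError("fractions sum to more than 1")
    frac_other = max(0.0, 1.0 - frac_gc - frac_au - frac_gu)
    counts = largest_remainder_counts(
        n_pairs, [frac_gc, frac_au, frac_gu, frac_other]
    )
    labels = ["GC", "AU", "GU", "other"]
    rng = np.random.default_rng(seed)
    records = []
    res = 1
    for label, count in zip(labels, counts):
        for _ in range(count):
            b1, b2 = _PAIR_BASES[label]
            if rng.random() < 0.5:
                b1, b2 = b2, b1
            helix = helix_labels[int(rng.integers(len(helix_labels)))]
            records.append((helix, f"r{res}", f"r{res + 1}", b1, b2))
            res += 2
    perm = rng.permutation(len(records))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        fh.write("helix_id\tres_i\tres_j\tbase_i\tbase_j\n")
        for i in perm:
            fh.write("\t".join(records[i]) + "\n")
    manifest = {
        "seed": seed,
        "n_pairs": n_pairs,
        "counts": dict(zip(labels, counts)),
        "file": out_path.name,
    }
    manifest_path = out_path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# structures

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7

STRUCTURE_SCENARIOS = ("ideal_helix", "wrapped_helix", "core_plus_accessory",
                       "random_complex")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension-reference-frame atom placement."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_ideal_helix(
    n_res: int,
    phi: float = -57.0,
    psi: float = -47.0,
    resname: str = "GLY",
) -> list[dict]:
    """Backbone coordinates of an ideal alpha-helix.

    Returns one dict per residue with N, CA, C, O positions (numpy arrays).
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords: list[dict] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = coords[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N,
                        _ANGLE_CA_C_N, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, _BOND_N_CA,
                         _ANGLE_C_N_CA, 180.0)
        c = _place_atom(prev["C"], n, ca, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl O in the peptide plane, trans to the next amide N
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            nxt = coords[i + 1]["N"]
            d = -(_unit(nxt - res["C"]) + _unit(res["CA"] - res["C"]))
        else:
            d = -(_unit(coords[i - 1]["C"] - res["C"]) + _unit(res["CA"] - res["C"]))
        res["O"] = res["C"] + _BOND_C_O * _unit(d)
        res["resname"] = resname
    return coords


def _unit(v):
    return v / np.linalg.norm(v)


def _structure_to_pdb(
    helix: list[dict],
    wrappers_core: Sequence[np.ndarray],
    wrappers_accessory: Sequence[np.ndarray],
    out_path: Path,
    chain_core: str = "A",
    chain_accessory: str = "B",
) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_core)
    seq = 1
    for res in helix:
        r = gemmi.Residue()
        r.name = res["resname"]
        r.seqid = gemmi.SeqId(seq, " ")
        r.het_flag = "A"
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(element)
            p = res[name]
            a.pos = gemmi.Position(p[0], p[1], p[2])
            a.occ = 1.0
            r.add_atom(a)
        chain.add_residue(r)
        seq += 1
    for pos in wrappers_core:
        r = gemmi.Residue()
        r.name = "ALA"
        r.seqid = gemmi.SeqId(seq, " ")
        r.het_flag = "A"
        a = gemmi.Atom()
        a.name = "CB"
        a.element = gemmi.Element("C")
        a.pos = gemmi.Position(pos[0], pos[1], pos[2])
        a.occ = 1.0
        r.add_atom(a)
        chain.add_residue(r)
        seq += 1
    model.add_chain(chain)
    if len(wrappers_accessory) > 0:
        bchain = gemmi.Chain(chain_accessory)
        bseq = 1
        for pos in wrappers_accessory:
            r = gemmi.Residue()
            r.name = "ALA"
            r.seqid = gemmi.SeqId(bseq, " ")
            r.het_flag = "A"
            a = gemmi.Atom()
            a.name = "CB"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(pos[0], pos[1], pos[2])
            a.occ = 1.0
            r.add_atom(a)
            bchain.add_residue(r)
            bseq += 1
        model.add_chain(bchain)
    st.add_model(model)
    st.write_pdb(str(out_path))


def _helix_bonds(n_res: int) -> list[tuple[int, int]]:
    """(donor_index, acceptor_index) 0-based, donor i+4 -> acceptor i."""
    return [(i + 4, i) for i in range(n_res - 4)]


def _true_rho(
    bonds: list[tuple[int, int]],
    helix: list[dict],
    wrapper_positions: Sequence[np.ndarray],
    radius: float,
) -> list[int]:
    """Plain distance scan over the generator's own wrapper coordinates."""
    out = []
    for donor, acceptor in bonds:
        ca_d, ca_a = helix[donor]["CA"], helix[acceptor]["CA"]
        k = 0
        for w in wrapper_positions:
            if (np.linalg.norm(w - ca_d) <= radius
                    or np.linalg.norm(w - ca_a) <= radius):
                k += 1
        out.append(k)
    return out


def _random_points_near(
    rng: np.random.Generator, center: np.ndarray, k: int,
    dmin: float = 2.0, dmax: float = 5.0,
) -> list[np.ndarray]:
    pts = []
    for _ in range(k):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v)
        pts.append(center + v * rng.uniform(dmin, dmax))
    return pts


def gen_structure(
    scenario: str,
    seed: int,
    out_path: Union[str, Path],
    n_res: int = 10,
    k_wrappers: int = 5,
    radius: float = 6.5,
    rho_threshold: int = 5,
) -> dict:
    """Write a synthetic PDB file plus manifest; returns the manifest.

    Scenarios:

    * ``ideal_helix`` — bare poly-glycine helix; n_res − 4 backbone bonds.
    * ``wrapped_helix`` — helix plus ``k_wrappers`` carbon wrappers per bond
      (true per-bond rho recorded post hoc; neighbouring spheres overlap).
    * ``core_plus_accessory`` — long, half-wrapped core helix with an
      accessory chain lifting designed-deficient bonds above threshold.
    * ``random_complex`` — randomized helix and wrapper clouds for
      oracle-equivalence and monotonicity testing.
    """
    scenario = _norm_scenario(scenario)
    if scenario not in STRUCTURE_SCENARIOS:
        raise ValueError(
            f"unknown structure scenario {scenario!r}; known: {STRUCTURE_SCENARIOS}"
        )
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    wrappers_core: list[np.ndarray] = []
    wrappers_acc: list[np.ndarray] = []

    if scenario == "ideal_helix":
        helix = build_ideal_helix(n_res)
        bonds = _helix_bonds(n_res)
    elif scenario == "wrapped_helix":
        helix = build_ideal_helix(n_res)
        bonds = _helix_bonds(n_res)
        for donor, _ in bonds:
            wrappers_core.extend(
                _random_points_near(rng, helix[donor]["CA"], k_wrappers,
                                    2.0, radius - 1.5)
            )
    elif scenario == "core_plus_accessory":
        n_res = max(n_res, 40)
        helix = build_ideal_helix(n_res)
        bonds = _helix_bonds(n_res)
        # wrap the first-half bonds well; leave a long bare tail so the
        # last bonds stay below threshold in the core-only condition
        n_wrapped = len(bonds) // 2
        for donor, _ in bonds[:n_wrapped]:
            wrappers_core.extend(
                _random_points_near(rng, helix[donor]["CA"],
                                    rho_threshold + 2, 2.0, 4.0)
            )
        # accessory chain protects the last two bonds
        for donor, _ in bonds[-2:]:
            wrappers_acc.extend(
                _random_points_near(rng, helix[donor]["CA"],
                                    rho_threshold + 2, 2.0, 4.0)
            )
    else:  # random_complex
        n_res = int(rng.integers(8, 25))
        helix = build_ideal_helix(n_res)
        bonds = _helix_bonds(n_res)
        center = np.mean([r["CA"] for r in helix], axis=0)
        for _ in range(int(rng.integers(0, 30))):
            wrappers_core.append(center + rng.normal(scale=8.0, size=3))
        for _ in range(int(rng.integers(0, 30))):
            wrappers_acc.append(center + rng.normal(scale=8.0, size=3))

    rho_core = _true_rho(bonds, helix, wrappers_core, radius)
    rho_plus = _true_rho(bonds, helix, wrappers_core + wrappers_acc, radius)

    if scenario == "core_plus_accessory":
        crossed = sum(
            1 for rc, rp in zip(rho_core, rho_plus)
            if rc < rho_threshold <= rp
        )
        if crossed < 1:
            raise RuntimeError("accessory design failed to protect any bond")

    _structure_to_pdb(helix, wrappers_core, wrappers_acc, out_path)
    manifest = {
        "seed": seed,
        "scenario": scenario,
        "n_res": n_res,
        "radius": radius,
        "rho_threshold": rho_threshold,
        "n_bonds_expected": len(bonds),
        "bonds": [
            {"donor_seq": d + 1, "acceptor_seq": a + 1, "rho_core": rc,
             "rho_with_accessory": rp}
            for (d, a), rc, rp in zip(bonds, rho_core, rho_plus)
        ],
        "n_atoms": 4 * len(helix) + len(wrappers_core) + len(wrappers_acc),
        "n_wrappers_core": len(wrappers_core),
        "n_wrappers_accessory": len(wrappers_acc),
        "file": out_path.name,
    }
    out_path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
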