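"""Structural deficiency: underwrapped backbone hydrogen bonds (dehydrons).

A backbone amide-to-carbonyl hydrogen bond is detected geometrically
(N···O distance and N–H···O angle, with the amide hydrogen rebuilt at its
ideal position when absent). Each bond's *wrapping number* rho counts the
nonpolar carbonaceous groups — carbon atoms covalently bonded only to
carbon or hydrogen — inside the union of two desolvation spheres centred
on the donor and acceptor CA atoms. Bonds with rho below a threshold are
underprotected; the fraction of such bonds is the structure's deficiency.

Comparing a core subset of chains with and without additional "wrapper"
chains (e.g. mitochondrion-specific accessory subunits around the
mitochondrially encoded OXPHOS core) quantifies how much third-party
packing protects the core's hydrogen bonds: the bond set is fixed by the
core, so extra wrapper chains can only raise rho, never lower it.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .types import Atom, AtomicStructure, Residue

logger = logging.getLogger(__name__)

# Carbon atoms of the standard residues whose bonded neighbours are all
# carbon or hydrogen. Backbone CA (bonded to N) and carbonyl C (bonded to O)
# never qualify.
NONPOLAR_CARBONS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset(),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

_BOND_INFERENCE_CUTOFF = 1.9  # Angstrom, fallback for nonstandard residues


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric backbone H-bond definition."""

    max_no_distance: float = 3.5  # N...O, Angstrom
    min_nho_angle: float = 140.0  # N-H...O, degrees
    min_separation: int = 2  # |i - j| within a chain

    def as_dict(self) -> dict:
        return {
            "max_no_distance": self.max_no_distance,
            "min_nho_angle": self.min_nho_angle,
            "min_separation": self.min_separation,
        }


@dataclass(frozen=True)
class BackboneHBond:
    donor: tuple[str, int, str]  # residue id of the amide N
    acceptor: tuple[str, int, str]  # residue id of the carbonyl O
    n_o_distance: float
    nho_angle: float


@dataclass
class WrappingResult:
    hbond: BackboneHBond
    rho: int
    underprotected: bool


@dataclass
class DeficiencyReport:
    subset_label: str
    n_hbonds: int
    n_underprotected: int
    parameters: dict
    per_bond: list[WrappingResult] = field(default_factory=list)

    @property
    def deficiency_pct(self) -> float:
        return 100.0 * self.n_underprotected / self.n_hbonds


@dataclass
class ConditionSummary:
    condition: str
    mean_pct: float
    sd_pct: Optional[float]
    n: int


def _select_residues(
    structure: AtomicStructure,
    chains: Optional[Iterable[str]] = None,
    residue_ids: Optional[Iterable[tuple[str, int, str]]] = None,
) -> list[Residue]:
    chain_set = set(chains) if chains is not None else None
    id_set = set(residue_ids) if residue_ids is not None else None
    out = []
    for r in structure.residues:
        if any(a.is_water for a in r.atoms):
            continue
        if chain_set is not None and r.chain_id not in chain_set:
            continue
        if id_set is not None and r.residue_id not in id_set:
            continue
        out.append(r)
    return out


def _ideal_amide_h(res: Residue, prev_c: np.ndarray) -> Optional[np.ndarray]:
    """Place the amide hydrogen on the external bisector at N."""
    n_atom, ca_atom = res.atom("N"), res.atom("CA")
    if n_atom is None or ca_atom is None:
        return None
    n = n_atom.coords
    u1 = n - ca_atom.coords
    u2 = n - prev_c
    norm1, norm2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if norm1 == 0 or norm2 == 0:
        return None
    direction = u1 / norm1 + u2 / norm2
    d = np.linalg.norm(direction)
    if d == 0:
        return None
    return n + 1.01 * direction / d


def detect_backbone_hbonds(
    structure: AtomicStructure,
    subset_chains: Optional[Iterable[str]] = None,
    subset_residues: Optional[Iterable[tuple[str, int, str]]] = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[BackboneHBond]:
    """Detect backbone amide-N → carbonyl-O hydrogen bonds within a subset.

    Residues lacking backbone atoms are skipped with a warning; proline
    never donates; bonds between sequence neighbours (|i−j| < 2 in the same
    chain) are excluded. Both partners must lie inside the subset. The
    amide H is taken from the file if present, else rebuilt at the ideal
    position, which requires the preceding residue's carbonyl carbon (taken
    from the full structure so chain interiors are unaffected by subsetting).
    """
    residues = _select_residues(structure, subset_chains, subset_residues)
    residues = [r for r in residues if not any(a.is_hetero for a in r.atoms)]
    if not residues:
        raise ValueError("empty subset: no residues to analyse")

    # preceding-residue carbonyl carbon lookup over the whole structure
    prev_c: dict[tuple[str, int, str], np.ndarray] = {}
    by_chain: dict[str, list[Residue]] = {}
    for r in structure.residues:
        if any(a.is_water or a.is_hetero for a in r.atoms):
            continue
        by_chain.setdefault(r.chain_id, []).append(r)
    for chain_residues in by_chain.values():
        for prev, cur in zip(chain_residues, chain_residues[1:]):
            c = prev.atom("C")
            if c is not None:
                prev_c[cur.residue_id] = c.coords

    usable: list[Residue] = []
    for r in residues:
        present = [r.atom(name) is not None for name in ("N", "CA", "C", "O")]
        if all(present):
            usable.append(r)
        elif any(present):
            # partial backbone is worth flagging; side-chain-only residues
            # (wrapper pseudo-atoms, truncated ligand peptides) are not peptide
            # units and pass silently
            logger.warning(
                "residue %s %s lacks backbone atoms; skipped", r.name, r.residue_id
            )
    if not usable:
        raise ValueError("no residues with complete backbone in subset")

    index_in_chain = {r.residue_id: i for ch in by_chain.values() for i, r in enumerate(ch)}
    bonds: list[BackboneHBond] = []
    for donor in usable:
        if donor.name == "PRO":
            continue
        n = donor.atom("N").coords
        h_atom = donor.atom("H") or donor.atom("HN")
        if h_atom is not None:
            h = h_atom.coords
        else:
            pc = prev_c.get(donor.residue_id)
            if pc is None:
                continue  # chain start: no peptide bond to build H from
            h = _ideal_amide_h(donor, pc)
            if h is None:
                continue
        for acceptor in usable:
            if acceptor.residue_id == donor.residue_id:
                continue
            if donor.chain_id == acceptor.chain_id:
                di = index_in_chain.get(donor.residue_id)
                ai = index_in_chain.get(acceptor.residue_id)
                if di is not None and ai is not None and abs(di - ai) < criteria.min_separation:
                    continue
            o = acceptor.atom("O").coords
            dist = float(np.linalg.norm(n - o))
            if dist > criteria.max_no_distance:
                continue
            angle = _angle_deg(n - h, o - h)
            if angle < criteria.min_nho_angle:
                continue
            bonds.append(
                BackboneHBond(
                    donor=donor.residue_id,
                    acceptor=acceptor.residue_id,
                    n_o_distance=dist,
                    nho_angle=angle,
                )
            )
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def nonpolar_carbons(
    structure: AtomicStructure,
    wrapper_chains: Optional[Iterable[str]] = None,
    include_hetero: bool = False,
) -> list[Atom]:
    """All nonpolar carbonaceous-group carbons in the wrapper selection.

    Standard residues use connectivity templates; nonstandard residues fall
    back to distance-based bond inference at 1.9 Å with a warning. Waters
    never contribute; hetero-compounds only with ``include_hetero``.
    """
    chain_set = set(wrapper_chains) if wrapper_chains is not None else None
    candidates: list[Atom] = []
    fallback: list[Atom] = []
    for res in structure.residues:
        if chain_set is not None and res.chain_id not in chain_set:
            continue
        for a in res.atoms:
            if a.is_water or a.element != "C":
                continue
            if a.is_hetero and not include_hetero:
                continue
            template = NONPOLAR_CARBONS.get(res.name)
            if template is not None:
                if a.atom_name in template:
                    candidates.append(a)
            else:
                fallback.append(a)
    if fallback:
        logger.warning(
            "%d carbons in nonstandard residues: using distance-based bond "
            "inference at %.1f Å",
            len(fallback),
            _BOND_INFERENCE_CUTOFF,
        )
        heavy = [a for a in structure.atoms if not a.is_water and not a.is_hydrogen]
        coords = np.array([a.coords for a in heavy])
        tree = cKDTree(coords)
        for a in fallback:
            neighbours = tree.query_ball_point(a.coords, _BOND_INFERENCE_CUTOFF)
            ok = True
            for idx in neighbours:
                other = heavy[idx]
                if other is a:
                    continue
                if other.element not in ("C", "H"):
                    ok = False
                    break
            if ok:
                candidates.append(a)
    return candidates


def wrapping_numbers(
    hbonds: Sequence[BackboneHBond],
    structure: AtomicStructure,
    wrapper_chains: Optional[Iterable[str]] = None,
    radius: float = 6.5,
    include_hetero: bool = False,
) -> list[int]:
    """Wrapping number rho for each bond: nonpolar carbons within ``radius``
    of the donor CA or the acceptor CA (union of the two spheres, each
    wrapper counted once)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    wrappers = nonpolar_carbons(structure, wrapper_chains, include_hetero)
    ca_by_res = {
        r.residue_id: r.atom("CA").coords
        for r in structure.residues
        if r.atom("CA") is not None
    }
    if not wrappers:
        return [0] * len(hbonds)
    coords = np.array([a.coords for a in wrappers])
    tree = cKDTree(coords)
    out: list[int] = []
    for b in hbonds:
        near_d = tree.query_ball_point(ca_by_res[b.donor], radius)
        near_a = tree.query_ball_point(ca_by_res[b.acceptor], radius)
        out.append(len(set(near_d) | set(near_a)))
    return out


def wrapping_number(
    hbond: BackboneHBond,
    structure: AtomicStructure,
    wrapper_chains: Optional[Iterable[str]] = None,
    radius: float = 6.5,
    include_hetero: bool = False,
) -> int:
    return wrapping_numbers([hbond], structure, wrapper_chains, radius,
                            include_hetero)[0]


def structural_deficiency(
    structure: AtomicStructure,
    core_chains: Optional[Iterable[str]] = None,
    wrapper_chains: Optional[Iterable[str]] = None,
    radius: float = 6.5,
    rho_threshold: int = 19,
    criteria: HBondCriteria = HBondCriteria(),
    include_hetero: bool = False,
    subset_label: str = "",
) -> DeficiencyReport:
    """Deficiency of a core subset: fraction of its backbone H-bonds with
    rho below threshold, wrapping counted over ``wrapper_chains``."""
    core_chains = list(core_chains) if core_chains is not None else None
    wrapper_chains = (
        list(wrapper_chains) if wrapper_chains is not None else core_chains
    )
    hbonds = detect_backbone_hbonds(structure, core_chains, criteria=criteria)
    if not hbonds:
        raise ValueError("no backbone hydrogen bonds in core subset")
    rhos = wrapping_numbers(hbonds, structure, wrapper_chains, radius,
                            include_hetero)
    per_bond = [
        WrappingResult(hbond=b, rho=r, underprotected=r < rho_threshold)
        for b, r in zip(hbonds, rhos)
    ]
    n_under = sum(w.underprotected for w in per_bond)
    return DeficiencyReport(
        subset_label=subset_label or ",".join(core_chains or ["all"]),
        n_hbonds=len(hbonds),
        n_underprotected=n_under,
        parameters={
            "radius": radius,
            "rho_threshold": rho_threshold,
            "hbond_criteria": criteria.as_dict(),
            "include_hetero": include_hetero,
            "core_chains": core_chains,
            "wrapper_chains": wrapper_chains,
            "source_id": structure.source_id,
        },
        per_bond=per_bond,
    )


def compare_with_accessory(
    structure: AtomicStructure,
    core_chains: Iterable[str],
    accessory_chains: Iterable[str],
    radius: float = 6.5,
    rho_threshold: int = 19,
    criteria: HBondCriteria = HBondCriteria(),
    include_hetero: bool = False,
) -> tuple[DeficiencyReport, DeficiencyReport]:
    """Core deficiency without versus with accessory chains as wrappers.

    The H-bond set is identical in both reports (bonds live in the core),
    so the +accessory deficiency can never exceed the −accessory one.
    """
    core = list(core_chains)
    accessory = list(accessory_chains)
    if set(core) & set(accessory):
        raise ValueError("core and accessory chain sets overlap")
    without = structural_deficiency(
        structure, core, core, radius, rho_threshold, criteria,
        include_hetero, subset_label="-accessory",
    )
    with_acc = structural_deficiency(
        structure, core, core + accessory, radius, rho_threshold, criteria,
        include_hetero, subset_label="+accessory",
    )
    return without, with_acc


def aggregate_reports(
    grouped: dict[str, Sequence[DeficiencyReport]],
) -> list[ConditionSummary]:
    """Mean and sample SD (n−1) of deficiency per condition; SD absent at n=1."""
    out: list[ConditionSummary] = []
    for condition, reports in grouped.items():
        if not reports:
            raise ValueError(f"no reports for condition {condition!r}")
        vals = np.array([r.deficiency_pct for r in reports], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out.append(
            ConditionSummary(
                condition=condition,
                mean_pct=float(np.mean(vals)),
                sd_pct=sd,
                n=len(vals),
            )
        )
    return out
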