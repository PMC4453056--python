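"""Core domain types shared across the pipeline.

All downstream analyses consume only these containers; the io layer is the
sole producer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FEATURE_KINDS = ("rRNA", "tRNA", "CDS")

SITE_CLASSES = (
    "secondary",
    "secondary_A_minor",
    "tertiary_canonical",
    "tertiary_noncanonical",
)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: an rRNA, tRNA or protein-coding feature.

    ``copy_index`` distinguishes duplicated genes (same symbol annotated more
    than once); ``fragment_index`` distinguishes the pieces of a split /
    trans-spliced gene within one copy. Both are 1 for an ordinary
    single-copy, unfragmented gene.
    """

    symbol: str
    feature_kind: str
    length_nt: int
    protein_length_aa: Optional[int] = None
    is_partial: bool = False
    copy_index: int = 1
    fragment_index: int = 1

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.length_nt < 1:
            raise ValueError("length_nt must be >= 1")
        if self.protein_length_aa is not None and self.feature_kind != "CDS":
            raise ValueError("protein_length_aa only valid for CDS features")
        if self.copy_index < 1 or self.fragment_index < 1:
            raise ValueError("copy_index and fragment_index are 1-based")


@dataclass
class OrganelleGenome:
    """An annotated organellar genome record."""

    organism: str
    taxon_group: str
    genome_size_bp: int
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_size_bp < 1:
            raise ValueError("genome_size_bp must be >= 1")
        seen = set()
        for f in self.features:
            key = (f.symbol, f.copy_index, f.fragment_index)
            if key in seen:
                raise ValueError(f"duplicate feature key {key}")
            seen.add(key)


@dataclass
class Atom:
    """One atom of a parsed structure (highest-occupancy conformer only)."""

    element: str
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: np.ndarray  # (3,) in Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_water: bool = False
    is_hetero: bool = False

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    chain_id: str
    seq: int
    insertion_code: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class AtomicStructure:
    """Chains of residues of atoms, ordered by (chain, seq, insertion code)."""

    source_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def select_chains(self, chain_ids) -> "AtomicStructure":
        wanted = set(chain_ids)
        return AtomicStructure(
            source_id=self.source_id,
            residues=[r for r in self.residues if r.chain_id in wanted],
        )


@dataclass(frozen=True)
class InteractionSite:
    """A pair of alignment columns (1-based) with a structural class label."""

    col_i: int
    col_j: int
    site_class: str

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(
                f"unknown site class {self.site_class!r}; "
                f"expected one of {SITE_CLASSES}"
            )
        if self.col_i == self.col_j:
            raise ValueError("col_i and col_j must differ")
        if self.col_i < 1 or self.col_j < 1:
            raise ValueError("alignment columns are 1-based")


@dataclass
class StructureAlignment:
    """Gapped rRNA alignment with classified interaction sites."""

    sequences: list[str]
    seq_ids: list[str]
    seq_groups: list[str]
    sites: list[InteractionSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("ragged alignment: sequences differ in length")
        if len(self.seq_groups) != len(self.sequences):
            raise ValueError("seq_groups cardinality mismatch")
        if len(self.seq_ids) != len(self.sequences):
            raise ValueError("seq_ids cardinality mismatch")
        width = self.width
        for s in self.sites:
            if s.col_i > width or s.col_j > width:
                raise ValueError(
                    f"site ({s.col_i},{s.col_j},{s.site_class}) outside "
                    f"alignment of width {width}"
                )

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def has_site(self, site: InteractionSite) -> bool:
        cached = self.__dict__.get("_site_set")
        if cached is None or len(cached) != len(self.sites):
            cached = set(self.sites)
            self.__dict__["_site_set"] = cached
        return site in cached
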