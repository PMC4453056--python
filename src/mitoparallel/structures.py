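"""PDB / mmCIF reading via gemmi, reduced to the pipeline's atom model.

Waters, hetero-compounds and hydrogens are retained but flagged so that the
wrapping calculation can exclude them by default. When a file carries
alternate locations, only the highest-occupancy conformer of each atom is
kept (ties broken by altloc letter order).
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import gemmi
import numpy as np

from .types import Atom, AtomicStructure, Residue


class StructureParseError(ValueError):
    """Raised for unreadable or empty coordinate files."""


def parse_structure(source: Union[str, Path], source_id: str | None = None) -> AtomicStructure:
    """Parse a PDB or mmCIF file (by path) into an :class:`AtomicStructure`."""
    path = Path(source)
    if not path.exists():
        raise StructureParseError(f"no such coordinate file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as err:
        raise StructureParseError(f"unreadable coordinate file {path}: {err}") from err
    return _convert(st, source_id or path.stem)


def parse_structure_text(text: str, fmt: str = "pdb", source_id: str = "inline") -> AtomicStructure:
    """Parse coordinate data held in memory; ``fmt`` is ``pdb`` or ``cif``."""
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "cif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except StructureParseError:
        raise
    except Exception as err:
        raise StructureParseError(f"unreadable {fmt} text: {err}") from err
    return _convert(st, source_id)


def _convert(st: gemmi.Structure, source_id: str) -> AtomicStructure:
    if len(st) == 0:
        raise StructureParseError("no atoms")
    st.setup_entities()
    model = st[0]
    residues: list[Residue] = []
    n_atoms = 0
    for chain in model:
        chain_res: list[Residue] = []
        for res in chain:
            is_water = res.is_water()
            is_hetero = (res.het_flag == "H") and not is_water
            icode = res.seqid.icode.strip()
            out = Residue(
                name=res.name,
                chain_id=chain.name,
                seq=res.seqid.num,
                insertion_code=icode,
                atoms=[],
            )
            # keep the best conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or (atom.occ, _alt_rank(atom.altloc)) > (
                    prev.occ, _alt_rank(prev.altloc)
                ):
                    best[atom.name] = atom
            for atom in res:
                if best.get(atom.name) is not atom:
                    continue
                out.atoms.append(
                    Atom(
                        element=atom.element.name,
                        atom_name=atom.name,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        insertion_code=icode,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=atom.altloc if atom.altloc != "\0" else "",
                        is_water=is_water,
                        is_hetero=is_hetero,
                    )
                )
            n_atoms += len(out.atoms)
            chain_res.append(out)
        chain_res.sort(key=lambda r: (r.seq, r.insertion_code))
        residues.extend(chain_res)
    if n_atoms == 0:
        raise StructureParseError("no atoms")
    return AtomicStructure(source_id=source_id, residues=residues)


def _alt_rank(altloc: str) -> int:
    """Higher rank wins ties; earlier altloc letters rank higher."""
    if not altloc or altloc == "\0":
        return 0
    return -ord(altloc)
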