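"""Per-genome gene-length census.

For each mitochondrial genome: total rRNA nucleotides (SSU + LSU + 5S when
present, fragments summed, one copy per gene), mean tRNA length over all
annotated tRNAs, and summed amino-acid lengths of the mitochondrially
encoded subunits of OXPHOS complexes I, III, IV and V. Genomes missing any
gene of a complex lack that complex's value; a duplicated OXPHOS gene drops
the affected complex and the grand total (duplicates are excluded from the
rRNA and OXPHOS tallies but deliberately *not* from the tRNA average).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import GeneFeature, OrganelleGenome

RRNA_SYMBOLS = ("rrnS", "rrnL", "rrn5")

COMPLEX_GENES: dict[str, tuple[str, ...]] = {
    "cI": ("nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"),
    "cIII": ("cytb",),
    "cIV": ("cox1", "cox2", "cox3"),
    "cV": ("atp6", "atp8"),
}

OXPHOS_GENES = tuple(g for genes in COMPLEX_GENES.values() for g in genes)


@dataclass
class CensusRow:
    organism: str
    taxon_group: str
    genome_size_kb: float
    total_rrna_nt: Optional[int]
    mean_trna_nt: Optional[float]
    len_cI_aa: Optional[int]
    len_cIII_aa: Optional[int]
    len_cIV_aa: Optional[int]
    len_cV_aa: Optional[int]
    total_oxphos_aa: Optional[int]


def _usable(features: Iterable[GeneFeature], include_partial: bool) -> list[GeneFeature]:
    return [f for f in features if include_partial or not f.is_partial]


def total_rrna_length(genome: OrganelleGenome, include_partial: bool = False) -> Optional[int]:
    """Summed rRNA length: fragments summed per copy, longest copy per gene.

    Absent (None) when neither SSU nor LSU is annotated.
    """
    feats = _usable(genome.features, include_partial)
    total = 0
    seen_core = False
    for symbol in RRNA_SYMBOLS:
        copies: dict[int, int] = {}
        for f in feats:
            if f.feature_kind == "rRNA" and f.symbol == symbol:
                copies[f.copy_index] = copies.get(f.copy_index, 0) + f.length_nt
        if copies:
            if symbol in ("rrnS", "rrnL"):
                seen_core = True
            total += max(copies.values())
    return total if seen_core else None


def mean_trna_length(genome: OrganelleGenome, include_partial: bool = False) -> Optional[float]:
    """Arithmetic mean length over all annotated tRNAs, duplicates included."""
    lengths = [
        f.length_nt
        for f in _usable(genome.features, include_partial)
        if f.feature_kind == "tRNA"
    ]
    if not lengths:
        return None
    return sum(lengths) / len(lengths)


def oxphos_complex_lengths(
    genome: OrganelleGenome, include_partial: bool = False
) -> dict[str, Optional[int]]:
    """Summed protein lengths per OXPHOS complex, with exclusion rules.

    Returns a mapping with keys cI, cIII, cIV, cV and total. A complex is
    absent when any of its genes is missing (or lacks a protein length) or
    when any of its genes is duplicated; the total is absent unless all four
    complexes are present.
    """
    feats = _usable(genome.features, include_partial)
    by_symbol: dict[str, list[GeneFeature]] = {}
    for f in feats:
        if f.feature_kind == "CDS" and f.symbol in OXPHOS_GENES:
            by_symbol.setdefault(f.symbol, []).append(f)

    def gene_length(symbol: str) -> Optional[int]:
        copies = {f.copy_index for f in by_symbol.get(symbol, [])}
        if len(copies) != 1:
            return None  # missing or duplicated -> complex excluded
        aa = sum(
            f.protein_length_aa or 0 for f in by_symbol[symbol]
        )
        return aa if aa > 0 else None

    out: dict[str, Optional[int]] = {}
    for cx, genes in COMPLEX_GENES.items():
        lengths = [gene_length(g) for g in genes]
        out[cx] = sum(lengths) if all(v is not None for v in lengths) else None  # type: ignore[arg-type]
    if all(out[cx] is not None for cx in COMPLEX_GENES):
        out["total"] = sum(out[cx] for cx in COMPLEX_GENES)  # type: ignore[misc]
    else:
        out["total"] = None
    return out


def build_census(
    genomes: Iterable[OrganelleGenome],
    exclude_groups: Iterable[str] = (),
    include_partial: bool = False,
) -> list[CensusRow]:
    """One census row per genome, ordered by organism name.

    ``exclude_groups`` drops whole taxon groups (e.g. parasites) before any
    statistic is computed.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("build_census requires at least one genome")
    excluded = set(exclude_groups)
    rows: list[CensusRow] = []
    for g in sorted(genomes, key=lambda g: g.organism):
        if g.taxon_group in excluded:
            continue
        ox = oxphos_complex_lengths(g, include_partial)
        rows.append(
            CensusRow(
                organism=g.organism,
                taxon_group=g.taxon_group,
                genome_size_kb=g.genome_size_bp / 1000.0,
                total_rrna_nt=total_rrna_length(g, include_partial),
                mean_trna_nt=mean_trna_length(g, include_partial),
                len_cI_aa=ox["cI"],
                len_cIII_aa=ox["cIII"],
                len_cIV_aa=ox["cIV"],
                len_cV_aa=ox["cV"],
                total_oxphos_aa=ox["total"],
            )
        )
    return rows


def census_to_frame(rows: list[CensusRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    return df


def write_census_tsv(rows: list[CensusRow], path) -> None:
    census_to_frame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
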