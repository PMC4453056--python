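"""Base-pair composition of the conserved rRNA helix core.

Classifies pairs into G:C / A:U / G:U / other, reports composition
fractions over a chosen helix set, and accounts hydrogen bonds with the
standard Watson–Crick / wobble bond counts (G:C = 3, A:U = 2, G:U = 2).
The differential between two structures' totals measures the stability
cost of A/U-biased pairing: a pure G:C→A:U swap loses one bond per pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

_NUCLEOTIDES = frozenset("ACGU")


@dataclass(frozen=True)
class HBondWeights:
    gc: int = 3
    au: int = 2
    gu: int = 2
    other: int = 2

    def of(self, pair_type: str) -> int:
        return {"GC": self.gc, "AU": self.au, "GU": self.gu,
                "other": self.other}[pair_type]


@dataclass(frozen=True)
class BasePairRecord:
    helix_id: str
    res_i: str
    res_j: str
    base_i: str
    base_j: str

    @property
    def pair_type(self) -> str:
        return classify_basepair(self.base_i, self.base_j)


@dataclass
class HelixSet:
    helix_ids: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.helix_ids:
            raise ValueError("helix set is empty")


@dataclass
class CompositionReport:
    n_pairs: int
    counts: dict[str, int]
    weights: HBondWeights = field(default_factory=HBondWeights)

    @property
    def frac_gc(self) -> float:
        return 100.0 * self.counts["GC"] / self.n_pairs

    @property
    def frac_au(self) -> float:
        return 100.0 * self.counts["AU"] / self.n_pairs

    @property
    def frac_other(self) -> float:
        return 100.0 * (self.counts["GU"] + self.counts["other"]) / self.n_pairs

    @property
    def fractions_exact(self) -> dict[str, Fraction]:
        n = self.n_pairs
        return {k: Fraction(100 * v, n) for k, v in self.counts.items()}

    @property
    def hbond_total(self) -> int:
        return sum(self.weights.of(k) * v for k, v in self.counts.items())


def classify_basepair(base_i: str, base_j: str) -> str:
    """Symmetric pair-type label: GC, AU, GU, or other."""
    bi, bj = base_i.upper().replace("T", "U"), base_j.upper().replace("T", "U")
    if bi not in _NUCLEOTIDES or bj not in _NUCLEOTIDES:
        raise ValueError(f"non-nucleotide base pair ({base_i!r}, {base_j!r})")
    pair = frozenset((bi, bj))
    if pair == frozenset("GC"):
        return "GC"
    if pair == frozenset("AU"):
        return "AU"
    if pair == frozenset("GU"):
        return "GU"
    return "other"


def default_helix_set() -> HelixSet:
    """The shipped conserved-LSU-core helix set (editable placeholder list)."""
    text = resources.files("mitoparallel.data").joinpath(
        "lsu_core_helices.txt"
    ).read_text()
    return load_helix_set_text(text, description="conserved LSU core (shipped)")


def load_helix_set_text(text: str, description: str = "") -> HelixSet:
    ids = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate helix ids in helix set")
    return HelixSet(helix_ids=frozenset(ids), description=description)


def load_helix_set(path: Union[str, Path]) -> HelixSet:
    return load_helix_set_text(Path(path).read_text(), description=str(path))


def read_basepair_tsv(source: Union[str, Path]) -> list[BasePairRecord]:
    """Read a pair table: helix_id, res_i, res_j, base_i, base_j (TSV, header)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = ["helix_id", "res_i", "res_j", "base_i", "base_j"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    return [
        BasePairRecord(
            helix_id=row.helix_id, res_i=row.res_i, res_j=row.res_j,
            base_i=row.base_i, base_j=row.base_j,
        )
        for row in df.itertuples()
    ]


def composition(
    pairs: Iterable[BasePairRecord],
    helix_set: Optional[HelixSet] = None,
    weights: HBondWeights = HBondWeights(),
    canonical_only: bool = False,
) -> CompositionReport:
    """Composition fractions and hydrogen-bond total over a helix set.

    ``canonical_only`` restricts the tally to GC/AU/GU pairs (the default
    counts every annotated pair in the selected helices).
    """
    if helix_set is None:
        helix_set = default_helix_set()
    counts = {"GC": 0, "AU": 0, "GU": 0, "other": 0}
    for p in pairs:
        if p.helix_id not in helix_set.helix_ids:
            continue
        t = p.pair_type
        if canonical_only and t == "other":
            continue
        counts[t] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no pairs in helix set")
    return CompositionReport(n_pairs=n, counts=counts, weights=weights)


def hbond_differential(a: CompositionReport, b: CompositionReport) -> int:
    """Hydrogen-bond total of ``a`` minus that of ``b`` (same weights only)."""
    if a.weights != b.weights:
        raise ValueError("reports computed with different hydrogen-bond weights")
    return a.hbond_total - b.hbond_total


def composition_to_frame(report: CompositionReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_pairs": report.n_pairs,
                "n_gc": report.counts["GC"],
                "n_au": report.counts["AU"],
                "n_gu": report.counts["GU"],
                "n_other": report.counts["other"],
                "frac_gc": report.frac_gc,
                "frac_au": report.frac_au,
                "frac_other": report.frac_other,
                "hbond_total": report.hbond_total,
            }
        ]
    )
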