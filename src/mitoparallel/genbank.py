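"""GenBank flat-file reading and writing for organellar genome records.

Parsing is delegated to Biopython; this module maps records onto the
pipeline's domain types, normalizes gene symbols against a synonym table,
and resolves duplicated versus fragmented genes.

A repeated gene symbol is treated as a new *fragment* of the previous copy
when the feature carries a ``/note`` containing the word "fragment" (the
usual marking of split or trans-spliced organellar genes); otherwise it is
counted as a new *copy*. Compound ``join()`` locations within a single
feature are always summed into one length.
"""
from __future__ import annotations

import io
import re
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .types import GeneFeature, OrganelleGenome


class GenBankParseError(ValueError):
    """Raised for malformed GenBank input."""


# One-letter amino-acid codes for tRNA symbol normalization.
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

_CANONICAL = [
    "rrnS", "rrnL", "rrn5",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cytb", "cox1", "cox2", "cox3", "atp6", "atp8",
]

_SYNONYMS: dict[str, str] = {}


def _add_synonyms(symbol: str, *alts: str) -> None:
    _SYNONYMS[symbol.lower()] = symbol
    for a in alts:
        _SYNONYMS[a.lower()] = symbol


_add_synonyms("rrnS", "rns", "12s", "12s rrna", "12s ribosomal rna",
              "s-rrna", "srrna", "ssu", "rrn12", "mt-rnr1", "rnr1",
              "small subunit ribosomal rna", "ssu rrna")
_add_synonyms("rrnL", "rnl", "16s", "16s rrna", "16s ribosomal rna",
              "l-rrna", "lrrna", "lsu", "rrn16", "mt-rnr2", "rnr2",
              "21s", "21s rrna", "large subunit ribosomal rna", "lsu rrna")
_add_synonyms("rrn5", "5s", "5s rrna", "5s ribosomal rna", "rrn5s")
for _i in ("1", "2", "3", "4", "4L", "5", "6"):
    _add_synonyms(f"nad{_i}", f"nd{_i}", f"mt-nd{_i}", f"nadh{_i}",
                  f"nadh dehydrogenase subunit {_i}")
_add_synonyms("cytb", "cob", "cyb", "mt-cyb", "cytochrome b",
              "apocytochrome b")
for _i, _rom in (("1", "i"), ("2", "ii"), ("3", "iii")):
    _add_synonyms(f"cox{_i}", f"cox{_rom}", f"co{_i}", f"co{_rom}",
                  f"mt-co{_i}", f"coi" if _i == "1" else f"co{_rom}",
                  f"cytochrome c oxidase subunit {_i}",
                  f"cytochrome c oxidase subunit {_rom}")
_add_synonyms("atp6", "atpase6", "atpase 6", "mt-atp6",
              "atp synthase f0 subunit 6", "atp synthase subunit 6")
_add_synonyms("atp8", "atpase8", "atpase 8", "mt-atp8",
              "atp synthase f0 subunit 8", "atp synthase subunit 8")

_TRN_RE = re.compile(r"^trn([a-z])\b", re.IGNORECASE)
_TRNA_RE = re.compile(r"^trna[-_ ]([a-z]{3})\b", re.IGNORECASE)
_MTT_RE = re.compile(r"^mt-t([a-z])\b", re.IGNORECASE)


def normalize_gene_name(raw: str) -> str:
    """Map an annotation label onto a canonical organellar gene symbol.

    Unknown labels pass through as ``other:<raw>``; tRNA labels collapse to
    ``trn<one-letter amino acid>`` regardless of isoacceptor annotation.
    """
    if not raw:
        raise ValueError("empty gene label")
    text = raw.strip()
    key = text.lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = _TRNA_RE.match(key)
    if m and m.group(1) in _AA3_TO_1:
        return "trn" + _AA3_TO_1[m.group(1)]
    m = _TRN_RE.match(text)
    if m:
        return "trn" + m.group(1).upper()
    m = _MTT_RE.match(key)
    if m:
        return "trn" + m.group(1).upper()
    return f"other:{text}"


def _feature_symbol(feat: SeqFeature) -> Optional[str]:
    # /gene wins over /product, mirroring NCBI organellar annotation practice
    for qual in ("gene", "product"):
        vals = feat.qualifiers.get(qual)
        if vals:
            return normalize_gene_name(str(vals[0]))
    return None


def _is_partial(feat: SeqFeature) -> bool:
    if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
        return True
    loc = str(feat.location)
    return "<" in loc or ">" in loc


def _protein_length(feat: SeqFeature, length_nt: int) -> Optional[int]:
    trans = feat.qualifiers.get("translation")
    if trans:
        return len(str(trans[0]))
    if length_nt % 3 == 0 and length_nt >= 6:
        return length_nt // 3 - 1
    return None


def parse_genbank_record(
    text: str,
    taxon_group: Optional[str] = None,
) -> OrganelleGenome:
    """Parse one GenBank flat-file record into an :class:`OrganelleGenome`.

    ``taxon_group`` overrides the group label; otherwise a source-feature
    note of the form ``taxon_group:<label>`` is honoured, falling back to
    ``"unknown"``.
    """
    if "FEATURES" not in text:
        raise GenBankParseError("no features")
    try:
        record = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as err:  # Biopython raises plain ValueError subclasses
        line_no = _failing_line(text)
        raise GenBankParseError(
            f"malformed GenBank record near line {line_no}: {err}"
        ) from err

    organism = record.annotations.get("organism") or record.id or "unknown"
    group = taxon_group
    for feat in record.features:
        if feat.type == "source":
            for note in feat.qualifiers.get("note", []):
                m = re.match(r"taxon_group:(\S+)", str(note))
                if m and group is None:
                    group = m.group(1)
    if group is None:
        group = "unknown"

    features: list[GeneFeature] = []
    copy_counter: dict[str, int] = {}
    frag_counter: dict[tuple[str, int], int] = {}
    for feat in record.features:
        kind = {"rRNA": "rRNA", "tRNA": "tRNA", "CDS": "CDS"}.get(feat.type)
        if kind is None:
            continue
        symbol = _feature_symbol(feat)
        if symbol is None:
            continue
        length_nt = sum(len(part) for part in feat.location.parts)
        notes = " ".join(str(n) for n in feat.qualifiers.get("note", []))
        is_fragment = "fragment" in notes.lower()
        if symbol in copy_counter and is_fragment:
            copy_index = copy_counter[symbol]
            frag_counter[(symbol, copy_index)] += 1
        else:
            copy_index = copy_counter.get(symbol, 0) + 1
            copy_counter[symbol] = copy_index
            frag_counter[(symbol, copy_index)] = 1
        features.append(
            GeneFeature(
                symbol=symbol,
                feature_kind=kind,
                length_nt=length_nt,
                protein_length_aa=(
                    _protein_length(feat, length_nt) if kind == "CDS" else None
                ),
                is_partial=_is_partial(feat),
                copy_index=copy_index,
                fragment_index=frag_counter[(symbol, copy_index)],
            )
        )

    return OrganelleGenome(
        organism=organism,
        taxon_group=group,
        genome_size_bp=len(record.seq),
        features=features,
    )


def _failing_line(text: str) -> int:
    """Best-effort location of the first structurally bad line."""
    lines = text.splitlines()
    if not lines or not lines[0].startswith("LOCUS"):
        return 1
    for i, line in enumerate(lines[1:], start=2):
        if line.strip() == "//":
            return i
    return len(lines)


def write_genbank_record(genome: OrganelleGenome, sequence: Optional[str] = None) -> str:
    """Serialize a genome back to GenBank flat-file text.

    Features are laid out head-to-tail on the forward strand; fragments carry
    a ``/note="fragment N"`` so that re-parsing recovers copy and fragment
    indices. CDS features get a synthetic ``/translation`` of the recorded
    protein length.
    """
    if sequence is None:
        sequence = "A" * genome.genome_size_bp
    if len(sequence) != genome.genome_size_bp:
        raise ValueError("sequence length does not match genome_size_bp")
    record = SeqRecord(
        Seq(sequence),
        id="SYN000001",
        name=re.sub(r"\W", "_", genome.organism)[:16] or "synthetic",
        description=f"{genome.organism} mitochondrion, synthetic record",
        annotations={"molecule_type": "DNA", "organism": genome.organism,
                     "topology": "circular"},
    )
    record.features.append(
        SeqFeature(
            FeatureLocation(0, genome.genome_size_bp),
            type="source",
            qualifiers={
                "organism": [genome.organism],
                "note": [f"taxon_group:{genome.taxon_group}"],
            },
        )
    )
    pos = 0
    for f in genome.features:
        end = pos + f.length_nt
        if end > genome.genome_size_bp:
            raise ValueError("features do not fit in genome_size_bp")
        quals: dict[str, list[str]] = {"gene": [f.symbol]}
        if f.fragment_index > 1:
            quals["note"] = [f"fragment {f.fragment_index}"]
        if f.is_partial:
            quals["pseudo"] = [""]
        if f.feature_kind == "CDS" and f.protein_length_aa is not None:
            quals["translation"] = ["M" + "A" * (f.protein_length_aa - 1)]
        record.features.append(
            SeqFeature(FeatureLocation(pos, end), type=f.feature_kind,
                       qualifiers=quals)
        )
        pos = end + 10 if end + 10 <= genome.genome_size_bp else end
    out = io.StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()
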