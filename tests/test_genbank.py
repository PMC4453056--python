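"""GenBank parsing, symbol normalization and round-tripping."""
import pytest
from hypothesis import given, settings, strategies as st

from mitoparallel.genbank import (
    GenBankParseError,
    normalize_gene_name,
    parse_genbank_record,
    write_genbank_record,
)
from mitoparallel.types import GeneFeature, OrganelleGenome

MINIMAL = """\
LOCUS       SYNTEST              {size} bp    DNA     circular     01-JAN-2000
DEFINITION  synthetic test record.
ACCESSION   SYNTEST
FEATURES             Location/Qualifiers
     source          1..{size}
                     /organism="Testus testus"
{features}ORIGIN
//
"""


def record_with(features: str, size: int = 3000) -> str:
    return MINIMAL.format(size=size, features=features)


class TestNormalizeGeneName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("ND4L", "nad4L"),
            ("COB", "cytb"),
            ("cytB", "cytb"),
            ("MT-CYB", "cytb"),
            ("COXI", "cox1"),
            ("CO1", "cox1"),
            ("MT-CO1", "cox1"),
            ("16S", "rrnL"),
            ("l-rRNA", "rrnL"),
            ("rnl", "rrnL"),
            ("12S ribosomal RNA", "rrnS"),
            ("rns", "rrnS"),
            ("5S rRNA", "rrn5"),
            ("ATPase6", "atp6"),
            ("NADH dehydrogenase subunit 2", "nad2"),
            ("tRNA-Ala", "trnA"),
            ("trnL(uag)", "trnL"),
            ("MT-TF", "trnF"),
        ],
    )
    def test_synonyms(self, raw, expected):
        assert normalize_gene_name(raw) == expected

    def test_unknown_label_passes_through(self):
        assert normalize_gene_name("hypothetical ORF") == "other:hypothetical ORF"

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            normalize_gene_name("")


class TestParseGenbank:
    def test_single_rrna_span(self):
        text = record_with(
            '     rRNA            1..1500\n                     /gene="rrnL"\n'
        )
        genome = parse_genbank_record(text)
        (f,) = genome.features
        assert (f.symbol, f.feature_kind, f.length_nt) == ("rrnL", "rRNA", 1500)

    def test_joined_cds_length_and_protein(self):
        text = record_with(
            "     CDS             join(1..300,401..700)\n"
            '                     /gene="cox2"\n'
        )
        (f,) = parse_genbank_record(text).features
        assert f.length_nt == 600
        assert f.protein_length_aa == 199  # 600/3 minus the stop codon

    def test_translation_qualifier_wins(self):
        text = record_with(
            "     CDS             1..600\n"
            '                     /gene="cox2"\n'
            '                     /translation="M' + "A" * 198 + '"\n'
        )
        (f,) = parse_genbank_record(text).features
        assert f.protein_length_aa == 199

    def test_two_trnas_are_separate_single_copies(self):
        text = record_with(
            '     tRNA            1..70\n                     /gene="trnA"\n'
            '     tRNA            101..172\n                     /gene="trnC"\n'
        )
        feats = parse_genbank_record(text).features
        assert [(f.symbol, f.length_nt, f.copy_index) for f in feats] == [
            ("trnA", 70, 1),
            ("trnC", 72, 1),
        ]

    def test_repeated_symbol_without_note_is_a_copy(self):
        text = record_with(
            '     rRNA            1..950\n                     /gene="rrnS"\n'
            '     rRNA            1001..1960\n                     /gene="rrnS"\n'
        )
        feats = parse_genbank_record(text).features
        assert [(f.copy_index, f.fragment_index) for f in feats] == [(1, 1), (2, 1)]

    def test_repeated_symbol_with_fragment_note_is_a_fragment(self):
        text = record_with(
            '     rRNA            1..1000\n                     /gene="rrnL"\n'
            "     rRNA            1101..1900\n"
            '                     /gene="rrnL"\n'
            '                     /note="fragment 2"\n'
        )
        feats = parse_genbank_record(text).features
        assert [(f.copy_index, f.fragment_index) for f in feats] == [(1, 1), (1, 2)]

    def test_pseudo_flag_marks_partial(self):
        text = record_with(
            '     tRNA            1..65\n                     /gene="trnA"\n'
            "                     /pseudo\n"
        )
        (f,) = parse_genbank_record(text).features
        assert f.is_partial

    def test_genome_size_from_locus(self):
        text = record_with(
            '     rRNA            1..1500\n                     /gene="rrnL"\n',
            size=16569,
        )
        assert parse_genbank_record(text).genome_size_bp == 16569

    def test_taxon_group_from_source_note(self):
        text = record_with(
            "     source          1..3000\n"
            '                     /note="taxon_group:fungi"\n'
            '     rRNA            1..1500\n                     /gene="rrnL"\n'
        )
        assert parse_genbank_record(text).taxon_group == "fungi"

    def test_no_features_error(self):
        with pytest.raises(GenBankParseError, match="no features"):
            parse_genbank_record("LOCUS       X 10 bp\nORIGIN\n//\n")

    def test_malformed_record_names_line(self):
        with pytest.raises(GenBankParseError, match="line"):
            parse_genbank_record("FEATURES\ngarbage without a locus\n")


class TestLocationArithmetic:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        spans=st.lists(st.tuples(st.integers(1, 500), st.integers(1, 300)),
                       min_size=1, max_size=6)
    )
    def test_joined_span_lengths_sum(self, spans):
        """1-based inclusive spans: feature length is sum(end - start + 1)."""
        parts, pos = [], 1
        for gap, length in spans:
            start = pos + gap
            end = start + length - 1
            parts.append((start, end))
            pos = end + 1
        loc = ",".join(f"{s}..{e}" for s, e in parts)
        if len(parts) > 1:
            loc = f"join({loc})"
        text = record_with(
            f"     rRNA            {loc}\n"
            '                     /gene="rrnL"\n',
            size=pos + 100,
        )
        (f,) = parse_genbank_record(text).features
        assert f.length_nt == sum(e - s + 1 for s, e in parts)


class TestRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lengths=st.lists(st.integers(min_value=50, max_value=2000),
                         min_size=1, max_size=8),
        kinds=st.data(),
    )
    def test_symbols_kinds_lengths_roundtrip(self, lengths, kinds):
        """Writing a synthetic genome and re-parsing reproduces the
        (symbol, kind, length) triples exactly."""
        symbols = ["rrnS", "rrnL", "trnA", "trnC", "cox1", "nad4L", "atp8",
                   "cytb"]
        feats = []
        for i, ln in enumerate(lengths):
            symbol = symbols[i % len(symbols)]
            kind = ("rRNA" if symbol.startswith("rrn")
                    else "tRNA" if symbol.startswith("trn") else "CDS")
            aa = None
            if kind == "CDS":
                ln = max(6, ln - ln % 3)
                aa = ln // 3 - 1
            feats.append(GeneFeature(symbol=symbol, feature_kind=kind,
                                     length_nt=ln, protein_length_aa=aa))
        size = sum(f.length_nt for f in feats) + 10 * len(feats) + 100
        genome = OrganelleGenome(organism="Round tripper", taxon_group="fungi",
                                 genome_size_bp=size, features=feats)
        reparsed = parse_genbank_record(write_genbank_record(genome))
        got = [(f.symbol, f.feature_kind, f.length_nt) for f in reparsed.features]
        want = [(f.symbol, f.feature_kind, f.length_nt) for f in genome.features]
        assert got == want
        assert reparsed.genome_size_bp == genome.genome_size_bp
        assert reparsed.taxon_group == genome.taxon_group

    def test_fragment_indices_roundtrip(self):
        feats = [
            GeneFeature(symbol="rrnL", feature_kind="rRNA", length_nt=1000),
            GeneFeature(symbol="rrnL", feature_kind="rRNA", length_nt=800,
                        fragment_index=2),
            GeneFeature(symbol="rrnS", feature_kind="rRNA", length_nt=950),
            GeneFeature(symbol="rrnS", feature_kind="rRNA", length_nt=960,
                        copy_index=2),
        ]
        genome = OrganelleGenome(organism="Fragmentia", taxon_group="protists",
                                 genome_size_bp=5000, features=feats)
        reparsed = parse_genbank_record(write_genbank_record(genome))
        got = [(f.symbol, f.copy_index, f.fragment_index, f.length_nt)
               for f in reparsed.features]
        assert got == [("rrnL", 1, 1, 1000), ("rrnL", 1, 2, 800),
                       ("rrnS", 1, 1, 950), ("rrnS", 2, 1, 960)]
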