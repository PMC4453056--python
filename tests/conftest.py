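import pathlib

import pytest

from mitoparallel.alignments import parse_structure_alignment
from mitoparallel.genbank import parse_genbank_record
from mitoparallel.simulate import gen_alignment, gen_genomes, gen_structure
from mitoparallel.structures import parse_structure


@pytest.fixture(scope="session")
def census_demo(tmp_path_factory) -> dict:
    """10 genomes: 2 missing atp8, 1 with duplicated cox1, 7 complete."""
    out = tmp_path_factory.mktemp("census_demo")
    manifest = gen_genomes(10, "census_demo", seed=20240, out_dir=out)
    manifest["dir"] = out
    return manifest


@pytest.fixture(scope="session")
def census_demo_genomes(census_demo):
    d = pathlib.Path(census_demo["dir"])
    return [
        parse_genbank_record((d / rec["file"]).read_text())
        for rec in census_demo["genomes"]
    ]


@pytest.fixture(scope="session")
def recovery_alignment(tmp_path_factory):
    """300 sequences, 50 secondary sites, p_canonical=0.9, p_gap=0.1."""
    out = tmp_path_factory.mktemp("aln")
    manifest = gen_alignment(
        n_seqs=300, sites=50, p_canonical=0.9, p_gap=0.1, seed=4171,
        out_dir=out,
    )
    aln = parse_structure_alignment(
        out / "aln.fasta", out / "sites.tsv", out / "groups.tsv"
    )
    return aln, manifest


@pytest.fixture(scope="session")
def ideal_helix_structure(tmp_path_factory):
    out = tmp_path_factory.mktemp("helix")
    manifest = gen_structure("ideal_helix", seed=9, out_path=out / "h.pdb",
                             n_res=10)
    return parse_structure(out / "h.pdb"), manifest
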