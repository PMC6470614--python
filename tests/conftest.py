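import pytest

from pepscan.reference import published_screen_counts
from pepscan.synthetic import make_paper_like_fixture, write_bundle, \
    write_peptide_tsv


@pytest.fixture(scope="session")
def fixture_bundle():
    """Miniature study-shaped proteome + peptide DB with exact ground truth."""
    return make_paper_like_fixture(seed=7)


@pytest.fixture(scope="session")
def reference():
    """Packaged literature count tables."""
    return published_screen_counts()


@pytest.fixture()
def bundle_dir(fixture_bundle, tmp_path):
    """The fixture bundle written to disk (FASTA, TSV, GenBank, ledger)."""
    out = tmp_path / "bundle"
    write_bundle(fixture_bundle.proteins, fixture_bundle.truth, out)
    write_peptide_tsv(fixture_bundle.peptides, out / "peptides.tsv")
    return out


GENBANK_MICRO = """\
LOCUS       MICRO                   33 bp    DNA     linear   UNA 01-JAN-2000
DEFINITION  three-gene micro fixture.
ACCESSION   MICRO
VERSION     MICRO.1
FEATURES             Location/Qualifiers
     CDS             1..9
                     /gene="psaA"
                     /transl_table=11
     CDS             10..21
                     /gene="rbcL"
                     /transl_table=11
                     /translation="MKL*"
     CDS             22..30
                     /gene="orf999"
                     /transl_table=11
ORIGIN
        1 atggcttaaa tgaaactttt aatgtgttaa tcc
//
"""


@pytest.fixture()
def micro_genbank(tmp_path):
    """Hand-written 3-CDS GenBank file.

    CDS 1..9 is ATG GCT TAA -> "MA" by table-11 translation (trailing stop
    stripped); CDS 10..21 carries an explicit /translation "MKL*"; CDS
    22..30 is ATG TGT TAA -> "MC".
    """
    path = tmp_path / "micro.gb"
    path.write_text(GENBANK_MICRO)
    return path
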