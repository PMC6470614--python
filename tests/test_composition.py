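"""Amino-acid composition tables and reference comparison."""

from collections import Counter
from fractions import Fraction

import pytest

from pepscan.classification import classify_all, default_schema
from pepscan.composition import (
    PLASTID_GROUP, compare_composition, composition,
    load_reference_composition, write_composition_tsv,
)
from pepscan.genome_io import ProteinRecord
from pepscan.synthetic import GeneratorConfig, generate


def labelled(symbol, seq):
    return classify_all([ProteinRecord(symbol, seq, symbol)], default_schema())[0]


class TestComposition:
    def test_single_protein_all_alanine(self):
        table = composition([labelled("psaA", "AAAA")])
        assert table.percent(PLASTID_GROUP, "A") == 100.0
        assert table.total_aa(PLASTID_GROUP) == 4

    def test_order_independence(self):
        a = composition([labelled("psaA", "AC"), labelled("psaB", "CA")])
        b = composition([labelled("psaB", "CA"), labelled("psaA", "AC")])
        assert a.percent("Photosystems", "A") == 50.0
        assert a.counts == b.counts

    def test_unclassified_protein_rejected(self):
        with pytest.raises(ValueError, match="unclassified"):
            composition([ProteinRecord("psaA", "MKL", "r")])

    def test_nonstandard_residue_goes_to_other_bucket(self, caplog):
        with caplog.at_level("WARNING", logger="pepscan"):
            table = composition([labelled("psaA", "MKXL")])
        assert table.total_aa(PLASTID_GROUP) == 3
        assert table.other_counts[PLASTID_GROUP]["X"] == 1
        assert any("non-standard" in r.message for r in caplog.records)

    def test_unrounded_percents_sum_to_100_per_group(self, fixture_bundle):
        table = composition(fixture_bundle.proteins)
        for group in table.groups:
            total = sum(table.fraction(group, aa) for aa in set("ACDEFGHIKLMNPQRSTVWY"))
            assert total == Fraction(1)

    def test_category_totals_sum_to_plastid_total(self, fixture_bundle):
        table = composition(fixture_bundle.proteins)
        categories = [g for g in table.groups if g != PLASTID_GROUP]
        assert sum(table.total_aa(g) for g in categories) \
            == table.total_aa(PLASTID_GROUP)

    def test_merge_equals_concatenation(self, fixture_bundle):
        proteins = fixture_bundle.proteins
        half = len(proteins) // 2
        whole = composition(proteins)
        first, second = composition(proteins[:half]), composition(proteins[half:])
        merged = Counter(first.counts[PLASTID_GROUP])
        merged.update(second.counts[PLASTID_GROUP])
        assert merged == whole.counts[PLASTID_GROUP]

    def test_generated_composition_converges_to_targets(self):
        # law of large numbers at ~50,000 residues: within 0.5 points
        targets = {"L": 0.106, "I": 0.090, "A": 0.104, "G": 0.16,
                   "S": 0.14, "T": 0.14, "V": 0.13, "E": 0.13}
        cfg = GeneratorConfig(
            n_proteins={"Metabolism": 100}, length_range=(480, 520),
            background_frequencies=targets, seed=11, accidental_free=False,
        )
        proteins, _ = generate(cfg)
        table = composition(proteins)
        assert table.total_aa(PLASTID_GROUP) > 45_000
        for aa, freq in targets.items():
            assert table.percent(PLASTID_GROUP, aa) == pytest.approx(
                100 * freq, abs=0.5
            )


class TestCompare:
    def test_identical_tables_give_zero_differences(self):
        table = composition([labelled("psaA", "ACDE")])
        ref = {aa: table.percent(PLASTID_GROUP, aa) for aa in "ACDE"}
        assert set(compare_composition(table, ref).values()) == {0.0}

    def test_signed_differences(self):
        table = composition([labelled("psaA", "A" * 60 + "C" * 40)])
        diffs = compare_composition(table, {"A": 50.0, "C": 50.0})
        assert diffs == {"A": 10.0, "C": -10.0}

    def test_combined_residue_rows(self):
        table = composition([labelled("psaA", "DDNNEEQQAA")])
        diffs = compare_composition(table, {"D+N": 30.0, "E+Q": 40.0})
        assert diffs == {"D+N": 10.0, "E+Q": 0.0}

    def test_isoleucine_difference_against_literature_reference(self):
        # a proteome with 9.0% Ile against the published 5.3% -> +3.7 points
        seq = "I" * 90 + "A" * 910
        table = composition([labelled("psaA", seq)])
        ref = load_reference_composition()["total_aa"]
        assert table.percent(PLASTID_GROUP, "I") == 9.0
        assert compare_composition(table, {"I": ref["I"]})["I"] == pytest.approx(3.7)

    def test_reference_table_has_combined_rows(self):
        ref = load_reference_composition()
        assert "D+N" in ref["total_aa"] and "E+Q" in ref["total_aa"]
        assert ref["total_aa"]["I"] == 5.3


def test_tsv_layout_rows_and_total(tmp_path, fixture_bundle):
    table = composition(fixture_bundle.proteins)
    path = tmp_path / "comp.tsv"
    write_composition_tsv(table, path, "params")
    lines = path.read_text().splitlines()
    assert lines[0] == "# params"
    assert lines[1].startswith("AA\tPlastid")
    assert len(lines) == 23  # comment + header + 20 AA rows + Total AA
    assert lines[-1].startswith("Total AA\t")
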