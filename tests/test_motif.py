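"""Motif scanning, tabulation and density arithmetic."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from pepscan.classification import classify_all, default_schema
from pepscan.genome_io import ProteinRecord
from pepscan.motif import (
    count_occurrences, density, scan_proteome, tabulate,
)
from pepscan.peptide_db import PeptideRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_hits(peptides, proteins):
    """Independent oracle: triple loop over proteins × offsets × peptides."""
    hits = []
    for protein in proteins:
        for i in range(len(protein.sequence)):
            for pep in peptides:
                if protein.sequence[i : i + 3] == pep.sequence:
                    hits.append((protein.record_id, i, pep.sequence))
    return hits


def labelled(symbol, seq, record_id=None):
    return classify_all(
        [ProteinRecord(symbol, seq, record_id or symbol)], default_schema()
    )[0]


class TestCountOccurrences:
    @pytest.mark.parametrize(
        "peptide, sequence, expected",
        [("AAA", "AAAA", 2), ("IPP", "MIPPG", 1), ("LVQ", "MKT", 0),
         ("AAP", "AAPAAP", 2), ("AAA", "AA", 0)],
    )
    def test_overlapping_window_counts(self, peptide, sequence, expected):
        assert count_occurrences(peptide, sequence) == expected

    def test_invalid_peptide_rejected(self):
        with pytest.raises(ValueError):
            count_occurrences("AAAA", "AAAA")


class TestScan:
    def test_positions_mode_returns_every_offset(self):
        protein = labelled("psaA", "AAPAAP")
        hits = scan_proteome([PeptideRecord("AAP", 5.0)], [protein])
        assert [(h.position, h.peptide) for h in hits] == [(0, "AAP"), (3, "AAP")]
        assert hits[0].terminal_class == "XXP"
        assert hits[0].category == "Photosystems"

    def test_unique_pairs_mode_collapses_per_protein(self):
        protein = labelled("psaA", "AAPAAP")
        hits = scan_proteome(
            [PeptideRecord("AAP", 5.0)], [protein], mode="unique_pairs"
        )
        assert [(h.position, h.peptide) for h in hits] == [(0, "AAP")]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            scan_proteome([], [], mode="bogus")

    def test_window_with_nonstandard_residue_never_matches(self):
        protein = ProteinRecord("psaA", "AXPAAP", "r", "Photosystems", "Photosystem I")
        hits = scan_proteome([PeptideRecord("AAP", 5.0)], [protein])
        assert [h.position for h in hits] == [3]

    def test_planted_fixture_recovered_exactly(self, fixture_bundle):
        fx = fixture_bundle
        hits = scan_proteome(fx.peptides, fx.proteins)
        assert len(hits) == fx.truth.total_planted()
        for hit in hits:
            assert hit.position in fx.truth.positions[hit.record_id][hit.peptide]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        # draw peptides mostly from the protein alphabet so matches are dense
        peptides = [
            PeptideRecord("".join(rng.choices(AA[:6], k=3)), 5.0)
            for _ in range(data.draw(st.integers(1, 12)))
        ] + [PeptideRecord("".join(rng.choices(AA, k=3)), 5.0) for _ in range(3)]
        peptides = list({p.sequence: p for p in peptides}.values())
        proteins = [
            labelled("psaA", "".join(rng.choices(AA[:6], k=rng.randint(3, 300))),
                     f"r{i}")
            for i in range(data.draw(st.integers(1, 5)))
        ]
        hits = scan_proteome(peptides, proteins)
        assert [(h.record_id, h.position, h.peptide) for h in hits] \
            == brute_force_hits(peptides, proteins)
        unique = scan_proteome(peptides, proteins, mode="unique_pairs")
        assert len(unique) == len(
            {(h.record_id, h.peptide) for h in hits}
        )


class TestDensity:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(751, 50333, 1.49), (742, 50229, 1.48), (53, 2654, 2.00),
         (19, 1784, 1.07), (0, 1000, 0.00), (177, 11017, 1.61)],
    )
    def test_half_up_rounding_to_two_decimals(self, count, total, expected):
        assert density(count, total) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            density(1, 0)


class TestTabulate:
    def test_category_table_totals_and_density(self):
        proteins = [labelled("psaA", "AAP" + "G" * 2651)]  # total AA 2654
        hits = scan_proteome([PeptideRecord("AAP", 5.0)], proteins)
        table = tabulate(hits, proteins, "category")
        assert table.cell("XXP", "Photosystems") == 1
        assert table.column_total("Photosystems") == 1
        assert table.group_total_aa["Photosystems"] == 2654
        assert table.grand_total == 1

    def test_no_hits_gives_zero_cells_and_densities(self, fixture_bundle):
        table = tabulate([], fixture_bundle.proteins, "category")
        assert table.grand_total == 0
        assert all(
            table.column_density(g) == 0.0 or table.group_total_aa[g] > 0
            for g in table.groups
        )
        assert {table.cell(c, g) for c in table.class_labels
                for g in table.groups} == {0}

    def test_class_rows_partition_each_column(self, fixture_bundle):
        fx = fixture_bundle
        hits = scan_proteome(fx.peptides, fx.proteins)
        for grouping in ("category", "photosystem_subcategory", "protein"):
            table = tabulate(hits, fx.proteins, grouping)
            for g in table.groups:
                assert table.column_total(g) == sum(
                    table.cell(c, g) for c in table.class_labels
                )
            assert table.grand_total == sum(
                table.column_total(g) for g in table.groups
            )

    def test_additivity_over_disjoint_protein_sets(self, fixture_bundle):
        fx = fixture_bundle
        half = len(fx.proteins) // 2
        parts = fx.proteins[:half], fx.proteins[half:]
        whole = tabulate(scan_proteome(fx.peptides, fx.proteins), fx.proteins)
        pieces = [tabulate(scan_proteome(fx.peptides, p), p) for p in parts]
        for cls in whole.class_labels:
            for g in whole.groups:
                assert whole.cell(cls, g) == sum(t.cell(cls, g) for t in pieces)

    def test_photosystem_subcategory_grouping_excludes_other_hits(self, fixture_bundle):
        fx = fixture_bundle
        hits = scan_proteome(fx.peptides, fx.proteins)
        table = tabulate(hits, fx.proteins, "photosystem_subcategory")
        ps_hits = [h for h in hits if h.category == "Photosystems"]
        assert table.grand_total == len(ps_hits)
        assert sum(table.group_total_aa.values()) == sum(
            p.length for p in fx.proteins if p.category == "Photosystems"
        )

    def test_empty_photosystems_warns(self, caplog):
        proteins = [labelled("rbcL", "MKLAAP")]
        with caplog.at_level("WARNING", logger="pepscan"):
            table = tabulate([], proteins, "photosystem_subcategory")
        assert table.grand_total == 0
        assert any("no Photosystems" in r.message for r in caplog.records)
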