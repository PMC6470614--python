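"""Synthetic-proteome generator: determinism, capacity, exact recovery."""

import pytest

from pepscan.composition import PLASTID_GROUP, composition
from pepscan.motif import scan_proteome, tabulate
from pepscan.peptide_db import PeptideRecord, terminal_class
from pepscan.synthetic import (
    GeneratorConfig, Plant, generate, make_paper_like_fixture, write_bundle,
)


class TestGenerate:
    def test_single_protein_two_plants_found_at_ledger_offsets(self):
        cfg = GeneratorConfig(
            n_proteins={"Photosystems": 1}, length_range=(30, 30),
            plants=(Plant("AAP", 2),), seed=5,
        )
        proteins, truth = generate(cfg)
        (protein,) = proteins
        positions = truth.positions[protein.record_id]["AAP"]
        assert len(positions) == 2
        hits = scan_proteome([PeptideRecord("AAP", 5.0)], proteins)
        assert sorted(h.position for h in hits) == sorted(positions)

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(
            n_proteins={"Metabolism": 3, "Unknown": 2},
            plants=(Plant("IPP", (1, 2)),), seed=42,
        )
        for d in ("a", "b"):
            proteins, truth = generate(cfg)
            write_bundle(proteins, truth, tmp_path / d)
        for name in ("proteins.fasta", "annotations.tsv", "genome.gb",
                     "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        base = dict(n_proteins={"Metabolism": 2}, plants=(Plant("IPP", 1),))
        a, _ = generate(GeneratorConfig(seed=1, **base))
        b, _ = generate(GeneratorConfig(seed=2, **base))
        assert [p.sequence for p in a] != [p.sequence for p in b]

    def test_uniform_background_composition_converges(self):
        cfg = GeneratorConfig(
            n_proteins={"Unknown": 100}, length_range=(500, 500),
            seed=9, accidental_free=False,
        )
        proteins, _ = generate(cfg)
        table = composition(proteins)
        assert table.total_aa(PLASTID_GROUP) == 50_000
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert table.percent(PLASTID_GROUP, aa) == pytest.approx(5.0, abs=1.0)

    def test_infeasible_plant_count_raises_capacity_error(self):
        cfg = GeneratorConfig(
            n_proteins={"Unknown": 1}, length_range=(20, 20),
            plants=(Plant("AAP", 10),), seed=0,
        )
        with pytest.raises(ValueError, match="capacity"):
            generate(cfg)

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError, match="length_range"):
            GeneratorConfig(n_proteins={"Unknown": 1}, length_range=(5, 30))
        with pytest.raises(ValueError, match="categories"):
            GeneratorConfig(n_proteins={"Nonsense": 1})
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(
                n_proteins={"Unknown": 1},
                background_frequencies={"A": 0.5, "C": 0.2},
            )

    def test_plants_never_overlap(self):
        cfg = GeneratorConfig(
            n_proteins={"Metabolism": 5}, length_range=(60, 80),
            plants=(Plant("IPP", 2), Plant("GAY", 2)), seed=3,
        )
        _, truth = generate(cfg)
        for per_pep in truth.positions.values():
            spans = sorted(
                (pos, pos + 3) for v in per_pep.values() for pos in v
            )
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                assert s1 >= e0


class TestExactRecovery:
    @pytest.mark.parametrize("mode", ["positions", "unique_pairs"])
    @pytest.mark.parametrize(
        "grouping", ["category", "photosystem_subcategory", "protein"]
    )
    def test_tabulate_of_scan_reproduces_ledger(self, fixture_bundle, grouping, mode):
        fx = fixture_bundle
        hits = scan_proteome(fx.peptides, fx.proteins, mode=mode)
        table = tabulate(hits, fx.proteins, grouping, mode)
        expected = fx.truth.expected_cells(fx.proteins, grouping, mode)
        observed = {k: v for k, v in table.cells.items() if v}
        assert observed == {k: v for k, v in expected.items() if v}


class TestPaperLikeFixture:
    def test_all_symbols_classify_without_fallback(self, fixture_bundle, caplog):
        from pepscan.classification import classify_all
        with caplog.at_level("WARNING", logger="pepscan"):
            classify_all([p for p in fixture_bundle.proteins])
        assert not any("not in schema" in r.message for r in caplog.records)

    def test_database_has_four_catch_all_peptides(self, fixture_bundle):
        xxx = [p.sequence for p in fixture_bundle.peptides
               if terminal_class(p.sequence).label == "XXX"]
        assert sorted(xxx) == ["GPM", "IWH", "LVE", "LVQ"]

    def test_scan_totals_equal_ledger_totals(self, fixture_bundle):
        fx = fixture_bundle
        hits = scan_proteome(fx.peptides, fx.proteins)
        assert len(hits) == fx.truth.total_planted()

    def test_seven_categories_and_about_2000_residues(self, fixture_bundle):
        fx = fixture_bundle
        assert len({p.category for p in fx.proteins}) == 7
        assert 1_500 <= sum(p.length for p in fx.proteins) <= 2_500

    def test_distinct_seeds_give_distinct_fixtures(self):
        assert make_paper_like_fixture(1).proteins[0].sequence \
            != make_paper_like_fixture(2).proteins[0].sequence
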