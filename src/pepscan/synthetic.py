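"""Synthetic proteomes with planted tripeptides and an exact ground truth.

The generator emulates the statistical structure the screen operates on — a
proteome partitioned into the seven functional categories, proteins of
varying length with a controllable background amino-acid composition, and
tripeptide occurrences planted at known positions — so every pipeline stage
is testable without any external download.

In ``accidental_free`` mode the background alphabet excludes every residue
occurring in a planted peptide, and plants are laid out in 5-residue slots
(3 residues + 2 background spacers). Any 3-residue window not exactly equal
to a plant then contains at least one background residue, so a peptide built
entirely from plant residues can never occur by accident: its true
occurrence count equals the ledger exactly. Plants never straddle protein
boundaries and never overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from ._util import STANDARD_AA, logger
from .classification import CATEGORIES, CategorySchema, classify, default_schema
from .genome_io import ProteinRecord, write_annotation_tsv, write_protein_fasta
from .peptide_db import CLASS_LABELS, PeptideRecord, terminal_class

#: One codon per amino acid (valid under genetic code table 11), used to
#: back-translate synthetic proteins into GenBank fixtures.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"
# Plant slot width: 3 peptide residues + 2 background spacers. The 2-residue
# gap means any 3-residue window not wholly inside one plant contains at
# least one background residue, and windows touching two plants contain two.
_SLOT = 5


@dataclass(frozen=True)
class Plant:
    """A tripeptide to plant: per-protein count (int or inclusive range)
    into proteins of ``target_categories`` (None = every category)."""

    peptide: str
    count_per_protein: int | tuple[int, int] = 1
    target_categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        terminal_class(self.peptide)  # validates


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generator settings.

    ``n_proteins`` maps category → protein count; lengths are uniform on
    the inclusive ``length_range`` (minimum 10); ``background_frequencies``
    (must sum to 1) default to uniform over the allowed alphabet.
    """

    n_proteins: dict[str, int]
    length_range: tuple[int, int] = (80, 120)
    background_frequencies: dict[str, float] | None = None
    plants: tuple[Plant, ...] = ()
    seed: int = 0
    accidental_free: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range} (min >= 10)")
        unknown = set(self.n_proteins) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if self.background_frequencies is not None:
            total = sum(self.background_frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"background frequencies sum to {total}, not 1")


@dataclass
class GroundTruth:
    """Ledger of planted occurrences.

    ``positions[record_id][peptide]`` lists 0-based planted start offsets;
    ``accidental_free[peptide]`` says whether the planted count is
    guaranteed to equal the true occurrence count.
    """

    positions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    accidental_free: dict[str, bool] = field(default_factory=dict)

    def planted_count(self, record_id: str, peptide: str) -> int:
        return len(self.positions.get(record_id, {}).get(peptide, []))

    def total_planted(self, peptide: str | None = None) -> int:
        return sum(
            len(pos)
            for per_protein in self.positions.values()
            for pep, pos in per_protein.items()
            if peptide is None or pep == peptide
        )

    def expected_cells(
        self,
        proteins: list[ProteinRecord],
        grouping: str = "category",
        mode: str = "positions",
    ) -> dict[tuple[str, str], int]:
        """Expected class × group counts, for comparison with ``tabulate``."""
        cells: dict[tuple[str, str], int] = {}
        by_id = {p.record_id: p for p in proteins}
        for record_id, per_pep in self.positions.items():
            protein = by_id[record_id]
            if grouping == "category":
                group = protein.category
            elif grouping == "photosystem_subcategory":
                if protein.category != "Photosystems":
                    continue
                group = protein.subcategory
            elif grouping == "protein":
                group = protein.gene_symbol
            else:
                raise ValueError(f"unknown grouping {grouping!r}")
            for pep, pos in per_pep.items():
                if not pos:
                    continue
                n = len(pos) if mode == "positions" else 1
                key = (terminal_class(pep).label, group)
                cells[key] = cells.get(key, 0) + n
        return cells


def _category_symbols(schema: CategorySchema) -> dict[str, list[str]]:
    by_cat: dict[str, list[str]] = {c: [] for c in schema.categories}
    for gene, sub in schema.gene_map.items():
        by_cat[schema.subcategory_to_category[sub]].append(gene)
    return by_cat


def generate(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate a labelled synthetic proteome and its ground-truth ledger.

    Reproducible: the single integer seed drives one explicit NumPy
    Generator stream; equal configs give byte-identical outputs. If
    ``out_dir`` is given, the bundle is written there (protein FASTA,
    annotation TSV, GenBank fixture, ledger JSON).

    Raises
    ------
    ValueError
        If the requested plant count cannot fit a protein's slot capacity.
    """
    rng = np.random.default_rng(config.seed)
    schema = default_schema()
    symbols = _category_symbols(schema)

    plant_residues = set("".join(p.peptide for p in config.plants))
    if config.accidental_free:
        alphabet = sorted(STANDARD_AA - plant_residues)
        if not alphabet:
            raise ValueError("plants use all 20 residues; no background left")
    else:
        alphabet = sorted(STANDARD_AA)
    if config.background_frequencies is None:
        probs = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        weights = [config.background_frequencies.get(a, 0.0) for a in alphabet]
        dropped = set(config.background_frequencies) - set(alphabet)
        if dropped:
            logger.warning(
                "background frequencies for %s renormalised away "
                "(accidental-free alphabet)", sorted(dropped),
            )
        total = sum(weights)
        if total <= 0:
            raise ValueError("background frequencies exclude whole alphabet")
        probs = np.array(weights) / total

    truth = GroundTruth(
        accidental_free={
            p.peptide: config.accidental_free for p in config.plants
        }
    )
    proteins: list[ProteinRecord] = []
    lo, hi = config.length_range
    idx = 0
    for category in CATEGORIES:
        n = config.n_proteins.get(category, 0)
        pool = symbols[category]
        for j in range(n):
            idx += 1
            record_id = f"synth{idx:04d}"
            symbol = pool[j % len(pool)]
            length = int(rng.integers(lo, hi + 1))
            residues = list(
                np.array(alphabet)[rng.choice(len(alphabet), size=length, p=probs)]
            )
            # plant into 4-wide slots so plants never overlap and always
            # keep a background spacer between them
            wanted: list[str] = []
            for plant in config.plants:
                if (
                    plant.target_categories is not None
                    and category not in plant.target_categories
                ):
                    continue
                c = plant.count_per_protein
                count = (
                    int(rng.integers(c[0], c[1] + 1)) if isinstance(c, tuple) else c
                )
                wanted.extend([plant.peptide] * count)
            n_slots = length // _SLOT
            if len(wanted) > n_slots:
                raise ValueError(
                    f"cannot plant {len(wanted)} peptides into {record_id}: "
                    f"length {length} has capacity for {n_slots}"
                )
            if wanted:
                slots = rng.choice(n_slots, size=len(wanted), replace=False)
                per_pep = truth.positions.setdefault(record_id, {})
                for pep, slot in zip(wanted, slots):
                    pos = int(slot) * _SLOT
                    residues[pos : pos + 3] = list(pep)
                    per_pep.setdefault(pep, []).append(pos)
                for pos_list in per_pep.values():
                    pos_list.sort()
            protein = classify(
                ProteinRecord(
                    gene_symbol=symbol,
                    sequence="".join(residues),
                    record_id=record_id,
                ),
                schema,
            )
            proteins.append(protein)

    if out_dir is not None:
        write_bundle(proteins, truth, out_dir)
    return proteins, truth


def write_bundle(
    proteins: list[ProteinRecord], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write the formats the pipeline consumes plus the ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_protein_fasta(proteins, out / "proteins.fasta")
    write_annotation_tsv(proteins, out / "annotations.tsv")
    write_genbank(proteins, out / "genome.gb")
    ledger = {
        "positions": truth.positions,
        "accidental_free": truth.accidental_free,
    }
    (out / "ground_truth.json").write_text(json.dumps(ledger, indent=2) + "\n")


def write_genbank(
    proteins: list[ProteinRecord], path: str | Path,
    record_id: str = "SYNPLASTID",
) -> None:
    """Back-translate proteins into a single synthetic GenBank record with
    one CDS feature (carrying ``/gene`` and ``/translation``) per protein."""
    nt_parts: list[str] = []
    features: list[SeqFeature] = []
    offset = 0
    spacer = "TTATTATT"  # non-coding filler between genes
    for p in proteins:
        cds = "".join(_CODON[aa] for aa in p.sequence) + _STOP
        features.append(
            SeqFeature(
                FeatureLocation(offset, offset + len(cds), strand=1),
                type="CDS",
                qualifiers={
                    "gene": [p.gene_symbol],
                    "translation": [p.sequence],
                    "transl_table": ["11"],
                    "note": [f"synthetic; source record {p.record_id}"],
                },
            )
        )
        nt_parts.append(cds)
        nt_parts.append(spacer)
        offset += len(cds) + len(spacer)
    record = SeqRecord(
        Seq("".join(nt_parts)),
        id=record_id,
        name=record_id,
        description="synthetic plastid-like fixture",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    record.features = features
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# Miniature study-shaped fixture


@dataclass(frozen=True)
class FixtureBundle:
    """A miniature screen-ready input set with exact ground truth."""

    proteins: list[ProteinRecord]
    truth: GroundTruth
    peptides: list[PeptideRecord]
    config: GeneratorConfig


#: Fixture peptide database: 10 tripeptides spanning several C-terminal
#: classes, including the four catch-all (XXX) class members LVQ, LVE, IWH
#: and GPM. IC50 values are synthetic (all < 20 μM).
FIXTURE_PEPTIDES: tuple[tuple[str, float], ...] = (
    ("IPP", 5.0), ("AKL", 14.0), ("GAY", 12.0), ("VFK", 18.0),
    ("LRV", 19.0), ("FQG", 15.0), ("LVQ", 2.2), ("LVE", 3.9),
    ("IWH", 1.9), ("GPM", 9.8),
)


def make_paper_like_fixture(seed: int = 0) -> FixtureBundle:
    """A ~20-protein, ~2,000-residue proteome over all 7 categories with a
    10-peptide database and planted, accident-free occurrences.

    Planted peptides: IPP everywhere (1-2 copies per protein), GAY in
    Photosystems, LVQ everywhere, VFK in Ribosomal Proteins and Metabolism. Every database peptide either
    uses plant residues only or would need a residue (e.g. I, L, V) that the
    accidental-free background excludes in an arrangement no plant boundary
    can produce, so scanning the fixture recovers the ledger exactly for
    the whole database.
    """
    config = GeneratorConfig(
        n_proteins={
            "Genetic System": 3, "Ribosomal Proteins": 3, "Photosystems": 5,
            "ATP Synthesis": 2, "Metabolism": 3, "Transport": 2, "Unknown": 2,
        },
        length_range=(80, 120),
        plants=(
            Plant("IPP", (1, 2)),
            Plant("GAY", 1, target_categories=("Photosystems",)),
            Plant("LVQ", 1),
            Plant("VFK", 1, target_categories=("Ribosomal Proteins", "Metabolism")),
        ),
        seed=seed,
        accidental_free=True,
    )
    proteins, truth = generate(config)
    peptides = [
        PeptideRecord(seq, ic50, "synthetic fixture value")
        for seq, ic50 in FIXTURE_PEPTIDES
    ]
    # non-planted database peptides are accident-free too when they are
    # built from residues absent from the background alphabet
    plant_residues = set("".join(p.peptide for p in config.plants))
    for rec in peptides:
        truth.accidental_free.setdefault(
            rec.sequence, set(rec.sequence) <= plant_residues
        )
    return FixtureBundle(proteins, truth, peptides, config)


def write_peptide_tsv(peptides: list[PeptideRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sequence\tic50_uM\tsource\n")
        for p in peptides:
            fh.write(f"{p.sequence}\t{p.ic50}\t{p.source_note or ''}\n")
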