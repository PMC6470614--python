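"""Functional classification of plastid genes.

Plastid protein coding genes fall into seven broad functional categories —
genetic system, ribosomal proteins, photosystems, ATP synthesis, metabolism,
transport, unknown — each split into subcategories (e.g. the photosystems
category holds phycobilisomes, photosystem I/II, the cytochrome complex and
the redox system). The schema is curation, not algorithm, so it ships as an
editable config (`data/plastid_gene_categories.tsv`, covering the 205 genes
of the *Palmaria* sp. (Japan) plastid) and users screening other genomes can
supply their own.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from ._util import logger
from .genome_io import ProteinRecord, with_labels

#: The seven categories, in canonical display order.
CATEGORIES = (
    "Genetic System",
    "Ribosomal Proteins",
    "Photosystems",
    "ATP Synthesis",
    "Metabolism",
    "Transport",
    "Unknown",
)

#: Short column labels used in printed tables.
CATEGORY_ABBREV = dict(
    zip(CATEGORIES, ("GS", "RP", "PS", "ATP", "Meta", "TP", "UK"))
)

#: Photosystems subcategories, in canonical display order.
PHOTOSYSTEM_SUBCATEGORIES = (
    "Phycobilisomes",
    "Photosystem I",
    "Photosystem II",
    "Cytochrome complex",
    "Redox system",
)

FALLBACK_CATEGORY = "Unknown"
FALLBACK_SUBCATEGORY = "Unique ORFs"


@dataclass(frozen=True)
class CategorySchema:
    """Gene → subcategory → category mapping.

    Gene-symbol matching is case-insensitive (annotation casing varies);
    symbols are stored lower-cased internally.
    """

    categories: tuple[str, ...]
    subcategory_to_category: dict[str, str]
    gene_map: dict[str, str]  # lower-cased gene symbol -> subcategory

    def lookup(self, gene_symbol: str) -> tuple[str, str] | None:
        """(category, subcategory) for a symbol, or None if unlisted."""
        sub = self.gene_map.get(gene_symbol.lower())
        if sub is None:
            return None
        return self.subcategory_to_category[sub], sub


@dataclass(frozen=True)
class SchemaReport:
    """Validation summary: symbol count, duplicates, per-subcategory tally."""

    n_genes: int
    duplicates: tuple[str, ...]
    empty_subcategories: tuple[str, ...]
    subcategory_tally: dict[str, int] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return not self.duplicates


def _schema_from_rows(rows: list[tuple[str, str, str]]) -> CategorySchema:
    """Build a schema from (gene, subcategory, category) rows.

    A gene symbol listed under two different subcategories is an error.
    """
    sub_to_cat: dict[str, str] = {}
    gene_map: dict[str, str] = {}
    categories: list[str] = []
    for gene, sub, cat in rows:
        if cat not in categories:
            categories.append(cat)
        if sub in sub_to_cat and sub_to_cat[sub] != cat:
            raise ValueError(
                f"subcategory {sub!r} mapped to both {sub_to_cat[sub]!r} and {cat!r}"
            )
        sub_to_cat[sub] = cat
        key = gene.lower()
        if key in gene_map and gene_map[key] != sub:
            raise ValueError(
                f"gene {gene!r} listed under both {gene_map[key]!r} and {sub!r}"
            )
        gene_map[key] = sub
    order = [c for c in CATEGORIES if c in categories]
    order += [c for c in categories if c not in order]
    return CategorySchema(tuple(order), sub_to_cat, gene_map)


def load_schema(path: str | Path) -> CategorySchema:
    """Load a schema config from TSV (``gene``/``subcategory``/``category``
    columns), YAML or JSON ({category: {subcategory: [genes]}} nesting)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        with path.open() as fh:
            nested = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        rows = [
            (gene, sub, cat)
            for cat, subs in nested.items()
            for sub, genes in subs.items()
            for gene in genes
        ]
    else:
        with path.open(newline="") as fh:
            rows = [
                (row["gene"], row["subcategory"], row["category"])
                for row in csv.DictReader(fh, delimiter="\t")
            ]
    return _schema_from_rows(rows)


def default_schema() -> CategorySchema:
    """The packaged 205-gene red-algal plastid schema."""
    ref = resources.files("pepscan.data") / "plastid_gene_categories.tsv"
    with resources.as_file(ref) as path:
        return load_schema(path)


def save_schema(schema: CategorySchema, path: str | Path) -> None:
    """Write a schema back to TSV (lossless round-trip of the mapping)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "subcategory", "category"])
        for gene, sub in schema.gene_map.items():
            writer.writerow([gene, sub, schema.subcategory_to_category[sub]])


def classify(protein: ProteinRecord, schema: CategorySchema) -> ProteinRecord:
    """Attach category/subcategory labels; unlisted symbols fall back to
    Unknown / Unique ORFs with a warning (classification is total)."""
    hit = schema.lookup(protein.gene_symbol)
    if hit is None:
        logger.warning(
            "gene symbol %r not in schema; classified as %s / %s",
            protein.gene_symbol, FALLBACK_CATEGORY, FALLBACK_SUBCATEGORY,
        )
        return with_labels(protein, FALLBACK_CATEGORY, FALLBACK_SUBCATEGORY)
    category, subcategory = hit
    return with_labels(protein, category, subcategory)


def classify_all(
    proteins: list[ProteinRecord], schema: CategorySchema | None = None
) -> list[ProteinRecord]:
    if schema is None:
        schema = default_schema()
    return [classify(p, schema) for p in proteins]


def validate_schema(schema: CategorySchema) -> SchemaReport:
    """Tally the schema for comparison against its source curation.

    Duplicates cannot survive :func:`load_schema` (it raises), so a loaded
    schema always reports zero; the field exists for schemas built by hand.
    """
    tally = Counter(schema.gene_map.values())
    dupes = tuple(
        sym for sym, n in Counter(schema.gene_map.keys()).items() if n > 1
    )
    empty = tuple(
        sub for sub in schema.subcategory_to_category if tally[sub] == 0
    )
    return SchemaReport(
        n_genes=len(schema.gene_map),
        duplicates=dupes,
        empty_subcategories=empty,
        subcategory_tally=dict(tally),
    )
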