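"""Tripeptide motif scanning and count tabulation — the screen's core.

Every database tripeptide is matched against every protein sequence.
Overlapping occurrences all count (a match at offset *i* does not mask one
at *i*+1): each occurrence is a distinct candidate fragment a protease
could liberate. Counts are aggregated into class × group tables — the
12 C-terminal classes as rows, and as columns either the 7 functional
categories, the 5 photosystem subcategories, or individual proteins —
with the enrichment statistic

    peptide/AA density (%) = 100 × matches / total residues in the group,

rounded half-up to 2 decimals for display.

Two counting modes exist because "number of peptides found" is ambiguous:
``positions`` counts every positional occurrence (the default);
``unique_pairs`` counts each (peptide, protein) pair once.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from ._util import STANDARD_AA, logger, round_half_up
from .classification import CATEGORIES, PHOTOSYSTEM_SUBCATEGORIES
from .genome_io import ProteinRecord
from .peptide_db import CLASS_LABELS, PeptideRecord, terminal_class

MODES = ("positions", "unique_pairs")
GROUPINGS = ("category", "photosystem_subcategory", "protein")
PHOTOSYSTEMS = "Photosystems"


@dataclass(frozen=True)
class MatchHit:
    """One occurrence of a database tripeptide in a protein.

    ``position`` is the 0-based start offset:
    ``protein.sequence[position : position + 3] == peptide``.
    Category labels are copied from the (classified) protein so downstream
    tabulation needs no join.
    """

    peptide: str
    gene_symbol: str
    record_id: str
    position: int
    terminal_class: str
    category: str | None = None
    subcategory: str | None = None


def count_occurrences(peptide: str, sequence: str) -> int:
    """Number of (overlapping) occurrences of a tripeptide in a sequence.

    >>> count_occurrences("AAA", "AAAA")
    2
    """
    if len(peptide) != 3 or set(peptide) - STANDARD_AA:
        raise ValueError(f"not a valid tripeptide: {peptide!r}")
    return sum(
        1 for i in range(len(sequence) - 2) if sequence[i : i + 3] == peptide
    )


def scan_proteome(
    peptides: list[PeptideRecord],
    proteins: list[ProteinRecord],
    mode: str = "positions",
) -> list[MatchHit]:
    """All matches of the peptide set against the protein set.

    Ordering is deterministic: by protein (input order), then position.
    A window containing a non-standard residue can never match because
    peptides contain only the 20 standard letters.

    ``mode="unique_pairs"`` keeps one hit (the first occurrence) per
    (peptide, protein) pair.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    wanted = {p.sequence: p.terminal_class.label for p in peptides}
    hits: list[MatchHit] = []
    for protein in proteins:
        seen_pairs: set[str] = set()
        seq = protein.sequence
        for i in range(len(seq) - 2):
            window = seq[i : i + 3]
            label = wanted.get(window)
            if label is None:
                continue
            if mode == "unique_pairs":
                if window in seen_pairs:
                    continue
                seen_pairs.add(window)
            hits.append(
                MatchHit(
                    peptide=window,
                    gene_symbol=protein.gene_symbol,
                    record_id=protein.record_id,
                    position=i,
                    terminal_class=label,
                    category=protein.category,
                    subcategory=protein.subcategory,
                )
            )
    return hits


def density(match_count: int, total_aa: int, ndigits: int = 2) -> float:
    """Peptide/AA density in percent, rounded half-up.

    >>> density(751, 50333)
    1.49
    """
    if total_aa <= 0:
        raise ValueError(f"total_aa must be positive, got {total_aa}")
    if match_count < 0:
        raise ValueError(f"match_count must be non-negative, got {match_count}")
    return round_half_up(Fraction(100 * match_count, total_aa), ndigits)


@dataclass(frozen=True)
class CountTable:
    """Class × group count matrix with totals, denominators and densities."""

    grouping: str
    mode: str
    groups: tuple[str, ...]
    cells: dict[tuple[str, str], int]  # (class label, group) -> count
    group_total_aa: dict[str, int]
    class_labels: tuple[str, ...] = CLASS_LABELS

    def cell(self, class_label: str, group: str) -> int:
        return self.cells.get((class_label, group), 0)

    def column_total(self, group: str) -> int:
        return sum(self.cell(c, group) for c in self.class_labels)

    def row_total(self, class_label: str) -> int:
        return sum(self.cell(class_label, g) for g in self.groups)

    @property
    def grand_total(self) -> int:
        return sum(self.cells.values())

    @property
    def total_aa(self) -> int:
        return sum(self.group_total_aa.values())

    def column_density(self, group: str) -> float:
        aa = self.group_total_aa[group]
        return density(self.column_total(group), aa) if aa else 0.0

    @property
    def overall_density(self) -> float:
        return density(self.grand_total, self.total_aa) if self.total_aa else 0.0


def _group_key(grouping: str):
    if grouping == "category":
        return lambda p: p.category
    if grouping == "photosystem_subcategory":
        return lambda p: p.subcategory if p.category == PHOTOSYSTEMS else None
    return lambda p: p.gene_symbol


def tabulate(
    hits: list[MatchHit],
    proteins: list[ProteinRecord],
    grouping: str = "category",
    mode: str = "positions",
) -> CountTable:
    """Aggregate hits into a class × group table.

    Group columns are the 7 functional categories, the 5 photosystem
    subcategories (hits outside Photosystems are excluded), or individual
    gene symbols in input order. ``Total AA`` per group sums the lengths of
    that group's proteins; hits must have been produced from them.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    key = _group_key(grouping)

    if grouping == "category":
        groups: tuple[str, ...] = CATEGORIES
    elif grouping == "photosystem_subcategory":
        groups = PHOTOSYSTEM_SUBCATEGORIES
        if not any(p.category == PHOTOSYSTEMS for p in proteins):
            logger.warning("no Photosystems proteins; subcategory table is empty")
    else:
        seen: dict[str, None] = {}
        for p in proteins:
            seen.setdefault(p.gene_symbol)
        groups = tuple(seen)

    group_total_aa = {g: 0 for g in groups}
    for p in proteins:
        g = key(p)
        if g in group_total_aa:
            group_total_aa[g] += p.length

    cells: dict[tuple[str, str], int] = defaultdict(int)
    for hit in hits:
        if grouping == "category":
            g = hit.category
        elif grouping == "photosystem_subcategory":
            g = hit.subcategory if hit.category == PHOTOSYSTEMS else None
        else:
            g = hit.gene_symbol
        if g is None or g not in group_total_aa:
            continue
        cells[(hit.terminal_class, g)] += 1
    return CountTable(
        grouping=grouping,
        mode=mode,
        groups=groups,
        cells=dict(cells),
        group_total_aa=group_total_aa,
    )


def write_hits_tsv(
    hits: list[MatchHit], path: str | Path, header_comment: str | None = None
) -> None:
    with Path(path).open("w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["peptide", "gene", "record_id", "position", "class",
             "category", "subcategory"]
        )
        for h in hits:
            writer.writerow(
                [h.peptide, h.gene_symbol, h.record_id, h.position,
                 h.terminal_class, h.category or "", h.subcategory or ""]
            )


def write_count_table_tsv(
    table: CountTable, path: str | Path, header_comment: str | None = None
) -> None:
    """TSV mirroring the printed class × group layout, totals and densities."""
    with Path(path).open("w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Peptide", "All"] + list(table.groups))
        for cls in table.class_labels:
            writer.writerow(
                [cls, table.row_total(cls)]
                + [table.cell(cls, g) for g in table.groups]
            )
        writer.writerow(
            ["Total", table.grand_total]
            + [table.column_total(g) for g in table.groups]
        )
        writer.writerow(
            ["Total AA", table.total_aa]
            + [table.group_total_aa[g] for g in table.groups]
        )
        writer.writerow(
            ["Peptide/AA (%)", f"{table.overall_density:.2f}"]
            + [f"{table.column_density(g):.2f}" for g in table.groups]
        )
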