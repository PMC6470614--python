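"""Amino-acid composition per protein group.

Composition is reported for the whole proteome ("Plastid") and for each
functional category, as residue counts and percentages of the group total.
Percentages are exact internally (rational arithmetic) and rounded half-up
to one decimal only for display, matching how composition tables are
printed. A packaged reference table carries literature proximate-analysis
values for *P. palmata* (total-AA and protein columns); proximate analysis
cannot distinguish Asp from Asn or Glu from Gln, so comparisons support
combined-residue rows (``D+N``, ``E+Q``).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

from ._util import STANDARD_AA, logger, round_half_up
from .genome_io import ProteinRecord

#: Amino acids in the alphabetical-by-full-name order of printed tables.
AA_DISPLAY_ORDER = "ARDNCEQGHILKMFPSTWYV"

#: Full names for display; cysteine is shown as "Cystine" to mirror the
#: printed table (internally it is always the letter C).
AA_NAMES = {
    "A": "Alanine", "R": "Arginine", "D": "Aspartic acid", "N": "Asparagine",
    "C": "Cystine", "E": "Glutamic acid", "Q": "Glutamine", "G": "Glycine",
    "H": "Histidine", "I": "Isoleucine", "L": "Leucine", "K": "Lysine",
    "M": "Methionine", "F": "Phenylalanine", "P": "Proline", "S": "Serine",
    "T": "Threonine", "W": "Tryptophan", "Y": "Tyrosine", "V": "Valine",
}

PLASTID_GROUP = "Plastid"


@dataclass(frozen=True)
class CompositionTable:
    """Residue counts and percentages per group.

    ``counts[group][aa]`` are integer tallies over the 20 standard residues;
    non-standard residues land in ``other_counts`` and are excluded from the
    percentage denominator.
    """

    counts: dict[str, Counter]
    other_counts: dict[str, Counter]

    @property
    def groups(self) -> list[str]:
        return list(self.counts)

    def total_aa(self, group: str) -> int:
        return sum(self.counts[group].values())

    def fraction(self, group: str, aa: str) -> Fraction:
        """Exact share of ``aa`` in ``group`` (0 for an empty group)."""
        total = self.total_aa(group)
        if total == 0:
            return Fraction(0)
        return Fraction(self.counts[group][aa], total)

    def percent(self, group: str, aa: str, ndigits: int = 1) -> float:
        """Display percentage, rounded half-up."""
        return round_half_up(100 * self.fraction(group, aa), ndigits)

    def percent_mapping(self, group: str, ndigits: int = 1) -> dict[str, float]:
        return {aa: self.percent(group, aa, ndigits) for aa in AA_DISPLAY_ORDER}


def composition(proteins: list[ProteinRecord]) -> CompositionTable:
    """Tally residues for the whole set plus one group per category.

    Proteins must be classified; a non-standard residue is excluded from the
    20-AA tally, counted in an ``other`` bucket, and warned about.
    """
    counts: dict[str, Counter] = {PLASTID_GROUP: Counter()}
    other: dict[str, Counter] = {PLASTID_GROUP: Counter()}
    for protein in proteins:
        group = protein.category
        if group is None:
            raise ValueError(
                f"protein {protein.gene_symbol!r} is unclassified; "
                "run classification first"
            )
        counts.setdefault(group, Counter())
        other.setdefault(group, Counter())
        for residue in protein.sequence:
            if residue in STANDARD_AA:
                counts[PLASTID_GROUP][residue] += 1
                counts[group][residue] += 1
            else:
                logger.warning(
                    "non-standard residue %r in %s excluded from composition",
                    residue, protein.gene_symbol,
                )
                other[PLASTID_GROUP][residue] += 1
                other[group][residue] += 1
    return CompositionTable(counts, other)


def _group_value(table: CompositionTable, group: str, key: str) -> Fraction:
    """Percent of one AA or a '+'-combined row (e.g. ``D+N``), exact."""
    return sum(
        (100 * table.fraction(group, aa) for aa in key.split("+")),
        Fraction(0),
    )


def compare_composition(
    table: CompositionTable,
    reference: dict[str, float],
    group: str = PLASTID_GROUP,
    ndigits: int = 1,
) -> dict[str, float]:
    """Signed differences (table − reference) in percentage points.

    Reference keys are single letters or combined rows like ``"D+N"``
    (aspartic acid + asparagine, indistinguishable in proximate analysis).
    Rounding is applied to each side before differencing so the result
    matches what a reader computes from printed one-decimal columns.
    """
    diffs: dict[str, float] = {}
    for key, ref_value in reference.items():
        ours = round_half_up(_group_value(table, group, key), ndigits)
        diffs[key] = round_half_up(ours - ref_value, ndigits)
    return diffs


def load_reference_composition() -> dict[str, dict[str, float]]:
    """Literature proximate AA composition of *P. palmata* (published
    values, not computed here): columns ``total_aa`` and ``protein``."""
    ref = resources.files("pepscan.data") / "palmata_reference_composition.tsv"
    out: dict[str, dict[str, float]] = {"total_aa": {}, "protein": {}}
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows, delimiter="\t"):
            for col in ("total_aa", "protein"):
                if row.get(col):
                    out[col][row["aa"]] = float(row[col])
    return out


def write_composition_tsv(
    table: CompositionTable, path: str | Path, header_comment: str | None = None
) -> None:
    """TSV with AA rows and one column per group (plastid first)."""
    groups = [PLASTID_GROUP] + [g for g in table.groups if g != PLASTID_GROUP]
    with Path(path).open("w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["AA"] + groups)
        for aa in AA_DISPLAY_ORDER:
            writer.writerow(
                [AA_NAMES[aa]] + [f"{table.percent(g, aa):.1f}" for g in groups]
            )
        writer.writerow(["Total AA"] + [table.total_aa(g) for g in groups])
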