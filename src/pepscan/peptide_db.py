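"""The tripeptide activity database: loading, validation, IC50 filtering,
and C-terminal class labels.

Angiotensin-I-converting-enzyme (ACE) inhibitory tripeptides are curated in
activity databases with a half-maximal inhibitory concentration (IC50, μM).
The screen keeps only potent tripeptides (IC50 strictly below a threshold,
20 μM by default) and groups them by their C-terminal residue — the residue
that dominates binding to ACE's S1' pocket. Eleven C-terminal residues
(P, Y, A, L, W, G, R, V, F, K, N) get their own class (``XXP`` … ``XXN``);
everything else falls in the catch-all class ``XXX``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from ._util import STANDARD_AA, logger

#: C-terminal residues with a dedicated class, in canonical display order.
CLASS_RESIDUES = "PYALWGRVFKN"

#: The 12 terminal-class labels in canonical display order (``XXX`` last).
CLASS_LABELS = tuple(f"XX{r}" for r in CLASS_RESIDUES) + ("XXX",)


@dataclass(frozen=True)
class PeptideRecord:
    """One database tripeptide with its activity value.

    Parameters
    ----------
    sequence
        Three one-letter codes from the 20 standard amino acids.
    ic50
        Half-maximal ACE-inhibitory concentration in μM; must be positive.
    source_note
        Optional free-text provenance.
    """

    sequence: str
    ic50: float
    source_note: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.sequence) != 3:
            raise ValueError(
                f"peptide {self.sequence!r} is not a tripeptide "
                "(only tripeptides are in scope)"
            )
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"peptide {self.sequence!r} contains non-standard "
                f"residue(s) {sorted(bad)}"
            )
        if not self.ic50 > 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")

    @property
    def terminal_class(self) -> "TerminalClass":
        return terminal_class(self.sequence)


@dataclass(frozen=True)
class TerminalClass:
    """C-terminal grouping of a tripeptide.

    ``label`` is ``"XX" + residue`` for the 11 residues with their own class,
    ``"XXX"`` otherwise; ``terminal_residue`` is the actual last residue, or
    ``"other"`` for the catch-all class.
    """

    label: str
    terminal_residue: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown terminal class label {self.label!r}")
        if (self.label == "XXX") != (self.terminal_residue == "other"):
            raise ValueError(
                "label is XXX iff the terminal residue has no dedicated class"
            )


def terminal_class(sequence: str) -> TerminalClass:
    """Classify a tripeptide by its C-terminal residue.

    >>> terminal_class("IPP").label
    'XXP'
    >>> terminal_class("LVQ").label
    'XXX'
    """
    if len(sequence) != 3 or set(sequence) - STANDARD_AA:
        raise ValueError(f"not a valid tripeptide: {sequence!r}")
    last = sequence[-1]
    if last in CLASS_RESIDUES:
        return TerminalClass(label=f"XX{last}", terminal_residue=last)
    return TerminalClass(label="XXX", terminal_residue="other")


def load_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Load a peptide activity table from TSV or CSV.

    The file needs header columns ``sequence`` and ``ic50_uM`` (an optional
    ``source`` column is carried through); lines starting with ``#`` are
    comments. Duplicate sequences collapse to the minimum IC50 — the most
    potent report wins — with a warning, since databases may list one
    peptide from several source proteins.

    Raises
    ------
    ValueError
        On a malformed row (named by row number) or a non-tripeptide entry.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
        sample = "".join(lines[:1])
        delimiter = "\t" if "\t" in sample else "," if sample else "\t"
        reader = csv.DictReader(lines, delimiter=delimiter)
        if sample and not {"sequence", "ic50_uM"} <= set(reader.fieldnames or ()):
            raise ValueError(
                f"{path}: need header columns 'sequence' and 'ic50_uM', "
                f"found {reader.fieldnames}"
            )
        best: dict[str, PeptideRecord] = {}
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                seq = (row["sequence"] or "").strip().upper()
                ic50 = float(row["ic50_uM"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row {i}: {exc}") from exc
            try:
                rec = PeptideRecord(seq, ic50, (row.get("source") or None))
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
            if seq in best:
                logger.warning(
                    "duplicate peptide %s (rows collapse to minimum IC50)", seq
                )
                if rec.ic50 < best[seq].ic50:
                    best[seq] = rec
            else:
                best[seq] = rec
    return list(best.values())


def example_peptide_table() -> list[PeptideRecord]:
    """The packaged example activity table (synthetic IC50 values): 10
    tripeptides spanning several classes, including the four catch-all
    members LVQ, LVE, IWH and GPM."""
    from importlib import resources

    ref = resources.files("pepscan.data") / "example_peptides.tsv"
    with resources.as_file(ref) as path:
        return load_peptide_table(path)


def filter_by_ic50(
    records: list[PeptideRecord], threshold: float = 20.0
) -> list[PeptideRecord]:
    """Keep records with IC50 strictly below ``threshold`` μM, order preserved."""
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return [r for r in records if r.ic50 < threshold]
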