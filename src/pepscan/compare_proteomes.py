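"""Two-proteome comparison of screen results.

Closely related plastids carry near-identical gene sets, so their screens
are compared cell-by-cell (count deltas per class × group) and as peptide
sets keyed on (peptide sequence, gene symbol) — not position, because
orthologous proteins differ in length. The set view matters because two
proteomes can show almost identical counts while the underlying peptide
sequences differ, which changes which proteases would release them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .motif import CountTable, MatchHit

Pair = tuple[str, str]  # (peptide sequence, gene symbol)


@dataclass(frozen=True)
class ComparisonReport:
    """Cell-wise deltas and per-category shared/unique peptide sets."""

    table_a: CountTable
    table_b: CountTable
    delta: dict[tuple[str, str], int]  # (class, group) -> a - b
    shared_peptides: dict[str, tuple[Pair, ...]]  # category -> sorted pairs
    only_a: dict[str, tuple[Pair, ...]]
    only_b: dict[str, tuple[Pair, ...]]

    @property
    def delta_grand_total(self) -> int:
        return sum(self.delta.values())

    def delta_column_total(self, group: str) -> int:
        return sum(v for (c, g), v in self.delta.items() if g == group)


def _pairs_by_category(hits: list[MatchHit]) -> dict[str, set[Pair]]:
    out: dict[str, set[Pair]] = {}
    for h in hits:
        out.setdefault(h.category or "Unknown", set()).add(
            (h.peptide, h.gene_symbol)
        )
    return out


def compare(
    table_a: CountTable,
    hits_a: list[MatchHit],
    table_b: CountTable,
    hits_b: list[MatchHit],
) -> ComparisonReport:
    """Compare two screens built with identical grouping, mode and classes.

    Raises on mismatched grouping/mode/class labels — the delta would be
    meaningless otherwise.
    """
    if table_a.grouping != table_b.grouping:
        raise ValueError(
            f"grouping mismatch: {table_a.grouping!r} vs {table_b.grouping!r}"
        )
    if table_a.mode != table_b.mode:
        raise ValueError(f"mode mismatch: {table_a.mode!r} vs {table_b.mode!r}")
    if table_a.class_labels != table_b.class_labels:
        raise ValueError("class-label mismatch")

    groups = list(table_a.groups)
    groups += [g for g in table_b.groups if g not in groups]
    delta = {
        (cls, g): table_a.cell(cls, g) - table_b.cell(cls, g)
        for cls in table_a.class_labels
        for g in groups
    }

    pairs_a = _pairs_by_category(hits_a)
    pairs_b = _pairs_by_category(hits_b)
    categories = sorted(set(pairs_a) | set(pairs_b))
    shared = {
        c: tuple(sorted(pairs_a.get(c, set()) & pairs_b.get(c, set())))
        for c in categories
    }
    only_a = {
        c: tuple(sorted(pairs_a.get(c, set()) - pairs_b.get(c, set())))
        for c in categories
    }
    only_b = {
        c: tuple(sorted(pairs_b.get(c, set()) - pairs_a.get(c, set())))
        for c in categories
    }
    return ComparisonReport(table_a, table_b, delta, shared, only_a, only_b)


def write_comparison(
    report: ComparisonReport, tsv_path: str | Path, json_path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Side-by-side TSV (class × {a, b, delta} per group) plus a JSON
    set-difference report."""
    ta, tb = report.table_a, report.table_b
    groups = list(ta.groups) + [g for g in tb.groups if g not in ta.groups]
    with Path(tsv_path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cols = [f"{g}:{side}" for g in groups for side in ("a", "b", "delta")]
        fh.write("Peptide\t" + "\t".join(cols) + "\n")
        for cls in ta.class_labels:
            row = [cls]
            for g in groups:
                a, b = ta.cell(cls, g), tb.cell(cls, g)
                row += [str(a), str(b), str(a - b)]
            fh.write("\t".join(row) + "\n")
        row = ["Total"]
        for g in groups:
            a, b = ta.column_total(g), tb.column_total(g)
            row += [str(a), str(b), str(a - b)]
        fh.write("\t".join(row) + "\n")
    payload = {
        "grand_total_a": ta.grand_total,
        "grand_total_b": tb.grand_total,
        "delta_grand_total": report.delta_grand_total,
        "shared_peptides": {
            c: [list(p) for p in v] for c, v in report.shared_peptides.items()
        },
        "only_a": {c: [list(p) for p in v] for c, v in report.only_a.items()},
        "only_b": {c: [list(p) for p in v] for c, v in report.only_b.items()},
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
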