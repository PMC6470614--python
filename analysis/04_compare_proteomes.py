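#!/usr/bin/env python
"""Compare two synthetic proteomes the way the two-species screen does.

Generates a second fixture with a different seed (standing in for a
related species' plastid), screens both with the same peptide database,
and reports per-category count deltas and shared/unique peptide sets.
Outputs under results/comparison/.
"""

import json
from pathlib import Path

from pepscan.compare_proteomes import compare, write_comparison
from pepscan.motif import scan_proteome, tabulate
from pepscan.synthetic import make_paper_like_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "comparison"
SEED_A, SEED_B = 7, 8


def main() -> None:
    a = make_paper_like_fixture(seed=SEED_A)
    b = make_paper_like_fixture(seed=SEED_B)
    hits_a = scan_proteome(a.peptides, a.proteins)
    hits_b = scan_proteome(a.peptides, b.proteins)
    table_a = tabulate(hits_a, a.proteins)
    table_b = tabulate(hits_b, b.proteins)
    report = compare(table_a, hits_a, table_b, hits_b)

    OUT.mkdir(parents=True, exist_ok=True)
    write_comparison(report, OUT / "comparison.tsv", OUT / "comparison_sets.json")
    print(f"a: {table_a.grand_total} matches, b: {table_b.grand_total}, "
          f"delta {report.delta_grand_total}")
    for g in table_a.groups:
        print(f"  {g:20s} delta {report.delta_column_total(g):+d}")
    sets = json.loads((OUT / "comparison_sets.json").read_text())
    n_shared = sum(len(v) for v in sets["shared_peptides"].values())
    n_a = sum(len(v) for v in sets["only_a"].values())
    n_b = sum(len(v) for v in sets["only_b"].values())
    print(f"peptide-gene pairs: {n_shared} shared, {n_a} only in a, "
          f"{n_b} only in b")


if __name__ == "__main__":
    main()
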