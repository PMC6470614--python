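#!/usr/bin/env python
"""Generate the study-shaped synthetic input bundle.

Creates a miniature plastid-like proteome (20 proteins over the 7
functional categories, ~2,000 residues) with planted tripeptide
occurrences and an exact ground-truth ledger, plus the 10-peptide activity
table, under results/fixture/. Downstream drivers screen this bundle.
"""

from pathlib import Path

from pepscan.genome_io import total_aa
from pepscan.synthetic import make_paper_like_fixture, write_bundle, \
    write_peptide_tsv

OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"
SEED = 7


def main() -> None:
    fx = make_paper_like_fixture(seed=SEED)
    write_bundle(fx.proteins, fx.truth, OUT)
    write_peptide_tsv(fx.peptides, OUT / "peptides.tsv")
    print(f"seed {SEED}: {len(fx.proteins)} proteins, "
          f"{total_aa(fx.proteins)} residues, "
          f"{fx.truth.total_planted()} planted occurrences -> {OUT}")


if __name__ == "__main__":
    main()
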