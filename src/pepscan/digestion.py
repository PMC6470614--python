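"""In-silico releasability of matched peptides under digestive proteases.

Human digestive enzymes cleave on the C-terminal side of characteristic
residues: pepsin after Asp, Glu, Leu, Phe, Trp, Tyr; chymotrypsin after
Phe, Trp, Tyr; elastase after Ala, Gly, Ile, Leu, Ser, Val; and prolyl
endopeptidase after Pro. A matched tripeptide's C-terminus can therefore be
generated by any enzyme whose specificity set contains its last residue.

The N-boundary rule — the match starts at the protein N-terminus, or the
preceding residue is cleavable by some enzyme — is this package's minimal
model extension for full release; digestion of the far side of the bond is
a binary site model with no missed cleavages, pH or kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from ._util import STANDARD_AA
from .genome_io import ProteinRecord
from .motif import MatchHit


@dataclass(frozen=True)
class EnzymeSpec:
    """A protease and the residues after which it cleaves (P1 specificity)."""

    name: str
    c_term_residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.c_term_residues:
            raise ValueError(f"{self.name}: empty specificity set")
        bad = set(self.c_term_residues) - STANDARD_AA
        if bad:
            raise ValueError(f"{self.name}: non-standard residues {sorted(bad)}")


@dataclass(frozen=True)
class ReleasabilityFlag:
    """Release annotation for one hit.

    ``fully_releasable`` requires both a C-terminal-generating enzyme and a
    cleavable N boundary.
    """

    hit: MatchHit
    c_releasable_by: frozenset[str]
    n_boundary_cleavable: bool
    fully_releasable: bool

    def __post_init__(self) -> None:
        if self.fully_releasable and not (
            self.c_releasable_by and self.n_boundary_cleavable
        ):
            raise ValueError(
                "fully_releasable requires a C-terminal enzyme and a "
                "cleavable N boundary"
            )


def default_enzymes() -> list[EnzymeSpec]:
    """The four digestive enzymes of the standard model (packaged config)."""
    ref = resources.files("pepscan.data") / "digestive_enzymes.yaml"
    with resources.as_file(ref) as path:
        return load_enzymes(path)


def load_enzymes(path: str | Path) -> list[EnzymeSpec]:
    """YAML list of ``{name, c_term_residues}`` entries."""
    with Path(path).open() as fh:
        entries = yaml.safe_load(fh) or []
    return [
        EnzymeSpec(e["name"], frozenset(e["c_term_residues"])) for e in entries
    ]


def annotate_releasability(
    hits: list[MatchHit],
    proteins: list[ProteinRecord],
    enzymes: list[EnzymeSpec] | None = None,
) -> list[ReleasabilityFlag]:
    """Annotate each hit with the enzymes able to generate its C-terminus
    and whether its N boundary is cleavable.

    Raises if a hit references a protein/position not in ``proteins``.
    """
    if enzymes is None:
        enzymes = default_enzymes()
    cleavable_after = frozenset().union(*(e.c_term_residues for e in enzymes)) \
        if enzymes else frozenset()
    by_key = {(p.record_id, p.gene_symbol): p for p in proteins}
    flags: list[ReleasabilityFlag] = []
    for hit in hits:
        protein = by_key.get((hit.record_id, hit.gene_symbol))
        if protein is None or not (
            0 <= hit.position and protein.sequence[hit.position : hit.position + 3] == hit.peptide
        ):
            raise ValueError(
                f"hit {hit.peptide} @ {hit.gene_symbol}:{hit.position} does not "
                "reference a known protein position"
            )
        c_by = frozenset(
            e.name for e in enzymes if hit.peptide[-1] in e.c_term_residues
        )
        n_ok = hit.position == 0 or (
            protein.sequence[hit.position - 1] in cleavable_after
        )
        flags.append(
            ReleasabilityFlag(
                hit=hit,
                c_releasable_by=c_by,
                n_boundary_cleavable=n_ok,
                fully_releasable=bool(c_by) and n_ok,
            )
        )
    return flags


def write_releasability_tsv(
    flags: list[ReleasabilityFlag], path: str | Path,
    header_comment: str | None = None,
) -> None:
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "peptide\tgene\trecord_id\tposition\tclass\t"
            "c_releasable_by\tn_boundary_cleavable\tfully_releasable\n"
        )
        for f in flags:
            h = f.hit
            fh.write(
                f"{h.peptide}\t{h.gene_symbol}\t{h.record_id}\t{h.position}\t"
                f"{h.terminal_class}\t{','.join(sorted(f.c_releasable_by))}\t"
                f"{f.n_boundary_cleavable}\t{f.fully_releasable}\n"
            )
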