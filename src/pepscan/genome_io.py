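"""Extraction of translated protein sequences from annotated genomes.

The screen's substrate is the set of protein coding genes (PCGs) of an
organellar genome, read either from a GenBank flat file (one record per
CDS feature) or from a protein multi-FASTA with a gene-annotation table.
Plastid genomes use NCBI genetic code table 11; the annotation's
``/translation`` qualifier, when present, is taken as authoritative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import logger, percent

PLASTID_GENETIC_CODE = 11


@dataclass(frozen=True)
class ProteinRecord:
    """One translated CDS.

    ``gene_symbol`` comes from the ``/gene`` qualifier, falling back to
    ``/locus_tag`` then ``/product``; unique open reading frames keep their
    ``orfNNN`` name. ``category``/``subcategory`` are attached later by
    functional classification. ``internal_stop`` flags a conceptual
    translation containing ``*`` before the final codon.
    """

    gene_symbol: str
    sequence: str
    record_id: str
    category: str | None = None
    subcategory: str | None = None
    internal_stop: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if "*" in self.sequence:
            raise ValueError("sequence must not contain stop symbols after processing")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeSummary:
    """Headline genome statistics: size, GC%, and feature counts."""

    total_nt: int
    gc_percent: float
    n_pcg: int
    n_trna: int
    n_rrna: int
    n_intron: int

    def __post_init__(self) -> None:
        if not 0 <= self.gc_percent <= 100:
            raise ValueError("gc_percent out of range")
        if min(self.total_nt, self.n_pcg, self.n_trna, self.n_rrna, self.n_intron) < 0:
            raise ValueError("counts must be non-negative")


def _cds_gene_symbol(feature) -> str | None:
    for qualifier in ("gene", "locus_tag", "product"):
        values = feature.qualifiers.get(qualifier)
        if values and values[0].strip():
            return values[0].strip()
    return None


def read_genbank_proteins(path: str | Path) -> list[ProteinRecord]:
    """One :class:`ProteinRecord` per CDS feature of a GenBank flat file.

    The ``/translation`` qualifier is used when present (the deposited
    annotation is authoritative); otherwise the CDS is extracted and
    translated with genetic code table 11. A trailing stop is stripped;
    an internal stop triggers a warning and flags the record.
    """
    proteins: list[ProteinRecord] = []
    for record in SeqIO.parse(str(path), "genbank"):
        for feature in record.features:
            if feature.type != "CDS":
                continue
            symbol = _cds_gene_symbol(feature)
            translations = feature.qualifiers.get("translation")
            if translations:
                aa = translations[0].strip().upper()
            else:
                try:
                    nt = feature.extract(record.seq)
                except Exception as exc:
                    raise ValueError(
                        f"{path}: CDS {symbol or feature.location} has neither a "
                        f"translation nor parsable coordinates: {exc}"
                    ) from exc
                aa = str(Seq(nt).translate(table=PLASTID_GENETIC_CODE))
            aa = aa.rstrip("*")
            internal_stop = "*" in aa
            if internal_stop:
                logger.warning(
                    "internal stop in conceptual translation of %s (%s)",
                    symbol, record.id,
                )
                aa = aa.replace("*", "")
            if symbol is None:
                raise ValueError(
                    f"{path}: CDS feature at {feature.location} has no gene, "
                    "locus_tag or product qualifier"
                )
            proteins.append(
                ProteinRecord(
                    gene_symbol=symbol,
                    sequence=aa,
                    record_id=record.id,
                    internal_stop=internal_stop,
                )
            )
    return proteins


def read_protein_fasta(
    path: str | Path, annotations: str | Path | None = None
) -> list[ProteinRecord]:
    """Read a protein multi-FASTA, labelling records via an annotation table.

    The table is TSV with columns ``record_id`` and ``gene_symbol``. FASTA
    ids missing from the table keep their id as gene symbol, with a warning.
    Duplicate FASTA ids are an error.
    """
    id_to_symbol: dict[str, str] = {}
    if annotations is not None:
        with Path(annotations).open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                id_to_symbol[row["record_id"]] = row["gene_symbol"]

    proteins: list[ProteinRecord] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        symbol = id_to_symbol.get(record.id)
        if symbol is None:
            symbol = record.id
            if annotations is not None:
                logger.warning(
                    "FASTA id %s not in annotation table; using id as gene symbol",
                    record.id,
                )
        proteins.append(
            ProteinRecord(
                gene_symbol=symbol,
                sequence=str(record.seq).upper().rstrip("*"),
                record_id=record.id,
            )
        )
    return proteins


def write_protein_fasta(proteins: list[ProteinRecord], path: str | Path) -> None:
    """Write proteins as multi-FASTA; the id is the record_id, the
    description the gene symbol (round-trips through ``read_protein_fasta``)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.record_id, description=p.gene_symbol)
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def write_annotation_tsv(proteins: list[ProteinRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "gene_symbol", "length"])
        for p in proteins:
            writer.writerow([p.record_id, p.gene_symbol, p.length])


def dedupe_genes(proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Collapse identical (gene_symbol, sequence) pairs, keeping first.

    Genes inside repeated regions (e.g. duplicated rRNA-operon flanks) can
    appear as two identical CDS copies; by default both are kept and counted.
    """
    seen: set[tuple[str, str]] = set()
    out: list[ProteinRecord] = []
    for p in proteins:
        key = (p.gene_symbol, p.sequence)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def total_aa(proteins: list[ProteinRecord]) -> int:
    """Total residue count — the denominator of every density statistic."""
    return sum(p.length for p in proteins)


def summarize_genome(path: str | Path) -> GenomeSummary:
    """Genome size, GC% (1 decimal, half-up) and feature counts by type."""
    total_nt = gc = n_pcg = n_trna = n_rrna = n_intron = 0
    for record in SeqIO.parse(str(path), "genbank"):
        seq = str(record.seq).upper()
        total_nt += len(seq)
        gc += seq.count("G") + seq.count("C")
        for feature in record.features:
            if feature.type == "CDS":
                n_pcg += 1
            elif feature.type == "tRNA":
                n_trna += 1
            elif feature.type == "rRNA":
                n_rrna += 1
            elif feature.type == "intron":
                n_intron += 1
    gc_percent = percent(gc, total_nt, 1) if total_nt else 0.0
    return GenomeSummary(total_nt, gc_percent, n_pcg, n_trna, n_rrna, n_intron)


def with_labels(
    protein: ProteinRecord, category: str, subcategory: str
) -> ProteinRecord:
    """Return a copy of ``protein`` carrying classification labels."""
    return replace(protein, category=category, subcategory=subcategory)
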