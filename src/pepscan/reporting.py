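"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` chains the stages — protein extraction, classification,
composition, motif scan, tabulation at all three groupings, releasability
annotation and (optionally) the two-proteome comparison — and writes each
table as TSV with a parameter header comment, plus a JSON manifest listing
input/output checksums and every parameter needed to re-run bit-identically.
Any stage error aborts with the stage name and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classification import classify_all, default_schema, load_schema
from .compare_proteomes import compare, write_comparison
from .composition import composition, write_composition_tsv
from .digestion import annotate_releasability, default_enzymes, load_enzymes, \
    write_releasability_tsv
from .genome_io import dedupe_genes, read_genbank_proteins, read_protein_fasta
from .motif import scan_proteome, tabulate, write_count_table_tsv, write_hits_tsv
from .peptide_db import filter_by_ic50, load_peptide_table


@dataclass
class PipelineParams:
    """User-facing knobs of a run; defaults are the screen's standard ones."""

    ic50_max: float = 20.0
    mode: str = "positions"
    dedupe: bool = False
    seed: int = 0


@dataclass
class RunManifest:
    """Inputs, parameters and outputs of one run, with SHA-256 checksums."""

    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    parameters: dict[str, object] = field(default_factory=dict)
    tool_version: str = __version__
    started: str = ""
    finished: str = ""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_proteins(path: Path, schema, params: PipelineParams):
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        proteins = read_genbank_proteins(path)
    else:
        annotations = path.with_suffix(".tsv")
        proteins = read_protein_fasta(
            path, annotations if annotations.exists() else None
        )
    if params.dedupe:
        proteins = dedupe_genes(proteins)
    return classify_all(proteins, schema)


def run_pipeline(
    genome_a: str | Path,
    peptides: str | Path,
    out_dir: str | Path,
    genome_b: str | Path | None = None,
    schema_path: str | Path | None = None,
    enzymes_path: str | Path | None = None,
    params: PipelineParams | None = None,
) -> Path:
    """Run the full screen and write the table suite plus a manifest.

    Outputs in ``out_dir``: ``composition.tsv``, ``hits.tsv``,
    ``counts_category.tsv``, ``counts_photosystem_subcategory.tsv``,
    ``counts_protein.tsv``, ``releasability.tsv`` and, with a second
    genome, ``comparison.tsv`` + ``comparison_sets.json``; always
    ``manifest.json``.
    """
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        parameters={
            "ic50_max": params.ic50_max,
            "mode": params.mode,
            "dedupe_genes": params.dedupe,
            "seed": params.seed,
            "schema": str(schema_path) if schema_path else "packaged default",
            "enzymes": str(enzymes_path) if enzymes_path else "packaged default",
        },
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for name, p in ("genome_a", genome_a), ("genome_b", genome_b), ("peptides", peptides):
        if p is not None:
            manifest.inputs[name] = _sha256(Path(p))
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)
        manifest.outputs[path.name] = _sha256(path)

    note = (
        f"ic50_max={params.ic50_max} mode={params.mode} "
        f"dedupe={params.dedupe} seed={params.seed} pepscan={__version__}"
    )
    stage = "setup"
    try:
        stage = "peptide_db"
        db = filter_by_ic50(load_peptide_table(peptides), params.ic50_max)
        stage = "schema"
        schema = load_schema(schema_path) if schema_path else default_schema()
        enzymes = load_enzymes(enzymes_path) if enzymes_path else default_enzymes()
        stage = "extract"
        proteins_a = _load_proteins(Path(genome_a), schema, params)
        stage = "composition"
        comp = composition(proteins_a)
        path = out / "composition.tsv"
        write_composition_tsv(comp, path, note)
        emit(path)
        stage = "match"
        hits_a = scan_proteome(db, proteins_a, mode=params.mode)
        path = out / "hits.tsv"
        write_hits_tsv(hits_a, path, note)
        emit(path)
        table_a = None
        for grouping in ("category", "photosystem_subcategory", "protein"):
            table = tabulate(hits_a, proteins_a, grouping, params.mode)
            if grouping == "category":
                table_a = table
            path = out / f"counts_{grouping}.tsv"
            write_count_table_tsv(table, path, note)
            emit(path)
        stage = "digest"
        flags = annotate_releasability(hits_a, proteins_a, enzymes)
        path = out / "releasability.tsv"
        write_releasability_tsv(flags, path, note)
        emit(path)
        if genome_b is not None:
            stage = "compare"
            proteins_b = _load_proteins(Path(genome_b), schema, params)
            hits_b = scan_proteome(db, proteins_b, mode=params.mode)
            table_b = tabulate(hits_b, proteins_b, "category", params.mode)
            report = compare(table_a, hits_a, table_b, hits_b)
            tsv, js = out / "comparison.tsv", out / "comparison_sets.json"
            write_comparison(report, tsv, js, note)
            emit(tsv)
            emit(js)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "tool_version": manifest.tool_version,
                "parameters": manifest.parameters,
                "inputs": manifest.inputs,
                "outputs": manifest.outputs,
                "started": manifest.started,
                "finished": manifest.finished,
            },
            indent=2,
        )
        + "\n"
    )
    return out
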