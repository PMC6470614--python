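# Methods

## The screen

Given a set of translated protein coding genes (PCGs) and a tripeptide
activity database, the screen is a motif-count procedure:

1. keep database tripeptides with IC50 strictly below a threshold
   (default 20 μM — "potent" by the usual convention for ACE-inhibitory
   tripeptides); duplicates collapse to the minimum IC50;
2. label each tripeptide by its C-terminal residue: eleven residues
   (P, Y, A, L, W, G, R, V, F, K, N) define their own class (`XXP` … `XXN`);
   all others fall into the catch-all `XXX`. The C-terminal residue
   dominates binding in ACE's active-site pocket, which is why the
   classification keys on it;
3. count every overlapping occurrence of every kept tripeptide in every
   protein, and aggregate into class × group tables with the density
   statistic `100 × matches / group residues` (half-up, 2 decimals).

Only tripeptides are screened: longer motifs occur too rarely for count
statistics at proteome scale, and dipeptides so often that the counts
overestimate recoverable activity.

### Counting semantics

"Number of peptides found" is ambiguous between positional occurrences and
distinct (peptide, protein) pairs. The default mode is `positions` — every
occurrence is a candidate fragment a protease could liberate, so all are
counted, including overlapping ones (a match at offset *i* does not mask
one at *i*+1). `unique_pairs` mode collapses to one hit per (peptide,
protein) pair and is a flag everywhere a mode is accepted. Windows
containing a non-standard residue never match. Tables built in different
modes or groupings refuse to be compared.

### Rounding

Printed composition and density tables round ties away from zero, so all
displayed percentages use exact rational arithmetic quantised half-up
(1 decimal for composition, 2 for densities). Full precision is kept
internally; rounding happens only at display. This reproduces, e.g.,
printed densities 1.49 (751/50,333), 2.00 (53/2,654) and 1.07 (19/1,784)
exactly, where banker's rounding would not.

## Genome handling

GenBank CDS features are translated with genetic code table 11 (plastid);
when a `/translation` qualifier is present it wins over conceptual
translation, because the deposited annotation is authoritative. Trailing
stops are stripped; an internal stop raises a warning and flags the
record. Gene symbols come from `/gene`, falling back to `/locus_tag` then
`/product`. Internal coordinates are 0-based half-open; the 1-based
inclusive convention exists only at the parser boundary. Genes present in
two identical copies (duplicated repeat regions) are kept as distinct
records by default; `--dedupe-genes` collapses identical (symbol,
sequence) pairs, since published residue totals may count each PCG once.

## Functional classification

The 7-category, 23-subcategory schema is curation, not computation, so it
ships as an editable TSV (`gene`, `subcategory`, `category`) covering the
205 plastid genes of *Palmaria* sp. (Japan); users screening other genomes
supply their own. Matching is case-insensitive; unlisted symbols classify
as Unknown / Unique ORFs with a warning, so classification is total. One
curatorial choice: the published per-protein photosystem table lists psbH
both under photosystem II and once inside the photosystem I block; the
schema assigns psbH to photosystem II only, and the packaged literature
table keeps the printed rows verbatim.

## Composition references

Literature proximate-analysis values for *P. palmata* ship as a packaged
reference table marked as published data. Acid hydrolysis deamidates Asn
and Gln, so references combine Asp+Asn and Glu+Gln; comparisons accept
combined-residue keys (`D+N`, `E+Q`) and sum the computed shares before
differencing. Differences are taken on the rounded one-decimal values,
matching what a reader computes from printed columns.

## Releasability model

Digestive proteases cleave C-terminal to characteristic residues: pepsin
{D, E, L, F, W, Y}, chymotrypsin {F, W, Y}, elastase {A, G, I, L, S, V},
prolyl endopeptidase {P} (config-driven YAML; trypsin etc. can be added).
A hit's C-terminus is generatable by any enzyme whose set contains its
last residue. The N-boundary rule — hit starts at the protein N-terminus,
or the preceding residue is in the union of enzyme sets — is this
package's minimal extension to define `fully_releasable`, and is labelled
a model extension in output. It is a binary site model: no missed
cleavages, no P1′ exclusion (e.g. no special-casing of cleavage before
proline), no pH or kinetics.

## Synthetic data

The generator emulates what the screen consumes: a proteome partitioned
into the 7 categories (gene symbols drawn from the shipped schema so
classification is exact), protein lengths uniform on a configurable range
(default 80–120 residues), residues i.i.d. from configurable background
frequencies, and planted tripeptides with per-protein counts (fixed or a
range) restricted to target categories. A single integer seed drives one
NumPy Generator; equal configs give byte-identical bundles (FASTA,
annotation TSV, back-translated GenBank, ledger JSON).

Accident-freeness is by construction: the background alphabet excludes all
plant residues, and plants occupy 5-residue slots (3 residues + 2
spacers), so any window not wholly inside one plant contains background
residues and windows touching two plants contain two. A peptide built
entirely from plant residues therefore occurs exactly as often as planted.
Plants never overlap and never straddle protein boundaries; overlap
behaviour of the matcher is tested on hand-written micro-sequences
("AAAA") instead. Plant capacity is `length // 5`; infeasible requests
raise an error stating it.

The study-shaped fixture (`make_paper_like_fixture`) is a 20-protein,
~2,000-residue proteome over all 7 categories with a 10-peptide database
whose catch-all class members are LVQ, LVE, IWH and GPM (synthetic IC50s,
all < 20 μM). What the generator does **not** emulate: realistic codon
usage, genome synteny, length/composition correlations, or evolutionary
divergence between compared proteomes — so passing tests demonstrate
correctness of the counting machinery, not biological realism of any
particular count.

## Problem sizes and numerical choices

The oracle-equivalence suite checks the scanner against a naive triple
loop on 200 random proteomes (10 of them at 10,000 residues, the rest
50–3,000; up to 50 peptides; both counting modes) — sizes chosen so the
whole suite runs in seconds while covering the regime the screen operates
in. Composition-convergence checks use 50,000 generated residues, where
the binomial standard error (~0.1 points per residue type) sits well
inside the 0.5–1 point tolerances asserted. Degenerate inputs are errors,
not coercions: zero-residue density denominators, non-tripeptide database
rows, duplicate FASTA ids and dangling hit references all raise; data
hygiene fallbacks (unknown gene symbols, non-standard residues) warn and
continue.

## Known limitations

- Absolute screen totals depend on the genome annotation and the database
  snapshot used; they are inputs, not reproducible constants. The shipped
  literature tables carry one internal inconsistency (class rows summing
  to 753 against a printed total of 751), preserved verbatim and asserted
  as documented.
- IC50 values are taken at face value across sources; no activity
  prediction or QSAR scoring is attempted for unmeasured peptides.
- Releasability is qualitative; it does not model digestion efficiency or
  fragment bioavailability.
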