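# Methods

## Scope and data model

The package analyses paired-chain single-cell TCR data for a set of
samples (one repertoire per animal), each carrying a condition label
(e.g. acute / chronic / latent infection). Inputs are per-contig tables
in the 10x `filtered_contig_annotations.csv` dialect or AIRR
Rearrangement TSV, plus an optional per-cell annotation table
(barcode, sample, group, transcriptional cluster) produced by any
upstream gene-expression pipeline. Gene-expression processing itself
(normalisation, clustering, differential expression) is deliberately out
of scope: clusters enter only as labels.

Barcodes are unique only within a sample; every cross-sample operation
keys on (sample_id, barcode).

## Quality filter

A cell is analysed only if it has **exactly one TRA and one TRB contig**
after per-contig predicates (productive, is-cell, high-confidence; each
independently toggleable, all on by default — 10x's filtered output
largely enforces them already, so the toggles mostly matter for AIRR
inputs where missing flags default to true). Predicates are applied
*before* the chain count, so a barcode whose second TRB is
non-productive still passes. Discards are counted per reason (no/multi
TRA, no/multi TRB, checked in that order) and the report must reconcile:
retained + discards = distinct barcodes. Identical
(barcode, locus, CDR3 nt) rows are deduplicated. Cellranger-style
booleans are parsed case-insensitively with `"None"` → false. CDR3
strings are used verbatim, including the canonical C…F flanks.

## Clonotype definition

Clone = identical paired CDR3 **nucleotide** sequence (CDRβ3 appended to
CDRα3). Synonymous amino-acid matches are distinct clones. V/J genes are
recorded per clone (as a multiset of (TRBV, TRAV) pairs over member
cells, since calls can disagree) but are not part of the key. Expanded =
≥ 2 distinct barcodes; lowly expanded = 1. Ranking ties among equal
clone sizes are broken by clone-id string order, purely for determinism.

## Diversity

Shannon entropy of clone-size proportions, natural log; evenness is
Pielou's J = H / ln S, which is log-base independent and lies in [0, 1].
A monoclonal repertoire (S = 1) is assigned evenness 0 by convention
(the 0/0 limit), with a warning. Cell counts (distinct barcodes) weight
the proportions, not UMIs.

## Overlap and convergence networks

Public clones are exact clonotype-key matches across repertoires
(amino-acid-level matching available but off by default). Restrictions:
all clones, expanded only, or each repertoire's top-n clones.

Similarity networks place one node per (clone, sample) — identical
clonotypes from two animals are distinct nodes joined at distance 0 —
and connect clones by Levenshtein distance on CDR3 amino-acid sequences.
Two threshold semantics are provided because either is defensible: the
default `sum` mode draws an edge when dist(TRB) + dist(TRA) ≤ t, and
`per_chain` requires both distances ≤ t; the comparison is inclusive
(≤ 7 by default). Note sum mode at a threshold is a subset of per-chain
mode at the same threshold. Distances are computed once per unique
sequence pair (edlib's banded Needleman–Wunsch) and broadcast to nodes;
tests verify equality with an exhaustive recursive implementation and an
all-pairs brute force.

## Germline usage

Usage vectors count TRBV (or TRAV, or both) genes either per cell
(default; matches cell-count displays, inflated by expansion) or per
clone (majority (TRBV, TRAV) pair of its members, ties to the
lexicographically smallest). Gene names are canonicalised (uppercase,
allele suffix stripped, dotted separators hyphenated) so external usage
tables in other dialects can be compared. Pairing matrices count cells
per (TRBV, TRAV) combination; marginals equal single-chain usage, and
the chord-diagram export lists pairs with ≥ 5 cells by default.
Correlation is Pearson on frequency vectors aligned to the union gene
set (Spearman optional); a constant vector yields NA for its pairs.
Hierarchical clustering uses average linkage on 1 − r, with NA distances
treated as maximal (2.0) and leaf order made deterministic by sorting
inputs by sample id.

## Expansion × phenotype

Per-clone and per-stratum cluster compositions are cell-level fractions;
unannotated barcodes are dropped (never imputed) and logged. The
association test builds, per cluster, a 2×2 table of
(expanded vs lowly expanded) × (in vs out of cluster) at the cell level
(a clone-level variant, each clone voting its majority cluster, is
provided to counter pseudo-replication), tests it with Fisher's exact
test (chi-square optional), applies a Haldane–Anscombe 0.5 correction to
the odds ratio when any cell is zero, and adjusts p-values across
clusters by Benjamini–Hochberg. The underlying figure-style displays are
descriptive; the formal test is this package's addition to make the
contrast assertable.

Motif matrices are position-by-residue frequencies over (by default
unique) CDR3 amino-acid sequences of one exact length — no alignment or
padding across lengths; the dominant length is reported as the default
stratum. Contrasts are entrywise differences, so each position row sums
to zero.

## Synthetic cohorts

The generator's defaults encode the study design the analysis targets:
6 samples, 3 conditions × 2 replicates, 300 clones each.

- **Clone sizes**: i.i.d. from a truncated power law P(k) ∝ k^(−α) on
  {1..1000} (geometric alternative available). Presets: α = 3.0
  ("acute-like": mostly singletons, evenness near 1) and α = 1.8
  ("chronic/latent-like": heavy tails, clones of hundreds of cells,
  occasionally ~1000). The names are documentation shorthand only.
- **Germline**: one base TRBV/TRAV frequency profile per specificity
  group (a single shared profile by default, since all cells share one
  antigen); each sample's profile is Dirichlet(κ·base) perturbed,
  κ = 100 by default (larger κ = tighter within-group similarity).
- **CDR3s**: amino-acid lengths TRB 12–17, TRA 10–16 (bell-shaped
  defaults), first codon cysteine, last phenylalanine, middle codons
  uniform over the 61 sense codons; translation by the standard code.
  Clonotype keys are resampled on collision, so keys identify planted
  clones perfectly — real-data collisions are outside the generator's
  scope.
- **Cluster labels**: cell in a clone of size k falls in cluster c with
  probability ∝ π_c·k^β₁ for c in the condition's target set
  (default targets: cluster 1 acute, 5 chronic, 2 latent), ∝ π_c
  otherwise. At k = 1 this is exactly the baseline π, so lowly expanded
  cells sit at baseline. The exact model-implied expanded-vs-lowly
  log odds ratio for the target set is computed from the planted sizes
  and stored in the manifest; `beta1_for_target_log_or` inverts it
  numerically (Brent) when an experiment needs a specific effect size.
- **Contamination**: per-cell TRA dropout (4%), TRB dropout (3%) and an
  extra random TRB (3%) — modest, realistic 10x failure modes whose only
  role is to exercise the QC filter. All rates configurable, zero for
  exact-recovery experiments.
- **Public clones**: each clone is copied into one other random sample
  with probability 0.01 (as a singleton), recorded in the manifest —
  matching the minimal-overlap regime the analysis expects.
- **RNG**: one seed; per-sample substreams via fixed-offset
  SeedSequences, so regenerating one sample never disturbs another, and
  cohort emission is byte-deterministic.

What the generator does **not** emulate: realistic VDJ junction
statistics (no OLGA-style recombination model — CDR3s are uniform random
codons), sequencing errors within CDR3s, UMI-depth structure, shared
convergent motifs between samples, or any real transcriptional
covariance behind the cluster labels. Passing recovery tests therefore
shows the pipeline's bookkeeping and statistics are correct under the
assumed structure, not that the structure matches any particular real
dataset.

## Numerical and testing choices

Entropy uses scipy's implementation, checked against literal summation
to 1e-12. Evenness comparisons in property tests exclude the uniform
fixed point. The network builder is verified against an O(n²) brute
force at n = 50 and several thresholds/modes. End-to-end experiments use
seeded replicate counts and problem sizes chosen to keep the whole suite
fast while leaving comfortable statistical margins: 100 replicates for
the evenness contrast (S = 300) and germline-grouping recovery
(S = 120 clones/sample, κ = 200, three well-separated profiles);
~3000 cells for recovering a planted log-OR of 1.5 within ±0.3;
200 single-sample replicates for the null false-positive check
(observed flag rate ≪ the 10% bound). The pipeline writes TSVs with
fixed column orders and "NA" for missing values so reruns are
byte-identical.

## Known limitations

- The clonotype key ignores V/J genes; two recombination events yielding
  identical paired CDR3 nucleotides would merge (vanishingly rare, but
  real).
- Cell-level association inherits pseudo-replication from large clones;
  the clone-level variant trades power for independence. Neither models
  within-clone correlation explicitly (no mixed model).
- Usage correlation treats gene frequencies as unstructured vectors;
  no compositional (log-ratio) transform is applied.
- The similarity network is exact but O(n²) in unique sequences;
  repertoires beyond ~10⁴ clones will be slow.
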