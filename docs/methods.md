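# Methods

## Contig peptide database

A transcriptome assembly gives contigs whose reading frame and strand
relative to the coding sequence are unknown. The database builder
therefore translates each contig codon-by-codon at offsets 0, 1 and 2
from the 5′ end (frames 1–3) under the standard genetic code
(translation table 1; appropriate for plant nuclear transcripts). The
phrase "three forward frames" is taken literally: assembled transcripts
are normally reported sense-strand, so reverse-complement frames are an
option (`--frames 6`, ids `_f4`–`_f6`) rather than the default.

Decisions that the translation step had to fix:

* **Ambiguity**: input is uppercased and U→T normalized; any codon
  containing a character outside A/C/G/T translates to `X`. An
  ambiguous codon is never treated as a stop, so `X` never causes a
  split — conservative with respect to segment integrity. `X` residues
  count toward the minimum-length threshold.
* **Trailing partial codons** (< 3 nt) are dropped silently.
* **Stop splitting**: each frame translation is split into its maximal
  `*`-free substrings; empty segments from leading/trailing/consecutive
  stops are omitted. Segment numbers refer to the pre-filter split
  order so an entry id always identifies the same genomic region
  regardless of the length threshold.
* **Minimum length**: segments shorter than 5 residues are removed
  (boundary inclusive — a 5-mer is kept). Applied per segment, not per
  contig.
* **Naming**: default `canonical` ids are frame-qualified
  (`<contig>_f<frame>[_<segment>]`) and therefore collision-free. The
  frame-blind convention seen in legacy databases (`contig_1`,
  `contig_1_2`) is available as `paper` style; because it cannot
  distinguish frames, the builder emits a warning on the first id
  collision.
* **No de-duplication**: identical peptide sequences arising from
  different contigs/frames are all retained; entry counts are raw.

The codon lookup uses the Biopython codon table; FASTA parsing uses
`Bio.SeqIO`. `count_entries` streams over header lines in constant
memory so multi-million-entry databases can be validated cheaply.

## IP-MS evidence aggregation and candidate filtering

PSM reports are consumed as tab-separated tables (spectrum id, peptide,
semicolon-separated protein accessions, sample label), the common
denominator of PeptideShaker-style exports; a column-name mapping
adapts other layouts. Aggregation counts **distinct peptide strings**
(modifications are not modelled) and PSMs per accession and sample.

* **Extension grouping** collapses contig-derived accessions onto their
  base contig: frame-qualified ids unambiguously; frame-blind ids by
  stripping one trailing `_<number>` when the remainder itself ends in
  `_<number>` (the `contig_<n>` convention). Other accessions pass
  through.
* **Shared peptides**: default policy `all` credits a shared peptide to
  every matched protein (naive spectral counting). Policy `razor`
  credits it only to the protein with the most distinct peptides
  (ties: lexicographically smallest accession), which conserves the
  total spectrum count.
* **Candidate filter**: `n_peptides >= 3 and n_spectra >= 6`, both
  inclusive. These defaults are the acceptance rule the workflow was
  built around; both are parameters.
* **Control subtraction** (off by default): a candidate is discarded
  when its control spectral count strictly exceeds
  `max_control_fraction` (default 0.5) times its bait count. The
  underlying study ran wild-type control IPs without stating a rule;
  this explicit one is provided as a documented option.
* **Coverage** is exact substring matching of peptides against the
  protein sequence, all occurrences counted, overlapping intervals
  merged, reported as percent of residues covered. I and L are distinct
  unless `equate_il` is set (search-engine conventions differ).

Out of scope by design: spectrum scoring, FDR estimation, PTM
localization, and enrichment statistics — the module consumes search
engine output, it does not rank spectra.

## Homolog annotation

"Best fit" is implemented as the highest Smith–Waterman local-alignment
score using BLOSUM62 with affine gap penalties, open 11 / extend 1 (a
gap of length L costs 11 + L), the standard protein-search default;
matrix and penalties are configurable. Ties break by higher percent
identity, then lexicographically smaller accession, making the result
independent of reference order. Percent identity is computed over all
aligned columns of the best alignment, gap columns included. No
E-values are computed — ranking is by raw score, since database-size
calibration is outside this package's scope. Alignment itself is
Biopython's `PairwiseAligner`; a hand-rolled affine-gap DP serves as an
independent cross-check in the tests.

Replacement granularity: a homolog substitutes for **all** frame/segment
entries of its candidate contig, one homolog entry per contig, leaving
unmapped entries untouched. The operation is idempotent for a fixed
mapping; mappings that reference absent contigs are skipped with a
warning.

## DEG calling and tissue-specificity classification

A gene is a DEG when `padj < alpha` (strict; default 0.05) and
`|log2FC| >= log2(min_fold)` (inclusive; default 2-fold, so |log2FC| ≥ 1
qualifies). Missing adjusted p-values never qualify. Multiple-testing
correction is taken as given from the upstream RNA-seq pipeline.

Per direction of change, a gene's membership across leaf/stem/root
determines exactly one of seven Venn categories (common, three
tissue-specific, three pairs); the category counts partition the union
of the three sets. Increased and decreased memberships are tallied
independently, so a gene up in one tissue and down in another appears
once per direction. A gene absent from a tissue's table is not a DEG
there. Percentages are relative to each tissue's total DEG count and
rounded half-up to the nearest integer, matching the reporting style of
the tissue-Venn figures this mirrors.

Plasticity between genotypes is the fold ratio of DEG counts over
matched tissues. Both conventions are computed — ratio of summed totals
and mean of per-tissue ratios — because "average fold" is ambiguous;
the headline value (rounded half-up to one decimal) comes from the
configured method, default `ratio_of_totals`. On the published
per-tissue totals, (998, 1195, 587) vs (5521, 4426, 2607), the two
conventions give 4.52 and 4.56, both printing as 4.5/4.6 at one
decimal; ratio-of-totals reproduces the published 4.5.

## Synthetic data and what tests show

The generators exist because the original raw inputs (contigs, spectra,
reads) are not practical to ship or reprocess; each emits plain-text
data plus serialized truth, byte-reproducible for a fixed seed.

* **Contigs**: uniform A/C/G/T sequences (default 200 contigs, lengths
  30–300 nt, here also run at 0–300 to exercise degenerate lengths),
  stop codons substituted per frame-1 codon at density 0.05, positions
  masked to N at a small fraction (0.02–0.05). The expected database is
  computed by a naive translator with a literal 64-codon table and
  character-wise splitting — deliberately independent of the main
  implementation, so agreement is a genuine two-path check.
* **PSM reports**: noiseless mode draws interactor counts inside the
  acceptance region (3–8 peptides, 6–20 spectra) and background counts
  in its complement (≤ 2 peptides, or 3–4 peptides with ≤ 5 spectra),
  so the filter must separate the classes perfectly; any error is an
  implementation bug, not noise. A negative-binomial mode (means 10 vs
  2 spectra, dispersion 2) produces overlapping count distributions,
  and recovery is then checked against direct evaluation of the drawn
  counts rather than labels.
* **DE tables**: planted genes receive `padj ~ U(0, alpha/10)` and
  signed `|log2FC| ~ N(2.5, 0.1)` in exactly their member tissues;
  all other gene/tissue cells get null `padj ~ U(0,1)` with
  `log2FC ~ U(-0.9, 0.9)`, which is below the fold threshold, so chance
  significance cannot create a spurious DEG. The default planted
  common-DEG counts (74 increased, 154 decreased) mirror the
  cross-tissue tallies of the motivating study. Setting the effect
  below 1 is a built-in negative control.

These models are intentionally minimal: real PSM data has shared
peptides, modification variants and decoys; real DE tables have
correlated p-values and fold changes near the thresholds. Passing tests
therefore demonstrate the correctness of the set logic, counting and
thresholds — not robustness to biological or instrumental noise.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale — hundreds of contigs,
500 proteins, ~1200-gene DE tables — which exercises every code path;
all operations are linear or near-linear in input size except pairwise
alignment (quadratic in sequence length, used on candidate sets of
tens, not millions). Rounding uses explicit half-up (not banker's)
wherever a headline figure is printed. Seeds are surfaced on every
generator; NumPy's `default_rng` is the only randomness source.

## Known limitations

* The frame-blind (`paper`) naming cannot be inverted safely; grouping
  heuristics for such accessions rely on the `contig_<n>` convention.
* Coverage requires the protein sequence; contig-grouped evidence has
  no single defined sequence, so coverage is left absent there.
* Best-fit annotation is exhaustive pairwise alignment — appropriate
  for tens of candidates against thousands of references, not for
  proteome-vs-proteome searches.
* The DE stage classifies; it does not test. Inputs must already carry
  corrected p-values.
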