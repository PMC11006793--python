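# Methods

## Problem and scope

`smorfkit` classifies small open reading frames (smORFs, 2–101 codons
including the stop) as coding or non-coding from sequence alone, and applies
the trained model to scan genomes for novel smORF candidates with ATG and
near-cognate start codons. Positives are mRNA coding sequences; negatives
are maximal ATG-initiated ORFs extracted from non-coding transcripts. Every
example carries its three upstream nucleotides so that the
translation-initiation-site (TIS) context can be encoded.

## Encoders

All probability tables are fitted separately on the positive and negative
training sets with additive smoothing (pseudocount 1 added to every cell
before normalization), so every stored probability is strictly positive and
every log-ratio finite, including for hexamers or codons unseen in training.
Logarithms are natural throughout; the base only rescales features and the
classifier is scale-insensitive, but the choice is fixed for
reproducibility.

- **TIS nucleotide bias** — sites −3, −2, −1 index the upstream trinucleotide
  and sites 4, 5, 6 the codon immediately after the start codon (ORF
  positions 4–6, 1-based). The feature is the per-site log-ratio of the
  observed nucleotide, kept as a 6-dim vector rather than summed, because
  the per-site biases differ widely. An `N` at a site contributes 0
  (equivalent to probability 0.25 on both sides), which keeps the encoder
  total for edge-padded upstream contexts.
- **Codon usage bias** — per-codon probability is codon count over
  encoding-amino-acid-class count (the three stop codons form one class);
  the feature is the *mean* log-ratio over all codons including the stop, so
  it is length-invariant.
- **Hexamer score** — the *sum* of log-ratios over in-frame hexamers
  (windows at codon boundaries, step 3 nt). The sum is deliberate: the score
  grows with ORF length, and that correlation is itself informative.
- **Fickett position parameter** — for each nucleotide, max/(min+1) of its
  counts at the three codon positions; position preference only, no content
  parameter or lookup-table weighting. Output order (T, A, C, G).
- **k-mers and gapped pairs** — sliding-window (step 1) relative
  frequencies; windows containing `N` are skipped. g-gap features are
  nucleotide pairs separated by g arbitrary bases (16-dim), g-bigap are
  dinucleotide pairs (256-dim) — the unique dimension assignment that makes
  the complete schema total 1169 (33 + 64 + 256 + 3·16 + 3·256).

Three schemas ship: `complete` (1169), `reduced33` (the basic + TIS +
in-frame block, 33) and `final32` — the 33 features ordered by the published
relevance/redundancy ranking with the last-ranked feature (2-mer TT)
dropped. `final32` is hard-coded so users can skip re-running selection.

## Data handling

Coordinates are 0-based half-open internally; GFF3/GTF are converted on
read, BED on write. Negative-set ORF extraction takes the longest
ATG-initiated, stop-terminated ORF over the three forward frames (ties go to
the 5′-most); requiring ATG matches the annotated starts of the positive
set. Upstream context that would run past the transcript 5′ end is
N-padded. Redundancy removal is greedy longest-first clustering on exact
global-alignment identity (matched columns over alignment length, Biopython
`PairwiseAligner`), dropping a record when identity ≥ 0.9 *and*
shorter/longer length ratio ≥ 0.9 against a retained representative —
adequate at the scale this package targets; equal lengths tie-break on id.
Train/test assembly balances classes by downsampling, splits 2:1 per label,
and removes test records redundant with same-label train records. Every
stochastic operation takes an explicit seed (default 42).

## Training and evaluation

Classifiers (LR, SVM, RF, GTB) come from scikit-learn; the default is a
random forest with `max_features='sqrt'`, 200 trees. Scores are
positive-class probabilities; the decision rule is score ≥ cutoff (ties
positive). Cross-validation is stratified k-fold (shuffled index modulo k
per class, fold sizes within a class differ by ≤ 1), and the feature tables
are re-fitted on each fold's training part only — no test-fold record ever
reaches the encoders. Undefined 0/0 rates are reported as 0 with a flag so
fold averaging stays total; an MCC denominator of 0 yields 0. ROC/PR curves
sweep the cutoff over all distinct scores plus the {0, 1} boundaries with
trapezoid AUC; with ties this reproduces the Mann–Whitney probability of
correct ranking exactly. The PR curve is stored as (recall, precision)
points; the published axis convention is swapped relative to common
practice, which affects plot labelling only, never the AUC.

## Feature selection

Ablation repeatedly cross-validates all leave-one-component-out subsets and
permanently drops the component whose removal performs best (highest mean
MCC, ties to higher ACC, then name). mRMR uses the mutual-information
quotient: features are discretized into 3 bins at mean ± one standard
deviation (classic mRMR practice), MI is computed in nats
(`sklearn.metrics.mutual_info_score`), the first pick maximizes relevance
and each later pick maximizes relevance over mean MI against the selected
set; ties break on ascending feature name. IFS cross-validates every nested
top-i subset and returns the smallest size attaining the maximal mean MCC.
`ifs_select` operates on raw records (tables per fold); `ifs_select_matrix`
is the same loop over a pre-encoded matrix for features that do not depend
on fitted tables.

## Cutoff calibration and genome scanning

`choose_cutoff` returns the smallest candidate threshold (distinct scores ∪
{0, 1}) whose precision reaches the target with at least one predicted
positive, or 1.0 ("reject all") when the target is unattainable — the
mechanism by which hopeless start codons drop out of the scan. The shipped
default cutoff map is ATG/CTG 0.780, GTG/ACG 0.968, TTG/ATT/ATC/ATA 1.000,
with AAG and AGG absent (always rejected); it is fully overridable.

The scanner enumerates, per strand and frame, every span from a configured
start codon to the nearest in-frame stop with 11–101 codons by default.
All qualifying starts sharing a stop are reported (a `longest_only` flag
collapses to the 5′-most). Codons containing `N` are never starts or stops
and candidates containing `N` are discarded, since the probability tables
are N-unaware. CDS-containment removal drops a candidate only when its
interval lies entirely inside a single same-strand CDS feature interval;
per-exon CDS features make single-interval containment the operative rule,
and no splice-aware projection is attempted. Gene-overlap annotation is
strand-agnostic with precedence protein_coding > lncRNA > pseudogene >
transcribed_pseudogene > other. Translation forces the first residue to Met
for every start codon, as near-cognate initiation uses the initiator
Met-tRNA.

## Synthetic data

The generator states a world with two knobs. Codon bias: within each
synonymous family the lexicographically first codon gets weight
1 + 3·strength, others 1, renormalized over the 61 sense codons — at
strength 0 this is exactly the uniform codon distribution used for
negatives, so the null is a true null. TIS bias: an extra probability mass
of 0.5·strength is split evenly over the enriched nucleotides — A/G at −3,
C at −1, G at +4 (Kozak-like) — and removed proportionally from the rest;
the +4 enrichment overrides the first base of the second codon, resampling
if that would create a stop. Lengths are uniform on 11–101 codons for both
classes (the genome-scan bounds), so length itself carries no signal.
Defaults are 500 records per class at strength 1.

The toy-genome generator plants ORFs (no internal in-frame stop by
construction) at evenly spaced known coordinates on either strand of random
uniform-background contigs, and can wrap chosen planted ORFs in decoy
gene+CDS annotation. What a green test establishes: the scanner, encoders,
selection and calibration behave correctly on sequences with planted,
known structure. What it does not: performance on real transcripts —
real mRNAs have GC/isochore structure, splicing, biased backgrounds and
much subtler class contrasts, so synthetic accuracy figures must not be
read as biological performance claims.

## Numerical and degenerate-case choices

Pseudocount 1 everywhere; probability-table invariants hold to 1e−9.
Sequences shorter than a pattern span yield all-zero frequency vectors;
an ORF shorter than 6 nt scores 0 hexamers with a warning. Empty datasets
are errors for fitting, empty candidate sets produce valid empty output
files. All tie-breaks (clustering order, ablation, mRMR, IFS) are
deterministic and documented above.

## Known limitations

- Redundancy removal is O(n²) with exact alignment: fine for thousands of
  records, not for the full-transcriptome scale where a dedicated
  clustering tool would be substituted.
- The scanner holds one contig in memory at a time; it is streaming-safe
  across contigs but not within a contig.
- Only the position parameter of the Fickett statistic is implemented, by
  design.
- A convolutional model variant and comparisons against external
  coding-potential tools are out of scope.
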