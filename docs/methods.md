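# Methods

## Data model and filtering

The experimental unit is one (gene, T-DNA insertion) event with an RT-PCR
expression call: `Ac` (activated), `NE` (no significant effect), `ND`
(non-detectable) or `Ko` (knockout). ND calls carry no usable signal and Ko
genes are physically disrupted rather than enhancer-regulated, so both are
dropped; NE is relabelled `NAc` and the task is binary Ac vs NAc. Training
sets are drawn class-balanced (uniformly at random within class under a
caller-supplied seed); the remainder forms the independent test set. Events
are never merged: the same gene observed under different insertions appears
as separate records, distinguished downstream by distance weighting.

The mutant table is a headered TSV (`line_id, gene_id, chrom, tls, strand,
enhancer_pos, status`) — the simplest lossless carrier of this information.
Coordinates are 1-based inclusive (GFF3 convention) throughout.

## Sequence windows

- **PROMOTER**: 1,500 bp immediately upstream of the TLS on the coding
  strand, excluding the TLS base; clipped (with a warning) only at contig
  edges. The window is TLS-anchored rather than TSS-anchored because
  activation-tagging datasets typically annotate only the start codon; the
  1,500 bp allow for a rice-scale 5' UTR plus 1 kb of upstream promoter.
- **MIDDLE**: 300 bp centered on `floor((tls + enhancer)/2)`, oriented on the
  gene's coding strand. When the anchors are closer than 300 bp the window is
  clipped to the bases strictly *between* them (both anchors excluded), so
  its length never exceeds the distance; this is the only reading under
  which the window stays "between" the anchors. The coding-strand
  orientation of MIDDLE is a choice — RevKmer is orientation-free but Kmer
  is not.

Ambiguous bases (N) are retained in sequences; encoders skip affected
windows rather than imputing.

## Feature encodings

**CpG islands.** Sliding-window detection (window 100 bp, step 1, minimum
island length 200 bp, GC ≥ 50%, OE ≥ 0.6, the classic newcpgreport-style
convention): an island is a maximal run of passing windows, reported with
five aggregate features (count, total length, mean 3'-edge distance to the
TLS, mean GC%, mean OE). OE of a window is `count(CG)·w / (count(C)·count(G))`.
"CpG ratio" is taken as GC percentage; the raw CpG count is kept on the
island objects. Note that window-based detection extends island boundaries
into flanks wherever overlapping windows still pass — coordinates are
context-dependent at the margins, which the tests exercise explicitly.

**Motifs.** Each IUPAC consensus is converted to a position frequency model
(uniform over the allowed bases per position, pseudocount 0.01 elsewhere,
renormalised) and scored as log₂ odds against a strand-symmetrised 0-order
background estimated from the promoter set. Exact p-values come from dynamic
programming over discretised scores (2,000 bins across the score span);
hits on both strands are kept at p ≤ 2.5 × 10⁻⁴. That threshold is the
loosest level at which an exact match to a 6-bp consensus — the length of
common plant core elements such as the G-box — survives under a uniform
background (best-case p = 0.25⁶ ≈ 2.44 × 10⁻⁴); conventional stricter
defaults silently discard every hit of short motifs. A palindromic site
scoring identically on both strands at the same coordinates is counted
once. Per motif the promoter is summarised by hit count, mean score,
coding-strand fraction and mean TLS distance (ratios 0 when absent). The
bundled library holds 40 curated, widely documented plant cis-element
consensi; full-scale collections load from any two-column TSV. The motif
"alignment score" of the conservation feature is the scan log-odds score.

**Kmer / RevKmer.** Sliding occurrence counts for k = 3–6 by default
(5,440 / 2,760 features); the 3–9 range (349,504 / 174,920) is supported but
the shipped default keeps the end-to-end suites at desk scale. RevKmer
collapses each k-mer with its reverse complement, represented by the
lexicographically smaller member; collapsed counts sum the pair (palindromes
counted once).

**DNP / TNP.** Relative oligonucleotide frequency × per-property value, over
a property table: 15 dinucleotide properties × 16 dinucleotides = 240 dims,
12 trinucleotide properties × 64 trinucleotides = 768 dims. The bundled
tables are **synthetic stand-ins** — standardized seeded random values in
the documented TSV layout — because the curated physicochemical index
collections they emulate are not redistributable here; every shape-dependent
result (dimensions, covariance structure) is index-agnostic, and users
supply real tables via `PropertyTable.from_tsv`.

**DACC / TACC.** Property values are standardized across oligonucleotides
(mean 0, sd 1), mapped along the sequence into one signal per property, and
summarised by auto-covariances (per property) and cross-covariances (per
ordered property pair) at lags 1..4: 15 properties → 60 + 840 = 900 dims;
12 → 48 + 528 = 576. Covariances are mean-centred within the sequence, so
homopolymers give exact zeros, and the encoding is invariant to affine
rescaling of any property row.

**PseKNC.** k-tuple frequencies (normalised to sum 1) extended by λ = 4
correlation factors θⱼ — the mean squared standardized dinucleotide-property
difference at offset j — with weight w = 0.2 and a shared denominator
1 + wΣθ, so the full vector always sums to 1. The feature length is 4^k + λ,
which is what the defining equations' index ranges force. λ must be smaller
than the sequence length.

## Statistical machinery

- **Fragment selection**: per-fragment Welch (unequal-variance) two-sample
  t-tests between Ac and NAc occurrence counts, keeping p < 0.05 *without*
  multiple-testing correction — deliberate: the filter is a noise reducer
  ahead of an SVM, not an inference procedure, and its null retention
  (~5%) is exactly what the tests assert. Zero-variance fragments are
  dropped. Retained-fragment reports are sorted by p-value, so a
  significant-motif list (G-box and relatives, on planted data) falls out
  directly.
- **Distance model**: maximum-likelihood logistic fit (statsmodels) of label
  on distance; coefficient standard errors are exposed for recovery checks.
  PROMOTER feature vectors are multiplied by P(Ac | d) *after* per-feature
  scaling; the weighting preserves direction, shrinks the norm by a factor
  in (0,1], and separates duplicate promoters observed at different
  distances.
- **F-score**: the LIBSVM `fselect` convention
  `F = ((x̄⁺−x̄)² + (x̄⁻−x̄)²)/(s²⁺ + s²⁻)`; +∞ when a nonconstant column has
  zero within-class variance, 0 for constants. Available as an optional
  per-model selection step.
- **mRMR**: greedy mutual-information-difference (MID) ranking on 3-bin
  equal-frequency discretised columns, deterministic index tie-break; the
  first pick is the pure max-relevance column. MID was chosen over MIQ as
  the variant whose score is well-defined when redundancy is zero.
- **Incremental selection**: stratified k-fold CV accuracy of ranked
  prefixes 1..N; the smallest prefix attaining the maximum wins.

## Two-layer architecture

Sixteen first-layer models — CGI/DNP/TNP/DACC/TACC/PseKNC on both regions,
Kmer+Motif and RevKmer+Motif on PROMOTER, Kmer and RevKmer on MIDDLE — each
scale features to [−1, 1], apply their fragment filters (fitted on training
data only), apply promoter weighting, and grid-search an RBF SVM
(C ∈ {2⁻¹, 2³, 2⁷}, γ ∈ {scale, 2⁻⁷, 2⁻³}, 3-fold internal CV; a coarse
subgrid of the usual LIBSVM ranges — the full grid is reachable through the
config but buys little here at ~40× the cost). The winning settings are
Platt-calibrated (`CalibratedClassifierCV`, sigmoid, ensemble=False) to
yield class confidences. PseKNC picks k ∈ 2..6 per region by a quick CV
sweep at fixed hyperparameters. A degenerate (all-constant) feature matrix
falls back to a class-prior dummy so the bundle always holds 16 well-formed
members (strict mode raises instead); this keeps small fixtures and
pathological regions from invalidating the whole bundle.

Meta-features are the 48 values (predicted label, positive confidence,
negative confidence) in fixed roster order. For training the second layer
they are generated **out-of-fold** (5 inner stratified folds, first layer
fully refitted per fold): resubstitution meta-features make every overfit
first-layer model look perfect and demonstrably drag the stack below the
distance-only baseline, while OOF generation lets mRMR + incremental
selection identify genuinely predictive models. Resubstitution remains
available as a config option. The final integrator is the LADTree.

**LADTree.** An alternating decision tree grown by LogitBoost: prediction
nodes carry additive values, splitter nodes are single-feature threshold
tests, and a new splitter may attach under *any* existing prediction node.
Per boosting iteration the working response z = (y−p)/(p(1−p)) and weights
w = p(1−p) are formed from the additive score F (p = 1/(1+e^(−2F))); the
(precondition node, feature, threshold) triple minimising weighted squared
error is attached with its two leaf values halved (LogitBoost step).
Prediction sums the values of every prediction node on every matching path;
the label is the score's sign. Ten boosting iterations by default (the
customary default for this learner; more iterations measurably overfit the
48-dim meta space). Candidate thresholds are up to 32 quantile midpoints
per feature; the split search uses prefix sums over sorted columns.
A depth-1 gradient-boosted classifier behind the same contract serves as an
independent cross-check in the tests, never as the implementation.

**Evaluation.** Stratified k-fold CV (default k = 5) refits *everything* —
fragment filters, scalers, distance logistic, SVM grids, meta generation,
mRMR/IFS, LADTree — inside each training fold; fold confusion matrices are
pooled (micro-averaged). Acc, Sn, Sp as percentages; MCC × 100; undefined
ratios reported as 0 with a flag. Distance-stratified accuracy uses
half-open (lo, hi] bins at 0–2, 2–5, 5–10, 10–15, 15–20, 20–25, >25 kb;
empty bins are flagged, never interpolated.

## Synthetic screens

One gene per synthetic contig, placed so the full 1,500-bp promoter fits;
the enhancer coordinate sits at a log-uniform distance (200 bp – 40 kb) on
the promoter side (+ strand) or mirror-image (− strand, 50/50). Activation
is Bernoulli(logistic(β₀ + β₁d)) with defaults β₀ = 1.5, β₁ = −10⁻⁴/bp —
β₁ ≤ 0 enforced, matching the negative distance–activation correlation the
method presumes. Promoter backgrounds are i.i.d. with GC 0.44 (rice-like);
no higher-order background model, for test transparency. Motifs are planted
conditional on the label at configurable rates — defaults: G-box CACGTG at
0.9 (Ac) vs 0.1 (NAc), ABRE ACGTGKC at 0.6/0.2, W-box TTGACY label-neutral
at 0.5/0.5 — at uniform positions with random orientation, so
strand-agnostic detectors are favoured exactly as theory predicts. Every
latent draw (distance, activation probability, label, planted motifs) is
recorded in a truth table; identical seeds give byte-identical FASTA/GFF3/
TSV output.

What the generator does *not* emulate: real promoter composition beyond GC
content (no CpG-island structure, no TATA positioning, no repeat content),
correlated insertions, or expression-level heterogeneity. Passing tests
therefore demonstrate that the machinery recovers planted signal under the
stated noise model — not field performance on rice data.

## Problem sizes and observed behaviour

The shipped study scale is a balanced 150+150 training set drawn from a
500-record pool, k-mers at 3–6, 40 library motifs, 5 outer CV folds with 5
inner stacking folds. At this scale one full training takes ~25 s and a
5-fold CV a couple of minutes on one CPU. On planted-signal screens the
pipeline's CV accuracy sits in the low-to-mid 70s — above both the 70%
bar and the distance-only logistic baseline (high 60s/70), with
Kmer-family first-layer models far ahead of the CGI/DNP/TNP group, the
same ordering the stacking is designed around. The margin over the
distance-only baseline is structurally modest under the default
conditions: distance enters every PROMOTER channel through the weighting,
so the baseline already captures most of the usable signal and the planted
motifs contribute the remainder. Permuted labels drive CV accuracy to
chance (±binomial noise), and label-free steps are bitwise reproducible
under a fixed seed.

## Known limitations

- The bundled property tables are synthetic stand-ins; absolute DNP/TNP/
  DACC/TACC/PseKNC values are meaningful only relative to a user-supplied
  real index set.
- The curated motif library is 40 entries, not a full cis-element
  collection; motif-channel coverage scales with the library supplied.
- Exact-match hits of motifs shorter than 6 bp can never reach the p-value
  threshold (their null probability exceeds it); such entries contribute
  structural zeros, mirroring the behaviour of standard scanners.
- Second-layer CV figures are honest (OOF stacking, per-fold refits) and
  therefore not comparable to resubstitution-style stacked accuracies,
  which run far higher on the same data.
- The PseKNC k-range is configurable (2..6 default; 2..7 supported); the
  k picked per region is data-dependent and logged rather than fixed.
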