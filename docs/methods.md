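# Methods

## Scope and data model

All genomic intervals are 0-based half-open internally; BED is read
verbatim and GFF3 converted (`start-1`) at the file boundary only.
Sequences are uppercased on ingest; symbols outside {A,C,G,T,N} become N
with a warning. Soft-masking is ignored (no masking policy is assumed).

## Motifs and scanning

Motifs are IUPAC strings with a per-motif mismatch allowance. The
built-in preset `ringrose7+gtgt` holds the eight classical PRE motifs
(EN1 `GSNMACGCCCC`, G10 `GAGAGAGAGA` — both allowing one mismatch — GAF
`GAGAG`, PF `GCCATHWY`, PM `CNGCCATNDNND`, PS `GCCAT`, Z `YGAGYG`, GTGT
`GTGT`); `comparison` adds six further published motifs for baseline
runs, and `random_kmers` draws control k-mers unique also under reverse
complement.

Scanning reports every window on either strand whose mismatch count
against the (degenerate) pattern is within the allowance. Conventions
fixed here:

- a position that falls outside its IUPAC set costs one mismatch
  regardless of the code's degeneracy;
- N in the sequence never matches (conservative);
- a pattern equal to its own reverse complement is scanned on the
  forward strand only, so palindromic hits are not double-counted;
- occurrences of nested motifs (e.g. PS inside PF/PM) are counted
  independently per motif.

Motif pairs are counted between occurrence midpoints at a configurable
cutoff, default 219 bp — the documented default of the predecessor
PREdictor line; this package measures midpoint-to-midpoint (the
historical choice between starts, midpoints and ends is not
recoverable, so the convention is explicit and configurable). Self-pairs
count unordered occurrence pairs (k mutually close occurrences of one
motif yield k(k-1)/2).

## Window scoring

A sequence is scored as the maximum over sliding windows (CPREdictor
default 500 bp — the size that generalizes best for that model; SVM-MOCCA
default 3 kb — matching its training sequences; step 10 bp everywhere,
including genome scans). A window counts an occurrence or pair only if
it is *fully contained* in the window. This makes the fast implementation
(each event is converted to its admissible window-start interval and
accumulated with a difference array over the start grid) exactly equal
to independently rescanning every window, which the test suite asserts.
Sequences shorter than the window are scored as one window.

## CPREdictor

Pair weights are `ln[(mean pair count per positive sequence + α) /
(mean per negative sequence + α)]` with α = 1 by default. The
pseudocount keeps all weights finite and mirrors the Markov-chain
pseudocount convention; it is configurable because the historical
normalization is not restated anywhere authoritative. Means are per
sequence, not per kilobase — training sets are uniformly 3 kb, where the
two are equivalent up to a constant. Natural logarithms throughout;
the base only rescales scores and is absorbed by threshold calibration.
The Dummy PREdictor sets every weight to 1, so its score is exactly the
window's total pair count (asserted against exhaustive enumeration).

## Markov chains and negative sets

Order-n chains store pseudocounted transition counts for every n-mer
context. Training is double-stranded: counts are accumulated on each
sequence and its reverse complement, so training on a set and on its
reverse complements is exactly identical (tested). Windows containing N
are skipped rather than erroring, since genome input contains gaps. A
pseudocount of 1 per nucleotide per context guarantees no zero
transition. The initial-context distribution is proportional to the
transition-count row sums — observed context frequency plus the uniform
pseudocount mass. This mirrors the conditional pseudocount, makes the
model serializable as a single count table, and resolves what happens
for never-observed initial contexts (they keep uniform mass).

"Dummy" negative sets are generated at 100× the positive count, 3 kb
each, from an order-4 chain trained on the respective positive set
(dummy PREs) or on the genome (dummy genomic); coding controls are
non-overlapping 3 kb fragments of concatenated coding sequence. The
synthetic test corpus plants a configurable number of motif copies
inside one cluster window per positive (window width = the smallest of
the per-motif spacings, so every planted pair is mutually in range) over
chain-generated background, and returns the placement log as ground
truth.

## SVM-MOCCA

One multi-class SVM per motif (libsvm one-vs-one with majority vote, via
scikit-learn's SVC), trained on the landscape vectors of all of that
motif's occurrences across all training classes. The landscape of an
occurrence is the |M| + 16 vector of (a) occurrences of each motif whose
midpoint lies within ±250 bp of the occurrence midpoint (the occurrence
itself included) and (b) counts of the 16 ordered dinucleotides starting
in the same ±250 bp base window, clamped at sequence ends. The default
class roster is PRE (positive) plus the three control classes
(dummy-PRE, dummy-genomic, coding); any ≥2 non-empty classes are
accepted. Class codes follow declaration order with the positive class
first, which also fixes majority-vote tie-breaking deterministically.
A motif with occurrences in fewer than two classes gets no SVM and
weight 0, with a warning.

SVM hyperparameters are deliberately exposed (C, gamma, coef0, kernel
degree 1/2/3). Defaults: C = 1, coef0 = 0, and **variance-scaled gamma**
(libsvm's `scale`, 1/(dim·Var[X])). Dinucleotide counts in a ±250 bp
window average ~30, so a fixed gamma of 1/dim produces polynomial-kernel
values of order 10⁶, which conditions the dual optimization poorly
(measured: ~1000× slower fits); variance scaling keeps kernel values
O(1). Passing an explicit float restores any fixed gamma.

`f(m, s)` is the raw count of occurrences of m in s classified into the
positive class; `w_m` applies the same α = 1 log-odds form as the pair
weights. Windowed scoring classifies each occurrence once against its
full-sequence landscape (flanks may extend past window edges) and then
credits `w_m` to every window containing the occurrence.

### Quadratic expansion

For a quadratic polynomial kernel, each one-vs-one decision function
`Σ_s α_s y_s (γ⟨x_s, x⟩ + c₀)² + b` is rewritten exactly as
`xᵀQx + ℓ·x + c` with `Q = γ² Xᵀdiag(αy)X`, `ℓ = 2γc₀ Xᵀαy`,
`c = c₀²Σαy + b` (equality to libsvm decision values is asserted to
1e-6 relative). Machines separating the positive class from each
negative class are summed, oriented so positive values favour the
positive class, across all motif SVMs. Unordered pairs collapse
`Q_ij + Q_ji`; the 16 dinucleotides merge with their reverse complements
into 10 features (4 self-complementary + 6 pairs), giving 18 merged
features and 18·19/2 = 171 unique feature-pair weights for the 8-motif
preset.

## Evaluation

PR curves are computed at every distinct score threshold (ties processed
together; predicted positive means score ≥ threshold). AUC is
trapezoidal over recall with the recall-0 anchor extending the first
precision value; the convention is fixed here for testability (an
external PR library's exact interpolation would be unknowable) and is
verified against an O(n²) threshold-sweep oracle. Cross-validation
shuffles each set independently per repetition (default 50), takes the
first 110 sequences of each set for training and then 50 positives /
5000 evaluation-class negatives for testing — a 1:100 imbalance
reflecting roughly a thousand ~1 kb PREs in a ~140 Mb genome. Mean AUC
gets a normal 95% CI (z = 1.96).

Threshold calibration scores held-out positives against freshly
generated background (default 44,626 × 3 kb ≈ 133.9 Mb, one genome
equivalent) and picks the threshold with the highest recall whose
precision meets the target (default 0.80), linearly interpolating
between adjacent thresholds when the target falls strictly between
their precisions; the final threshold is the mean over 10 regenerated
background draws (seeds derived as seed+rep). An unreachable target
returns the top score with a flag.

## Genome-wide prediction

Windows scoring strictly above the threshold (strict, consistent with
calibration returning interpolated, non-attained values) are merged when
they overlap by ≥1 bp — book-ended regions share no base under the
half-open convention and stay apart — with the merged score the maximum
of the constituents (the maximum, not the mean, because the window
maximum is also the sequence-score rule). Core fragments rescan a merged
prediction at sizes 500/600/750/1000/1500/2000/2500/3000 bp (those that
fit), step 50 bp, and keep the window maximizing score/length; ties go
to the smaller size, then leftmost. Overlap sensitivity extends the
reference set ±1 kb by default (factor-to-recruiter distancing); target
genes are all overlapping genes, else the endpoint-nearest gene(s) with
exact ties kept. The chromosome roster is whatever the FASTA contains;
euchromatic-arm restriction is a filter, not hard-coded.

## Synthetic data: what it does and does not show

The generators emulate k-mer composition (the Markov chains) and the two
discriminative signals the classifiers target: motif-pair clustering
(planted clusters) and distinctive local landscapes (CA-rich flanks
around planted occurrences). They do not emulate chromatin context,
positional biases along chromosomes, repeat structure, or correlated
motif grammar beyond the planted cluster — so passing recovery tests
demonstrates correctness of the algorithms under their own assumptions,
not field performance on real ChIP-derived region sets.

## Problem sizes in the test suite

Tests and the acceptance script run at fixture scale by choice: corpora
of tens of positives and hundreds-to-ten-thousand negatives at 1–3 kb,
1 Mb generated sequence for the k-mer-profile check, and calibration at
1000 negatives per repetition. The full-scale defaults (50 CV
repetitions, 44,626 calibration negatives, whole-genome scans) are the
library defaults and are exercised end-to-end at reduced sizes by
`mocca-pre pipeline --synthetic`.

## Known limitations

- SVM probability calibration, GC-stratified or shuffle-based negatives,
  PWM scoring and motif discovery are out of scope.
- The quadratic expansion is exact only for degree-2 polynomial kernels;
  linear/cubic models cannot be condensed this way.
- `mocca-pre pipeline` supports the synthetic recipe; assembling a full
  genome run from real data is done with the individual subcommands.
- Serialized SVM bundles use joblib pickles and are not portable across
  scikit-learn major versions.
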