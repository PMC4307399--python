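# Methods

This note records the model, the conventions chosen where the method
leaves freedom, what the synthetic data generator does and does not
emulate, and the known limitations.

## Model and fitting

A window of n residues is encoded as 19 + n(n−1) + K features:

| block | length (n=15, K=500) | content |
|---|---|---|
| composition | 19 | counts of each residue type, **Y omitted** as reference (last in alphabetical one-letter order); omitting one type avoids an exact "counts sum to n" collinearity with the intercept, though the indicator block keeps the design rank-deficient regardless |
| hydrophilicity pairs | 105 | Bⱼ·Bₖ for all j&lt;k, (j,k) lexicographic |
| side-chain-mass pairs | 105 | Sⱼ·Sₖ, same order |
| pair indicators | 500 | 1 iff selected pair (j,k,a,b) matches the window |

Scales are z-scored over the 20 canonical residues with population
statistics (mean 0, SD 1, tolerance 1e−9). Hydrophilicity is the
Parker–Guo–Hodges (1986) HPLC scale; masses are monoisotopic side-chain
masses. Because of the z-scoring, any constant offset (e.g. including the
backbone mass) is immaterial; both scales are also replaceable by a
two-column TSV.

Every window of every training peptide becomes one design-matrix row whose
target is the peptide's 0/1 epitope label — windows are never relabeled
individually. Coefficients are the minimal-norm ordinary-least-squares
solution (SVD, relative singular-value cutoff 1e−10). The design is
collinear by construction (indicator columns overlap composition columns),
so the minimal-norm convention is what makes fits reproducible: fitted
*scores* are invariant to duplicated columns and to training-row order,
which the tests assert. No regularization is applied.

A peptide of length L yields L−n+1 window scores; its epitope propensity
is their arithmetic mean (for 20-mers at n=15: 6 windows), thresholded at
0.5 by default for a binary call. The threshold is exposed everywhere
(`--threshold`), and ROC analysis is threshold-free.

## Pair selection

For each of the 400·n(n−1)/2 candidate position-specific residue pairs,
occurrences are counted over all training windows per class. Pairs with
total count below the mean over the full candidate space (zeros included)
are eliminated first; on realistic data roughly half survive, and the
point of the filter is that the downstream frequency ratio is unstable at
small counts. Survivors are ranked by the information value

D = f₁·ln(f₁/P₁) + f₀·ln(f₀/P₀),

with fₜ = countₜ/(count₁+count₀) and the prior Pₜ = (windows in class t)/
(all windows) — for balanced data P₁ = P₀ = 0.5. The natural logarithm is
used (ranking is base-invariant) with the 0·ln 0 := 0 convention for
pure-class pairs; D is the KL divergence of the pair's class split from
the prior, hence ≥ 0 with equality iff the split matches the prior. Ties
are broken by ascending (j, k, a, b) for cross-platform determinism. The
top K = 500 survivors are kept (`--top-pairs`); if fewer survive, all are
selected with a warning.

By default cross-validation refits the catalog on each training fold
(no selection leakage); `--global-catalog` selects once on the whole
dataset instead, since either protocol is defensible.

## Evaluation conventions

* **Metrics.** Sn = TP/(TP+FN), P = TP/(TP+FP), F = 2·P·Sn/(P+Sn),
  Acc = (TP+TN)/total; zero denominators yield 0 with a warning. AUC is
  computed by threshold sweep with trapezoidal integration and standard
  tie handling, so it equals the pairwise Mann–Whitney statistic exactly
  (asserted against a brute-force pairwise oracle).
* **Folds.** Stratified, seeded shuffling; per-fold class proportions are
  within one record of the global proportions. Held-out scores are pooled
  across folds into a single confusion table and AUC by default;
  `--fold-aggregation mean` averages per-fold metrics instead. Pooling is
  the more robust choice when folds are small.
* **Resampling.** Trial t uses seed master_seed + t both to draw the
  balanced negative subset (uniform, without replacement; positives first
  in output order) and for fold assignment. Trials are summarized by the
  best and worst F and by per-metric means with 95% normal-approximation
  CIs, mean ± 1.96·sd/√T.
* **Window scan.** Sizes 5–19 by default; sizes exceeding the peptide
  length are skipped with a warning. The scan reports CV and
  self-consistency F per size and flags the CV-F argmax; closeness of the
  two at the chosen size is the usual reliability heuristic, and 15 is the
  package default window size.

## Synthetic data: what it emulates, and what it does not

`generate_dataset` emulates the *structure* of experimentally derived
linear-epitope benchmarks: fixed-length 20-mer peptides, an unbalanced
positive/negative split, and noisy negatives — with probability
`negative_flip_rate` a record labeled 0 is drawn from the positive
sequence model, mimicking reported non-epitopes that are in truth
epitopes. Class signal is planted as position-specific residue pairs
(imposed by overwriting the two positions with per-class enrichment
probabilities; overlapping pairs apply in list order, later wins) and
optionally as a composition bias on the positive background. Background
residues are i.i.d. uniform over the 20 canonical residues by default;
real proteomes are not uniform, real epitopes carry secondary-structure
and solvent-accessibility signal, and real peptides are not independent
draws. Passing tests therefore demonstrate that the machinery recovers
linearly encodable signal at realistic sizes — not that the model attains
any particular accuracy on real antigens.

Two fixture subtleties matter when interpreting planted-signal tests:

1. **Window images.** A pair planted at peptide positions (j,k) appears at
   shifted window coordinates (j−s+1, k−s+1) in each window s containing
   both positions; recovery is checked against these images
   (`pair_window_images`).
2. **Composite pairs outrank their atoms.** When two pairs are planted
   independently at rate p in positives, both co-occur in ≥ 2p−1 of
   positives but almost never in negatives, so *cross* pairs (one residue
   from each planted pair) have an even purer class split than the planted
   pairs themselves and legitimately rank above them by D. The
   planted-recovery property tests therefore use configurations whose
   planted positions cannot co-occur inside one window (cross distances
   ≥ n), and sizes (2000+2000) at which the frequency pre-filter has
   adequate counts (~24 per candidate) to exclude small-count pairs whose
   frequency ratio is pure by chance. At 500+500 with three mutually
   interacting pairs the top of the ranking is occupied by such composite
   keys — the selector is then correctly ranking conjunctions of the
   signal above its atoms, which is visible in the acceptance output as
   near-ceiling CV AUC alongside low top-6 recovery of the atomic pairs.

The noisy-resampling study fixture plants six pairs (enrichment 0.9 vs
0.02) positioned so every window contains signal, making the clean-data
classifier near-ceiling; the across-trial F spread (standard deviation
over trials — a less outlier-dominated statistic than the max−min range)
is then dominated by which mislabeled negatives each balanced subset
happens to draw, which is precisely the phenomenon the repeated-trials
protocol exists to expose.

## Problem sizes and numerical choices

The shipped studies use 500+500 peptides for the planted-signal CV study
and 150 positives with a 375-negative pool, 10 trials per noise condition,
for the resampling study; at n = 15, K = 500 these run in about a minute
on one CPU while keeping per-trial counts large enough for stable
selection. All randomness flows from explicit integer seeds
(per-trial seed = master + t); reruns are byte-identical in every emitted
TSV/CSV/JSON, which is asserted end-to-end. Model JSON embeds both scales
and the full catalog so prediction needs no side files, and floats
serialize via repr so scores round-trip bit-identically.

## Limitations

* Linear model, no regularization: with more features than informative
  windows the fit interpolates; self-consistency results are optimistic by
  design and are only used relative to CV.
* The α composition block is position-independent; a position-specific
  variant is not implemented.
* The operating threshold 0.5 is a convention; published-style Sn/P values
  depend on the (unknowable) operating point, so ROC/AUC is the primary
  comparison metric.
* No redundancy reduction, structure features, or per-residue score maps.
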