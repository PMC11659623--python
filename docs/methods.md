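# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## Problem setting

A *sample* is a complex odorant mixture characterized analytically by the
set of volatile molecules detected in it (with an optional relative peak
area per molecule as a concentration proxy) and sensorially by a panel of
assessors using rate-all-that-apply (RATA): each panelist rates the
intensity of at most five applicable descriptors from a fixed vocabulary
(17 descriptors in the study shape this package mirrors) on an integer
scale; unrated descriptors count as zero. Three prediction tasks are
supported: binary origin-type classification, top-5 descriptor
classification, and per-descriptor regression of summed panel scores.

## Labels

Consensus scores are the exact integer sums of panel ratings per (sample,
descriptor). A sample's label set is the five descriptors with the highest
consensus score. Ties across the fifth-place boundary are resolved by a
uniform draw without replacement among exactly the tied descriptors, from a
generator seeded by (seed, sample id) — descriptors strictly above the cut
are never at risk, and the same seed always reproduces the same labels.
Label selection is performed once per dataset, before any train/test
splitting, so every method sees identical targets.

Descriptors that end up in no label set are excluded from the
classification vocabulary (the regression task keeps the full vocabulary).
`remove_class` refuses to drop a descriptor that occurs in a computed label
set: silently mutilating labels is treated as an error, not a request.

## Substructural features

The feature space is built from a *reference pool* of molecules (the
package ships a 54-molecule synthetic stand-in of typical spirit volatiles:
esters, fatty acids, phenols, terpenoids, lactones; any user pool file can
be substituted). Every unordered pair is compared by maximum-common-
substructure search with atoms matched by element, bonds by bond order,
connected substructures only, ring matching relaxed, and the *atom count*
as the objective; each search is bounded to 1 s per pair with the best
result so far kept. Results below `min_atoms = 2` atoms are discarded
(single atoms carry no substructural signal) and duplicates are merged by
canonical SMARTS round-tripping. Output order is deterministic (atom count
descending, then SMARTS text), so pattern sets and matrices are
byte-reproducible.

The applicability of a pattern to a molecule is, in the default
`match_count` mode, the number of distinct substructure matches; in
`overlap_length` mode it is the pattern's atom count if the pattern matches
at all. Both modes are zero exactly when the pattern is absent. The
correctness anchor is an exhaustive oracle in the test suite: for random
small molecules, MCS atom counts are compared against enumeration of all
common connected subgraphs (subgraph monomorphism with element and
bond-order labels), and match counts against brute-force embedding
counting.

## OWSum

Let #(F_j, C_i) be the number of training samples of class i whose feature
set contains feature j, and len(C_i) the total feature count of class i.

* CP1(i, j) = #(F_j, C_i) / Σ_n #(F_j, C_n) — class given feature; columns
  sum to 1 per feature.
* CP2(i, j) = #(F_j, C_i) / len(C_i) — feature given class; rows sum to 1
  per class.
* tf-idf(i, j) = (#(F_j, C_i) / len(C_i)) · log10(|C| / #{classes
  containing F_j}). The log base is a global rescaling and cannot change
  any ranking; base 10 is fixed for reproducibility and configurable.

The influence value is weight × conditional probability (weight ≡ 1 in the
same-weighted variant). A sample's class score is the plain sum of
influence values over its present features; unknown test-time features
contribute 0, and no per-sample normalization is applied (a common positive
divisor cannot change an arg-max or a top-5). Ties in prediction are broken
by descending score then ascending class name.

For the descriptor task a presence rule accounts for class imbalance: a
standard scaler (mean/population-SD) is fitted on the fold's training
presence matrix, and a feature counts as present for a sample exactly when
its standardized value is positive. Zero-variance features are non-present
for everyone — a feature occurring in every training sample carries no
discriminating signal. The rule is off by default for the type task and
switchable per config.

Interpretability outputs: the influence difference value(a, j) − value(b, j)
ranks features driving class a over class b (antisymmetric by
construction); class dissimilarity is the sum of absolute influence
differences, reported together with the arc-width transform
1.1^(dissimilarity·1000) used for drawing dissimilarity diagrams.

## Class weights

Per cross-validation fold, descriptor weights for the classification loss
are w = 0 if the descriptor is absent from the fold's training labels, else
w = log(1 + y/x) with x the fold frequency and y a reference frequency
(natural log). By default the reference is the training fold itself, so all
fold-fitted quantities are functions of training data only and held-out
samples cannot leak into them; in leave-one-out the alternative
dataset-wide reference never differs from the fold count by more than one,
so the substantive content of the scheme — absent classes contribute
nothing, rare classes are not swamped — is unchanged. The dataset-wide
reference remains available via `class_weight_all="dataset"`.

## CNN

Input: per sample, the applicability rows of its detected molecules
(sorted by molecule id), optionally row-scaled by relative peak area
(default off — scaling is exposed as a flag, and the classification default
follows the unscaled variant), stacked per batch and zero-padded to a
common height with a mask of real-row counts.

Architecture (all configurable): conv 1→8 channels, 3×3, stride 2, ReLU;
conv 8→16, 3×3, stride 2, ReLU; adaptive max-pool to a 1×8 grid computed
*only over each sample's real rows*; fully connected 128→64, ReLU; linear
64→outputs. Design rationale:

* Strides of 2 keep full leave-one-out training fast on a single CPU.
* Pooling the molecule-row dimension globally (1×…) treats the rows as the
  unordered set they are: each pooled unit asks whether any detected
  molecule activates a learned applicability motif. A gridded row pooling
  (e.g. 4×4, also available via `pool_size`) instead ties features to
  arbitrary positions in the sorted molecule list and generalized markedly
  worse from 15 training samples in development experiments.
* Masked pooling plus the zero-padding convention makes predictions exactly
  invariant to extra zero rows (the model internally guarantees enough
  padded height that every real-influenced convolution output exists, so
  the invariance is an identity, not an approximation).

Training is full-batch Adam (default learning rate 1e-2), deterministic
given the seed: parameter init comes from one seeded generator and data
order is fixed, so loss curves are bitwise reproducible on CPU. The
classification loss is the mean over classes of w_c · BCE_c (w_c the fold
class weights; a zero-weight class contributes exactly nothing); regression
uses L1 by default (MSE available) on raw summed RATA scores. Epoch
defaults are 11 (classification) and 21 (regression), mirroring the
original training protocol; the synthetic benchmarks and the reproduction
script train for 150 epochs, the point past which the full-batch loss curve
has long flattened at desk scale.

## Baselines

* *Educated guessing*: the five most frequent descriptors of the training
  folds (frequencies double as ranking scores; rank-5 ties break
  lexicographically). Implemented in leave-one-out form; a global variant
  is a flag.
* *Subject X*: for each panelist, their per-sample top-5 is scored against
  the top-5 of the summed ratings of all other panelists; metrics are
  computed per panelist and averaged.
* *One-vs-rest SVM / random forest*: per descriptor and fold, a LinearSVC
  (max_iter 200, features standardized on the training rows only) or a
  100-tree random forest (seeded) over binary molecule-presence vectors;
  top-5 by decision score / positive-class probability. Single-class
  training labels yield a constant score with a warning rather than a
  crash.

## Metrics

Multi-label predictions are scored micro: F1, Matthews correlation and
ROCAUC are computed on the flattened (sample, class) matrix, i.e. from
pooled confusion counts — per-class metrics are meaningless at 16-sample
scale under heavy imbalance. ROCAUC uses the underlying score vectors
(OWSum class scores, CNN logits, SVM decision values, RF probabilities,
guess frequencies) and is reported as undefined, never zero, when the
flattened truth is single-class. Regression is scored by the Pearson
correlation of the flattened predicted and true matrices across all
held-out folds; constant inputs give NaN (undefined). Reports carry both
per-fold entries and the pooled aggregate; the pooled aggregate is the
headline number.

## Synthetic data

The generator emulates the study shape: 16 samples in two origin types
(9:7 split), a 240-molecule pool drawn per seed from a programmatic
vocabulary of homologous series plus named phenols/terpenoids/lactones,
100–200 detected molecules per sample, log-normal(0, 1) relative peak
areas (positive and right-skewed, like relative GC peak areas), 17
descriptors, 11 panelists, integer ratings capped at 10.

Planted structure:

* two *exclusive* molecules per type, present in every sample of that type
  and never in the other — origin classification is separable by
  construction and influence-difference signs have a known ground truth;
* three disjoint *driver* molecules per descriptor; a sample's latent
  intensity for a descriptor is 1 + 2·(drivers present), clipped to the
  rating scale — the simplest monotone structure a substructure-based
  learner can exploit;
* a third of descriptors are affine to each type: their drivers' inclusion
  odds are tilted (weights 4.0 vs 0.25 against a neutral 1.0), so
  descriptor profiles differ between types and an origin-aware model can
  beat global frequency guessing.

Panelists rate the latent top-5 (shared deterministic tie order) with ±1
integer jitter clipped to [1, 10]; with probability ε (`noise_rate`,
default 0.3) a rated descriptor is swapped for a uniformly drawn
currently-unrated one. The swap-based noise keeps ratings sparse integers
(additive Gaussian noise would not); at ε = 0 every panelist reproduces the
latent top-5 exactly and inter-panelist F1 is 1, at ε = 1 the rated set is
(near-)uniform so inter-panelist precision sits at chance, 5/17. The
default ε = 0.3 produces the qualitative ordering observed in real panels:
models > educated guessing > single-panelist agreement at full noise.

What passing tests on this generator do **not** show: real GC–MS data has
correlated detection errors, shared biosynthetic pathways between
molecules, odor-threshold effects (a trace compound can dominate an odor),
and panelist-specific vocabulary biases — none of which are modelled. The
synthetic benchmark demonstrates that each component recovers the structure
it is designed to recover, not field performance.

## Problem sizes and degenerate inputs

The packaged benchmarks run at study scale (16 samples) with a 12-molecule
reference pool for CNN featurization (≈ 14 patterns) — chosen so the full
LOO × 3-seed benchmark completes in minutes on one CPU while leaving the
qualitative model ordering intact. Degenerate inputs are defined, not
accidental: all-zero score vectors predict the k alphabetically first
classes with a warning flag; unknown features score 0; a pool pair with an
empty MCS is skipped; ROCAUC/PCC on degenerate truths are reported as
undefined.

## Known limitations

* The CNN is a minimal NumPy implementation: full-batch training only, no
  GPU, no mini-batching, no early stopping or hyperparameter search (a
  fixed-default config replaces automated search).
* MCS search is connected-substructure only; disconnected MCS is not
  supported by the underlying engine.
* Influence values are comparable between classes, not interpretable in
  absolute terms; molecule-level aroma attribution in mixtures remains
  confounded by thresholds and interactions.
* Regression of summed RATA scores at 16-sample scale yields modest Pearson
  correlations on synthetic data; the pipeline reports them honestly rather
  than tuning toward any particular value.
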