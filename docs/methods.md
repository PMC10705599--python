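# Methods notes

## Model and assumptions

The package scores a patient by two redundancy-penalized weighted means of
phi coefficients — one over sensitive-class features present in the
patient, one over resistant-class features — and classifies by the side of
a Youden-optimal line through the origin of the (resistant, sensitive)
score plane. The design assumes:

- the response is binary and both classes are represented in training;
- predictive signal is carried by *many correlated* binary features rather
  than a few strong ones, so averaging over all retained features buys
  robustness to per-feature call errors;
- co-occurrence measured on a large unlabeled background cohort is a
  usable proxy for the redundancy structure of features in the labeled
  cohort (the background need not be labeled, only representative).

Expression binarization is strictly rank-based and performed within each
cohort, never by transferring numeric thresholds; any strictly monotone
transform of a gene's values leaves the features unchanged, which is what
makes mixed RNA-seq/microarray use possible.

## Parameters

| parameter | default | meaning |
|---|---|---|
| level fractions | 0.60 … 0.05 (12 levels) | cohort fraction flagged per level; level 1 weakest, level 12 most stringent; level-1 features are dropped before selection |
| phi cutoff | 0.13 | minimum phi (per class) for a feature to be retained; comparison is ≥ |
| cluster height | 2.0 | tree-cut height for complete-linkage clustering of the similarity matrix |
| cluster metric | `profile` | dissimilarity = Euclidean distance between rows of K; `one_minus_k` (range [0,1]) is available |
| `loo_adjust` | on | leave-one-out weight recomputation for training score pairs |

The level fractions are a package choice (no canonical values exist): a
uniform grid from 60% down to 5% of the cohort, levels nested by
construction so that stringent levels are subsets of lenient ones. Counts
are `ceil(f_L · n)` with ties broken by sample identifier, making output
deterministic.

On the clustering dissimilarity: `1 − K` lies in [0, 1], where a cut at
height 2 could never split anything under complete linkage; the default
therefore clusters feature *similarity profiles* (rows of K) under
Euclidean distance, where exact duplicates are at distance 0 and a cut at
2 is meaningful. Note that profile distances grow with the number of
features (two unrelated features are at distance ≥ √2 from their own
coordinates alone), so the effective granularity of a fixed cut height
depends on the feature-set size; the height is exposed in configuration
for that reason. Sensitive- and resistant-class features are clustered and
penalized independently, since they enter separate scores.

Features absent from the background corpus keep an identity similarity row
(ε contribution from the self term only) and are logged, rather than being
dropped: missing background coverage should not silently delete evidence.

## Leave-one-out training scores

When fitting the D-line, each training subject's weights are recomputed
with that subject excluded, so its own label cannot inflate its score
pair; the frozen model always carries full-cohort weights for prediction.
A caveat discovered during development: the self-exclusion shift is
label-dependent (removing a responder lowers the phi of its own present
sensitive features; removing a non-responder raises them), with magnitude
of order 1/n per feature. When the planted/true effect is weak, this shift
can exceed the between-subject score spread, flattening or even inverting
the training score pairs — the fit then falls back to slope 1 with a
warning. Final-score *ranking* (hence AUROC) is unaffected, because
prediction uses full-cohort weights; only the placement of the decision
line degrades. The adjustment can be disabled via `loo_adjust: false`.

## D-line fitting

Candidate lines are the midpoints of consecutive sorted point angles plus
the extremes; the Youden index is piecewise constant between point angles,
so this search is exact. Points exactly on a candidate line, and patients
at the origin (no features), count as resistant-side — a conservative
convention, matching the prediction rule that a final score of exactly 0
maps to non-pCR. Ties in J are broken by the widest optimal angle
interval, then by the smaller slope. If J is identical across all
candidates (pathological, e.g. all score pairs equal), slope 1 is returned
with a warning and flagged in the model. The line passes through the
origin; an intercept was considered and deliberately not implemented —
with both scores non-negative and approximately scale-matched (both are
means of phi weights), a one-parameter family keeps the decision boundary
interpretable and the exact search trivial.

## What the redundancy penalty does — and does not — do

ε_i counts the effective multiplicity of feature i among the patient's
present features (restricted to i's cluster, so an accumulation of many
negligible overlaps cannot inflate it). Dividing by √ε_i *dampens* double
counting: m exact copies of a feature carry total weight √m in the score
rather than m. The cancellation is exact only when a patient's present
class features are all mutual duplicates (then the score equals their
common ω regardless of m); in mixed feature sets a duplicated feature
still gains influence at rate √m. This is a property of the square-root
penalty itself — an ε-linear penalty (weights 1/ε) would cancel exact
duplicates completely but shrink partially-overlapping features more
aggressively. The square-root form is retained as the method's defining
choice; the corresponding acceptance test of exact invariance documents
the deviation rather than papering over it.

## Synthetic data: what it emulates, what it does not

`generate_cohort` plants a transcriptional signature (log-normal
expression, mean shift of `effect_size` within-gene SDs on the log scale
in the responding class for sensitive-driving genes, in the non-responding
class for resistant-driving genes), sparse Bernoulli mutations with a few
response-linked mutation/AGR genes, and Bernoulli(pcr_rate) labels.
`generate_background` gives every feature a background sample set built
from a per-block core (blocks = contiguous gene groups), so within-block
Ochiai similarity is ≈ strength² + chance while between-block pairs sit at
the chance level `background_occurrence`; strength 1 makes within-block
sets identical.

Defaults (n = 200 subjects, 500 genes, 25 + 25 signature genes, effect
size 3, pCR rate 0.45, background of 1,000 samples, co-occurrence strength
0.8) represent a mid-sized neoadjuvant trial cohort with a strong
signature and a pan-cancer-scale background. Under these conditions the
planted signal is strong enough that held-out AUROC saturates near 1;
passing tests therefore demonstrate correct mechanics (signal recovery,
redundancy control, error tolerance), not the harder discrimination levels
attainable on real trials, where effects are weaker, labels noisier, and
batch structure real. The generator does not emulate batch effects,
library-size artifacts, subtype confounding, or realistic linkage between
mutations and expression.

## Numerical conventions

- Phi of a constant vector is undefined and reported as NaN, never 0;
  undefined features are excluded from selection with a log entry.
- Ochiai similarity of an empty background set is 0 off-diagonal and 1 on
  the diagonal by convention.
- All randomness is `numpy.random.default_rng` seeded explicitly; CLI
  artifacts carry no timestamps, so equal configurations reproduce files
  byte for byte. Model JSON round-trips floats exactly (shortest-repr).
- Evaluation splits are label-stratified so that small test sets always
  contain both classes.
- Simulated feature errors flip cells independently (false positives among
  zeros, false negatives among ones); a whole-feature corruption mode is
  available as an option.

## Known limitations

- The phi cutoff (0.13) admits a nontrivial chance rate of noise features
  at small n (≈ 3% per class at n = 200, more at smaller cohorts); the
  method relies on averaging, not multiple-testing control, by design.
- A fixed cluster-cut height interacts with feature-set size (see above).
- Scores are not calibrated probabilities; the final score is a distance,
  meaningful for ranking and thresholding at 0.
- Prediction requires feature-id overlap with the training representation;
  cohorts profiled on disjoint gene sets cannot be scored.
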