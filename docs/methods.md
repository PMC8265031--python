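# Methods

## The classifier and its value function

The diagnostic model is a k-nearest-neighbor classifier (k = 7) over a
labeled reference set of 26 serum samples (13 Good, 13 Poor), each
described by eight positive mass-spectral feature intensities.  Class
encoding is fixed at Poor = −1, Good = +1.  A reported clinical result
aggregates three technical replicates: unanimous replicates yield
Good/Poor, anything else Indeterminate.

Published descriptions of the test enumerate seven m/z positions (5843,
11445, 11529, 11759, 11903, 12452, 12579) while using eight features and
referring throughout their results to an 11685 (sometimes 11686) feature,
a C-terminally truncated serum amyloid A isoform.  The canonical feature
list here therefore includes 11685.  This is a documented reading of an
inconsistent source, not a silent fix.

The distance metric inside the original test is not public.  We use
Euclidean distance on log-transformed intensities (default), consistent
with the log-space standardization used for the surrogate models and with
the multiplicative character of spectral intensities; a raw-intensity
switch (`log_transform=False`) is provided.  Distance ties at the k-th
neighbor are broken by lowest reference-sample index via a stable sort;
ties have measure zero for continuous data, so this choice affects only
degenerate inputs.  Both k and the reference-set size are configurable so
small problems can be brute-force verified.

The value function of an instance is f(S) = classification of the 7NN
restricted to the coordinates in S, for every S ⊆ M, with f(∅) = 0
(uninformative).  A `SubsetValueTable` stores all 2^|M| values indexed by
bitmask; the documented canonical enumeration (export order) is by subset
size, then lexicographically by member tuple in canonical feature order.

## Exact Shapley values

`shapley_values` evaluates the coalition-weighted sum directly.  Weights
|S|!(|M|−|S|−1)!/|M|! are assembled from exact integer factorials with a
single final division; on ±1 games every intermediate product is an
integer below 2^53, so the result is exact to one rounding.  An
independent permutation oracle (average marginal contribution over all
|M|! orderings, refused above |M| = 10) cross-checks the weighted sum in
the tests.

Instance taxonomy: an exact attribution is *uniform* when all Shapley
values are equal (tolerance 1e−9, configurable), otherwise *boundary*
when the designated probe pair (default 11529/11685, the two dominant
features) have unequal values, otherwise *other*.  Uniformity is defined
by equality, not by the value 1/8, so the taxonomy generalizes to
|M| ≠ 8.  Replicate agreement is measured per feature by the
perpendicular distance |ψ_a − ψ_b|/√2 from the replicate-pair point to
the y = x line, histogrammed with counts normalized by
(#features × #samples).

## Interaction metrics

All four pairwise metrics are functions of the cached subset-value table,
so the classifier is evaluated exactly 2^|M| times per instance
regardless of how many metrics are requested.

* SII — coalition-weighted second difference with weight
  |S|!(|M|−|S|−2)!/(2(|M|−1)!).  We keep the pair-of-indices
  normalization; the subset-of-two convention found in some libraries is
  exactly twice this and is exposed as `pair_convention=False`.
* SII main effect — ψ_i minus the sum of i's off-diagonal SIIs.
* STII — the order-2 Shapley-Taylor index, weight 2|S|!(|M|−|S|−1)!/|M|!;
  its main effect is f({i}) − f(∅).  The Shapley-Taylor construction is
  efficient: Σ mains + Σ unordered pairs = f(M) − f(∅), verified against
  brute force on random tables (on a uniform-Good instance,
  8·(+1) + 28·(−1/4) = +1).
* Harsanyi dividend — f({i,j}) − f({i}) − f({j}) − 2f(∅), the pure pair
  synergy ignoring larger coalitions.
* Shapley partial sum (SPS) — the part of ψ_j contributed by coalitions
  already containing i, weight (|M|−|S|−2)!(|S|+1)!/|M|!.  Asymmetric by
  design; `shapley_split` returns both the with-i and without-i terms,
  which recompose ψ_j to 1e−12.

HD and SPS matrices leave the diagonal undefined (NaN, omitted from long
exports) rather than zero-filled, so "not defined" is distinguishable
from "computed as 0".  On a uniform instance the constants are
±1/8 (SV), ∓1/14 (SII), ∓1/4 (STII), ∓1 (HD), ±5/8 (SII main), ±1 (STII
main) and 0 (SPS); their signs look counter-intuitive because a binary
classifier's two-feature coalition can never beat two individually
correct single features — a known interpretability limit of these indices
for categorical outputs, and we do not invent a normalization to hide it.

## SHAP approximations

All three replace f(S) by a conditional expectation of the *full*
classifier given the in-S feature values, evaluated over the complete
256-subset lattice and plugged into the exact Shapley weighted sum (no
sampled-coalition weighting).  The empty-subset expectation is produced
by the same machinery — everything replaced or unconditioned — rather
than forced to 0; for a balanced, self-consistent reference set it is
close to 0, and the per-attribution value is stored so the deviation from
the exact convention is visible.  E[f(M)] is always computed without
sampling and equals f(M).

* Kernel SHAP: E[f(S)] is the mean full classification of the 26 hybrids
  formed by keeping the instance's in-S values and substituting each
  reference sample's out-of-S values.  Deterministic.
* Multivariate Gaussian: mean and covariance estimated from the 26
  reference samples in log space; the out-of-S conditional is the
  standard Gaussian conditional; N = 1000 Monte-Carlo draws per
  expectation (configurable).  The covariance receives diagonal shrinkage
  `shrinkage · trace/m` (default 1e−6) because 26 samples of 8 strongly
  correlated features are near-singular and conditional sampling needs a
  Cholesky factorization; shrinkage 0 raises with an instruction to
  regularize.
* Gaussian copula: per-feature empirical CDFs of log intensity
  (plotting positions i/(n+1), linear interpolation between order
  statistics, exponential tails with scales taken from the extreme
  spacings, a deterministic micro-offset to break ties) map features to
  Gaussian scores; the score-space correlation is estimated from the
  reference scores, conditioning happens in score space, and draws are
  mapped back by the inverse PIT before classification.

Monte-Carlo explainers refuse to run without an explicit seed; identical
seeds give identical attributions, and the attribution variance across
seeds scales as 1/N (verified at N ∈ {100, 1000}).

`compare_to_exact` reports mean-square differences against exact values
(overall and restricted to uniform instances) and lists symmetry-axiom
violations: feature pairs with identical subset behavior in the exact
game but unequal approximate values.

## LIME surrogates

Features are standardized in log space, z_i = (log x_i − median_i)/s_i
with s_i = IQR_i/1.35 (the IQR of a Gaussian is 1.35σ), medians and IQRs
from the pooled reference samples.  Permutations are drawn independently
per feature as z ~ N(0, 1) and back-transformed with *class-specific*
median/IQR parameters, n_per_class per class; inter-feature correlations
are deliberately ignored, mirroring the procedure being studied.  Each
permutation is classified by the full 7NN and discarded when its
classification disagrees with its source class; the kept fraction defines
the training set.  Weights are w = exp(−d²/σ²) with d the Euclidean
distance to the explained instance in pooled-standardized space and σ the
mean kept-permutation distance (logistic surrogate) or half of it (SVM),
recomputed per explained instance since d depends on the instance; a
`sigma_multiplier` exposes tighter/looser locality for boundary studies.

Surrogate hyperparameters are unspecified in the source procedure, so
regularization is minimal and documented: logistic regression with
negligible ridge (C = 1e8, i.e. penalty ~1e−8) for numerical
conditioning, and a linear-kernel SVM with hinge loss at unit cost
(C = 1).  Labels are Poor = 0/Good = 1 for the logistic fit and −1/+1 for
the SVM, so positive coefficients always push toward Good.  The
explanation is the coefficient vector on standardized features (for the
SVM, the normal vector of the decision plane); the intercept is stored as
the null-set term.  Desk-scale default is 1e4 permutations per class;
5e5 per class (1e6 total) is available through `n_per_class`.

## Synthetic cohorts

The clinical reference set and patient cohort are not publicly available,
so the generator emulates their documented structure: multivariate
log-normal features (Gaussian in log space), equicorrelated with
correlation 0.7 — inside the strong inter-feature correlation range
expected for serum-amyloid-A isoform panels — with per-feature log-SD 0.5
(~1.6-fold scatter) around a grand log-mean of 5 (arbitrary intensity
units).  Class centers sit `separation` apart along the all-features
diagonal, the direction of the dominant shared-amplitude variance
(within-class SD ≈ 1.2 at the defaults); the default separation 6.0
places each center ~2.5 of those SDs from the midpoint, giving
well-separated classes with occasional near-boundary samples (under
self-prediction a reference sample rarely lands on the wrong side).
Technical replicates add i.i.d. Gaussian log-space noise (default SD
0.05, ~5% multiplicative).  Every output is a deterministic function of
(spec, seed), and truth labels are emitted separately from the feature
tables so they cannot leak into pipelines.

Deterministic constructors produce the two instance types used
throughout: `make_uniform_instance` starts at the class centroid and
steps deeper until an exhaustive check confirms that all 255 non-empty
subsets classify identically; `make_boundary_instance` bisects the
log-space segment between a Good- and a Poor-classified point down to a
tolerance, returning a point on the decision surface.

What the generator does *not* emulate: the real features' marginal
shapes, heteroscedastic noise, batch effects, or a non-equicorrelated
correlation structure (a heavier-tailed margin switch, `tail_df`, exists
only for stress-testing margin-sensitive methods such as the copula).  Tests passing on these cohorts therefore
demonstrate correctness of the algorithms and their documented
invariants, not fidelity of any particular attribution pattern to real
clinical data; cohort-level rates and approximation errors reported for
the clinical cohort are not reproducible here and are out of scope.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: 26-sample
reference sets, cohorts of tens to a hundred instances, 1e4 LIME
permutations per class, N ∈ {100, 1000} Monte-Carlo draws, and
permutation-oracle checks up to |M| = 6 — sizes chosen so the full
analytic structure is exercised in seconds to minutes on one CPU.  Exact
identities (efficiency, decompositions, oracle equivalence) are asserted
at 1e−12; pattern-equality tolerances default to 1e−9 and are
config-exposed; Monte-Carlo assertions use seed-pinned runs with wide
bands around the 1/N law.
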