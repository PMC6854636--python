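# Methods

This note documents the statistical models, numerical choices and
limitations of `rfnet`. Notation: there are p = 11 nodes (10 resilience
factors, RFs, plus general distress, GD); groups are CA+ / CA− (exposed /
non-exposed to childhood adversity); occasions t1 / t2 are the early- and
later-adolescence assessments. All scores are oriented so that higher =
more protective, except GD where higher = more distressed.

## Ground-truth model and the synthetic cohort

Ground truth is parameterized directly on the partial-correlation scale.
For each group × occasion cell, a symmetric zero-diagonal matrix W of
true partial correlations defines the precision matrix K = I − W; its
inverse, standardized to unit diagonal, is the sampling correlation
matrix. This makes the quantity the estimators target (the partial
correlation) the quantity the generator controls, so recovery statements
are exact rather than approximate. User-supplied matrices whose implied
precision is not positive definite are repaired by proportional
rescaling of all off-diagonal weights until the smallest eigenvalue of
I − W reaches 0.05 — this preserves sparsity pattern and relative edge
strengths, and the repair is recorded on the returned object.

The default base network draws RF–RF edges independently with
probability 0.35 and weights U(0.1, 0.3) (all positive — protective
factors empirically reinforce each other), and gives each RF a negative
GD edge with probability 0.6 and magnitude U(0.1, 0.25). Two scenarios
are built in:

* **null** — all four cells share one matrix, all means zero. Used for
  type-I calibration; every rejection is a false positive.
* **adversity** — the CA+ t1 cell shrinks all positive edges by a
  factor 0.7 (the deficit the group comparison should detect); CA+ means
  are shifted −0.25 SD on RFs and +0.35 SD on GD at both occasions
  (mid-range of the standardized group differences such designs report);
  and both groups share small occasion effects (rumination −0.15,
  distress tolerance +0.15 at t2).

Occasions are coupled by a Gaussian copula: the joint 2p × 2p covariance
has the two cells' correlation matrices as diagonal blocks and cross
block D^½ M D^½ with M the average of the two marginals and D the
per-node autocorrelation (default 0.5 for every node — a free scenario
parameter; the within-subject score correlation is not something the
emulated design reports). If the assembled joint matrix is not PSD the
cross block is attenuated by bisection, leaving marginals exact.

Aggression and expressive suppression are binarized at latent cuts −0.8
and −0.4 respectively, chosen so the protective-class prevalences
(≈ 0.79 and ≈ 0.66 at zero mean) match the class sizes printed for such
scales; 1 = protective (low aggression / low suppression).

Items follow a graded model: an item with standardized loading λ has
propensity λf + √(1 − λ²)ε, and the category code counts the item's
thresholds below it. Default loadings are 0.7 ± 0.05, category counts
cycle through 3–6, and the two restricted-range scales get
rarely-endorsed, reverse-coded items (endorsement rates ≈ 8% and ≈ 34%)
so that any-endorsement binarization reproduces a realistic class split.

What the generator does *not* emulate: missingness (complete cases by
contract — imputation is out of scope), non-Gaussian latent tails,
time-series dynamics beyond two exchangeable occasions, and
differential item functioning between groups. Passing tests therefore
demonstrate correctness of the machinery under a Gaussian copula world,
not robustness to those real-data features.

## Measurement

Scoring is a deliberately transparent two-step chain rather than a full
weighted-least-squares categorical CFA: (1) thresholds from
inverse-normal cumulative marginal proportions; (2) pairwise polychoric
correlations maximizing the bivariate-normal multinomial likelihood with
thresholds fixed, by bounded 1-D search on ρ ∈ (−0.999, 0.999);
(3) a single-factor fit minimizing the squared off-diagonal residuals of
R − aaᵀ (unweighted least squares; Levenberg–Marquardt from the leading
eigenvector); (4) occasion-pooled loadings and thresholds
(sample-size-weighted means), the lightweight analogue of invariance
constraints that keeps factor scores comparable over time; (5) Thurstone
regression scores R⁻¹a applied to item codes standardized with
occasion-*pooled* means/SDs, so genuine mean-level change survives
scoring. Which factor-score estimator the reference software uses with
its WLSMV fits is not documented; regression scoring is the standard,
documented stand-in.

Numerical details: bivariate-normal rectangle probabilities are computed
by Gauss–Legendre integration (48 nodes per threshold interval) of the
conditional normal CDF, accurate well below 1e-7; cell probabilities are
floored at 1e-12 in the likelihood. Pairwise polychoric matrices that
are not positive definite are eigenvalue-clipped at 1e-4 and
re-standardized (iterated until the floor holds); the smoothing is
flagged. Heywood communalities are clamped at 0.998 and flagged, never
silently. A correlation matrix with no common variance returns zero
loadings flagged degenerate (any one-spike vector would be an equally
good ULS optimum, so the zero solution is reported explicitly).

## Network estimation

Networks are Gaussian graphical models estimated by graphical lasso on
the Pearson correlation matrix of the scores (binary nodes enter as 0/1;
a mixed polychoric/polyserial input is available as an option — how
binarized nodes entered estimation in the emulated design is not
stated). The solver is an in-package numba-compiled block coordinate
descent (lasso on each row/column of the working covariance), with
convergence declared when the duality gap tr(SK) − p + λ‖K‖₁,off —
computed from the *true inverse* of the working covariance, not the
coefficient-recovered precision — falls below 1e-6. A jitted kernel
exists because permutation and bootstrap suites re-estimate 11-node
networks millions of times; it is verified in the test suite against
scikit-learn's independent implementation, against direct inversion at
λ = 0, and against the two-variable soft-threshold closed form.

Penalty selection minimizes EBIC = −2ℓ + E log n + 4γE log p with
ℓ = (n/2)(log det K − tr(SK)) (constants dropped — they cannot move the
arg-min), E the number of off-diagonal precision entries above 1e-8, and
γ = 0.5, over 100 log-spaced penalties from λ_max (the largest absolute
off-diagonal correlation, which yields an empty network) down to
λ_max/100, warm-started in descending order. Ties break toward the
sparser model. These defaults (γ, grid size, min-ratio) mirror the
established EBIC-glasso methodology; the emulated design states neither.
Partial correlations are w_ij = −K_ij/√(K_ii K_jj) with sub-1e-8 values
snapped to exact zeros.

Expected influence is the *signed* sum of edge weights (per node, or
globally over a node subset; global default is all 11 nodes, with an
option to restrict to the 10 RFs — whether published global-EI values
include GD-incident edges is not stated, so both are exposed). The
"signed sum" reading follows the expected-influence literature; an
absolute-sum reading exists but is not implemented as the default.

## Permutation comparison tests

Observed statistics come from networks estimated per dataset; the null
re-estimates both networks after relabeling with the *identical*
estimator configuration. Independent design: subjects pooled, group
labels permuted preserving group sizes. Paired design: each subject's
two occasion rows are swapped independently with probability ½ —
valid when the joint distribution is exchangeable over time, which the
generator's copula satisfies under the null. p-values use the add-one
rule (1 + #{|s*| ≥ |s_obs|})/(K + 1), two-tailed on the statistic
magnitude (for M, a maximum of absolute differences, the one-sided rule
on the magnitude coincides with this), so p ∈ [1/(K+1), 1] and never 0.
Per-edge differences get raw permutation p-values plus
Benjamini–Hochberg adjusted ones (reported side by side; whether the
emulated analyses adjusted edge-level tests is not documented, so both
are available). Estimation failures in permutations are tolerated up to
1% of K (the effective K shrinks accordingly); more aborts the test with
diagnostics. The default K is 5000; calibration suites use K = 200, a
pure compute scaling that leaves the test's validity untouched.

## Pathways

DP is the signed sum of the direct RF–GD weights; more negative =
stronger direct distress-dampening association. SP converts weights to
lengths ℓ = 1/|w| (−log|w| available behind a flag; the sign of the
traversed edges is reported alongside but does not enter the length),
runs Dijkstra from the GD node (undirected, so one single-source run
covers all RFs), and sums the per-RF shortest-path lengths; lower =
stronger routes. Ties break toward fewer hops, then the
lexicographically smallest node sequence, making reported paths
deterministic. Each RF's optimal route is classified direct (the single
edge), indirect, or none. Unreachable RFs contribute a penalty of twice
the largest finite shortest-path length — computed jointly across the
two networks in any comparison so the SP difference is well defined on
disconnected permuted networks — and the penalty used is recorded.
Published SP magnitudes depend on a transform and penalty convention
never stated; they are treated as non-reproducible descriptives, and the
package's SP values are interpreted only relative to each other.

## Robustness

Edge accuracy: nonparametric case resampling (default B = 2000),
percentile intervals per edge. Because the lasso biases edges toward
zero, these intervals describe sampling variability of the *penalized*
estimator; coverage of the true weight is approximate and slightly
anti-conservative for strong edges. Stability: for each drop proportion
in a 15-point grid (0.05–0.75), B subsamples without replacement are
re-estimated and the Spearman correlation between subset and full-sample
node-EI vectors computed (rank-based, hence invariant to monotone
rescaling; a degenerate constant EI vector counts as correlation 0). The
CS coefficient is the largest drop proportion — required to hold
cumulatively from the smallest drop up — at which that correlation
reaches 0.7 with 95% probability; 0 if even the smallest drop fails.
One-step (direct-neighbor) EI is used throughout.

## Group statistics

Rank tests follow the R conventions: rank-sum reports the first sample's
Mann–Whitney U with a tie-corrected, continuity-corrected normal
approximation (exact enumeration available; scipy's implementation backs
both), a Hodges–Lehmann estimate, and a Moses interval from the ordered
pairwise differences. Signed-rank drops zero differences, uses midranks,
and reports V = the positive-rank sum with the same correction scheme;
the exact mode enumerates the permutation distribution by dynamic
programming over doubled ranks (so midranks stay integral). The 2×2
chi-square applies the Yates correction with the deviation floored at
|O − E| — the convention that reproduces the published table statistics
exactly, although those tables cite the uncorrected test by name.
Cochran–Armitage uses the linear-by-linear statistic with hypergeometric
variance. Moderation fits score ~ occasion + group + occasion × group by
OLS (logistic link for binary outcomes, reporting the interaction odds
ratio) with subject-clustered robust standard errors by default — each
subject contributes both occasions, and how the emulated analyses
handled that dependence is not stated; naive errors are available behind
a flag. Interaction coefficients beyond ±15 on the logit scale are
flagged as possible separation.

## Problem sizes and calibration suites

The validation module fixes the study conditions used by the test suite
and the reproduction script: type-I error from 200 replicates of the
null scenario at 300 subjects/group with K = 200 permutations (both
designs; statistics M, ΔEI, ΔDP, ΔSP); power from 100 replicates of the
adversity scenario at 500/group; edge-sign recovery at 5000/group;
factor-score recovery at 2000 subjects with loadings 0.7; threshold
recovery at 10000 observations; stability extremes at n = 10000 with
B = 200. Monte-Carlo permutation suites use a 25-point penalty grid
(the full 100-point grid is the estimation default) — grid size is a
compute choice that applies identically to observed and permuted data,
so it cannot bias the permutation null.

## Known limitations

* The measurement chain is a principled simplification, not a WLSMV
  categorical CFA; fit statistics (χ², CFI, RMSEA) and formal invariance
  tests are out of scope.
* Complete cases only; panels with missing cells are rejected at the I/O
  layer.
* The glasso solver and EBIC machinery assume p small relative to n (the
  intended regime is p = 11, n in the hundreds); no block/screening
  optimizations for large p.
* Permutation p-values inherit the resolution 1/(K+1); with K = 200 the
  smallest attainable p is ≈ 0.005.
* Undirected models: pathway signs and "GD-corrected" edges cannot
  distinguish confounding from collider structure.
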