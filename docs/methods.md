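# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic-data tests do and do not establish.

## Shape model and superimposition

Specimens are 2D landmark configurations, k ordered points per face. The
pipeline follows the standard geometric-morphometric chain:

1. **Symmetrization.** Faces are treated as objects with bilateral
   symmetry. A configuration is mirrored across the vertical axis, its
   left/right homologous landmarks are swapped according to the schema's
   pair map, the relabelled reflection is rigidly aligned (rotation +
   translation, reflections excluded) to the original, and the two are
   averaged. The output is exactly invariant under the same
   reflect-relabel operation, which makes the procedure idempotent — a
   property the tests verify to 1e-10.
2. **Generalized Procrustes Analysis.** All configurations are centered
   and scaled to unit centroid size; each is rotated to the current
   consensus by the closed-form 2×2 solution (SVD of the
   cross-covariance, determinant constrained to +1); the consensus is
   re-estimated as the mean shape, re-normalized to unit centroid size,
   and the loop repeats until the root-mean-square consensus change
   drops below `tol` (default 1e-10, `max_iter` 100). The GPA fixed
   point is unique only up to a global rotation; all downstream
   statistics (distances, projections) are invariant to that rotation.
3. **Tangent projection.** Aligned coordinates are orthogonally
   projected onto the tangent plane at the consensus, `x ↦ x − (x·c −
   1)c` for the unit-size consensus `c`. In this space Euclidean and
   Procrustes distances agree to high order for small variation (the
   tests require 1% agreement below distance 0.1), and the Pythagorean
   decomposition used by the score identities is exact.
4. **Semilandmark sliding.** Curve interiors ("semilandmarks") carry no
   pointwise homology. Each may move along its local tangent — the chord
   through its flanking curve neighbours — and the vector of slide
   offsets minimizes the thin-plate-spline bending energy of the
   deformation from the consensus to the specimen. Because the bending
   energy is a positive-semidefinite quadratic form (affine deformations
   in its null space), the constrained minimum has a closed-form linear
   solution. Sliding and re-superimposition alternate for `max_cycles`
   (default 5); a cycle that fails to decrease the total energy is
   rolled back, so the returned energy trace is non-increasing by
   construction. Semilandmarks whose neighbours coincide are frozen with
   a warning.

The thin-plate-spline kernel is U(r) = r² log r² with U(0) = 0; the
bending-energy matrix is the upper-left k×k block of the inverse of the
bordered system [[K, Q], [Q', 0]], Q = [1 | x | y]. Coincident reference
landmarks raise a singular-kernel error. The same interpolant draws
deformation grids between mean shapes; the conventional three-fold
magnification of the mean difference is the default.

## Typicality scores

Let m_A and m_B be the two group mean shapes in tangent space,
Δ = m_B − m_A, PDM = ‖Δ‖ and u = Δ/PDM. For a specimen x (flattened):

- **CTDM** (cross-group typicality/distinctiveness): the signed
  projection (x − o)·u with origin o = (m_A + m_B)/2. This is the
  two-group between-group principal component. The means score exactly
  −PDM/2 and +PDM/2. Positive scores lie toward the second-named group;
  orientation is always an explicit argument because the two directions
  are equally natural. The midpoint origin (rather than the pooled
  specimen mean) makes the endpoint property exact for unequal group
  sizes; with balanced groups the two coincide, and the pooled origin is
  available as an option.
- **DfOM / DfIM**: the specimen's distance from the outgroup / its own
  group mean — tangent-space Euclidean by default, true partial
  Procrustes distance as an option. DfOM discards the direction of the
  deviation; CTDM keeps it, which is exactly why it tracks perceptual
  typicality ratings more closely in the simulated studies.

Composite anchors: within each group the minimum, mean and maximum of
the signed scores define three positions (farthest from the other group,
average, closest), six categories across both groups; for each anchor
the k = 6 group members nearest in score are averaged into a composite
shape. Ties in |score − anchor| break lexicographically on specimen id.

## Resampling inference

- **Kendall's tau** is tau-b (tie-corrected) throughout: per-face mean
  ratings retain ties even after averaging.
- **CI for tau**: case resampling — faces are drawn with replacement
  keeping (score, rating) pairs intact — with 2.5/97.5 percentile
  bounds over B = 10,000 replicates by default. Degenerate (constant)
  resamples are skipped and counted.
- **Difference between two dependent correlations** sharing the rating
  vector: the two score vectors stay fixed, preserving their mutual
  dependence, while ratings are resampled i.i.d. with replacement under
  the null; the statistic is τ(ctdm, r*) − τ(dfom, r*) and the p-value
  is two-sided with the add-one convention, so it is never exactly
  zero. A label-permutation null is available as an option; the two
  differ only in the tie composition of the resampled ratings.
- **Mean-shape test**: observed statistic is the tangent-space distance
  between group means; group labels are permuted preserving group
  sizes. Ties count against rejection (≥ convention). The group pair is
  canonicalized internally so the p-value does not depend on argument
  order.
- **Morphological disparity**: MD(g) = Σ‖x_i − x̄_g‖²/n_g (divisor n by
  convention, n−1 optional); for two groups the permutation statistic
  is |MD difference|, 9,999 permutations by default.
- **Cronbach's alpha** uses raters as items and faces as cases,
  α = k/(k−1)(1 − Σ item variances / variance of sums), computed from
  pairwise-complete covariances when raters saw random face subsets
  (flagged with a warning).

All resampling takes an explicit integer seed, records it in the result
object, and is bit-reproducible.

## 2AFC statistics

Trials pair one composite from each group; pair types are "i_j" with
i ∈ {1,2,3} (first group: farthest/average/closest) and j ∈ {4,5,6}
(second group: closest/average/farthest). Participants who spent at
most one month in the home culture (age in months minus months abroad)
are excluded; missing values retain the participant with a flag. The
left/right counterbalance check reports per-pair accuracy differences.
One-proportion z-tests against chance use the null variance
p₀(1−p₀)/n without continuity correction; Cochran's Q is the omnibus
test over the nine pair types (undefined when every participant row is
constant); the six planned comparisons (1_X and 2_X against 3_X, X ∈
{4,5,6}) use asymptotic McNemar tests, χ² = (b−c)²/(b+c), uncorrected
by default with the continuity-corrected variant as an option, and
Hochberg step-up adjustment with the comparisons within one face gender
as the family. Participants missing a trial are dropped per comparison.

## Synthetic data: what it emulates and what it does not

The generator produces two groups whose mean shapes differ by delta
along a single random direction u, with isotropic within-group noise.
Both u and the noise live in the subspace of tangent perturbations at
the base shape that are (a) symmetric under reflected relabelling and
(b) orthogonal to translation, rotation and scaling. Placing the truth
in this subspace means symmetrization and superimposition recover
generative parameters without attenuation — parameter-recovery tests
can then assert tight tolerances (1% on the separation in the
noise-free limit) instead of loose qualitative ones. Configurations are
handed to the pipeline under random rotations, translations and scales.

Defaults (the study conditions the package targets): 20-landmark
face-like template with two mirror-image sliding curves, n = 50 per
group, delta = 0.018, group disparities 0.0019 and 0.0015 (ingroup more
variable), ratings 3 + 34·axis + N(0, 0.62) clipped to [1, 5] — chosen
so the rank correlation between score and rating is ≈ 0.4 — and 2AFC
accuracy logistic(1.16 + 37·|score gap|), which spans roughly 0.85–0.96
across the nine pairings. The perturbation-basis dimension of the
default template is 18, so a target disparity MD maps to a per-dimension
noise sd of √(MD/18) (`noise_sd_for_disparity`).

Features of real face data the generator does **not** emulate:
anisotropic covariance concentrated in a few principal components,
allometry, digitization error correlated along curves, rater-level
(non-exchangeable) rating structure, and pixel-level appearance.
Passing tests therefore demonstrate correctness and calibration of the
algorithms under a known truth, not the empirical effect sizes of any
particular population comparison. One consequence worth noting: with
isotropic high-dimensional noise the outgroup-distance score carries
less rating signal than it does in real data, where variance
concentrates along a few axes; the qualitative ordering (axis
projection beats outgroup distance) is unaffected.

A second consequence: minimum-bending-energy sliding repositions
along-curve variation and, on this synthetic geometry, enlarges the
estimated between-mean separation by roughly 20% relative to the
generative (unslid) value. The generator's disparity/separation
calibration therefore refers to the symmetrize+GPA chain; the
acceptance script reports the slid separation separately.

## Problem sizes in tests and the acceptance script

Simulation-based checks use n = 50 per group (the study condition) with
200 replicates for power/win-rate properties, 500 replicates for the
mean-shape type-I rate, and 200 for the difference-test type-I rate;
bootstrap tests inside replicate loops run at B = 1,000 (the defaults
remain 10,000 for single analyses). The acceptance script runs one full
study at default size plus 100-replicate rates, completing in well
under a minute; the full test suite takes about five minutes.
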