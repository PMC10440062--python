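# Methods

## Superimposition

Shapes are 2D landmark configurations. Centroid size is
`CS = sqrt(Σ_i ||x_i − x̄||²)`; it is the size variable throughout and
is retained in the original units (mm when a digitising scale is
applied) for allometric analyses.

Generalised Procrustes analysis uses the *partial* Procrustes
convention: every configuration is centred and scaled to unit centroid
size once, then iteratively rotated onto the evolving consensus.
Rotations are proper (determinant +1); reflections are never allowed
because all specimens are photographed from the same side. The 2D
optimal rotation is computed in closed form from
`atan2(Σ cross(x_i, y_i), Σ dot(x_i, y_i))`.

**Sliding semi-landmarks.** A semi-landmark slides along the unit chord
between its two neighbouring landmarks *of the current specimen*, by
the scalar projection of its offset from the consensus onto that chord
(the minimum Procrustes distance criterion). Each sliding pass is
followed by re-centring, re-scaling and re-rotation. Sliding is applied
only during the first `slide_iterations` (default 5) GPA iterations:
chord sliding has a nearly neutral collective mode — all semi-landmarks
migrating together along the outline — along which the objective keeps
creeping downward indefinitely (measured at ~4e-6 SS per iteration on
typical data, with no fixed point within hundreds of iterations), so
iterating it to numerical convergence is ill-posed. Freezing the
semi-landmarks after a few passes, as the established superimposition
tools do with their small sliding-iteration caps, leaves a plain
rotation/averaging iteration that reaches the consensus-change
tolerance of 1e-10 in a handful of steps (cap 100; a non-converged fit
is returned with `converged=False` and a warning).

**Consensus and frame conventions.** The consensus is the coordinate-
wise mean of the aligned configurations with a single common rescale
applied to consensus and aligned jointly, so that *both* invariants
hold exactly: the consensus has unit centroid size and the mean of the
aligned coordinates equals the consensus. The output frame is made
canonical by rotating the consensus principal axis onto x with a
deterministic sign rule (the landmark farthest from the centroid gets
negative x). This makes GPA output invariant — to rounding — under
arbitrary per-specimen similarity transforms of the input, including
the orientation of the configuration that seeds the iteration.

**Unbending.** Live fish arch their bodies; the correction uses
landmarks that lie on a naturally straight axis (the scheme stores
them; in the salmonid scheme, landmarks 1-21-22-17 on the lateral
line). Per configuration: rotate so the chord through the first and
last reference landmarks is horizontal, least-squares fit a polynomial
(default quadratic) through the reference landmarks with abscissae
normalised by the chord length for conditioning, subtract the fitted
curve from every landmark's ordinate, rotate back. Reference landmarks
become collinear up to the fit residual, and an already-straight
configuration is returned unchanged in any orientation. The y-only
quadratic correction is one of several plausible conventions for this
operation and is labelled as such; degree and reference landmarks are
parameters.

**Outliers.** Procrustes distance of every aligned configuration to the
consensus, flagging those above `Q3 + k·IQR` (default k = 1.5). The
pipeline, mirroring standard practice when several operators digitise
the same photographs, removes the union of per-operator flags from all
operators' datasets (a switch disables the propagation). The flag count
is reported, never assumed.

## Statistics

**PCA / between-group PCA.** PCA drops components with eigenvalue below
1e-10 of the largest. Note that superimposition removes translation
*linearly* (rank ≤ 2k−2) but scale and rotation only nonlinearly, so
two further dimensions carry tiny-but-nonzero variance; routines that
need an invertible covariance handle this by rank reduction rather than
assuming 2k−4. bgPCA axes are the principal components of the (g)
group-mean shapes centred on their grand mean, giving at most g−1 axes;
individuals are projected onto them. Leave-one-out classification
re-estimates group means *and* axes per fold (the stricter reading) and
assigns the held-out specimen to the nearest projected group mean, ties
to the first label in sorted order.

**Procrustes ANOVA with RRPP.** The response is the (N × 2k′) matrix of
superimposed coordinates; sums of squares are sequential (type-I) and
multivariate (traces — summed squared Procrustes distances). Terms are
orthonormalised incrementally, so each term's SS is `||U_jᵀ Y||²` with
U_j the basis increment; `F = (SS_j/df_j)/(SS_res/df_res)`. For each
term, RRPP permutes the residuals of the reduced model (all preceding
terms) over specimens — because the term basis is orthogonal to the
reduced fit, only the permuted residual matrix enters the permuted
statistic, which makes 999–10 000 permutations cheap. One permutation
schedule is shared by all terms.
`p = (1 + #{F* ≥ F_obs}) / (n_perm + 1)`; the effect size
`Z = (log F_obs − mean log F*) / sd log F*` over the permuted
distribution. Empirical type-I error at α = 0.05 under a null is
measured at 0.044–0.047 (1000 simulated datasets, 999 permutations).

**Allometry adjustment.** Shape is regressed on log centroid size plus
the group factor; the adjusted data are the residuals plus the model
prediction at the grand-mean size for each row's group. The group
component is restored deliberately: the subsequent between-group test
must see the group signal, only the size effect is removed. With a zero
fitted slope the data pass through unchanged.

**Paired Hotelling T².** Operators (or trials) are compared on the PC
scores of the pooled superimposed data, paired by specimen. The paired
differences are reduced to the dimensions in which they actually vary
(difference-covariance eigenvalues above 1e-10 of the largest, at most
N−1), then `T² = N d̄ᵀ S⁻¹ d̄`, `F = T² (N−p)/(p (N−1)) ~ F(p, N−p)`.
At the rank ceiling p = N−1 the test is valid but conservative (part of
d̄ can fall outside the retained subspace), which is the regime of the
20-fish replicate subset; under a proper null with p < N the p-values
are uniform (KS-checked in the suite).

**Angle test.** The angle between two shape-change vectors in p
dimensions is compared with the null of two independent uniform
directions, whose angle density is ∝ sin^(p−2)θ. The CDF is evaluated
via the regularised incomplete beta function
(`P(Θ ≤ θ) = ½ I_{sin²θ}((p−1)/2, ½)` for θ ≤ 90°), so orthogonality
gives p = 0.5 exactly. Small p means "more aligned than chance".

**Bootstrap group distance.** Resample with replacement within each of
the two groups (sizes preserved), statistic = Euclidean distance
between resampled group mean shapes; mean, median and percentile 95 %
CI over n_boot (default 1000; the pipeline's fast profile uses 500).
Note the statistic is nonnegative-biased under the null.

**Repeatability (ICC).** One-way Procrustes ANOVA with individual as
the factor on a balanced design of m replicates:
`s²_A = (MS_among − MS_within)/m`, `R = s²_A/(s²_A + MS_within)`.
Identical replicates give R = 1 exactly (an MS_within below 1e-13 of
MS_among is treated as the identical-replicates case to absorb
rounding). The SS fraction (r²) of the individual term is reported
alongside.

**Nested variance partition.** Balanced complete crossing of
individuals × operators (× trials): sequential SS for individual,
operator-within-individual, and residual; fractions of total SS sum to
one. Fractions are the "variance explained" percentages quoted for the
replicate subset.

## Synthetic study design

The generator reproduces the structure of a two-river, four-operator
digitisation experiment on live salmonids. All shape-space magnitudes
are in template units (template centroid size 1).

| parameter | default | rationale |
|---|---|---|
| n per group | Spey 144 / Oykel 147 | the study's design size |
| operators | 4 | ditto |
| replicate subset | 10 fish per river × 3 trials | ditto |
| group effect ‖δ‖ | 0.0052 | centres river r² at ≈ 0.035 (see below) |
| individual variation | 5 orthonormal modes, SDs 0.010…0.0035 (total var ≈ 2.3e-4) | low-rank, PCA-like structure; sets total SS ≈ 0.05–0.07 at N ≈ 289 |
| operator bias ‖b‖ | 0.010 per operator, landmarks 1–12 only | head landmarks are the ambiguous ones; pairwise operator mean distances ≈ √2‖b‖ ≈ 0.010–0.016 |
| trial noise SD | 7e-4 per landmark (×2 tangentially at semis) | repeatability ≈ 0.93 and trial mean distances ≈ 2σ ≈ 0.0014; the tangential excess exercises sliding |
| allometry | 0.022 per unit log CS, log CS ~ U(log 110, log 160) mm | allometry r² ≈ 0.025–0.03 |
| arching | quadratic coefficient ~ U(−0.15, 0.15), centred on the reference chord | visible bends of a few % body depth; makes unbending necessary |
| embedding | per-photo rotation U(−π, π), translation, scale = CS in mm | one photo per fish, shared by operators and trials |

Calibration reasoning (one pass, at the design sample size): with
within-group variance V ≈ 2.6e-4 and n ≈ 145 per river, the sampling
noise of the estimated mean difference has norm ≈ √(2V·2/n) ≈ 0.0016,
so per-realisation river r² scatters with SD ≈ 0.009 around its mean;
‖δ‖ = 0.0052 puts the mean at ≈ 0.035. That scatter is a property of
the n = 289 design (it is invariant to rescaling all variances once the
mean r² is fixed), so individual realisations can land anywhere in
roughly 0.02–0.06 — exactly as a repeated real study would.

Structural choices: operator bias is a *fixed* field per operator —
that is what makes the error systematic rather than noise. The
between-river direction is built partly inside the individual-variation
subspace (weights 0.5 and 0.4 on the first two modes, remainder along a
deterministic "deeper body, pointed snout, larger eye" contrast),
because real population contrasts are not orthogonal to within-
population variation; this keeps bgPCA river classification at a
realistic ~65–75 % rather than near-perfect. Individual variation,
group, and allometric fields keep the unbending reference landmarks
collinear (biological variation moves fish along the lateral-line axis
but does not bend it — the premise of unbending); digitising error may
displace them.

What the generator does **not** emulate: photographer/parallax
variation between images, landmark-specific (anisotropic) digitising
error at fixed landmarks, operator learning across trials, and any
non-quadratic body deformation. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated error
model, not the magnitude of any of these unmodelled effects in real
photographs.

## Pipeline

Order of operations: unbend → drop excluded landmarks → per-operator
GPA and outlier union removal → Test 1 (pooled GPA, PCA scores,
pairwise operator T², between-operator bgPCA/LOO) → Test 2
(per-operator GPA, size ANOVA, allometry adjustment, river ANOVA and
bgPCA/LOO) → Test 3 (pairwise angles of river bwgPC1 directions, river-
vs-operator-difference angles, bootstrap river distances) → Test 4
(cross-merged datasets of the two operators with the greatest mean-
shape distance, same river analyses, angle comparisons) → Test 5
(per-operator trial T², repeatability, pooled nested partition).

All randomness is seeded: the run configuration carries one master
seed, and every consumer (each ANOVA, each bootstrap) derives a child
seed from it via `SeedSequence(master, spawn_key=(crc32(label),))`, so
reports are byte-identical across runs and the seeds used are echoed in
the report. Profiles: `fast` (999 permutations / 500 bootstrap, suited
to test suites) and `paper` (10 000 / 10 000).

Problem sizes used by the shipped checks: the suite and the acceptance
script run the full-design pipeline (291 fish × 4 operators) — a
single assessment takes a few seconds — with 999-permutation ANOVAs;
calibration checks use 1000 null datasets (type-I), 1e5 Monte-Carlo
direction pairs (angle null), and 500 paired-null simulations (T²).

## Known limitations

- Chord-tangent sliding only; bending-energy sliding is not
  implemented.
- No tangent-space projection before statistics: shape variation in
  this regime is ~1e-2, making the curvature correction numerically
  negligible; statistics operate on Procrustes coordinates directly.
- The exact unbending algorithm of the original desktop tools is
  undocumented; the quadratic y-only convention here is a reasonable
  reconstruction, not a re-implementation.
- 2D only; no missing-landmark estimation.
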