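# Methods

This note records the statistical model, the algorithmic choices made where
the design was genuinely open, the defaults and their units, and what the
synthetic data does and does not emulate.

## Superimposition and shape space

`morpho.gpa` implements full generalized Procrustes analysis: every
configuration is centered, scaled to unit centroid size, and rotated to the
running consensus by orthogonal Procrustes (reflections excluded); the
consensus is the renormalised mean, iterated until its RMS change falls
below `tol` (default 1e-10, max 100 iterations). Procrustes coordinates are
analysed directly — no tangent-space projection — which is appropriate in
the small-variation regime these crosses live in (per-coordinate shape
standard deviations of order 1e-3–1e-2 on unit-size configurations).
Landmark-only and semilandmark datasets get separate superimpositions.

Two consequences worth knowing:

- Centering and unit size are exact constraints, so the aligned data have
  rank at most kd − d − 1; the d(d−1)/2 rotational dimensions are removed
  only to first order and survive as eigenvalues ~1e-4 of the leading one.
  `pca_reduce` retains the smallest leading set of components reaching
  `variance_fraction` (default 0.95), which drops them in practice.
- The consensus frame is an arbitrary rotation of any external frame.
  Quantities that live in coordinate space (effect vectors, G matrices)
  must be compared after aligning frames; `morpho.gpa._optimal_rotation`
  against the mean shape does this.

## Thin-plate splines and semilandmarks

`tps_fit` solves the standard interpolating system with kernel
U(r) = r² log r in 2D and U(r) = −r in 3D. The 3D sign is chosen so the
kernel is conditionally positive definite on the complement of the affine
subspace; bending energies and the bending-energy matrix L_b (upper-left
block of the inverse system) are then nonnegative without correction. L_b
is symmetrised, annihilates affine displacements, and reproduces the
fitted spline's energy as Σ_dim y' L_b y.

Semilandmark templates are built by greedy dart-throwing on area-uniform
surface samples (minimum pairwise distance `radius`; when a `target_count`
is requested the radius is tuned multiplicatively until the count is within
15%). Templates transfer to new specimens by a TPS anchored on the fixed
landmarks, followed by exact nearest-point projection onto the target
triangulation (vectorised vertex/edge/face classification; exhaustive over
triangles, hence exact). Sliding minimises the bending energy of the
reference-to-target spline over tangent-plane displacements of the
semilandmarks — the closed-form generalized least squares with the basis
matrix of per-point tangent pairs — then re-projects onto the surface;
3 iterations by default. Tangent planes come from the nearest face normal,
with a local-PCA fallback for degenerate normals. The pre-projection energy
is non-increasing by construction; projection can perturb it at second
order. Fixed landmarks never move.

## Simulated 2D flattening

Each specimen is aligned to its principal axes (eigenvectors of its
landmark covariance, descending variance, largest component of each axis
positive), a plane is defined by three anchor landmarks, and all landmarks
are projected along the plane normal. When a surface mesh is supplied, the
first two anchors are refined iteratively to the innermost mesh vertex
along the current normal (candidates within a cylinder of 0.15x the
configuration extent), mimicking how a flat-laid bone actually rests. The
2D basis is the principal axes of the projected configuration with the
first axis sign-fixed and the second chosen right-handed with respect to
the plane normal. Orientation choices matter: the normal is taken toward
+z of the principal-axis frame so that similar specimens always flatten
with the same handedness — without this, mirror-flipped specimens form
artificial clusters that swallow the shape variance. A planar 3D shape and
its mirror are the same 3D object, so losslessness of flattening is only
testable after re-embedding the 2D result at z = 0.

## Measurement-error ANOVA

Two digitization sessions are superimposed jointly. The session effect is
tested against the specimen-by-session interaction with degrees of freedom
multiplied by the shape-space dimension m = kd − d − d(d−1)/2 − 1
(F on (m, (n−1)m) df). Percent measurement error uses one-way variance
components with sessions as replicates: s²_w = MS_within,
s²_b = (MS_among − MS_within)/2, %ME = 100 s²_w/(s²_w + s²_b), overall and
per landmark (per-landmark sums of squared coordinates). Other %ME
definitions exist; this within/total variance-component ratio is the
conventional one for digitization studies.

## Genotype probabilities

A two-state (homozygote/heterozygote) hidden Markov model per chromosome:
transition probabilities from the Haldane map function
r = (1 − e^(−2d/100))/2 between adjacent grid positions (no interference),
emission correct with probability 1 − `error_prob` at typed markers
(default 0.001), uniform at missing genotypes and pseudomarkers. The grid
is the union of markers and an equally spaced fill at `step` cM (default 1;
0 = markers only). Forward–backward posteriors are exact; the test suite
checks them against exhaustive enumeration of all genotype paths. The
expected heterozygote dosage at a grid position is the single regressor a
backcross QTL contributes.

## Mapping statistics

Pillai's trace per added term, with the standard F approximation
(s = min(q, df_h), m = (|q − df_h| − 1)/2, n* = (df_e − q − 1)/2). For
single-df terms this reduces to df1 = q, df2 = df_e − q + 1 and, at q = 1,
to the univariate F exactly. Scans residualize the phenotype and all
candidate dosage columns against the base design once per model, after
which every position costs one rank-1 quadratic form (H + E is constant),
so genome scans are a single matrix product.

The permutation penalty T permutes whole rows of the covariate-adjusted
phenotype residuals against the genotype block, runs a single-QTL scan per
permutation, and takes the (1 − alpha) quantile of the genome-wide max LOD
(defaults n_perm = 1000, alpha = 0.05). Max LOD is computed through the
max Pillai statistic (monotone at fixed df), so only one F-tail evaluation
per permutation is needed.

**Model score.** pLOD(gamma) = LOD(gamma) − T·|gamma|, where LOD(gamma) is
the *sum of sequential added-term LODs* over the model's QTL in canonical
(chromosome, position) order, each tested given the covariates and the
previously entered QTL. A joint multi-df Pillai test was considered and
rejected: its −log10 p increments shrink as the model grows (df dilution),
so a locus whose added-term LOD clearly exceeds T could still lower the
joint-test pLOD. The sequential sum keeps model-size increments on exactly
the scale the permutation threshold is calibrated on, and the canonical
order makes the score independent of search history.

**Search schedule.** Forward steps add the genome-wide best position given
the current model (ties break to lower chromosome then lower cM —
deterministic output); after each addition, every position is refined by
profile scans holding the others fixed, iterated to stability (≤3 rounds),
and backward drops are taken whenever removing a QTL raises pLOD. QTL on
one chromosome are kept ≥ `window` = 10 cM apart. The forward pass runs to
`max_qtl` (default 50) or until 3 consecutive additions fail to improve the
best visited pLOD; the returned model is the pLOD-argmax over all visited
models. Mapping is performed in the retained PC basis; effects are
back-rotated to coordinate space (norm-preserving, the basis being
orthonormal) for norms, per-axis decompositions, and G construction.

**Intervals and effect summaries.** Credible intervals normalize 10^LOD
over the chromosome grid and take the span of the smallest highest-density
set reaching 0.95. Per QTL the package reports ‖beta‖ (and a noise-bias
corrected ‖beta‖_adj = sqrt(max(‖beta‖² − (X'X)⁻¹_jj tr S, 0)), since the
raw norm of an estimated vector inflates by the trace of its sampling
covariance — ~20% at directional h² 0.15, n ≈ 430, q ≈ 32), the type-III
%SS of total Procrustes variance, the projection scores
v = Y beta'/‖beta‖ with the share of var(v) explained by the locus dosage,
the closed-form expectation h² = ‖beta‖⁴/(beta(B'B + 4 Sigma_e)beta') —
which reduces to genetic/(genetic + environmental) variance along beta for
a backcross, dosage variance 1/4 — and per-axis fractions
Σ_i beta²_{i,m}/‖beta‖².

## G matrices and comparison

G = B' C B with C the empirical covariance of expected dosages at the
fitted positions (captures linkage between same-chromosome QTL; the
unlinked closed form I/4 is available). P is the covariance of
covariate-adjusted Procrustes coordinates (toggleable to raw). Comparisons:
symmetric PSD matrix square roots (negative eigenvalues clipped at zero)
for d_H; leading-eigenvector angles folded to [0°, 90°] with p the fraction
of 100,000 random direction pairs at least as aligned (leading-eigenvalue
ties are reported as a multiplicity rather than silently resolved);
Krzanowski's H = Σ A_i A_i' with q_i the smallest eigenvector count
reaching 90% variance, whose eigenvalues equal Σ cos²δ_i by construction;
and eigenvalues of G pinv(P) (rank tolerance 1e-10 of the largest
eigenvalue) clipped to [0, 1] with the clip count reported. When many QTL
of similar magnitude contribute, G's leading eigenvalue is nearly
degenerate and the gmax angle is intrinsically noisy even when d_H and the
common subspace show near-identity; interpret it together with the
reported multiplicity.

## Synthetic data

The generator reproduces the study design: a multi-chromosome N2 backcross
(Markov chain with Haldane recombination, marginal P(AB) = 1/2, optional
genotyping error and missingness), 13-landmark 3D configurations with
additive QTL effects of Procrustes norm ~1e-3–1e-2, covariate effects, and
individual error with isotropic, diagonal, or factor-structured covariance
(the error structure of real data being unknown, all three are exposed
rather than asserting one). Effect and covariate directions are planted
through the shape-tangent projector at the mean shape, so superimposition
removes none of their magnitude; `beta_norm_for_h2` converts a target
directional heritability to an effect norm via ‖beta‖² = 4σ²h²/(1 − h²).
Configurations are then de-superimposed by random proper rotations,
translations, and scales exp(logCS) with logCS ~ N(0, 0.08) (scales
roughly 0.85–1.18), and the recorded log centroid size is measured from
the emitted configuration, so allometry is recoverable exactly as in real
data. Fixture surfaces are icosphere-based (super)ellipsoids.

What the generator does **not** emulate: spatially correlated digitization
error along ridges, the 19-autosome mouse map (tests use 1–5 chromosomes),
epistasis, imprinting or X-linkage, and real mandible geometry. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to violations of it.

## Problem sizes and numerics

The test suite and the acceptance script scale the study down to run
quickly while keeping the designs meaningful: calibration uses 200 null
replicates with 200 permutations each (n = 200, 3 chromosomes); recovery
uses 50 replicates at n = 430 with 20 markers per chromosome and
directional h² 0.15; estimator-consistency checks use n = 5000; the
acceptance run uses n = 427, 5 chromosomes, 8 QTL, 200 permutations.
Degenerate inputs (zero-size configurations, collinear/coplanar TPS
controls, aliased design columns, off-map positions, empty models) raise
`ValueError` with a specific message rather than propagating numerical
noise. All stochastic operations take explicit seeds; reruns are
byte-identical.

## Known limitations

- Haley–Knott regression on expected dosages slightly attenuates effects
  at positions far from markers relative to a full mixture likelihood.
- Type-III %SS does not sum exactly to 100 across correlated terms; the
  identity holds on orthogonal designs only.
- The sequential model LOD depends (weakly) on the canonical ordering at
  linked loci; the joint test is free of this but was rejected for the
  calibration mismatch described above.
- Sliding relaxes bending energy only (no Procrustes-distance criterion),
  and the slide→project loop is not guaranteed to decrease the
  post-projection energy monotonically, only the pre-projection one.
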