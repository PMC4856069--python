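# shapemapper

Multivariate mapping of quantitative trait loci (QTL) for landmark-based
shape in experimental crosses, with the geometric-morphometric toolchain the
analysis needs on either side: generalized Procrustes superimposition,
thin-plate-spline semilandmarks on triangulated surfaces, simulated 2D
flattening, and QTL-based genetic covariance (**G**) comparison.

The package targets the classic setting of craniofacial genetics in the
mouse: a backcross population phenotyped by a configuration of k landmarks
in 2 or 3 dimensions and genotyped at SNPs on a centimorgan map. Because
such datasets are rarely redistributable, a first-class synthetic-data
generator reproduces the study design (recombination by the Haldane map
function, additive shape QTL of specified directional heritability,
covariate effects, configurable error covariance), so the entire pipeline
is testable end to end from nothing.

## The model

After a full generalized Procrustes analysis and reduction to principal
components, the shape of individual *i* is modelled as

    y_i | M_i  ~  N_q( mu + sum_c x_ic beta_c + sum_j p_ij beta_j , S )

where `x_ic` are covariates (log centroid size, sex, direction of cross),
`p_ij = Pr(g_ij = AB | M_i)` is the expected heterozygote dosage at QTL *j*
from a hidden Markov model over the flanking markers (Haley–Knott
regression), and `beta_j` is the q-dimensional additive shape effect. Each
candidate term is tested by Pillai's trace `V = tr(H (H + E)^-1)` with the
standard F approximation; `LOD = -log10 p`. Multiple-QTL models gamma are
searched forward/backward under a penalized LOD,

    pLOD(gamma) = LOD(gamma) - T |gamma|,

with the penalty `T` the genome-wide 0.95-quantile of max LOD over
permutations. Per-QTL credible intervals come from the normalized
`10^LOD(theta)` profile (highest-density set). Effects are summarised by
their Procrustes-unit norm `||beta_j||`, the share of total Procrustes
variance, the projection scores `v = Y beta_j' / ||beta_j||`, and the
expected directional heritability
`h2_j = ||beta_j||^4 / (beta_j (B'B + 4 Sigma_e) beta_j')`. The
QTL-implied genetic covariance `G = B' C B` (C = dosage covariance, I/4
when unlinked) is compared across analyses via the root Euclidean distance
`d_H = ||G1^{1/2} - G2^{1/2}||`, the angle between leading eigenvectors
against a random-direction null, the Krzanowski common subspace, and the
spectrum of `G P^-` (multivariate heritability).

## Worked example

`examples/01_simulate_and_map.py` simulates a 3-chromosome backcross
(n = 430, 13 3D landmarks, three planted QTL at directional h² = 0.2) and
maps it:

```
planted QTL:
  chr1 @ 33.3 cM
  chr2 @ 43.3 cM
  chr3 @ 33.3 cM

permutation penalty T = 2.75 LOD per QTL
model found: 3 QTL (pLOD = 26.61)
  chr1 @ 37.0 cM, 95% CI [33.0, 41.0] cM, ||beta|| = 0.0038 Procrustes units, 0.87% of total shape variance, 19.8% along its own direction
  chr2 @ 42.0 cM, 95% CI [39.0, 45.0] cM, ||beta|| = 0.0041 Procrustes units, 0.99% of total shape variance, 23.7% along its own direction
  chr3 @ 35.0 cM, 95% CI [33.0, 36.0] cM, ||beta|| = 0.0045 Procrustes units, 1.17% of total shape variance, 27.5% along its own direction
```

All three loci are recovered inside their credible intervals; each explains
about 1% of total shape variance but a quarter of the variance along its
own direction — the typical signature of many small, individually
well-oriented shape QTL. The other examples cover semilandmark templates
(`02`), the 2D-flattening comparison (`03`, where the 2D arm maps the same
loci with wider credible intervals), G-matrix comparison (`04`) and
measurement-error ANOVA (`05`).

A thin CLI wraps the pipeline for shell use:

```sh
shapemapper simulate --n 430 --out-prefix sim
shapemapper run config.yaml       # full pipeline from a YAML config
shapemapper scan|permtest|gcompare ...
```

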