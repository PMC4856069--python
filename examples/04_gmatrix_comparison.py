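"""Build a QTL-based genetic covariance and compare it with the planted one.

G = B' C B sums the mapped additive effects weighted by the dosage
covariance. The estimated G is compared with the G implied by the planted
effects via the root Euclidean distance, the gmax angle against a
random-vector null, the Krzanowski shared subspace, and the spectrum of
G P^- (multivariate heritability).
"""

import numpy as np

from shapemapper.genoprob import calc_genoprob
from shapemapper.gmatrix import (
    CovMatrix,
    gmax_angle_test,
    krzanowski_subspace,
    multivariate_heritability,
    phenotypic_P,
    qtl_G,
    root_euclidean_distance,
)
from shapemapper.morpho import gpa, pca_reduce
from shapemapper.morpho.gpa import _optimal_rotation
from shapemapper.pipeline import _simulated_cross, rotate_fit_to_coords
from shapemapper.qtl import forward_backward_search, perm_threshold

cross = _simulated_cross({"n": 430, "n_chromosomes": 3, "n_qtl": 3, "h2_dir": 0.25}, 31)
res = gpa(cross.phenotypes)
pca = pca_reduce(res, 0.99)
probs = calc_genoprob(cross, step=1.0)
T = perm_threshold(pca.scores, cross.covariates, probs, n_perm=200, seed=41)
fit = forward_backward_search(pca.scores, cross.covariates, probs, T, max_qtl=6)
fit_coords = rotate_fit_to_coords(fit, pca.basis)
labels = res.aligned.coordinate_labels()

G_est = qtl_G(fit_coords, probs, labels=labels)
P = phenotypic_P(res.aligned.vectorized(), labels=labels, covariates=cross.covariates)

# the planted G, rotated into the GPA consensus frame
R = _optimal_rotation(cross.sim_truth.mean_shape, res.mean_shape)
B_true = np.stack([(q.beta.reshape(13, 3) @ R).ravel() for q in cross.sim_truth.qtls])
G_true = CovMatrix(B_true.T @ B_true / 4.0, labels=labels, kind="G")

print(f"captured {100 * np.trace(G_est.matrix) / np.trace(P.matrix):.1f}% of "
      "phenotypic variance in the mapped QTL (trace G / trace P)")
print(f"d_H(estimated, planted) = {root_euclidean_distance(G_est, G_true):.4f}")
angle, p, _ = gmax_angle_test(G_est, G_true, n_random=100_000, seed=5)
print(f"gmax angle = {angle:.1f} deg (p = {p:.2g} vs random directions)")
sub = krzanowski_subspace([G_est.matrix, G_true.matrix], var_fraction=0.9)
print(f"Krzanowski leading eigenvalue = {sub.eigenvalues[0]:.3f} (max 2 = identical)")
h2, _, _ = multivariate_heritability(G_est, P)
print(f"leading multivariate heritability (GP^-) = {h2[0]:.2f}")
# Small d_H, a small gmax angle with tiny p, and a leading Krzanowski
# eigenvalue near 2 all say the mapped G reproduces the planted genetic
# covariance; the GP^- eigenvalue is the heritability of the most heritable
# shape direction.
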