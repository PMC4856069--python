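"""Artificially flatten 3D landmark data to 2D and compare mapping precision.

Replays the classical 2D-imaging compromise: project each superimposed 3D
configuration onto its natural plane, re-superimpose in 2D, and map QTL in
both representations.
"""

import numpy as np

from shapemapper.genoprob import calc_genoprob
from shapemapper.morpho import LandmarkSample, flatten_to_2d, gpa, pca_reduce
from shapemapper.pipeline import _simulated_cross
from shapemapper.qtl import forward_backward_search, perm_threshold

cross = _simulated_cross({"n": 430, "n_chromosomes": 3, "n_qtl": 3, "h2_dir": 0.2}, 11)
res3 = gpa(cross.phenotypes)
probs = calc_genoprob(cross, step=1.0)

flat = np.stack(
    [
        flatten_to_2d(res3.aligned.config(i), (0, 1, 2)).config2d.coords
        for i in range(res3.aligned.n)
    ]
)
res2 = gpa(LandmarkSample(flat, ids=res3.aligned.ids))

for name, res in (("3D", res3), ("2D", res2)):
    pca = pca_reduce(res, 0.99)
    T = perm_threshold(pca.scores, cross.covariates, probs, n_perm=200, seed=21)
    fit = forward_backward_search(pca.scores, cross.covariates, probs, T, max_qtl=6)
    widths = [q["ci_right"] - q["ci_left"] for q in fit.qtl]
    med = np.median(widths) if widths else float("nan")
    print(
        f"{name}: {fit.n_qtl} QTL mapped, median credible interval "
        f"{med:.1f} cM ({pca.retained} shape dimensions used)"
    )
# The out-of-plane signal discarded by flattening typically costs detections
# and/or widens the credible intervals relative to the full 3D analysis.
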