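"""End-to-end orchestration: from a cross file (or simulation) to QTL and G.

The pipeline chains the stages of the analysis: read or simulate a cross,
superimpose the landmark phenotypes (GPA), optionally flatten them to 2D,
reduce to principal components, fit the covariate model, compute genotype
probabilities, calibrate the permutation penalty, run the forward/backward
model search, summarise effects, and build the QTL-based G matrix together
with the phenotypic P. Every stochastic stage takes its seed from the
config, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .genoprob import CrossData, calc_genoprob
from .gmatrix import phenotypic_P, qtl_G
from .morpho import LandmarkSample, flatten_to_2d, gpa, pca_reduce
from .qtl import (
    QtlModelFit,
    effect_summaries,
    fit_covariates,
    forward_backward_search,
    perm_threshold,
    plane_decomposition,
)

__all__ = ["PipelineConfig", "run_pipeline", "rotate_fit_to_coords"]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML mapping."""

    geno_csv: str | None = None
    pheno_csv: str | None = None
    out_dir: str = "results"
    seed: int = 1
    # GPA / reduction
    variance_fraction: float = 0.95
    # 2D arm
    flatten: bool = False
    flatten_anchors: tuple[int, int, int] = (0, 1, 2)
    # genotype probabilities
    step: float = 1.0
    error_prob: float = 0.001
    # permutations / search
    n_perm: int = 1000
    alpha: float = 0.05
    threshold: float | None = None  # explicit T overrides permutations
    max_qtl: int = 50
    window: float = 10.0
    # simulation (used when geno_csv is None)
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "flatten_anchors" in raw:
            raw["flatten_anchors"] = tuple(raw["flatten_anchors"])
        return cls(**raw)


def rotate_fit_to_coords(fit: QtlModelFit, basis: np.ndarray) -> QtlModelFit:
    """Express a fit obtained in a PC basis in original coordinate space.

    ``basis`` is the q_coords x q_scores orthonormal PC basis; effect rows
    and the residual covariance are back-rotated. Norms and traces of
    retained-space quantities are preserved because the basis is orthonormal.
    """
    return QtlModelFit(
        qtl=fit.qtl,
        covariate_columns=fit.covariate_columns,
        intercept=basis @ fit.intercept,
        covariate_effects=fit.covariate_effects @ basis.T,
        B=fit.B @ basis.T,
        S=basis @ fit.S @ basis.T,
        lod=fit.lod,
        plod=fit.plod,
        T=fit.T,
        search_path=fit.search_path,
    )


def _simulated_cross(sim: dict, seed: int) -> CrossData:
    from .synthetic import (
        MapSpec,
        QtlSpec,
        SimTruth,
        beta_norm_for_h2,
        default_mean_shape,
        isotropic_error_cov,
        shape_tangent_projector,
        simulate_backcross,
        simulate_shapes,
    )

    n = int(sim.get("n", 430))
    n_chrom = int(sim.get("n_chromosomes", 3))
    length = float(sim.get("chrom_length", 100.0))
    spacing = float(sim.get("marker_spacing", 5.0))
    k = int(sim.get("n_landmarks", 13))
    d = int(sim.get("dim", 3))
    sigma = float(sim.get("sigma", 0.004))
    h2 = float(sim.get("h2_dir", 0.15))
    n_qtl = int(sim.get("n_qtl", 3))

    map_spec = MapSpec([(str(i + 1), length) for i in range(n_chrom)], spacing)
    cross = simulate_backcross(map_spec, n=n, seed=seed)
    mean = default_mean_shape(k, d)
    rng = np.random.default_rng(seed + 1)
    proj = shape_tangent_projector(mean)
    qtls = []
    for j in range(n_qtl):
        direction = proj @ rng.standard_normal(k * d)
        direction /= np.linalg.norm(direction)
        beta = beta_norm_for_h2(h2, sigma) * direction
        chrom = str(j % n_chrom + 1)
        pos = float((j // n_chrom + 1) * length / (n_qtl // n_chrom + 2) + 10 * (j % 2))
        qtls.append(QtlSpec(chrom=chrom, pos=pos, beta=beta))
    cov_dir = rng.standard_normal((3, k * d)) @ proj
    cov_dir /= np.linalg.norm(cov_dir, axis=1, keepdims=True)
    truth = SimTruth(
        mean_shape=mean,
        qtls=qtls,
        size_effect=cov_dir[0] * 0.02,
        sex_effect=cov_dir[1] * 0.003,
        direction_effect=cov_dir[2] * 0.004,
        error_cov=isotropic_error_cov(k, d, sigma),
    )
    coords, covars = simulate_shapes(cross, truth, seed=seed + 2)
    cross.phenotypes = LandmarkSample(coords=coords, ids=cross.ids)
    cross.covariates = covars
    cross.sim_truth = truth
    return cross


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle and writes files.

    Outputs in ``out_dir``: ``covariates.csv`` (per-term Pillai tests),
    ``qtl.csv`` (one row per QTL with CI and effect sizes), ``model.json``
    (model descriptor incl. seeds and stage wall-times) and ``G.csv`` /
    ``P.csv``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {**asdict(config)}, "stages": {}}

    def mark(stage, start):
        log["stages"][stage] = round(time.time() - start, 3)

    s = time.time()
    if config.geno_csv is not None:
        cross = smio.read_cross_csv(config.geno_csv, config.pheno_csv)
    elif config.simulate is not None:
        cross = _simulated_cross(config.simulate, config.seed)
    else:
        raise ValueError("config needs either geno_csv/pheno_csv or a simulate block")
    if not isinstance(cross.phenotypes, LandmarkSample):
        raise ValueError("pipeline requires landmark phenotypes")
    mark("read", s)

    s = time.time()
    res = gpa(cross.phenotypes)
    sample = res.aligned
    mark("gpa", s)

    if config.flatten:
        s = time.time()
        flat = np.empty((sample.n, sample.k, 2))
        for i in range(sample.n):
            flat[i] = flatten_to_2d(sample.config(i), config.flatten_anchors).config2d.coords
        sample2d = LandmarkSample(coords=flat, ids=sample.ids, labels=sample.labels)
        res = gpa(sample2d)
        sample = res.aligned
        mark("flatten", s)

    s = time.time()
    pca = pca_reduce(res, config.variance_fraction)
    Y = pca.scores
    mark("pca", s)

    s = time.time()
    covfit = fit_covariates(Y, cross.covariates)
    pd.DataFrame(
        {
            "term": covfit.terms,
            "pillai": [covfit.pillai[t] for t in covfit.terms],
            "F": [covfit.F[t] for t in covfit.terms],
            "p": [covfit.p[t] for t in covfit.terms],
            "pct_ss": [covfit.pct_ss[t] for t in covfit.terms],
        }
    ).to_csv(out / "covariates.csv", index=False)
    mark("covariates", s)

    s = time.time()
    probs = calc_genoprob(cross, step=config.step, error_prob=config.error_prob)
    mark("genoprob", s)

    s = time.time()
    if config.threshold is not None:
        T = float(config.threshold)
    else:
        T = perm_threshold(
            Y,
            cross.covariates,
            probs,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed + 10,
        )
    mark("permutations", s)

    s = time.time()
    fit = forward_backward_search(
        Y, cross.covariates, probs, T, max_qtl=config.max_qtl, window=config.window
    )
    mark("search", s)

    s = time.time()
    k, d = sample.k, sample.d
    summaries = effect_summaries(
        fit, Y, probs, covariates=cross.covariates, shape_dims=None
    )
    fit_coords = rotate_fit_to_coords(fit, pca.basis)
    coord_labels = sample.coordinate_labels()
    rows = []
    for qinfo, summ, beta in zip(fit.qtl, summaries, fit_coords.B):
        fr = plane_decomposition(beta, k, d)
        rows.append(
            {
                "chrom": qinfo["chrom"],
                "pos": qinfo["pos"],
                "ci_left": qinfo["ci_left"],
                "ci_right": qinfo["ci_right"],
                "lod": qinfo["lod_added"],
                "norm": summ.norm,
                "norm_adjusted": summ.norm_adjusted,
                "pct_sst": summ.pct_sst,
                "pct_ss_proj": summ.pct_ss_proj,
                "expected_h2": summ.expected_h2,
                **{f"frac_{ax}": float(fr[m]) for m, ax in enumerate("xyz"[:d])},
            }
        )
    qtl_df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ci_left",
            "ci_right",
            "lod",
            "norm",
            "norm_adjusted",
            "pct_sst",
            "pct_ss_proj",
            "expected_h2",
            *[f"frac_{ax}" for ax in "xyz"[:d]],
        ],
    )
    qtl_df.to_csv(out / "qtl.csv", index=False)
    mark("effects", s)

    s = time.time()
    G = P = None
    if fit.n_qtl > 0:
        G = qtl_G(fit_coords, probs, labels=coord_labels)
        Yc = sample.vectorized()
        P = phenotypic_P(Yc, labels=coord_labels, covariates=cross.covariates)
        smio.write_cov_csv(G, out / "G.csv")
        smio.write_cov_csv(P, out / "P.csv")
    mark("gmatrix", s)

    log["threshold"] = T
    log["model"] = {
        "n_qtl": fit.n_qtl,
        "lod": fit.lod,
        "plod": fit.plod,
        "qtl": fit.qtl,
        "search_path": fit.search_path,
    }
    log["total_seconds"] = round(time.time() - t0, 3)
    with open(out / "model.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)

    return {
        "cross": cross,
        "gpa": res,
        "pca": pca,
        "covariate_fit": covfit,
        "probs": probs,
        "threshold": T,
        "fit": fit,
        "fit_coords": fit_coords,
        "effects": summaries,
        "qtl_table": qtl_df,
        "G": G,
        "P": P,
    }
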