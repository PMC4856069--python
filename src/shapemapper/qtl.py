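"""Multivariate multiple-QTL mapping of shape.

The phenotype is an n x q matrix of shape variables (Procrustes coordinates
or their leading principal components). At a candidate position the model is

    y_i ~ N_q(mu + sum_c x_ic beta_c + sum_j p_ij beta_j, S)

with covariates (log centroid size, sex, direction of cross) and expected
heterozygote dosages p_ij from the genotype-probability HMM (Haley-Knott
regression: one design column per backcross QTL). Each added term is tested
by Pillai's trace with its standard F approximation; LOD = -log10 p. Model
search is forward/backward over a penalized LOD, pLOD(gamma) =
LOD(gamma) - T |gamma|, with the penalty T taken as the genome-wide
(1 - alpha) quantile of max LOD over permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoprob import GenoProb

__all__ = [
    "ScanProfile",
    "QtlModelFit",
    "CovariateFit",
    "EffectSummary",
    "pillai_f",
    "build_design",
    "fit_covariates",
    "scan",
    "perm_threshold",
    "forward_backward_search",
    "bayes_interval",
    "effect_summaries",
    "plane_decomposition",
    "expected_h2",
]

COVARIATE_COLUMNS = ("logCS", "sex", "cross_direction")


def pillai_f(V: float, q: int, df_h: int, df_e: int):
    """F approximation of Pillai's trace V = tr(H (H+E)^-1).

    s = min(q, df_h), m = (|q - df_h| - 1)/2, n* = (df_e - q - 1)/2,
    F = ((2n*+s+1)/(2m+s+1)) * (V/s)/(1 - V/s) on (s(2m+s+1), s(2n*+s+1)) df.
    Reduces to the univariate F when q = 1.
    """
    s = min(q, df_h)
    m = (abs(q - df_h) - 1) / 2.0
    nstar = (df_e - q - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nstar + s + 1)
    if df2 <= 0:
        raise ValueError("not enough error degrees of freedom for this q")
    ratio = V / s
    ratio = min(max(ratio, 0.0), 1.0 - 1e-300)
    F = (df2 / df1) * ratio / (1.0 - ratio)
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


def build_design(covariates: pd.DataFrame, columns=COVARIATE_COLUMNS) -> np.ndarray:
    """Intercept + covariate columns as a numeric design matrix.

    ``cross_direction`` coded 1/2 is shifted to 0/1; other columns are used
    as-is.
    """
    cols = [np.ones(len(covariates))]
    for c in columns:
        v = np.asarray(covariates[c], dtype=float)
        if c == "cross_direction":
            v = v - v.min()
        cols.append(v)
    return np.column_stack(cols)


def _residualize(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of A on the column space of X."""
    coef, *_ = np.linalg.lstsq(X, A, rcond=None)
    return A - X @ coef


def _term_pillai(R: np.ndarray, Minv: np.ndarray, D: np.ndarray, df_e: int):
    """Vectorised single-df Pillai statistics for many candidate columns.

    ``R`` is the phenotype residualized against the base design, ``Minv`` the
    inverse of R'R, and ``D`` holds candidate columns already residualized
    against the same base design. Because H + E equals R'R for every
    candidate, V_j = (b_j Minv b_j') / (x_j'x_j) with b_j = D_j'R.
    """
    q = R.shape[1]
    xx = np.einsum("ij,ij->j", D, D)
    B = D.T @ R  # P x q
    quad = np.einsum("pj,jk,pk->p", B, Minv, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(xx > 1e-12, quad / xx, 0.0)
    V = np.clip(V, 0.0, 1.0 - 1e-15)
    # single-df Pillai F: df1 = q, df2 = df_e - q + 1 (vectorised conversion)
    df2 = df_e - q + 1
    F = (df2 / q) * V / (1.0 - V)
    p = stats.f.sf(F, q, df2)
    lods = -np.log10(np.maximum(p, 1e-300))
    return V, lods


@dataclass
class ScanProfile:
    """Per-chromosome LOD profiles for one added QTL term."""

    positions: dict[str, np.ndarray]
    lod: dict[str, np.ndarray]

    def max(self):
        """(chrom, pos, lod) at the genome-wide maximum (NaNs ignored)."""
        best = (None, np.nan, -np.inf)
        for chrom in self.positions:
            lods = self.lod[chrom]
            if np.all(np.isnan(lods)):
                continue
            j = int(np.nanargmax(lods))
            if lods[j] > best[2]:
                best = (chrom, float(self.positions[chrom][j]), float(lods[j]))
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.positions:
            for pos, lod in zip(self.positions[chrom], self.lod[chrom]):
                rows.append((chrom, pos, lod))
        return pd.DataFrame(rows, columns=["chrom", "pos", "lod"])


@dataclass
class CovariateFit:
    """Multivariate covariate model with per-term Pillai tests and %SS."""

    terms: list[str]
    pillai: dict[str, float]
    F: dict[str, float]
    df: dict[str, tuple[float, float]]
    p: dict[str, float]
    pct_ss: dict[str, float]
    coef: np.ndarray  # design columns x q (row 0 = intercept)
    residual_cov: np.ndarray
    pct_ss_residual: float


def fit_covariates(
    Y: np.ndarray,
    covariates: pd.DataFrame,
    columns=COVARIATE_COLUMNS,
    interactions: bool = False,
) -> CovariateFit:
    """Multivariate least squares of shape on the covariates.

    Per-term hypothesis SSCPs are type III (each column residualized against
    every other term); Pillai's trace per term with the F approximation; %SS
    per term is tr(H_term) as a percentage of the total (centered) SSCP
    trace.
    """
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    X = build_design(covariates, columns)
    names = ["intercept", *columns]
    if interactions:
        base = X[:, 1:]
        for i in range(len(columns)):
            for j in range(i + 1, len(columns)):
                X = np.column_stack([X, base[:, i] * base[:, j]])
                names.append(f"{columns[i]}:{columns[j]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient covariate design (aliased columns)")
    if n <= X.shape[1] + q:
        raise ValueError("too few specimens for this phenotype dimension")

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    E = resid.T @ resid
    df_e = n - X.shape[1]
    Yc = Y - Y.mean(axis=0)
    sst = float(np.trace(Yc.T @ Yc))

    pillai, Fs, dfs, ps, pct = {}, {}, {}, {}, {}
    EH_inv_cache = None
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        others = np.delete(X, j, axis=1)
        xr = _residualize(X[:, [j]], others)
        b = xr.T @ Y
        xx = float((xr * xr).sum())
        if xx < 1e-12:
            raise ValueError(f"aliased column {name!r}")
        H = (b.T @ b) / xx
        EH = E + H
        V = float(np.trace(np.linalg.solve(EH, H)))
        F, df1, df2, p = pillai_f(V, q, 1, df_e)
        pillai[name] = V
        Fs[name] = F
        dfs[name] = (df1, df2)
        ps[name] = p
        pct[name] = 100.0 * float(np.trace(H)) / sst
    return CovariateFit(
        terms=[nm for nm in names if nm != "intercept"],
        pillai=pillai,
        F=Fs,
        df=dfs,
        p=ps,
        pct_ss=pct,
        coef=coef,
        residual_cov=E / df_e,
        pct_ss_residual=100.0 * float(np.trace(E)) / sst,
    )


def _dosage_matrix(probs: GenoProb, chrom: str) -> np.ndarray:
    return probs.prob_ab[chrom]


def scan(
    Y: np.ndarray,
    covariates: pd.DataFrame | None,
    probs: GenoProb,
    fixed_positions: list[tuple[str, float]] | None = None,
    window: float = 10.0,
    covariate_columns=COVARIATE_COLUMNS,
) -> ScanProfile:
    """Genome scan for one additional QTL given covariates and a fixed model.

    At every grid position the expected-dosage column is added to the design
    (intercept + covariates + dosages of ``fixed_positions``) and tested by
    Pillai's trace; LOD = -log10 p. Positions within ``window`` cM of a fixed
    QTL on its own chromosome are skipped (NaN).
    """
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    if covariates is not None:
        X = build_design(covariates, covariate_columns)
    else:
        X = np.ones((n, 1))
    fixed_positions = fixed_positions or []
    for chrom, pos in fixed_positions:
        from .genoprob import dosage as _dos

        X = np.column_stack([X, _dos(probs, chrom, pos)])
    df_e = n - X.shape[1] - 1
    if df_e <= q:
        raise ValueError(
            f"n too small for phenotype dimension q={q}; reduce Y (e.g. pca_reduce)"
        )
    R = _residualize(Y, X)
    Minv = np.linalg.inv(R.T @ R)

    positions: dict[str, np.ndarray] = {}
    lods: dict[str, np.ndarray] = {}
    for chrom, grid in probs.positions.items():
        D = _residualize(_dosage_matrix(probs, chrom), X)
        _, lod = _term_pillai(R, Minv, D, df_e)
        for fchrom, fpos in fixed_positions:
            if fchrom == chrom:
                lod = np.where(np.abs(grid - fpos) < window, np.nan, lod)
        positions[chrom] = grid
        lods[chrom] = lod
    return ScanProfile(positions=positions, lod=lods)


def perm_threshold(
    Y: np.ndarray,
    covariates: pd.DataFrame | None,
    probs: GenoProb,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    covariate_columns=COVARIATE_COLUMNS,
) -> float:
    """Permutation penalty T: the (1 - alpha) quantile of genome-wide max LOD.

    The covariate-adjusted phenotype residuals are permuted as whole rows
    against the genotype block; each permutation gets a single-QTL genome
    scan and its maximum LOD is recorded. Error degrees of freedom match the
    unpermuted scan.
    """
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    if covariates is not None:
        X = build_design(covariates, covariate_columns)
    else:
        X = np.ones((n, 1))
    R0 = _residualize(Y, X)
    df_e = n - X.shape[1] - 1
    if df_e <= q:
        raise ValueError("n too small for phenotype dimension q")
    D_by_chrom = {
        chrom: _dosage_matrix(probs, chrom) - _dosage_matrix(probs, chrom).mean(axis=0)
        for chrom in probs.positions
    }
    rng = np.random.default_rng(seed)
    # Pillai V is monotone in LOD at fixed df, so track max V and convert once
    maxV = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Rp = R0[perm]
        Rp = Rp - Rp.mean(axis=0)
        Minv = np.linalg.inv(Rp.T @ Rp)
        best = 0.0
        for chrom, D in D_by_chrom.items():
            xx = np.einsum("ij,ij->j", D, D)
            Bm = D.T @ Rp
            quad = np.einsum("pj,jk,pk->p", Bm, Minv, Bm)
            with np.errstate(divide="ignore", invalid="ignore"):
                V = np.where(xx > 1e-12, quad / xx, 0.0)
            m = float(np.max(V))
            if m > best:
                best = m
        maxV[b] = best
    maxV = np.clip(maxV, 0.0, 1.0 - 1e-15)
    df2 = df_e - q + 1
    F = (df2 / q) * maxV / (1.0 - maxV)
    maxlod = -np.log10(np.maximum(stats.f.sf(F, q, df2), 1e-300))
    return float(np.quantile(maxlod, 1.0 - alpha))


@dataclass
class QtlModelFit:
    """A fitted multiple-QTL model gamma."""

    qtl: list[dict]  # chrom, pos, ci_left, ci_right, lod_added
    covariate_columns: tuple
    intercept: np.ndarray
    covariate_effects: np.ndarray  # (#covariates) x q
    B: np.ndarray  # (#QTL) x q effect matrix
    S: np.ndarray  # q x q residual covariance
    lod: float
    plod: float
    T: float
    search_path: list = field(default_factory=list)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    def positions(self) -> list[tuple[str, float]]:
        return [(q["chrom"], q["pos"]) for q in self.qtl]


def _fit_model(
    Y: np.ndarray,
    X_cov: np.ndarray,
    probs: GenoProb,
    positions: list[tuple[str, float]],
):
    """Multivariate fit of a QTL model; returns (coef, S, model LOD, dosages).

    The model LOD is the sum of sequential added-term Pillai LODs over the
    QTL in canonical (chromosome, position) order: each term is tested given
    the covariates and the previously entered QTL. This decomposition keeps
    model-size increments on the same scale as the single-QTL scans the
    permutation penalty T is calibrated on (a joint multi-df Pillai test
    would dilute later additions), and the canonical order makes the score
    independent of search history. 0 for the covariate-only model.
    """
    from .genoprob import dosage as _dos

    n, q = Y.shape
    D = (
        np.column_stack([_dos(probs, c, p) for c, p in positions])
        if positions
        else np.empty((n, 0))
    )
    X = np.column_stack([X_cov, D])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df_e_full = n - X.shape[1]
    S = resid.T @ resid / df_e_full
    if not positions:
        return coef, S, 0.0, D
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    lod = 0.0
    base = X_cov
    for i in order:
        dj = D[:, [i]]
        R = _residualize(Y, base)
        dr = _residualize(dj, base)
        df_e = n - base.shape[1] - 1
        Minv = np.linalg.inv(R.T @ R)
        _, lods = _term_pillai(R, Minv, dr, df_e)
        lod += float(lods[0])
        base = np.column_stack([base, dj])
    return coef, S, lod, D


def forward_backward_search(
    Y: np.ndarray,
    covariates: pd.DataFrame | None,
    probs: GenoProb,
    T: float,
    max_qtl: int = 50,
    window: float = 10.0,
    stall: int = 3,
    covariate_columns=COVARIATE_COLUMNS,
    ci_coverage: float = 0.95,
) -> QtlModelFit:
    """Forward/backward model search maximising the penalized LOD.

    Forward steps add the genome-wide best QTL given the current model; after
    each addition every position is refined by a profile scan holding the
    others fixed (iterated to stability) and backward drops are attempted
    whenever removing a QTL raises pLOD. The forward pass continues until
    ``max_qtl`` or until ``stall`` consecutive additions fail to improve the
    best pLOD seen; the returned model is the visited model with maximal
    pLOD. QTL on one chromosome are kept >= ``window`` cM apart. Ties break
    toward lower chromosome index then lower position, so the output is
    deterministic.
    """
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    X_cov = (
        build_design(covariates, covariate_columns)
        if covariates is not None
        else np.ones((n, 1))
    )

    def model_plod(positions):
        _, _, lod, _ = _fit_model(Y, X_cov, probs, positions)
        return lod - T * len(positions), lod

    current: list[tuple[str, float]] = []
    cur_plod, cur_lod = 0.0, 0.0
    visited: dict[tuple, tuple[float, float]] = {(): (0.0, 0.0)}
    path = [{"n_qtl": 0, "lod": 0.0, "plod": 0.0}]
    best_plod = 0.0
    since_best = 0

    def key(positions):
        return tuple(sorted(positions))

    chrom_order = {c: i for i, c in enumerate(probs.positions)}

    while len(current) < max_qtl:
        prof = scan(
            Y,
            covariates,
            probs,
            fixed_positions=current,
            window=window,
            covariate_columns=covariate_columns,
        )
        # deterministic argmax: highest LOD, ties to lower chrom then pos
        best = None
        for chrom in sorted(prof.positions, key=lambda c: chrom_order[c]):
            lods = prof.lod[chrom]
            if np.all(np.isnan(lods)):
                continue
            j = int(np.nanargmax(lods))
            cand = (float(lods[j]), chrom_order[chrom], float(prof.positions[chrom][j]))
            if best is None or cand[0] > best[0] + 1e-12:
                best = cand
        if best is None or best[0] <= 0:
            break
        new_pos = [(c, p) for c, p in current]
        chrom_name = list(probs.positions)[best[1]]
        new_pos.append((chrom_name, best[2]))

        # refine positions iteratively, holding the others fixed
        for _ in range(3):
            moved = False
            for i in range(len(new_pos)):
                others = new_pos[:i] + new_pos[i + 1 :]
                chrom_i = new_pos[i][0]
                prof_i = scan(
                    Y,
                    covariates,
                    probs,
                    fixed_positions=others,
                    window=window,
                    covariate_columns=covariate_columns,
                )
                lods = prof_i.lod[chrom_i]
                if np.all(np.isnan(lods)):
                    continue
                j = int(np.nanargmax(lods))
                p_new = float(prof_i.positions[chrom_i][j])
                if abs(p_new - new_pos[i][1]) > 1e-9:
                    new_pos[i] = (chrom_i, p_new)
                    moved = True
            if not moved:
                break

        plod_new, lod_new = model_plod(new_pos)
        visited[key(new_pos)] = (plod_new, lod_new)
        current, cur_plod, cur_lod = new_pos, plod_new, lod_new

        # backward drops while they help
        improved = True
        while improved and current:
            improved = False
            for i in range(len(current)):
                reduced = current[:i] + current[i + 1 :]
                k = key(reduced)
                if k in visited:
                    plod_r, lod_r = visited[k]
                else:
                    plod_r, lod_r = model_plod(reduced)
                    visited[k] = (plod_r, lod_r)
                if plod_r > cur_plod + 1e-12:
                    current, cur_plod, cur_lod = reduced, plod_r, lod_r
                    improved = True
                    break

        path.append({"n_qtl": len(current), "lod": cur_lod, "plod": cur_plod})
        if cur_plod > best_plod + 1e-12:
            best_plod = cur_plod
            since_best = 0
        else:
            since_best += 1
            if since_best >= stall:
                break

    final_key = max(visited, key=lambda k: visited[k][0])
    final_positions = list(final_key)
    plod, lod = visited[final_key]
    coef, S, _, D = _fit_model(Y, X_cov, probs, final_positions)

    n_cov = X_cov.shape[1]
    qtl_entries = []
    for i, (chrom, pos) in enumerate(final_positions):
        others = final_positions[:i] + final_positions[i + 1 :]
        prof_i = scan(
            Y,
            covariates,
            probs,
            fixed_positions=others,
            window=window,
            covariate_columns=covariate_columns,
        )
        left, peak, right = bayes_interval(
            prof_i.positions[chrom], prof_i.lod[chrom], coverage=ci_coverage
        )
        lods = prof_i.lod[chrom]
        j = prof_i.positions[chrom].searchsorted(pos)
        j = min(j, len(lods) - 1)
        lod_added = float(lods[j]) if np.isfinite(lods[j]) else float(np.nanmax(lods))
        qtl_entries.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ci_left": left,
                "ci_right": right,
                "lod_added": lod_added,
            }
        )

    return QtlModelFit(
        qtl=qtl_entries,
        covariate_columns=tuple(covariate_columns) if covariates is not None else (),
        intercept=coef[0],
        covariate_effects=coef[1:n_cov],
        B=coef[n_cov:],
        S=S,
        lod=lod,
        plod=plod,
        T=T,
        search_path=path,
    )


def bayes_interval(positions: np.ndarray, lod: np.ndarray, coverage: float = 0.95):
    """Bayes credible interval from the 10^LOD profile on one chromosome.

    The profile is normalized to a discrete density over grid positions; the
    smallest set of highest-density positions reaching ``coverage`` defines
    the interval (its span is returned together with the peak). A flat
    profile yields the whole chromosome.
    """
    positions = np.asarray(positions, dtype=float)
    lod = np.asarray(lod, dtype=float)
    ok = np.isfinite(lod)
    pos, ld = positions[ok], lod[ok]
    if len(pos) == 0:
        raise ValueError("empty profile")
    w = np.power(10.0, ld - ld.max())
    w = w / w.sum()
    order = np.argsort(-w, kind="stable")
    csum = np.cumsum(w[order])
    m = int(np.searchsorted(csum, coverage - 1e-12) + 1)
    chosen = pos[order[:m]]
    peak = float(pos[np.argmax(ld)])
    return float(chosen.min()), peak, float(chosen.max())


def expected_h2(beta: np.ndarray, B: np.ndarray, Sigma_e: np.ndarray) -> float:
    """Expected share of variance explained along a QTL's own direction.

    For a backcross with unlinked QTL,
    h2_j = ||beta_j||^4 / (beta_j (B'B + 4 Sigma_e) beta_j'),
    which reduces to genetic over genetic-plus-environmental variance in the
    beta_j direction (dosage variance 1/4). With a single QTL and isotropic
    error sigma^2 I this is ||beta||^2 / (||beta||^2 + 4 sigma^2).
    """
    beta = np.asarray(beta, dtype=float).ravel()
    nrm2 = float(beta @ beta)
    if nrm2 == 0:
        raise ValueError("zero-norm effect")
    denom = float(beta @ (B.T @ B + 4.0 * Sigma_e) @ beta)
    return nrm2 * nrm2 / denom


@dataclass
class EffectSummary:
    chrom: str
    pos: float
    norm: float
    norm_adjusted: float  # noise-bias-corrected estimate of ||beta||
    pct_sst: float
    scores: np.ndarray  # projection scores v
    pct_ss_proj: float
    expected_h2: float
    plane_fractions: np.ndarray | None = None


def effect_summaries(
    fit: QtlModelFit,
    Y: np.ndarray,
    probs: GenoProb,
    covariates: pd.DataFrame | None = None,
    shape_dims: tuple[int, int] | None = None,
) -> list[EffectSummary]:
    """Per-QTL effect sizes: norm, %SST, projection scores, expected h2.

    %SST is the type-III trace of the QTL's hypothesis SSCP over the total
    (centered) SSCP trace. The projection score v = Y beta' / ||beta|| is the
    shape variable most associated with the QTL's direction; %SS_proj is the
    share of var(v) explained by the QTL's dosage (variance of E[v | p_j]
    over variance of v). When ``shape_dims`` (k, d) is given, per-axis
    fractions of the squared effect are included.
    """
    from .genoprob import dosage as _dos

    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    X_cov = (
        build_design(covariates, fit.covariate_columns)
        if covariates is not None and fit.covariate_columns
        else np.ones((n, 1))
    )
    positions = fit.positions()
    D = (
        np.column_stack([_dos(probs, c, p) for c, p in positions])
        if positions
        else np.empty((n, 0))
    )
    X_full = np.column_stack([X_cov, D])
    Yc = Y - Y.mean(axis=0)
    sst = float(np.trace(Yc.T @ Yc))
    XtX_inv = np.linalg.inv(X_full.T @ X_full) if X_full.size else None

    out = []
    for j, (chrom, pos) in enumerate(positions):
        beta = fit.B[j]
        nrm = float(np.linalg.norm(beta))
        if nrm == 0:
            raise ValueError("zero-norm effect")
        # ||beta_hat||^2 inflates by the trace of its sampling covariance,
        # (X'X)^-1_jj * tr(S); subtract it for a less biased magnitude
        jj = X_cov.shape[1] + j
        var_tr = float(XtX_inv[jj, jj] * np.trace(fit.S))
        nrm_adj = float(np.sqrt(max(nrm**2 - var_tr, 0.0)))
        others = np.delete(X_full, X_cov.shape[1] + j, axis=1)
        xr = _residualize(D[:, [j]], others)
        b = xr.T @ Y
        xx = float((xr * xr).sum())
        pct_sst = 100.0 * float((b * b).sum()) / (xx * sst) if xx > 1e-12 else 0.0

        v = Y @ beta / nrm
        xj = D[:, j]
        Xj = np.column_stack([np.ones(n), xj])
        coef, *_ = np.linalg.lstsq(Xj, v, rcond=None)
        fitted = Xj @ coef
        pct_proj = 100.0 * float(np.var(fitted) / np.var(v)) if np.var(v) > 0 else 0.0

        h2 = expected_h2(beta, fit.B, fit.S)
        fracs = None
        if shape_dims is not None:
            fracs = plane_decomposition(beta, *shape_dims)
        out.append(
            EffectSummary(
                chrom=chrom,
                pos=pos,
                norm=nrm,
                norm_adjusted=nrm_adj,
                pct_sst=pct_sst,
                scores=v,
                pct_ss_proj=pct_proj,
                expected_h2=h2,
                plane_fractions=fracs,
            )
        )
    return out


def plane_decomposition(
    beta: np.ndarray, k: int, d: int, orientation: np.ndarray | None = None
) -> np.ndarray:
    """Share of a shape effect along each coordinate axis.

    ``beta`` is a k*d effect vector in landmark-major order; fraction m is
    the sum over landmarks of the squared effects on axis m divided by the
    squared norm, after an optional ``orientation`` rotation aligning axis d
    with a reference plane normal. Fractions sum to one.
    """
    beta = np.asarray(beta, dtype=float).reshape(k, d)
    if orientation is not None:
        beta = beta @ np.asarray(orientation, dtype=float).T
    nrm2 = float((beta**2).sum())
    if nrm2 == 0:
        raise ValueError("zero effect vector")
    return (beta**2).sum(axis=0) / nrm2
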