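"""Genotype probabilities for a backcross on a centimorgan map.

A backcross individual carries one of two genotype classes at every autosomal
locus: homozygous (AA) or heterozygous (AB). Observed marker genotypes are
noisy and may be missing, so the probability of the underlying genotype at any
map position -- marker or pseudomarker -- is computed with a two-state hidden
Markov model whose transition probabilities come from the Haldane map function
(no crossover interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AA, AB, MISSING = 0, 1, -1

__all__ = [
    "AA",
    "AB",
    "MISSING",
    "GeneticMap",
    "CrossData",
    "GenoProb",
    "haldane",
    "calc_genoprob",
    "dosage",
]


def haldane(d):
    """Recombination fraction for a map distance ``d`` in cM.

    r = (1 - exp(-2d/100)) / 2; monotone in ``d`` and bounded by 1/2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass
class GeneticMap:
    """Marker names and cM positions, one block per chromosome.

    ``chromosomes`` maps chromosome name -> (marker names, positions in cM).
    Positions must be non-decreasing and names unique genome-wide.
    """

    chromosomes: dict[str, tuple[list[str], np.ndarray]]

    def __post_init__(self):
        seen: set[str] = set()
        for chrom, (names, pos) in self.chromosomes.items():
            pos = np.asarray(pos, dtype=float)
            if len(names) != len(pos):
                raise ValueError(f"chromosome {chrom}: names/positions length mismatch")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"chromosome {chrom}: positions must be non-decreasing")
            dup = seen.intersection(names)
            if dup:
                raise ValueError(f"duplicate marker names: {sorted(dup)}")
            seen.update(names)
            self.chromosomes[chrom] = (list(names), pos)

    @property
    def marker_names(self) -> list[str]:
        out: list[str] = []
        for names, _ in self.chromosomes.values():
            out.extend(names)
        return out

    @property
    def n_markers(self) -> int:
        return sum(len(names) for names, _ in self.chromosomes.values())

    def chrom_of(self, marker: str) -> str:
        for chrom, (names, _) in self.chromosomes.items():
            if marker in names:
                return chrom
        raise KeyError(marker)

    def position_of(self, marker: str) -> float:
        for names, pos in self.chromosomes.values():
            if marker in names:
                return float(pos[names.index(marker)])
        raise KeyError(marker)


@dataclass
class CrossData:
    """One backcross population: map, genotypes, phenotypes, covariates.

    Genotypes are coded ``0`` (AA), ``1`` (AB) and ``-1`` (missing); columns
    follow ``genetic_map.marker_names``. ``phenotypes`` is whatever shape
    representation the analysis stage expects (a LandmarkSample before GPA, an
    n x q score matrix after) and ``covariates`` is a DataFrame holding at
    least ``logCS``, ``sex`` and ``cross_direction``.
    """

    genetic_map: GeneticMap
    genotypes: np.ndarray
    ids: list[str]
    phenotypes: object = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        n, m = self.genotypes.shape
        if m != self.genetic_map.n_markers:
            raise ValueError("genotype columns do not match the map")
        if len(self.ids) != n:
            raise ValueError("ids do not match genotype rows")
        bad = ~np.isin(self.genotypes, (AA, AB, MISSING))
        if bad.any():
            raise ValueError("invalid genotype codes present")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows do not match genotype rows")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def marker_slice(self, chrom: str) -> slice:
        """Column slice of ``genotypes`` covering one chromosome."""
        start = 0
        for name, (names, _) in self.genetic_map.chromosomes.items():
            if name == chrom:
                return slice(start, start + len(names))
            start += len(names)
        raise KeyError(chrom)


@dataclass
class GenoProb:
    """P(AB) on a marker + pseudomarker grid, per chromosome.

    ``positions[chrom]`` is the cM grid; ``prob_ab[chrom]`` is n x len(grid).
    P(AA) is the complement.
    """

    positions: dict[str, np.ndarray]
    prob_ab: dict[str, np.ndarray]
    step: float
    error_prob: float

    def grid_index(self, chrom: str, pos: float) -> int:
        """Nearest grid point to ``pos`` (ties resolve to the left point)."""
        grid = self.positions[chrom]
        idx = int(np.argmin(np.abs(grid - pos)))
        return idx

    @property
    def n(self) -> int:
        first = next(iter(self.prob_ab.values()))
        return first.shape[0]


def _chrom_grid(pos: np.ndarray, step: float) -> np.ndarray:
    """Marker positions plus equally spaced pseudomarkers at ``step`` cM."""
    if step <= 0 or len(pos) == 1:
        return pos.copy()
    fill = np.arange(pos[0], pos[-1], step)
    grid = np.union1d(np.round(pos, 9), np.round(fill, 9))
    return grid


def _forward_backward(obs: np.ndarray, rs: np.ndarray, error_prob: float) -> np.ndarray:
    """Two-state forward-backward over one chromosome grid.

    obs: n x P observation codes (MISSING where untyped / pseudomarker).
    rs: P-1 recombination fractions between adjacent grid points.
    Returns n x P posterior P(state == AB).
    """
    n, P = obs.shape
    # emission likelihoods e[:, :, s] = P(obs | state s)
    e = np.ones((n, P, 2))
    typed = obs >= 0
    if error_prob == 0:
        e[typed, 0] = obs[typed] == AA
        e[typed, 1] = obs[typed] == AB
    else:
        e[typed, 0] = np.where(obs[typed] == AA, 1 - error_prob, error_prob)
        e[typed, 1] = np.where(obs[typed] == AB, 1 - error_prob, error_prob)

    alpha = np.empty((n, P, 2))
    c = np.empty((n, P))
    alpha[:, 0] = 0.5 * e[:, 0]
    c[:, 0] = alpha[:, 0].sum(1)
    alpha[:, 0] /= c[:, 0][:, None]
    for t in range(1, P):
        r = rs[t - 1]
        # transition [[1-r, r], [r, 1-r]]
        prev = alpha[:, t - 1]
        pred0 = prev[:, 0] * (1 - r) + prev[:, 1] * r
        pred1 = prev[:, 0] * r + prev[:, 1] * (1 - r)
        a = np.stack([pred0, pred1], axis=1) * e[:, t]
        c[:, t] = a.sum(1)
        alpha[:, t] = a / c[:, t][:, None]

    beta = np.empty((n, P, 2))
    beta[:, -1] = 1.0
    for t in range(P - 2, -1, -1):
        r = rs[t]
        nxt = beta[:, t + 1] * e[:, t + 1]
        b0 = nxt[:, 0] * (1 - r) + nxt[:, 1] * r
        b1 = nxt[:, 0] * r + nxt[:, 1] * (1 - r)
        beta[:, t] = np.stack([b0, b1], axis=1) / c[:, t + 1][:, None]

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post[:, :, 1]


def calc_genoprob(cross: CrossData, step: float = 1.0, error_prob: float = 0.001) -> GenoProb:
    """Posterior genotype probabilities at markers and pseudomarkers.

    Runs the forward-backward algorithm chromosome by chromosome with
    transitions from :func:`haldane` between adjacent grid points and emission
    error ``error_prob`` at typed markers. Missing genotypes (and pseudomarker
    positions) emit uniformly. ``step = 0`` computes at markers only.
    """
    positions: dict[str, np.ndarray] = {}
    prob_ab: dict[str, np.ndarray] = {}
    n = cross.n
    for chrom, (names, mpos) in cross.genetic_map.chromosomes.items():
        if len(names) == 0:
            raise ValueError(f"chromosome {chrom} has no markers")
        grid = _chrom_grid(mpos, step)
        obs = np.full((n, len(grid)), MISSING, dtype=np.int8)
        geno = cross.genotypes[:, cross.marker_slice(chrom)]
        # align observed markers with grid slots
        gidx = np.searchsorted(grid, np.round(mpos, 9))
        for j, gi in enumerate(gidx):
            # duplicate marker positions share a grid slot: prefer typed data
            col = geno[:, j]
            take = obs[:, gi] == MISSING
            obs[take, gi] = col[take]
        rs = haldane(np.diff(grid)) if len(grid) > 1 else np.empty(0)
        prob_ab[chrom] = _forward_backward(obs, rs, error_prob)
        positions[chrom] = grid
    return GenoProb(positions=positions, prob_ab=prob_ab, step=step, error_prob=error_prob)


def dosage(probs: GenoProb, chrom: str, pos: float) -> np.ndarray:
    """Expected AB dosage per individual at a grid position.

    ``pos`` snaps to the nearest grid point; this single column is the
    regressor of the Haley-Knott-style shape model.
    """
    if chrom not in probs.positions:
        raise KeyError(f"unknown chromosome {chrom!r}")
    idx = probs.grid_index(chrom, pos)
    return probs.prob_ab[chrom][:, idx].copy()
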