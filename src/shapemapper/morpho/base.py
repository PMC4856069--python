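"""Landmark containers shared across the morphometric operations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LandmarkConfig", "LandmarkSample"]


@dataclass
class LandmarkConfig:
    """One specimen: k landmarks in d dimensions (d = 2 or 3).

    ``fixed_mask`` flags expert-placed landmarks (True) versus surface
    semilandmarks (False).
    """

    coords: np.ndarray
    labels: list[str] | None = None
    fixed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be k x d with d in {2, 3}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        k = self.coords.shape[0]
        if self.labels is None:
            self.labels = [f"L{i + 1}" for i in range(k)]
        if len(self.labels) != k:
            raise ValueError("labels do not match landmark count")
        if self.fixed_mask is None:
            self.fixed_mask = np.ones(k, dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.shape != (k,):
                raise ValueError("fixed_mask does not match landmark count")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class LandmarkSample:
    """n specimens sharing one landmark scheme; coords is n x k x d."""

    coords: np.ndarray
    ids: list[str] | None = None
    labels: list[str] | None = None
    fixed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] not in (2, 3):
            raise ValueError("coords must be n x k x d with d in {2, 3}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n, k, _ = self.coords.shape
        if self.ids is None:
            self.ids = [f"spec{i + 1:04d}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids do not match specimen count")
        if self.labels is None:
            self.labels = [f"L{i + 1}" for i in range(k)]
        if len(self.labels) != k:
            raise ValueError("labels do not match landmark count")
        if self.fixed_mask is None:
            self.fixed_mask = np.ones(k, dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[2]

    def config(self, i: int) -> LandmarkConfig:
        return LandmarkConfig(self.coords[i], labels=self.labels, fixed_mask=self.fixed_mask)

    def vectorized(self) -> np.ndarray:
        """n x (k*d) row-major flattening (x1 y1 z1 x2 y2 z2 ...)."""
        n = self.n
        return self.coords.reshape(n, -1)

    def coordinate_labels(self) -> list[str]:
        axes = "xyz"[: self.d]
        return [f"{lab}_{ax}" for lab in self.labels for ax in axes]
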