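"""Bivariate spatial-autocorrelation coupling of accessibility and price.

The social-equity question is whether park accessibility co-locates with
socioeconomic status. With x = accessibility and y = housing price, both
z-scored with the population standard deviation, the bivariate local
Moran statistic at residence i is

    I_i = z_x(i) * sum_j w_ij * z_y(j)

with w a row-standardized k-nearest-neighbor weight matrix, and the global
bivariate Moran is the mean of the local values. Significance is assessed
by conditional permutation: z_x(i) is held fixed while the neighbor values
of z_y are drawn at random from the remaining units. Significant units are
typed by the signs of z_x(i) and the spatial lag of z_y into H-H, H-L,
L-H, L-L; the rest are not significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CATEGORIES = ("HH", "HL", "LH", "LL", "NS")


@dataclass
class SpatialWeights:
    """Row-standardized KNN weights as neighbor index/weight arrays."""

    neighbors: np.ndarray  # (n, k) neighbor indices
    weights: np.ndarray  # (n, k) weights, rows sum to 1
    k: int
    row_standardized: bool = True

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def lag(self, z: np.ndarray) -> np.ndarray:
        return (self.weights * z[self.neighbors]).sum(axis=1)


@dataclass
class LisaResult:
    residence_ids: list[str]
    local_i: np.ndarray
    p_values: np.ndarray
    categories: np.ndarray  # strings from CATEGORIES
    global_i: float
    n_permutations: int
    alpha: float

    def category_counts(self) -> dict[str, int]:
        return {c: int((self.categories == c).sum()) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residence_id": self.residence_ids,
            "local_I": self.local_i,
            "p": self.p_values,
            "category": self.categories,
        }).set_index("residence_id")


def build_weights(points: np.ndarray, k: int = 8) -> SpatialWeights:
    """k-nearest-neighbor spatial weights, row-standardized.

    Duplicate coordinates make nearest-neighbor ties ill-defined; they are
    jittered by 1e-6 m (deterministically, by point index) with a warning.
    """
    pts = np.asarray(points, dtype=float).copy()
    n = len(pts)
    if k < 1 or k >= n:
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    _, uniq_idx = np.unique(pts, axis=0, return_index=True)
    if len(uniq_idx) < n:
        warnings.warn("duplicate coordinates jittered by 1e-6 m", stacklevel=2)
        dup = np.setdiff1d(np.arange(n), uniq_idx)
        pts[dup, 0] += 1e-6 * (1 + np.arange(len(dup)))
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        row = [j for j in idx[i] if j != i][:k]
        neighbors[i] = row
    weights = np.full((n, k), 1.0 / k)
    return SpatialWeights(neighbors=neighbors, weights=weights, k=k)


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()  # population standard deviation
    if sd == 0:
        raise ValueError(f"{name} is constant; z-scores undefined")
    return (v - v.mean()) / sd


def bivariate_moran(x: np.ndarray, y: np.ndarray, w: SpatialWeights,
                    n_perm: int = 999, seed: int | None = None,
                    alpha: float = 0.05,
                    residence_ids: list[str] | None = None) -> LisaResult:
    """Bivariate local Moran with conditional-permutation inference.

    Setting y equal to x reduces the statistic to the univariate local
    Moran. Pseudo p-values are two-sided:
    p_i = (#{|I_perm| >= |I_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    n = w.n
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != n or len(y) != n:
        raise ValueError("x, y must match the weights' unit count")
    zx = _zscore(x, "x")
    zy = _zscore(y, "y")

    lag_y = w.lag(zy)
    local = zx * lag_y
    global_i = float(local.mean())

    rng = np.random.default_rng(seed)
    k = w.k
    # draw neighbor values of z_y uniformly from the other n-1 units
    draw = rng.integers(0, n - 1, size=(n, n_perm, k))
    draw += draw >= np.arange(n)[:, None, None]  # skip self
    perm_lag = (w.weights[:, None, :] * zy[draw]).sum(axis=2)
    perm_i = zx[:, None] * perm_lag
    p = ((np.abs(perm_i) >= np.abs(local)[:, None]).sum(axis=1) + 1) / (n_perm + 1)

    cats = np.full(n, "NS", dtype=object)
    sig = p <= alpha
    hi_x = zx > 0
    hi_lag = lag_y > 0
    cats[sig & hi_x & hi_lag] = "HH"
    cats[sig & hi_x & ~hi_lag] = "HL"
    cats[sig & ~hi_x & hi_lag] = "LH"
    cats[sig & ~hi_x & ~hi_lag] = "LL"

    ids = residence_ids if residence_ids is not None else [str(i) for i in range(n)]
    return LisaResult(residence_ids=list(ids), local_i=local, p_values=p,
                      categories=cats.astype(str), global_i=global_i,
                      n_permutations=n_perm, alpha=alpha)
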