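"""Park quality attributes.

A park's supply capacity is a weighted composite of three attributes: its
area S (hm^2), an ecological-service value ESV summarizing how fragmented
its internal green cover is, and a recreational-facility capacity FCs
proxied by hard-surface area (hm^2). ESV is built from nine landscape-
pattern indices computed on the park's binary land-cover raster (green
patches under 4-connectivity), standardized by direction and integrated by
principal component analysis. The attribute weights come from an analytic-
hierarchy-process (AHP) pairwise judgment matrix with a Saaty consistency
test; the shipped defaults are the published composite weights
(S 0.7236, FCs 0.1931, ESV 0.0833).

The exact index formulas are documented in ``docs/landscape_metrics.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from parkequity.types import M2_PER_HM2, Park

#: Indices where larger is better (less fragmented).
POSITIVE_INDICES = ("AI", "LPI", "MESH")
#: Indices where larger is worse (more fragmented).
NEGATIVE_INDICES = ("PD", "LSI", "AREA_AM", "SHAPE_MN", "DIVISION", "SPLIT")
INDEX_COLUMNS = ("MESH", "SPLIT", "AI", "AREA_AM", "SHAPE_MN", "DIVISION",
                 "PD", "LPI", "LSI")


@dataclass
class ParkQuality:
    """The three supply-side attributes entering the composite."""

    park_id: str
    S: float  # park area, hm^2
    ESV: float  # dimensionless composite; may be negative
    FCs: float  # hard-surface area, hm^2

    def __post_init__(self) -> None:
        if self.FCs > self.S + 1e-9:
            raise ValueError(
                f"{self.park_id}: FCs ({self.FCs}) exceeds park area ({self.S})")


@dataclass
class SupplyWeights:
    """AHP weights for the supply composite C_j = w_s*S + w_fcs*FCs + w_esv*ESV."""

    w_s: float
    w_fcs: float
    w_esv: float
    cr: float | None = None

    def __post_init__(self) -> None:
        total = self.w_s + self.w_fcs + self.w_esv
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        # AHP-derived weights are strictly positive; zeros are allowed so the
        # classic area-only 2SFCA is expressible as (1, 0, 0)
        if min(self.w_s, self.w_fcs, self.w_esv) < 0:
            raise ValueError("weights must be non-negative")

    @property
    def passes_consistency(self) -> bool | None:
        return None if self.cr is None else self.cr < 0.1


#: Published composite weights; the generating judgment matrix is not
#: public, so these ship as constants and ``ahp_weights`` can regenerate
#: weights from a user matrix.
DEFAULT_WEIGHTS = SupplyWeights(w_s=0.7236, w_fcs=0.1931, w_esv=0.0833)


# ----------------------------------------------------- landscape indices


def compute_patch_indices(landcover: np.ndarray, cell_size: float,
                          park_id: str = "") -> pd.Series:
    """Nine landscape-pattern indices of the green class in a binary raster.

    Green cells (value 1) are grouped into patches by 4-connectivity. The
    landscape is the full raster. Units: MESH and AREA_AM in hm^2, PD in
    patches per 100 hm^2, AI and LPI in percent, the rest dimensionless.

    Raises ``ValueError`` if the raster has no green cell.
    """
    green = np.asarray(landcover) > 0
    if green.ndim != 2 or green.size == 0:
        raise ValueError("landcover must be a non-empty 2-D raster")
    n_green = int(green.sum())
    if n_green == 0:
        raise ValueError(f"park {park_id or '?'} has no green cell")

    labels = cc_label(green, connectivity=1)
    n_patches = int(labels.max())
    cell_area = cell_size * cell_size

    counts = np.bincount(labels.ravel())[1:]  # cells per patch
    areas_m2 = counts * cell_area

    # like-adjacencies per patch (single count) and overall
    horiz = labels[:, :-1][(labels[:, :-1] == labels[:, 1:]) & (labels[:, :-1] > 0)]
    vert = labels[:-1, :][(labels[:-1, :] == labels[1:, :]) & (labels[:-1, :] > 0)]
    g_per_patch = (np.bincount(horiz, minlength=n_patches + 1)
                   + np.bincount(vert, minlength=n_patches + 1))[1:]
    g_total = int(g_per_patch.sum())

    perims_m = (4 * counts - 2 * g_per_patch) * cell_size
    total_area_m2 = green.size * cell_area
    sum_sq = float((areas_m2.astype(float) ** 2).sum())

    mesh_hm2 = sum_sq / total_area_m2 / M2_PER_HM2
    split = total_area_m2 ** 2 / sum_sq
    division = 1.0 - sum_sq / total_area_m2 ** 2
    pd_per_100hm2 = n_patches / (total_area_m2 / M2_PER_HM2) * 100.0
    lpi = areas_m2.max() / total_area_m2 * 100.0
    area_am_hm2 = sum_sq / areas_m2.sum() / M2_PER_HM2
    shape_mn = float(np.mean(0.25 * perims_m / np.sqrt(areas_m2)))
    lsi = 0.25 * perims_m.sum() / np.sqrt(total_area_m2)
    ai = _aggregation_index(n_green, g_total)

    return pd.Series(
        {"MESH": mesh_hm2, "SPLIT": split, "AI": ai, "AREA_AM": area_am_hm2,
         "SHAPE_MN": shape_mn, "DIVISION": division, "PD": pd_per_100hm2,
         "LPI": lpi, "LSI": lsi},
        name=park_id or None,
    )


def _aggregation_index(n_cells: int, g_actual: int) -> float:
    """AI = 100 * g / max_g; max_g is the adjacency count of the most
    compact (square-ish) arrangement of n_cells. A single cell admits no
    adjacency; AI is defined as 0 there, with a warning."""
    m = int(np.floor(np.sqrt(n_cells)))
    if m * m == n_cells:
        max_g = 2 * m * (m - 1)
    elif n_cells <= m * (m + 1):
        max_g = 2 * m * (m - 1) + 2 * (n_cells - m * m) - 1
    else:
        max_g = 2 * m * (m - 1) + 2 * (n_cells - m * m) - 2
    if max_g == 0:
        warnings.warn("single-cell green class: AI defined as 0", stacklevel=3)
        return 0.0
    return 100.0 * g_actual / max_g


def indices_table(grids: dict[str, tuple[np.ndarray, float]]) -> pd.DataFrame:
    """Patch-index matrix over parks: rows park_id, columns the nine indices."""
    rows = [compute_patch_indices(arr, cell, park_id=pid)
            for pid, (arr, cell) in grids.items()]
    return pd.DataFrame(rows)


# ------------------------------------------------------- standardization


def standardize_indices(matrix: pd.DataFrame) -> pd.DataFrame:
    """Direction-aware min-max standardization to [0, 1].

    Positive indices map by (x-min)/(max-min); negative indices are
    inverted, (max-x)/(max-min), so larger always means better green
    structure. A constant column carries no ordering information and maps
    to 0.5 with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 parks")
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for col in matrix.columns:
        x = matrix[col].astype(float)
        lo, hi = x.min(), x.max()
        if np.isclose(hi, lo):
            warnings.warn(f"index {col} is constant across parks; mapped to 0.5",
                          stacklevel=2)
            out[col] = 0.5
        elif col in POSITIVE_INDICES:
            out[col] = (x - lo) / (hi - lo)
        else:
            out[col] = (hi - x) / (hi - lo)
    return out


# ------------------------------------------------------------ PCA / ESV


def esv_from_pca(standardized: pd.DataFrame) -> pd.Series:
    """Integrate the standardized indices into one ESV score per park.

    The columns are z-scored and decomposed via the correlation matrix;
    components with eigenvalue above 1 are retained (first component as a
    fallback when none qualifies). Component scores are combined with
    weights proportional to explained variance, and the composite is
    affinely rescaled to mean 50, standard deviation 25 across parks —
    scores can therefore be negative for strongly fragmented parks.

    Eigenvector sign is fixed by making each vector's largest-magnitude
    entry positive, so scores are reproducible across solvers.
    """
    if len(standardized) < 3:
        raise ValueError("ESV integration needs at least 3 parks")
    X = standardized.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        warnings.warn("all indices constant; ESV set to 50 for every park",
                      stacklevel=2)
        return pd.Series(50.0, index=standardized.index, name="ESV")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # deterministic sign: dominant loading positive
    for c in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[j, c] < 0:
            eigvec[:, c] = -eigvec[:, c]

    retained = eigval > 1.0
    if not retained.any():
        retained[0] = True
    lam = eigval[retained]
    scores = Z @ eigvec[:, retained]
    raw = scores @ (lam / lam.sum())

    sd_raw = raw.std()
    if sd_raw < 1e-12:
        esv = np.full(len(raw), 50.0)
    else:
        esv = 50.0 + 25.0 * (raw - raw.mean()) / sd_raw
    return pd.Series(esv, index=standardized.index, name="ESV")


# ------------------------------------------------------------------ FCs


def compute_fcs(park: Park, hard_area_m2: float | None = None) -> float:
    """Hard-surface area in hm^2, the proxy for facility carrying capacity.

    Uses an explicit hard-surface area (m^2) when given, otherwise the
    park's hard fraction times its area.
    """
    if hard_area_m2 is not None:
        if hard_area_m2 < 0:
            raise ValueError(f"hard_area_m2 must be >= 0, got {hard_area_m2}")
        fcs = hard_area_m2 / M2_PER_HM2
    else:
        if park.hard_fraction < 0:
            raise ValueError(
                f"{park.park_id}: hard fraction must be >= 0, got {park.hard_fraction}")
        fcs = park.hard_fraction * park.area_hm2
    if fcs > park.area_hm2 + 1e-9:
        raise ValueError(f"{park.park_id}: hard surface exceeds park area")
    return fcs


# ------------------------------------------------------------------ AHP

#: Saaty random consistency index by matrix order.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
            8: 1.41, 9: 1.45, 10: 1.49}


def ahp_weights(judgment: np.ndarray) -> SupplyWeights:
    """Weights and consistency ratio from a pairwise judgment matrix.

    The matrix rows/columns are ordered (S, FCs, ESV). Weights are the
    normalized principal eigenvector; CR = ((lambda_max - n)/(n - 1)) / RI(n).
    Raises on a non-reciprocal matrix (a_ji must equal 1/a_ij, a_ii = 1).
    """
    A = np.asarray(judgment, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or n < 2:
        raise ValueError("judgment matrix must be square, order >= 2")
    if not np.allclose(np.diag(A), 1.0, atol=1e-9):
        raise ValueError("judgment matrix diagonal must be all 1")
    if not np.allclose(A * A.T, np.ones_like(A), rtol=1e-6):
        raise ValueError("judgment matrix is not reciprocal (a_ji != 1/a_ij)")

    eigval, eigvec = np.linalg.eig(A)
    k = int(np.argmax(eigval.real))
    lam_max = float(eigval[k].real)
    w = np.abs(eigvec[:, k].real)
    w = w / w.sum()

    if n <= 2:
        cr = 0.0
    else:
        ri = SAATY_RI.get(n)
        if ri is None:
            raise ValueError(f"no Saaty random index for order {n}")
        cr = ((lam_max - n) / (n - 1)) / ri
    cr = max(cr, 0.0)

    if n != 3:
        raise ValueError("SupplyWeights holds three attributes; pass a 3x3 matrix")
    return SupplyWeights(w_s=float(w[0]), w_fcs=float(w[1]), w_esv=float(w[2]),
                         cr=float(cr))


def ahp_raw(judgment: np.ndarray) -> tuple[np.ndarray, float]:
    """General-order AHP: (weights, CR) for any supported matrix order."""
    A = np.asarray(judgment, dtype=float)
    n = A.shape[0]
    if not np.allclose(A * A.T, np.ones_like(A), rtol=1e-6):
        raise ValueError("judgment matrix is not reciprocal")
    eigval, eigvec = np.linalg.eig(A)
    k = int(np.argmax(eigval.real))
    lam_max = float(eigval[k].real)
    w = np.abs(eigvec[:, k].real)
    w = w / w.sum()
    cr = 0.0 if n <= 2 else max(((lam_max - n) / (n - 1)) / SAATY_RI[n], 0.0)
    return w, cr


# --------------------------------------------------------- park quality


def park_qualities(parks: list[Park],
                   landcover: dict[str, tuple[np.ndarray, float]]) -> dict[str, ParkQuality]:
    """Assemble ParkQuality for every park from land-cover rasters.

    ``landcover`` maps park_id to (binary raster, cell size). ESV is a
    cross-park composite, so all parks are scored together.
    """
    table = indices_table(landcover)
    esv = esv_from_pca(standardize_indices(table))
    out = {}
    for park in parks:
        out[park.park_id] = ParkQuality(
            park_id=park.park_id,
            S=park.area_hm2,
            ESV=float(esv.loc[park.park_id]),
            FCs=compute_fcs(park),
        )
    return out


def quality_table(qualities: dict[str, ParkQuality]) -> pd.DataFrame:
    """`park_quality.csv` layout: park_id, S_hm2, ESV, FCs_hm2."""
    return pd.DataFrame(
        [{"park_id": q.park_id, "S_hm2": q.S, "ESV": q.ESV, "FCs_hm2": q.FCs}
         for q in qualities.values()]
    ).set_index("park_id")
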