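"""Per-park binary land-cover rasters with a controlled number of green patches.

Each park gets a raster over its bounding box in which green cells (value 1)
form exactly ``n_patches`` 4-connected components, grown from well-separated
seed cells by randomized region growth restricted to the park polygon. The
patch count is the fragmentation dial the landscape-pattern indices respond
to: one patch is an intact green space, many patches a fragmented one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.measure import label as cc_label

from parkequity.types import Park


@dataclasses.dataclass
class Grid:
    """A raster with Esri-ASCII-style georeferencing.

    ``data[0, 0]`` is the top-left (north-west) cell; ``xll``/``yll`` locate
    the lower-left corner of the lower-left cell.
    """

    data: np.ndarray
    xll: float
    yll: float
    cell: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _cells_inside(polygon: Polygon, xll: float, yll: float, cell: float,
                  nrows: int, ncols: int) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the polygon."""
    cols = xll + (np.arange(ncols) + 0.5) * cell
    rows = yll + (nrows - np.arange(nrows) - 0.5) * cell
    xx, yy = np.meshgrid(cols, rows)
    return shapely.contains_xy(polygon, xx, yy)


def generate_park_landcover(
    park: Park,
    n_patches: int,
    seed: int,
    cell_size: float = 1.0,
    green_fraction: float = 0.7,
    max_tries: int = 20,
) -> Grid:
    """Generate the park's binary land-cover raster.

    Exactly ``n_patches`` 4-connected green components are produced; the
    green area is ``green_fraction`` of the park's interior cells (all of
    them when the fraction is 1 and a single patch is requested). The result
    is deterministic in ``seed``.

    Raises ``ValueError`` when the patch count is infeasible for the raster
    (more patches than can be mutually separated).
    """
    if n_patches < 1:
        raise ValueError(f"n_patches must be >= 1, got {n_patches}")
    if not (0 < green_fraction <= 1):
        raise ValueError(f"green_fraction must be in (0, 1], got {green_fraction}")

    minx, miny, maxx, maxy = park.polygon.bounds
    ncols = max(1, int(np.ceil((maxx - minx) / cell_size)))
    nrows = max(1, int(np.ceil((maxy - miny) / cell_size)))
    inside = _cells_inside(park.polygon, minx, miny, cell_size, nrows, ncols)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("park polygon contains no raster cell centers")
    if n_patches > n_inside:
        raise ValueError(
            f"n_patches={n_patches} infeasible: only {n_inside} cells inside park"
        )

    rng = np.random.default_rng(seed)
    target = max(n_patches, int(round(green_fraction * n_inside)))

    for attempt in range(max_tries):
        grid = _grow(inside, n_patches, target, rng)
        if grid is None:
            continue
        n_cc = cc_label(grid, connectivity=1).max()
        if n_cc == n_patches:
            return Grid(data=grid.astype(np.int8), xll=minx, yll=miny, cell=cell_size)
    raise ValueError(
        f"could not realize {n_patches} separated patches in a "
        f"{nrows}x{ncols} raster after {max_tries} attempts"
    )


def _grow(inside: np.ndarray, n_patches: int, target: int,
          rng: np.random.Generator) -> np.ndarray | None:
    """One randomized growth attempt; returns the binary grid or None."""
    nrows, ncols = inside.shape
    ii, jj = np.nonzero(inside)
    coords = np.column_stack([ii, jj])

    # Greedy farthest-point seeds so patches start well separated.
    first = rng.integers(len(coords))
    seeds = [coords[first]]
    if n_patches > 1:
        d2 = ((coords - seeds[0]) ** 2).sum(axis=1).astype(float)
        for _ in range(n_patches - 1):
            nxt = int(np.argmax(d2))
            if d2[nxt] <= 2:  # seeds would be adjacent — infeasible layout
                return None
            seeds.append(coords[nxt])
            d2 = np.minimum(d2, ((coords - seeds[-1]) ** 2).sum(axis=1))

    owner = np.full(inside.shape, -1, dtype=np.int32)  # -1 free, else patch id
    frontiers: list[list[tuple[int, int]]] = [[] for _ in range(n_patches)]
    for p, (r, c) in enumerate(seeds):
        owner[r, c] = p
        frontiers[p].append((int(r), int(c)))
    n_green = n_patches

    offs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    while n_green < target:
        open_patches = [p for p in range(n_patches) if frontiers[p]]
        if not open_patches:
            break
        grew_any = False
        for p in open_patches:
            if n_green >= target:
                break
            fr = frontiers[p]
            # pop a random frontier cell and try to claim a random neighbor
            idx = rng.integers(len(fr))
            fr[idx], fr[-1] = fr[-1], fr[idx]
            r, c = fr[-1]
            order = rng.permutation(4)
            claimed = False
            for o in order:
                dr, dc = offs[o]
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols):
                    continue
                if not inside[nr, nc] or owner[nr, nc] != -1:
                    continue
                # keep patches 4-separated: no neighbor may touch another patch
                touches_other = False
                for dr2, dc2 in offs:
                    ar, ac = nr + dr2, nc + dc2
                    if 0 <= ar < nrows and 0 <= ac < ncols:
                        if owner[ar, ac] not in (-1, p):
                            touches_other = True
                            break
                if touches_other:
                    continue
                owner[nr, nc] = p
                fr.append((nr, nc))
                n_green += 1
                claimed = True
                grew_any = True
                break
            if not claimed:
                fr.pop()  # cell exhausted
        if not grew_any and not any(frontiers[p] for p in range(n_patches)):
            break

    if n_green < n_patches:
        return None
    return (owner >= 0)
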