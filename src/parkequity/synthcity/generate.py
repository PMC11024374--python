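"""Synthetic-city generation.

The generator produces, deterministically from a seed: a jittered grid road
network; residences rejection-sampled with a configurable core/periphery
density ratio; a housing-price surface (linear distance-to-center gradient
plus moving-average-smoothed correlated noise); rectangular parks per size
class with 1-4 boundary entrances snapped to road nodes; candidate parcels
for future parks; and a regular grid of administrative blocks carrying mean
household sizes.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box
from shapely.ops import nearest_points

from parkequity.synthcity.config import ConfigurationError, ScenarioConfig
from parkequity.types import PARK_CLASSES, Block, City, M2_PER_HM2, Park, Residence


def generate_city(config: ScenarioConfig) -> City:
    """Generate a city from a validated scenario config.

    Deterministic given ``config.seed``: two calls with the same config
    produce identical cities.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width, height = config.extent

    roads = _road_network(config, rng)
    blocks = _blocks(config, rng)
    residences = _residences(config, rng, blocks)
    parks = _parks(config, rng, roads)
    parcels = _parcels(config, rng, parks)

    return City(
        parks=parks,
        residences=residences,
        roads=roads,
        parcels=parcels,
        blocks=blocks,
        extent=(width, height),
    )


# ---------------------------------------------------------------- roads


def _road_network(config: ScenarioConfig, rng: np.random.Generator) -> nx.Graph:
    width, height = config.extent
    s = config.road_grid.spacing_m
    jit = config.road_grid.jitter_fraction * s
    nx_nodes = int(width // s) + 1
    ny_nodes = int(height // s) + 1

    graph = nx.Graph()
    node_id = {}
    for gy in range(ny_nodes):
        for gx in range(nx_nodes):
            x = np.clip(gx * s + rng.uniform(-jit, jit), 0, width)
            y = np.clip(gy * s + rng.uniform(-jit, jit), 0, height)
            nid = gy * nx_nodes + gx
            node_id[(gx, gy)] = nid
            graph.add_node(nid, x=float(x), y=float(y))
    for (gx, gy), nid in node_id.items():
        for dx, dy in ((1, 0), (0, 1)):
            other = node_id.get((gx + dx, gy + dy))
            if other is not None:
                ax, ay = graph.nodes[nid]["x"], graph.nodes[nid]["y"]
                bx, by = graph.nodes[other]["x"], graph.nodes[other]["y"]
                graph.add_edge(nid, other, length_m=float(math.hypot(bx - ax, by - ay)))
    return graph


# ---------------------------------------------------------------- blocks


def _blocks(config: ScenarioConfig, rng: np.random.Generator) -> list[Block]:
    width, height = config.extent
    bx, by = config.blocks.nx, config.blocks.ny
    lo, hi = config.blocks.mean_household_size_range
    out = []
    for iy in range(by):
        for ix in range(bx):
            poly = box(ix * width / bx, iy * height / by,
                       (ix + 1) * width / bx, (iy + 1) * height / by)
            out.append(Block(
                block_id=f"B{iy * bx + ix:03d}",
                polygon=poly,
                mean_household_size=float(rng.uniform(lo, hi)),
            ))
    return out


def _block_for(blocks: list[Block], config: ScenarioConfig, x: float, y: float) -> Block:
    width, height = config.extent
    bx, by = config.blocks.nx, config.blocks.ny
    ix = min(int(x / width * bx), bx - 1)
    iy = min(int(y / height * by), by - 1)
    return blocks[iy * bx + ix]


# ------------------------------------------------------------ residences


def _in_core(config: ScenarioConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    w, h = config.extent
    return (x >= w / 4) & (x <= 3 * w / 4) & (y >= h / 4) & (y <= 3 * h / 4)


def _residences(config: ScenarioConfig, rng: np.random.Generator,
                blocks: list[Block]) -> list[Residence]:
    width, height = config.extent
    n = config.n_residences
    ratio = config.core_density_ratio

    # Rejection sampling from a two-level density: core keeps every draw,
    # periphery keeps 1/ratio of them.
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(64, 2 * (n - got))
        cx = rng.uniform(0, width, m)
        cy = rng.uniform(0, height, m)
        accept = _in_core(config, cx, cy) | (rng.uniform(size=m) < 1.0 / ratio)
        cx, cy = cx[accept], cy[accept]
        take = min(len(cx), n - got)
        xs[got:got + take] = cx[:take]
        ys[got:got + take] = cy[:take]
        got += take

    prices = _price_surface(config, rng, xs, ys)
    households = rng.integers(config.households_range[0],
                              config.households_range[1] + 1, size=n)

    out = []
    for i in range(n):
        blk = _block_for(blocks, config, xs[i], ys[i])
        out.append(Residence(
            residence_id=f"R{i:04d}",
            point=Point(float(xs[i]), float(ys[i])),
            households=int(households[i]),
            population=float(households[i] * blk.mean_household_size),
            price=float(prices[i]),
            block_id=blk.block_id,
        ))
    return out


def _price_surface(config: ScenarioConfig, rng: np.random.Generator,
                   xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Base minus distance-to-center gradient plus correlated noise.

    The noise is white noise on a coarse grid smoothed with a moving-average
    window one correlation length wide, rescaled to unit variance and then
    to the configured amplitude — a light-weight stand-in for a Gaussian
    process with that correlation length.
    """
    width, height = config.extent
    pf = config.price_field
    cx, cy = width / 2, height / 2
    dist = np.hypot(xs - cx, ys - cy)
    price = pf.base - pf.gradient_slope * dist

    if pf.noise_amplitude > 0 and len(xs) > 0:
        cell = max(pf.correlation_length_m / 4.0, 1.0)
        gnx = int(width / cell) + 2
        gny = int(height / cell) + 2
        noise = rng.standard_normal((gny, gnx))
        win = max(int(round(pf.correlation_length_m / cell)), 1)
        smooth = uniform_filter(noise, size=win, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        sampled = map_coordinates(smooth, [ys / cell, xs / cell], order=1,
                                  mode="nearest")
        price = price + pf.noise_amplitude * sampled
    return price


# ---------------------------------------------------------------- parks


def _rect_park(rng: np.random.Generator, area_m2: float,
               width: float, height: float) -> Polygon | None:
    aspect = rng.uniform(0.5, 2.0)
    w = math.sqrt(area_m2 * aspect)
    h = area_m2 / w
    if w > width or h > height:
        return None
    x0 = rng.uniform(0, width - w)
    y0 = rng.uniform(0, height - h)
    return box(x0, y0, x0 + w, y0 + h)


def _parks(config: ScenarioConfig, rng: np.random.Generator,
           roads: nx.Graph) -> list[Park]:
    width, height = config.extent
    nodes = list(roads.nodes)
    node_xy = np.array([[roads.nodes[n]["x"], roads.nodes[n]["y"]] for n in nodes])
    tree = cKDTree(node_xy)

    parks: list[Park] = []
    placed: list[Polygon] = []
    placed_cls: list[str] = []
    idx = 0
    for cls in PARK_CLASSES:
        count = config.park_mix.get(cls, 0)
        lo, hi = config.park_area_ranges[cls]
        for _ in range(count):
            area_hm2 = float(rng.uniform(lo, hi))
            area_m2 = area_hm2 * M2_PER_HM2
            want_core = bool(rng.uniform() < config.small_park_core_bias)
            valid: list[Polygon] = []
            cand = None
            for _try in range(200):
                cand = _rect_park(rng, area_m2, width, height)
                if cand is None:
                    raise ConfigurationError(
                        f"park_area_ranges[{cls}]: park of {area_hm2:.2f} hm^2 "
                        f"does not fit in extent {config.extent}"
                    )
                # small parks follow the dense fabric; larger parks need
                # open land and avoid the core
                c = cand.centroid
                c_core = bool(_in_core(config, np.array([c.x]), np.array([c.y]))[0])
                if cls in ("community", "regional"):
                    if want_core != c_core:
                        continue
                elif c_core and rng.uniform() < config.park_core_exclusion:
                    continue
                if any(cand.intersects(p) for p in placed):
                    continue
                valid.append(cand)
                if cls in ("community", "regional") or len(valid) >= 40:
                    break
            if not valid:
                poly = cand  # dense scenario: allow overlap after many tries
            elif cls in ("community", "regional"):
                poly = valid[0]
            else:
                # large parks are planned spread out: best-candidate
                # sampling maximizes distance to large parks already placed
                anchors = [p for p, pc in zip(placed, placed_cls)
                           if pc in ("citywide", "comprehensive")]
                if not anchors:
                    poly = valid[0]
                else:
                    poly = max(valid, key=lambda v: min(
                        v.centroid.distance(a.centroid) for a in anchors))
            placed.append(poly)
            placed_cls.append(cls)

            n_ent = int(rng.integers(1, 5))
            ent_pts, ent_nodes = _entrances(poly, tree, node_xy, nodes, n_ent)
            parks.append(Park(
                park_id=f"P{idx:03d}",
                polygon=poly,
                park_class=cls,
                area_hm2=area_hm2,
                entrances=ent_pts,
                entrance_nodes=ent_nodes,
                hard_fraction=float(rng.uniform(*config.hard_fraction_range)),
                n_patches=int(rng.integers(config.fragmentation_levels[0],
                                           config.fragmentation_levels[1] + 1)),
            ))
            idx += 1
    return parks


def _entrances(poly: Polygon, tree: cKDTree, node_xy: np.ndarray,
               nodes: list, n_ent: int) -> tuple[list[tuple[float, float]], list[int]]:
    """Entrances are boundary points nearest to the n_ent distinct road
    nodes closest to the park boundary."""
    centroid = poly.centroid
    # query generously, then rank candidate nodes by distance to the boundary
    k = min(len(nodes), max(16, 4 * n_ent))
    _, cand = tree.query([centroid.x, centroid.y], k=k)
    cand = np.atleast_1d(cand)
    bdist = [(poly.exterior.distance(Point(node_xy[c])), c) for c in cand]
    bdist.sort()
    pts, nids = [], []
    for _, c in bdist[:n_ent]:
        node_pt = Point(node_xy[c])
        on_boundary = nearest_points(poly.exterior, node_pt)[0]
        pts.append((float(on_boundary.x), float(on_boundary.y)))
        nids.append(int(nodes[c]))
    return pts, nids


# --------------------------------------------------------------- parcels


def _parcels(config: ScenarioConfig, rng: np.random.Generator,
             parks: list[Park]) -> list[Polygon]:
    width, height = config.extent
    lo, hi = config.parcel_area_range_hm2
    out: list[Polygon] = []
    for _ in range(config.n_candidate_parcels):
        area_m2 = float(rng.uniform(lo, hi)) * M2_PER_HM2
        poly = None
        for _try in range(100):
            cand = _rect_park(rng, area_m2, width, height)
            if cand is None:
                raise ConfigurationError(
                    f"parcel_area_range_hm2: parcel of {area_m2 / M2_PER_HM2:.2f} "
                    f"hm^2 does not fit in extent {config.extent}"
                )
            if all(not cand.intersects(p.polygon) for p in parks):
                poly = cand
                break
        out.append(poly if poly is not None else cand)
    return out
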