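"""Gaussian two-step floating catchment area (G2SFCA) accessibility.

Step 1 computes each park's supply-demand ratio R_j: composite supply
C_j = w_s*S_j + w_fcs*FCs_j + w_esv*ESV_j divided by the Gaussian-weighted
population within the park's catchment radius d0. Step 2 sums the
distance-weighted ratios over all parks reachable from each residence:
A_i = sum_j G(d_ij, d0_j) * R_j. Distances are network walking distances:
each residence snaps to its nearest road node (the Euclidean connector is
added) and reaches a park through its nearest entrance, so each
(residence, park) pair contributes exactly once — the park, not each
entrance, is the supply unit.

The decay kernel is the truncated Gaussian
G(d, d0) = (exp(-(d/d0)^2 / 2) - exp(-1/2)) / (1 - exp(-1/2)) for d <= d0
and 0 beyond, which is 1 at the gate and falls continuously to 0 at the
catchment edge.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from parkequity.quality import ParkQuality, SupplyWeights
from parkequity.types import CLASS_RADII_M, City, Park

logger = logging.getLogger(__name__)

_HALF = math.exp(-0.5)


@dataclass
class CatchmentConfig:
    """Catchment radii: one uniform d0, or the class-specific radii
    (community 500 m, regional 1000 m, citywide 2000 m, comprehensive
    3000 m) overlaid into a comprehensive score."""

    mode: str = "type_specific"  # "uniform" | "type_specific"
    d0_uniform: float = 2000.0
    d0_by_class: dict[str, float] = field(default_factory=lambda: dict(CLASS_RADII_M))

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "type_specific"):
            raise ValueError(f"unknown catchment mode {self.mode!r}")
        if self.d0_uniform <= 0 or any(v <= 0 for v in self.d0_by_class.values()):
            raise ValueError("all catchment radii must be > 0")

    def radius_for(self, park: Park) -> float:
        if self.mode == "uniform":
            return self.d0_uniform
        return self.d0_by_class[park.park_class]

    @property
    def max_radius(self) -> float:
        if self.mode == "uniform":
            return self.d0_uniform
        return max(self.d0_by_class.values())


class DistanceMatrix:
    """Sparse (residence, park) -> network meters, kept only within cutoff."""

    def __init__(self, entries: dict[tuple[str, str], float], cutoff: float):
        self.entries = entries
        self.cutoff = cutoff

    def get(self, residence_id: str, park_id: str) -> float | None:
        return self.entries.get((residence_id, park_id))

    def parks_of(self, residence_id: str):
        for (rid, pid), d in self.entries.items():
            if rid == residence_id:
                yield pid, d

    def __len__(self) -> int:
        return len(self.entries)


# ----------------------------------------------------------- distances


def _snap(points: np.ndarray, node_xy: np.ndarray, node_ids: list,
          snap_limit: float) -> tuple[list, np.ndarray, np.ndarray]:
    """Nearest-node snap; returns (node per point, connector m, included mask)."""
    tree = cKDTree(node_xy)
    dists, idx = tree.query(points)
    included = dists <= snap_limit
    if not included.all():
        warnings.warn(
            f"{int((~included).sum())} point(s) farther than {snap_limit} m "
            "from any road node were excluded", stacklevel=3)
    return [node_ids[i] for i in idx], dists, included


def network_distance(roads: nx.Graph, origins: list[tuple[float, float]],
                     destinations: list[tuple[float, float]], cutoff: float,
                     snap_limit: float = 500.0) -> dict[tuple[int, int], float]:
    """Truncated network distances between two point sets.

    Each point snaps to its nearest road node and the Euclidean connector is
    added on both ends; Dijkstra runs per destination, truncated at the
    cutoff. Returns {(origin index, destination index): meters} for pairs
    within the cutoff. Points beyond ``snap_limit`` of any node are excluded
    with a warning.
    """
    if roads.number_of_nodes() == 0:
        raise ValueError("road network is empty")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    node_ids = list(roads.nodes)
    node_xy = np.array([[roads.nodes[n]["x"], roads.nodes[n]["y"]] for n in node_ids])

    o_nodes, o_conn, o_in = _snap(np.asarray(origins, dtype=float), node_xy,
                                  node_ids, snap_limit)
    d_nodes, d_conn, d_in = _snap(np.asarray(destinations, dtype=float), node_xy,
                                  node_ids, snap_limit)

    max_o_conn = float(o_conn[o_in].max()) if o_in.any() else 0.0
    out: dict[tuple[int, int], float] = {}
    for j, (dn, dc, ok) in enumerate(zip(d_nodes, d_conn, d_in)):
        if not ok:
            continue
        lengths = nx.single_source_dijkstra_path_length(
            roads, dn, cutoff=cutoff - dc + max_o_conn, weight="length_m")
        for i, (on, oc, ook) in enumerate(zip(o_nodes, o_conn, o_in)):
            if not ook or on not in lengths:
                continue
            d = oc + lengths[on] + dc
            if d <= cutoff:
                out[(i, j)] = float(d)
    return out


def residence_park_distances(city: City, cutoff: float,
                             snap_limit: float = 500.0,
                             parks: list[Park] | None = None) -> DistanceMatrix:
    """Network distance from every residence to every park within cutoff.

    A park is reached through its nearest entrance: a multi-source Dijkstra
    from the park's entrance nodes (seeded with each entrance's own
    node-to-gate connector) realizes the min over entrances in one sweep.
    """
    parks = city.parks if parks is None else parks
    roads = city.roads
    if roads.number_of_nodes() == 0:
        raise ValueError("road network is empty")
    node_ids = list(roads.nodes)
    node_xy = np.array([[roads.nodes[n]["x"], roads.nodes[n]["y"]] for n in node_ids])
    pts = city.residence_points()
    r_nodes, r_conn, r_in = _snap(pts, node_xy, node_ids, snap_limit)

    max_conn = float(r_conn[r_in].max()) if r_in.any() else 0.0
    entries: dict[tuple[str, str], float] = {}
    for park in parks:
        if not park.entrance_nodes:
            continue
        # seed offsets: distance from the boundary gate to its road node
        seeds = {}
        for (ex, ey), node in zip(park.entrances, park.entrance_nodes):
            nx_, ny_ = roads.nodes[node]["x"], roads.nodes[node]["y"]
            off = math.hypot(ex - nx_, ey - ny_)
            if node not in seeds or off < seeds[node]:
                seeds[node] = off
        lengths = _multi_source_dijkstra(roads, seeds,
                                         cutoff=cutoff + max_conn)
        for i, res in enumerate(city.residences):
            if not r_in[i]:
                continue
            node = r_nodes[i]
            if node not in lengths:
                continue
            d = r_conn[i] + lengths[node]
            if d <= cutoff:
                entries[(res.residence_id, park.park_id)] = float(d)
    return DistanceMatrix(entries, cutoff)


def _multi_source_dijkstra(graph: nx.Graph, seeds: dict[int, float],
                           cutoff: float) -> dict[int, float]:
    """Dijkstra from several sources with per-source starting offsets."""
    import heapq

    dist: dict[int, float] = {}
    heap = [(off, node) for node, off in seeds.items()]
    heapq.heapify(heap)
    while heap:
        d, node = heapq.heappop(heap)
        if node in dist or d > cutoff:
            continue
        dist[node] = d
        for nbr, data in graph[node].items():
            nd = d + data["length_m"]
            if nbr not in dist and nd <= cutoff:
                heapq.heappush(heap, (nd, nbr))
    return dist


# ---------------------------------------------------------------- decay


def gaussian_decay(d, d0: float):
    """Truncated Gaussian decay weight in [0, 1]; accepts scalars or arrays."""
    if d0 <= 0:
        raise ValueError(f"d0 must be > 0, got {d0}")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be >= 0")
    w = (np.exp(-0.5 * (d / d0) ** 2) - _HALF) / (1.0 - _HALF)
    w = np.where(d >= d0, 0.0, w)
    return float(w) if w.ndim == 0 else w


# ----------------------------------------------------------- G2SFCA


def park_supply(quality: ParkQuality, weights: SupplyWeights) -> float:
    """Composite supply C_j; negative composites (possible because ESV may
    be negative) are floored at 0 with a warning."""
    c = weights.w_s * quality.S + weights.w_fcs * quality.FCs + weights.w_esv * quality.ESV
    if c < 0:
        warnings.warn(f"{quality.park_id}: negative composite supply {c:.4f} "
                      "floored at 0", stacklevel=2)
        return 0.0
    return float(c)


def supply_demand_ratios(city: City, qualities: dict[str, ParkQuality],
                         weights: SupplyWeights, catchment: CatchmentConfig,
                         distances: DistanceMatrix,
                         parks: list[Park] | None = None) -> pd.DataFrame:
    """Step 1: per-park C_j, Gaussian-weighted demand D_j, ratio R_j.

    R_j = 0 when no residence lies within the park's catchment (logged)."""
    parks = city.parks if parks is None else parks
    pop = {r.residence_id: r.population for r in city.residences}
    rows = []
    for park in parks:
        d0 = catchment.radius_for(park)
        c_j = park_supply(qualities[park.park_id], weights)
        d_j = 0.0
        for res in city.residences:
            d = distances.get(res.residence_id, park.park_id)
            if d is not None and d < d0:
                d_j += gaussian_decay(d, d0) * pop[res.residence_id]
        if d_j == 0.0:
            logger.info("park %s has no weighted demand within %.0f m; R_j = 0",
                        park.park_id, d0)
            r_j = 0.0
        else:
            r_j = c_j / d_j
        rows.append({"park_id": park.park_id, "C_j": c_j, "D_j": d_j, "R_j": r_j})
    return pd.DataFrame(rows).set_index("park_id")


def accessibility(city: City, ratios: pd.DataFrame, distances: DistanceMatrix,
                  catchment: CatchmentConfig,
                  parks: list[Park] | None = None) -> pd.DataFrame:
    """Step 2: A_i = sum over in-range parks of G(d_ij, d0_j) * R_j.

    Residences with no park in range get A_i = 0. Returns a table indexed
    by residence_id with columns A and population."""
    parks = city.parks if parks is None else parks
    d0_by_park = {p.park_id: catchment.radius_for(p) for p in parks}
    a = {r.residence_id: 0.0 for r in city.residences}
    for (rid, pid), d in distances.entries.items():
        d0 = d0_by_park.get(pid)
        if d0 is None or d >= d0:
            continue
        a[rid] += gaussian_decay(d, d0) * float(ratios.loc[pid, "R_j"])
    return pd.DataFrame({
        "A": pd.Series(a),
        "population": pd.Series({r.residence_id: r.population
                                 for r in city.residences}),
    }).rename_axis("residence_id")


def compute_accessibility(city: City, qualities: dict[str, ParkQuality],
                          weights: SupplyWeights, catchment: CatchmentConfig,
                          distances: DistanceMatrix | None = None,
                          parks: list[Park] | None = None) -> pd.DataFrame:
    """Both G2SFCA steps under one catchment config."""
    parks = city.parks if parks is None else parks
    if distances is None:
        distances = residence_park_distances(city, catchment.max_radius,
                                             parks=parks)
    ratios = supply_demand_ratios(city, qualities, weights, catchment,
                                  distances, parks=parks)
    return accessibility(city, ratios, distances, catchment, parks=parks)


def accessibility_profile(city: City, qualities: dict[str, ParkQuality],
                          weights: SupplyWeights,
                          uniform_radii=(500.0, 1000.0, 2000.0, 3000.0),
                          n_classes: int = 5,
                          parks: list[Park] | None = None) -> pd.DataFrame:
    """The full accessibility table: one column per uniform walking
    distance, the comprehensive type-specific score, and its geometric-
    interval class."""
    parks = city.parks if parks is None else parks
    max_r = max(max(uniform_radii), max(CLASS_RADII_M.values()))
    distances = residence_park_distances(city, max_r, parks=parks)
    out = {}
    for r in uniform_radii:
        cc = CatchmentConfig(mode="uniform", d0_uniform=r)
        out[f"A_{int(r)}"] = compute_accessibility(
            city, qualities, weights, cc, distances, parks=parks)["A"]
    cc = CatchmentConfig(mode="type_specific")
    comp = compute_accessibility(city, qualities, weights, cc, distances,
                                 parks=parks)
    out["A_comprehensive"] = comp["A"]
    table = pd.DataFrame(out)
    table["population"] = comp["population"]
    vals = table["A_comprehensive"].to_numpy()
    # degenerate small scenes: fewer distinct positive scores than classes
    n_distinct = len(np.unique(vals[vals > 0]))
    if n_distinct >= 2:
        labels, breaks, low_upper = classify_geometric(
            vals, min(n_classes, n_distinct))
    else:
        labels = (vals > 0).astype(int)
        breaks, low_upper = [], float(vals.max())
    table["access_class"] = labels
    table.attrs["breaks"] = breaks
    table.attrs["lowest_class_upper"] = low_upper
    return table.rename_axis("residence_id")


# ------------------------------------------------- geometric intervals


def classify_geometric(values: np.ndarray, n_classes: int
                       ) -> tuple[np.ndarray, list[float], float]:
    """Geometric-interval classification of accessibility scores.

    Zero scores form their own class (label 0). Positive scores are split
    into ``n_classes`` bands whose break points form a geometric
    progression between the smallest and largest positive score:
    b_m = a * (M/a)^(m/K). Labels run 1 (low) to K (high). Returns
    (labels, positive break points, upper bound of the lowest positive
    class)."""
    values = np.asarray(values, dtype=float)
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    labels = np.zeros(len(values), dtype=int)
    pos = values > 0
    if not pos.any():
        warnings.warn("all scores are zero; single zero class", stacklevel=2)
        return labels, [], 0.0
    a = values[pos].min()
    m_max = values[pos].max()
    distinct = np.unique(values[pos])
    if len(distinct) < n_classes:
        raise ValueError(
            f"need >= {n_classes} distinct positive values, got {len(distinct)}")
    ratio = m_max / a
    breaks = [float(a * ratio ** (m / n_classes)) for m in range(1, n_classes)]
    # a value sitting exactly on a break belongs to the lower class; the
    # tiny relative inflation keeps that decision stable against round-off
    edges = np.array(breaks) * (1 + 1e-9)
    labels[pos] = 1 + np.searchsorted(edges, values[pos], side="left")
    return labels, breaks, breaks[0] if breaks else float(m_max)
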