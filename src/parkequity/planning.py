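"""Blind-zone identification and new-park siting.

Explicit blind zones are residences that cannot reach any park entrance
within 3000 m of network walking; implicit blind zones are covered but
bottom-class served — dense areas whose demand swamps the nearby supply.
The optimization targets are the union of lowest-class residences and
significant L-L (low accessibility, low price) communities. The number of
new parks comes from a K-means curve (mean farthest member distance vs k,
knee at the largest positive second difference); their locations from a
global-best particle swarm minimizing population-weighted distance from
each target to its nearest site; land use enters afterwards by snapping
each site to the nearest free candidate parcel, whose area fixes the new
park's class and catchment radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points
from sklearn.cluster import KMeans

from parkequity.access import (
    DistanceMatrix,
    accessibility_profile,
    residence_park_distances,
)
from parkequity.equity import LisaResult, build_weights, bivariate_moran
from parkequity.quality import ParkQuality, SupplyWeights
from parkequity.types import City, M2_PER_HM2, Park, park_class_for_area, CLASS_RADII_M

EXPLICIT_CUTOFF_M = 3000.0

#: Class-typical quality defaults for not-yet-built parks: (ESV, hard
#: fraction). ESV uses the published class means; hard fraction a modest
#: recreational footprint.
DEFAULT_NEW_PARK_QUALITY = {
    "community": (77.53, 0.25),
    "regional": (-8.26, 0.15),
    "citywide": (42.74, 0.20),
    "comprehensive": (7.51, 0.20),
}


# ------------------------------------------------------------ blind zones


def identify_blind_zones(access_table: pd.DataFrame,
                         distances: DistanceMatrix) -> pd.DataFrame:
    """Label each residence explicit / implicit / none.

    ``access_table`` must carry A_comprehensive and access_class (0 = zero
    score, 1 = lowest positive class); ``distances`` must have been computed
    with a 3000 m cutoff so coverage is decidable.
    """
    if distances.cutoff < EXPLICIT_CUTOFF_M:
        raise ValueError("distances must be computed with a >= 3000 m cutoff")
    covered = {rid for (rid, _pid), d in distances.entries.items()
               if d <= EXPLICIT_CUTOFF_M}
    kinds = {}
    for rid, row in access_table.iterrows():
        if rid not in covered:
            kinds[rid] = "explicit"
        elif row["access_class"] <= 1:  # zero or lowest positive class
            kinds[rid] = "implicit"
        else:
            kinds[rid] = "none"
    return pd.DataFrame({"kind": pd.Series(kinds)}).rename_axis("residence_id")


def select_targets(access_table: pd.DataFrame, lisa: LisaResult) -> pd.DataFrame:
    """Optimization targets: lowest-class residences union significant L-L.

    Provenance records whether a residence qualified through low
    accessibility, the L-L coupling, or both."""
    low = set(access_table.index[access_table["access_class"] <= 1])
    lisa_frame = lisa.to_frame()
    ll = set(lisa_frame.index[lisa_frame["category"] == "LL"])
    union = sorted(low | ll)
    if not union:
        warnings.warn("no optimization targets: empty plan downstream", stacklevel=2)
    prov = {}
    for rid in union:
        if rid in low and rid in ll:
            prov[rid] = "both"
        elif rid in low:
            prov[rid] = "low_access"
        else:
            prov[rid] = "LL"
    return pd.DataFrame({"provenance": pd.Series(prov, dtype=object)}
                        ).rename_axis("residence_id")


# ------------------------------------------------------------- K curve


@dataclass
class KCurve:
    ks: list[int]
    values: list[float]  # mean farthest member distance per k
    chosen_k: int
    rule: str = "max_second_difference"


def target_features(access_table: pd.DataFrame, lisa: LisaResult,
                    target_ids: list[str]) -> np.ndarray:
    """Two clustering features per target: comprehensive accessibility and a
    socioeconomic-match score (local Moran), both min-max standardized."""
    lisa_frame = lisa.to_frame()
    a = access_table.loc[target_ids, "A_comprehensive"].to_numpy(dtype=float)
    m = lisa_frame.loc[target_ids, "local_I"].to_numpy(dtype=float)

    def minmax(v):
        span = v.max() - v.min()
        return np.zeros_like(v) if span == 0 else (v - v.min()) / span

    return np.column_stack([minmax(a), minmax(m)])


def kmeans_curve(features: np.ndarray, k_range=range(1, 13), n_init: int = 10,
                 seed: int = 0, k_override: int | None = None) -> KCurve:
    """Mean farthest-member distance per k; knee by max second difference."""
    X = np.asarray(features, dtype=float)
    n = len(X)
    ks = [k for k in k_range]
    if not ks or min(ks) < 1 or max(ks) > n:
        raise ValueError(f"k_range {ks} invalid for n={n} targets")
    degenerate = bool(np.allclose(X, X[0]))
    values = []
    for k in ks:
        if degenerate:
            values.append(0.0)
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        d = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
        far = [d[km.labels_ == c].max() for c in range(k) if (km.labels_ == c).any()]
        values.append(float(np.mean(far)))

    if k_override is not None:
        chosen = k_override
        rule = "override"
    elif len(ks) < 3:
        chosen = ks[0]
        rule = "first"
    else:
        v = np.array(values)
        second = v[:-2] - 2 * v[1:-1] + v[2:]  # at interior ks
        chosen = ks[1 + int(np.argmax(second))]
        rule = "max_second_difference"
    if np.allclose(values, 0.0):
        chosen, rule = 1, "degenerate_zero_curve"
    return KCurve(ks=ks, values=values, chosen_k=chosen, rule=rule)


# ----------------------------------------------------------------- PSO


def pso_site_selection(targets_xy: np.ndarray, populations: np.ndarray,
                       k: int, bounds: tuple[float, float, float, float],
                       n_particles: int = 30, n_iter: int = 200,
                       seed: int = 0) -> tuple[np.ndarray, list[float]]:
    """Global-best PSO for k park sites.

    Fitness of a candidate site set is the sum over targets of population
    times Euclidean distance to the nearest site. Constants: inertia 0.729,
    cognitive = social = 1.494, velocity clamped to 20% of the bounds span
    per axis. Returns (sites (k, 2), best-objective trace, one value per
    iteration); the trace is non-increasing. Deterministic given seed.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    T = np.asarray(targets_xy, dtype=float)
    P = np.asarray(populations, dtype=float)
    minx, miny, maxx, maxy = bounds
    lo = np.array([minx, miny])
    hi = np.array([maxx, maxy])
    span = hi - lo
    vmax = 0.2 * span

    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, size=(n_particles, k, 2))
    V = rng.uniform(-vmax, vmax, size=(n_particles, k, 2)) * 0.1

    def fitness(sites: np.ndarray) -> float:
        # (targets, sites) distances; min over sites
        d = np.linalg.norm(T[:, None, :] - sites[None, :, :], axis=2)
        f = float((P * d.min(axis=1)).sum())
        if not np.isfinite(f):
            raise ValueError("non-finite PSO fitness")
        return f

    pbest = X.copy()
    pbest_f = np.array([fitness(x) for x in X])
    g = int(np.argmin(pbest_f))
    gbest = pbest[g].copy()
    gbest_f = float(pbest_f[g])
    trace = [gbest_f]

    w, c1, c2 = 0.729, 1.494, 1.494
    for _ in range(n_iter):
        r1 = rng.uniform(size=(n_particles, k, 2))
        r2 = rng.uniform(size=(n_particles, k, 2))
        V = w * V + c1 * r1 * (pbest - X) + c2 * r2 * (gbest[None] - X)
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, lo, hi)
        for p in range(n_particles):
            f = fitness(X[p])
            if f < pbest_f[p]:
                pbest_f[p] = f
                pbest[p] = X[p].copy()
                if f < gbest_f:
                    gbest_f = f
                    gbest = X[p].copy()
        trace.append(gbest_f)
    return gbest, trace


# ------------------------------------------------------ class assignment


@dataclass
class SitingPlan:
    """New parks: PSO site, hosting parcel, and class/radius from its area."""

    sites: list[tuple[float, float]]
    parcel_ids: list[int]
    classes: list[str]
    radii_m: list[float]
    areas_hm2: list[float]
    objective_trace: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": [s[0] for s in self.sites],
            "y": [s[1] for s in self.sites],
            "parcel_id": self.parcel_ids,
            "park_class": self.classes,
            "radius_m": self.radii_m,
            "area_hm2": self.areas_hm2,
        })


def assign_park_classes(sites: np.ndarray, parcels: list[Polygon],
                        objective_trace: list[float] | None = None) -> SitingPlan:
    """Snap each site to the nearest unused candidate parcel (centroid
    distance); the parcel's area fixes class and catchment radius. One park
    per parcel — a contested parcel goes to the first site, later sites take
    their next-nearest free parcel."""
    sites = np.asarray(sites, dtype=float).reshape(-1, 2)
    if len(sites) > len(parcels):
        raise ValueError(
            f"{len(sites)} sites but only {len(parcels)} candidate parcels "
            f"(short by {len(sites) - len(parcels)})")
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in parcels])
    taken: set[int] = set()
    plan = SitingPlan(sites=[], parcel_ids=[], classes=[], radii_m=[],
                      areas_hm2=[],
                      objective_trace=list(objective_trace or []))
    for s in sites:
        order = np.argsort(np.linalg.norm(centroids - s, axis=1))
        pick = next(int(i) for i in order if int(i) not in taken)
        taken.add(pick)
        parcel = parcels[pick]
        area_hm2 = parcel.area / M2_PER_HM2
        cls = park_class_for_area(area_hm2)
        inside = nearest_points(parcel, Point(s))[0]  # site within its parcel
        plan.sites.append((float(inside.x), float(inside.y)))
        plan.parcel_ids.append(pick)
        plan.classes.append(cls)
        plan.radii_m.append(CLASS_RADII_M[cls])
        plan.areas_hm2.append(float(area_hm2))
    return plan


# ------------------------------------------------------------ evaluation


def plan_parks(plan: SitingPlan, city: City,
               quality_defaults: dict[str, tuple[float, float]] | None = None
               ) -> tuple[list[Park], dict[str, ParkQuality]]:
    """Materialize planned parks on their parcels with class-default quality.

    Entrances snap to road nodes the same way generated parks do."""
    from parkequity.synthcity.generate import _entrances

    defaults = quality_defaults or DEFAULT_NEW_PARK_QUALITY
    nodes = list(city.roads.nodes)
    node_xy = np.array([[city.roads.nodes[n]["x"], city.roads.nodes[n]["y"]]
                        for n in nodes])
    tree = cKDTree(node_xy)
    parks, qualities = [], {}
    for i in range(len(plan)):
        parcel = city.parcels[plan.parcel_ids[i]]
        esv, hard = defaults[plan.classes[i]]
        pts, nids = _entrances(parcel, tree, node_xy, nodes, n_ent=2)
        park = Park(
            park_id=f"N{i:03d}",
            polygon=parcel,
            park_class=plan.classes[i],
            area_hm2=plan.areas_hm2[i],
            entrances=pts,
            entrance_nodes=nids,
            hard_fraction=hard,
            n_patches=1,
        )
        parks.append(park)
        qualities[park.park_id] = ParkQuality(
            park_id=park.park_id, S=park.area_hm2, ESV=esv,
            FCs=hard * park.area_hm2)
    return parks, qualities


def evaluate_plan(city: City, plan: SitingPlan,
                  qualities: dict[str, ParkQuality], weights: SupplyWeights,
                  equity_k: int = 8, n_perm: int = 999, seed: int = 0,
                  quality_defaults: dict[str, tuple[float, float]] | None = None,
                  ) -> dict:
    """Before/after comparison of accessibility and equity.

    Re-runs the full accessibility profile and LISA typing with the planned
    parks appended (their quality from class defaults) and reports the mean
    comprehensive accessibility change, per-radius zero-accessibility
    counts, blind-zone counts, and LISA category counts."""
    new_parks, new_q = plan_parks(plan, city, quality_defaults)
    parks_after = city.parks + new_parks
    q_after = dict(qualities)
    q_after.update(new_q)

    before = accessibility_profile(city, qualities, weights)
    after = accessibility_profile(city, q_after, weights, parks=parks_after)

    pts = city.residence_points()
    w = build_weights(pts, k=equity_k)
    prices = city.prices()
    ids = [r.residence_id for r in city.residences]
    lisa_before = bivariate_moran(before["A_comprehensive"].to_numpy(), prices,
                                  w, n_perm=n_perm, seed=seed, residence_ids=ids)
    lisa_after = bivariate_moran(after["A_comprehensive"].to_numpy(), prices,
                                 w, n_perm=n_perm, seed=seed, residence_ids=ids)

    d_before = residence_park_distances(city, EXPLICIT_CUTOFF_M)
    d_after = residence_park_distances(city, EXPLICIT_CUTOFF_M, parks=parks_after)
    bz_before = identify_blind_zones(before, d_before)
    bz_after = identify_blind_zones(after, d_after)

    radii = (500, 1000, 2000, 3000)
    report = {
        "n_new_parks": len(plan),
        "mean_A_before": float(before["A_comprehensive"].mean()),
        "mean_A_after": float(after["A_comprehensive"].mean()),
        "delta_mean_A": float(after["A_comprehensive"].mean()
                              - before["A_comprehensive"].mean()),
        "zero_access_before": {f"A_{r}": int((before[f"A_{r}"] == 0).sum())
                               for r in radii},
        "zero_access_after": {f"A_{r}": int((after[f"A_{r}"] == 0).sum())
                              for r in radii},
        "blind_zones_before": bz_before["kind"].value_counts().to_dict(),
        "blind_zones_after": bz_after["kind"].value_counts().to_dict(),
        "lisa_before": lisa_before.category_counts(),
        "lisa_after": lisa_after.category_counts(),
        "global_moran_before": lisa_before.global_i,
        "global_moran_after": lisa_after.global_i,
    }
    return report
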