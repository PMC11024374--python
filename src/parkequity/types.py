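"""Core domain types shared across the pipeline.

Coordinates are abstract planar meters with the origin at the extent's
lower-left corner; no CRS is attached because every computation only needs
metric distances. Park areas are carried in hectares (hm^2), the unit the
four-class size taxonomy is defined in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from shapely.geometry import Point, Polygon

#: Park size classes ordered small to large, with their area cutoffs (hm^2)
#: and walking-catchment radii (m): community <2 hm2 / 500 m, regional
#: 2-5 hm2 / 1000 m, citywide 5-25 hm2 / 2000 m, comprehensive >=25 hm2 / 3000 m.
PARK_CLASSES = ("community", "regional", "citywide", "comprehensive")
CLASS_AREA_CUTOFFS_HM2 = {
    "community": (0.0, 2.0),
    "regional": (2.0, 5.0),
    "citywide": (5.0, 25.0),
    "comprehensive": (25.0, float("inf")),
}
CLASS_RADII_M = {
    "community": 500.0,
    "regional": 1000.0,
    "citywide": 2000.0,
    "comprehensive": 3000.0,
}

M2_PER_HM2 = 10_000.0


def park_class_for_area(area_hm2: float) -> str:
    """Return the park class whose area band contains ``area_hm2``."""
    if area_hm2 < 0:
        raise ValueError(f"park area must be non-negative, got {area_hm2}")
    for cls in PARK_CLASSES:
        lo, hi = CLASS_AREA_CUTOFFS_HM2[cls]
        if lo <= area_hm2 < hi:
            return cls
    raise AssertionError("unreachable: class bands cover [0, inf)")


@dataclass
class Park:
    """A park polygon with its supply-side attributes.

    Entrances are boundary points snapped onto road-network nodes; they
    define access distance only — the park itself is the supply unit, so a
    residence reaches a park through its nearest entrance and each
    (residence, park) pair contributes once to supply and demand.
    """

    park_id: str
    polygon: Polygon
    park_class: str
    area_hm2: float
    entrances: list[tuple[float, float]] = field(default_factory=list)
    entrance_nodes: list[int] = field(default_factory=list)
    hard_fraction: float = 0.0
    n_patches: int = 1

    @property
    def radius_m(self) -> float:
        return CLASS_RADII_M[self.park_class]

    @property
    def hard_area_hm2(self) -> float:
        return self.hard_fraction * self.area_hm2


@dataclass
class Residence:
    """A residential demand point.

    ``population`` is households times the containing block's mean household
    size; ``price`` is the housing price (currency per m^2) used as the
    socioeconomic proxy.
    """

    residence_id: str
    point: Point
    households: int
    population: float
    price: float
    block_id: str


@dataclass
class Block:
    """Administrative block: census unit supplying mean household size."""

    block_id: str
    polygon: Polygon
    mean_household_size: float

    @property
    def census_population(self) -> float:
        return self.mean_household_size  # scaled per-residence at generation


@dataclass
class City:
    """A complete analysis scene: supply, demand, network and land supply."""

    parks: list[Park]
    residences: list[Residence]
    roads: nx.Graph
    parcels: list[Polygon]
    blocks: list[Block]
    extent: tuple[float, float] = (0.0, 0.0)

    def residence_points(self):
        import numpy as np

        return np.array([(r.point.x, r.point.y) for r in self.residences])

    def populations(self):
        import numpy as np

        return np.array([r.population for r in self.residences], dtype=float)

    def prices(self):
        import numpy as np

        return np.array([r.price for r in self.residences], dtype=float)

    def in_core(self, x: float, y: float) -> bool:
        """True if (x, y) lies in the central core.

        The core is the axis-aligned square centered in the extent with half
        the extent's width and height (a quarter of the area) — the analogue
        of a dense old-town center.
        """
        w, h = self.extent
        return (w / 4 <= x <= 3 * w / 4) and (h / 4 <= y <= 3 * h / 4)
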