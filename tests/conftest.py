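"""Shared fixtures: hand-built toy cities and a small fast scenario."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point, box

from parkequity.quality import ParkQuality, SupplyWeights
from parkequity.synthcity.config import BlockGrid, RoadGrid, ScenarioConfig
from parkequity.types import Block, City, Park, Residence, park_class_for_area


def line_graph(n_nodes: int = 40, spacing: float = 100.0) -> nx.Graph:
    """A straight road along the x-axis: node i at (i*spacing, 0)."""
    g = nx.Graph()
    for i in range(n_nodes):
        g.add_node(i, x=i * spacing, y=0.0)
    for i in range(n_nodes - 1):
        g.add_edge(i, i + 1, length_m=spacing)
    return g


def make_park(park_id: str, entrance_node: int, graph: nx.Graph,
              area_hm2: float = 10.0) -> Park:
    """A park whose single entrance sits exactly on a road node."""
    x = graph.nodes[entrance_node]["x"]
    y = graph.nodes[entrance_node]["y"]
    side = (area_hm2 * 10_000) ** 0.5
    poly = box(x - side / 2, y, x + side / 2, y + side)
    return Park(park_id=park_id, polygon=poly,
                park_class=park_class_for_area(area_hm2), area_hm2=area_hm2,
                entrances=[(x, y)], entrance_nodes=[entrance_node])


def make_residence(rid: str, node: int, graph: nx.Graph,
                   population: float = 100.0, price: float = 10_000.0) -> Residence:
    x = graph.nodes[node]["x"]
    y = graph.nodes[node]["y"]
    return Residence(residence_id=rid, point=Point(x, y),
                     households=int(population), population=population,
                     price=price, block_id="B0")


def toy_city(parks, residences, graph) -> City:
    extent = (max(d["x"] for _, d in graph.nodes(data=True)) + 100, 200.0)
    blk = Block(block_id="B0", polygon=box(0, -100, extent[0], 100),
                mean_household_size=1.0)
    return City(parks=parks, residences=residences, roads=graph,
                parcels=[], blocks=[blk], extent=extent)


@pytest.fixture
def line_city():
    """One 10 hm^2 park at node 0; residences at nodes 0, 10, 20 (0/1000/2000 m)."""
    g = line_graph()
    park = make_park("P0", entrance_node=0, graph=g)
    residences = [make_residence(f"R{i}", node, g)
                  for i, node in enumerate((0, 10, 20))]
    return toy_city([park], residences, g)


def constant_quality(parks, esv: float = 0.0) -> dict[str, ParkQuality]:
    return {p.park_id: ParkQuality(park_id=p.park_id, S=p.area_hm2, ESV=esv,
                                   FCs=0.0)
            for p in parks}


def area_only_weights() -> SupplyWeights:
    """Classic unweighted G2SFCA: supply is the park area alone."""
    return SupplyWeights(w_s=1.0, w_fcs=0.0, w_esv=0.0)


def small_scenario(seed: int, n_residences: int = 120) -> ScenarioConfig:
    """A fast 3 km city for pipeline-level tests."""
    return ScenarioConfig(
        seed=seed,
        extent=(3000.0, 3000.0),
        road_grid=RoadGrid(spacing_m=300.0, jitter_fraction=0.2),
        n_residences=n_residences,
        core_density_ratio=4.0,
        households_range=(50, 300),
        park_mix={"community": 2, "regional": 1, "citywide": 1,
                  "comprehensive": 0},
        park_area_ranges={"community": (0.5, 2.0), "regional": (2.0, 5.0),
                          "citywide": (5.0, 10.0), "comprehensive": (25.0, 30.0)},
        n_candidate_parcels=12,
        parcel_area_range_hm2=(0.8, 8.0),
        blocks=BlockGrid(nx=4, ny=4),
        landcover_cell_m=2.0,
    )
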