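"""File formats the pipeline reads and writes.

GeoJSON for parks, entrances, residences and parcels; GraphML for the road
network (edge attribute ``length_m``, node attributes ``x``/``y``); CSV for
blocks; Esri ASCII grid (.asc) for per-park binary land cover. Writers are
deterministic (sorted keys, plain ``repr`` floats) so identical cities
serialize byte-identically.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
from shapely.geometry import Point, mapping, shape

from parkequity.synthcity.landcover import Grid, generate_park_landcover
from parkequity.types import Block, City, Park, Residence


# ------------------------------------------------------------- GeoJSON


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _write_geojson(path: Path, features: list[dict]) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def _read_geojson(path: Path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    return doc["features"]


# ----------------------------------------------------------- ASCII grid


def write_ascii_grid(grid: Grid, path) -> None:
    """Write an Esri ASCII grid (.asc)."""
    nrows, ncols = grid.data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cell!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in grid.data:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path) -> Grid:
    """Read an Esri ASCII grid (.asc) into a Grid."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {data.shape} does not match header {header}")
    return Grid(data=data.astype(np.int8), xll=header["xllcorner"],
                yll=header["yllcorner"], cell=header["cellsize"])


# ----------------------------------------------------------- write_city


def write_city(city: City, directory, landcover_cell_m: float = 1.0,
               landcover_green_fraction: float = 0.7,
               landcover_seed: int = 0) -> dict[str, Path]:
    """Serialize a city to a directory; returns the path of each artifact.

    Land-cover rasters are generated per park from ``landcover_seed`` offset
    by the park index, honoring each park's configured patch count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    park_feats = []
    ent_feats = []
    for park in city.parks:
        park_feats.append(_feature(park.polygon, {
            "park_id": park.park_id,
            "park_class": park.park_class,
            "area_hm2": park.area_hm2,
            "hard_fraction": park.hard_fraction,
            "n_patches": park.n_patches,
        }))
        for (ex, ey), node in zip(park.entrances, park.entrance_nodes):
            ent_feats.append(_feature(Point(ex, ey), {
                "park_id": park.park_id,
                "node_id": node,
            }))
    paths["parks"] = directory / "parks.geojson"
    _write_geojson(paths["parks"], park_feats)
    paths["entrances"] = directory / "entrances.geojson"
    _write_geojson(paths["entrances"], ent_feats)

    res_feats = [
        _feature(r.point, {
            "residence_id": r.residence_id,
            "households": r.households,
            "population": r.population,
            "price": r.price,
            "block_id": r.block_id,
        })
        for r in city.residences
    ]
    paths["residences"] = directory / "residences.geojson"
    _write_geojson(paths["residences"], res_feats)

    paths["parcels"] = directory / "parcels.geojson"
    _write_geojson(paths["parcels"],
                   [_feature(p, {"parcel_id": f"C{i:03d}"})
                    for i, p in enumerate(city.parcels)])

    paths["roads"] = directory / "roads.graphml"
    graph = nx.Graph()
    graph.add_nodes_from(sorted(city.roads.nodes(data=True)))
    graph.add_edges_from(sorted(city.roads.edges(data=True)))
    graph.graph["extent_w"] = float(city.extent[0])
    graph.graph["extent_h"] = float(city.extent[1])
    nx.write_graphml(graph, paths["roads"])

    paths["blocks"] = directory / "blocks.csv"
    pop_by_block: dict[str, float] = {b.block_id: 0.0 for b in city.blocks}
    for r in city.residences:
        pop_by_block[r.block_id] += r.population
    with open(paths["blocks"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "mean_household_size", "census_population",
                         "minx", "miny", "maxx", "maxy"])
        for b in city.blocks:
            minx, miny, maxx, maxy = b.polygon.bounds
            writer.writerow([b.block_id, repr(b.mean_household_size),
                             repr(pop_by_block[b.block_id]),
                             repr(minx), repr(miny), repr(maxx), repr(maxy)])

    lc_dir = directory / "landcover"
    lc_dir.mkdir(exist_ok=True)
    for i, park in enumerate(city.parks):
        grid = generate_park_landcover(
            park, park.n_patches, seed=landcover_seed + i,
            cell_size=landcover_cell_m, green_fraction=landcover_green_fraction)
        write_ascii_grid(grid, lc_dir / f"{park.park_id}.asc")
    paths["landcover"] = lc_dir
    return paths


# ------------------------------------------------------------ read_city


def read_city(directory) -> City:
    """Read a city previously written by :func:`write_city`."""
    directory = Path(directory)

    ent_by_park: dict[str, list[tuple[tuple[float, float], int]]] = {}
    for feat in _read_geojson(directory / "entrances.geojson"):
        props = feat["properties"]
        pt = shape(feat["geometry"])
        ent_by_park.setdefault(props["park_id"], []).append(
            ((pt.x, pt.y), int(props["node_id"])))

    parks = []
    for feat in _read_geojson(directory / "parks.geojson"):
        props = feat["properties"]
        ents = ent_by_park.get(props["park_id"], [])
        parks.append(Park(
            park_id=props["park_id"],
            polygon=shape(feat["geometry"]),
            park_class=props["park_class"],
            area_hm2=props["area_hm2"],
            entrances=[e[0] for e in ents],
            entrance_nodes=[e[1] for e in ents],
            hard_fraction=props["hard_fraction"],
            n_patches=props["n_patches"],
        ))

    residences = []
    for feat in _read_geojson(directory / "residences.geojson"):
        props = feat["properties"]
        residences.append(Residence(
            residence_id=props["residence_id"],
            point=shape(feat["geometry"]),
            households=props["households"],
            population=props["population"],
            price=props["price"],
            block_id=props["block_id"],
        ))

    parcels = [shape(f["geometry"])
               for f in _read_geojson(directory / "parcels.geojson")]

    roads = nx.read_graphml(directory / "roads.graphml", node_type=int)
    graph = nx.Graph()
    for n, data in roads.nodes(data=True):
        graph.add_node(n, x=float(data["x"]), y=float(data["y"]))
    for u, v, data in roads.edges(data=True):
        graph.add_edge(u, v, length_m=float(data["length_m"]))
    extent = (float(roads.graph.get("extent_w", 0.0)),
              float(roads.graph.get("extent_h", 0.0)))

    from shapely.geometry import box

    blocks = []
    with open(directory / "blocks.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            blocks.append(Block(
                block_id=row["id"],
                polygon=box(float(row["minx"]), float(row["miny"]),
                            float(row["maxx"]), float(row["maxy"])),
                mean_household_size=float(row["mean_household_size"]),
            ))

    return City(parks=parks, residences=residences, roads=graph,
                parcels=parcels, blocks=blocks, extent=extent)


def read_landcover(directory, park_id: str) -> Grid:
    return read_ascii_grid(Path(directory) / "landcover" / f"{park_id}.asc")
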