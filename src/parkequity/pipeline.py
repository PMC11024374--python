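"""End-to-end pipeline: generate -> quality -> access -> equity -> plan ->
evaluate, with file artifacts between stages and a reproducibility manifest.

Every stage reads the previous stage's files from the artifact directory, so
stages can be re-run independently (the CLI exposes each one); a chained run
equals :func:`run_pipeline` output. The manifest records package version,
seeds and a sha256 checksum per artifact — two runs with the same config are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from parkequity import __version__
from parkequity.access import accessibility_profile, residence_park_distances
from parkequity.equity import build_weights, bivariate_moran
from parkequity.planning import (
    EXPLICIT_CUTOFF_M,
    assign_park_classes,
    evaluate_plan,
    identify_blind_zones,
    kmeans_curve,
    pso_site_selection,
)
from parkequity.quality import (
    DEFAULT_WEIGHTS,
    ParkQuality,
    SupplyWeights,
    esv_from_pca,
    indices_table,
    compute_fcs,
    standardize_indices,
)
from parkequity.synthcity.config import ScenarioConfig, load_scenario
from parkequity.synthcity.generate import generate_city
from parkequity.synthcity.io import read_ascii_grid, read_city, write_city

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: scenario + per-stage parameter blocks."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    weights: SupplyWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    equity_k: int = 8
    equity_n_perm: int = 999
    equity_alpha: float = 0.05
    plan_k: int | None = None  # None = knee-selected
    pso_particles: int = 30
    pso_iters: int = 200
    n_access_classes: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "scenario" in raw:
            sc = raw["scenario"]
            if isinstance(sc, str):
                kwargs["scenario"] = load_scenario(Path(path).parent / sc)
            else:
                from parkequity.synthcity.config import _tupled, RoadGrid, PriceField, BlockGrid
                sc = _tupled(sc)
                if "road_grid" in sc:
                    sc["road_grid"] = RoadGrid(**_tupled(sc["road_grid"]))
                if "price_field" in sc:
                    sc["price_field"] = PriceField(**sc["price_field"])
                if "blocks" in sc:
                    sc["blocks"] = BlockGrid(**_tupled(sc["blocks"]))
                kwargs["scenario"] = ScenarioConfig(**sc)
        if "weights" in raw:
            w = raw["weights"]
            kwargs["weights"] = SupplyWeights(w_s=w["w_s"], w_fcs=w["w_fcs"],
                                              w_esv=w["w_esv"], cr=w.get("cr"))
        eq = raw.get("equity", {})
        kwargs["equity_k"] = eq.get("k", 8)
        kwargs["equity_n_perm"] = eq.get("n_perm", 999)
        kwargs["equity_alpha"] = eq.get("alpha", 0.05)
        pl = raw.get("planning", {})
        k = pl.get("k", "auto")
        kwargs["plan_k"] = None if k in ("auto", None) else int(k)
        kwargs["pso_particles"] = pl.get("n_particles", 30)
        kwargs["pso_iters"] = pl.get("n_iter", 200)
        return cls(**kwargs)


def reference_run_config(seed: int = 7) -> RunConfig:
    """The shipped reference run: the reference scenario plus a planning-
    context park count (k=6) in place of the knee, the same way a planner
    would fix the count from service-circle considerations."""
    from parkequity.synthcity.config import reference_scenario

    return RunConfig(scenario=reference_scenario(seed=seed), plan_k=6)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ----------------------------------------------------------------- stages


def stage_generate(config: RunConfig, outdir: Path) -> list[Path]:
    city = generate_city(config.scenario)
    sc = config.scenario
    lo, hi = sc.landcover_green_fraction
    paths = write_city(
        city, outdir,
        landcover_cell_m=sc.landcover_cell_m,
        landcover_green_fraction=(lo + hi) / 2,
        landcover_seed=sc.seed,
    )
    return [p for p in paths.values() if p.is_file()] + sorted(
        (outdir / "landcover").glob("*.asc"))


def load_qualities(outdir: Path) -> dict[str, ParkQuality]:
    table = pd.read_csv(outdir / "park_quality.csv").set_index("park_id")
    return {pid: ParkQuality(park_id=pid, S=row["S_hm2"], ESV=row["ESV"],
                             FCs=row["FCs_hm2"])
            for pid, row in table.iterrows()}


def stage_quality(config: RunConfig, outdir: Path) -> list[Path]:
    city = read_city(outdir)
    grids = {}
    for park in city.parks:
        grid = read_ascii_grid(outdir / "landcover" / f"{park.park_id}.asc")
        grids[park.park_id] = (grid.data, grid.cell)
    table = indices_table(grids)
    esv = esv_from_pca(standardize_indices(table))
    rows = []
    for park in city.parks:
        rows.append({"park_id": park.park_id, "S_hm2": park.area_hm2,
                     "ESV": float(esv.loc[park.park_id]),
                     "FCs_hm2": compute_fcs(park)})
    out = outdir / "park_quality.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    windex = outdir / "weights.yml"
    w = config.weights
    with open(windex, "w") as fh:
        yaml.safe_dump({"w_s": w.w_s, "w_fcs": w.w_fcs, "w_esv": w.w_esv,
                        "cr": w.cr}, fh)
    idx_path = outdir / "patch_indices.csv"
    table.rename_axis("park_id").to_csv(idx_path)
    return [out, windex, idx_path]


def stage_access(config: RunConfig, outdir: Path) -> list[Path]:
    city = read_city(outdir)
    qualities = load_qualities(outdir)
    table = accessibility_profile(city, qualities, config.weights,
                                  n_classes=config.n_access_classes)
    acc_path = outdir / "accessibility.csv"
    table.to_csv(acc_path)

    from parkequity.access import CatchmentConfig, supply_demand_ratios
    cc = CatchmentConfig(mode="type_specific")
    dist = residence_park_distances(city, cc.max_radius)
    ratios = supply_demand_ratios(city, qualities, config.weights, cc, dist)
    sr_path = outdir / "supply_ratios.csv"
    ratios.to_csv(sr_path)
    return [acc_path, sr_path]


def stage_equity(config: RunConfig, outdir: Path) -> list[Path]:
    city = read_city(outdir)
    table = pd.read_csv(outdir / "accessibility.csv").set_index("residence_id")
    w = build_weights(city.residence_points(), k=config.equity_k)
    ids = [r.residence_id for r in city.residences]
    lisa = bivariate_moran(
        table.loc[ids, "A_comprehensive"].to_numpy(), city.prices(), w,
        n_perm=config.equity_n_perm, seed=config.scenario.seed,
        alpha=config.equity_alpha, residence_ids=ids)
    lisa_path = outdir / "lisa.csv"
    lisa.to_frame().to_csv(lisa_path)
    summary = {"global_I": lisa.global_i,
               "n_permutations": lisa.n_permutations,
               "alpha": lisa.alpha,
               "category_counts": lisa.category_counts()}
    sum_path = outdir / "moran_summary.json"
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return [lisa_path, sum_path]


def stage_plan(config: RunConfig, outdir: Path) -> list[Path]:
    city = read_city(outdir)
    table = pd.read_csv(outdir / "accessibility.csv").set_index("residence_id")
    lisa_frame = pd.read_csv(outdir / "lisa.csv").set_index("residence_id")

    dist = residence_park_distances(city, EXPLICIT_CUTOFF_M)
    blind = identify_blind_zones(table, dist)
    bz_path = outdir / "blind_zones.csv"
    blind.to_csv(bz_path)

    low = set(table.index[table["access_class"] <= 1])
    ll = set(lisa_frame.index[lisa_frame["category"] == "LL"])
    union = sorted(low | ll)
    prov = {rid: ("both" if rid in low and rid in ll
                  else "low_access" if rid in low else "LL") for rid in union}
    targets = pd.DataFrame({"provenance": pd.Series(prov, dtype=object)}
                           ).rename_axis("residence_id")
    tg_path = outdir / "targets.csv"
    targets.to_csv(tg_path)

    paths = [bz_path, tg_path]
    if len(union) == 0:
        logger.warning("no optimization targets; empty siting plan")
        plan_frame = pd.DataFrame(columns=["x", "y", "parcel_id", "park_class",
                                           "radius_m", "area_hm2"])
    else:
        a = table.loc[union, "A_comprehensive"].to_numpy(dtype=float)
        m = lisa_frame.loc[union, "local_I"].to_numpy(dtype=float)

        def minmax(v):
            span = v.max() - v.min()
            return np.zeros_like(v) if span == 0 else (v - v.min()) / span

        feats = np.column_stack([minmax(a), minmax(m)])
        kmax = min(12, len(union) - 1) if len(union) > 2 else 1
        curve = kmeans_curve(feats, k_range=range(1, kmax + 1),
                             seed=config.scenario.seed,
                             k_override=config.plan_k)
        kc_path = outdir / "kcurve.csv"
        pd.DataFrame({"k": curve.ks, "mean_farthest_m": curve.values}
                     ).to_csv(kc_path, index=False)
        paths.append(kc_path)

        xy = np.array([[city.residences[i].point.x, city.residences[i].point.y]
                       for i, r in enumerate(city.residences)
                       if r.residence_id in set(union)])
        pops = np.array([r.population for r in city.residences
                         if r.residence_id in set(union)])
        k = min(curve.chosen_k, len(city.parcels))
        sites, trace = pso_site_selection(
            xy, pops, k, bounds=(0, 0, city.extent[0], city.extent[1]),
            n_particles=config.pso_particles, n_iter=config.pso_iters,
            seed=config.scenario.seed)
        plan = assign_park_classes(sites, city.parcels, objective_trace=trace)
        plan_frame = plan.to_frame()

    plan_path = outdir / "siting_plan.csv"
    plan_frame.to_csv(plan_path, index=False)
    geo_path = outdir / "siting_plan.geojson"
    feats_out = []
    for _, row in plan_frame.iterrows():
        feats_out.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
            "properties": {"parcel_id": int(row["parcel_id"]),
                           "park_class": row["park_class"],
                           "radius_m": float(row["radius_m"]),
                           "area_hm2": float(row["area_hm2"])},
        })
    with open(geo_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats_out}, fh,
                  sort_keys=True, separators=(",", ":"))
    paths += [plan_path, geo_path]
    return paths


def stage_evaluate(config: RunConfig, outdir: Path) -> list[Path]:
    city = read_city(outdir)
    qualities = load_qualities(outdir)
    plan_frame = pd.read_csv(outdir / "siting_plan.csv")
    from parkequity.planning import SitingPlan
    plan = SitingPlan(
        sites=[(r.x, r.y) for r in plan_frame.itertuples()],
        parcel_ids=[int(r.parcel_id) for r in plan_frame.itertuples()],
        classes=[r.park_class for r in plan_frame.itertuples()],
        radii_m=[float(r.radius_m) for r in plan_frame.itertuples()],
        areas_hm2=[float(r.area_hm2) for r in plan_frame.itertuples()],
    )
    report = evaluate_plan(city, plan, qualities, config.weights,
                           equity_k=config.equity_k,
                           n_perm=config.equity_n_perm,
                           seed=config.scenario.seed)
    ev_path = outdir / "evaluation.json"
    with open(ev_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return [ev_path]


STAGES = [
    ("generate", stage_generate),
    ("quality", stage_quality),
    ("access", stage_access),
    ("equity", stage_equity),
    ("plan", stage_plan),
    ("evaluate", stage_evaluate),
]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all six stages and write ``manifest.json``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "parkequity",
        "version": __version__,
        "seed": config.scenario.seed,
        "stages": [],
    }
    for name, fn in STAGES:
        logger.info("stage %s", name)
        try:
            paths = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed: {exc}; fix the stage's "
                f"inputs in {outdir} and re-run from this stage") from exc
        manifest["stages"].append({
            "name": name,
            "outputs": {p.relative_to(outdir).as_posix(): _sha256(p)
                        for p in paths if p.is_file()},
        })
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
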