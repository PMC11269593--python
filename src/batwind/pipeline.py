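"""End-to-end orchestration: simulate → prep → fit → classify → site → overlap.

A :class:`PipelineConfig` carries every knob (grid geometry, season months,
thinning window, regularization grid, folds, background size, omission
rates, criterion weights, siting class bounds, roost buffer, per-stage
seeds) with defaults mirroring the study conditions the pipeline emulates.

Each stage is a disk-to-disk function on a workspace directory, so stages
can be re-run independently (and are what the CLI subcommands and the
numbered analysis drivers call).  ``run_pipeline`` chains all of them
deterministically and writes a provenance manifest (config hash, seeds,
chosen regularization multipliers, thresholds, record-count funnel)
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import conflict as C
from . import habitat as H
from . import landscape as L
from . import maxent as M
from . import occurrences as O
from . import siting as S
from .grids import GridSpec, RasterLayer, read_raster, write_raster
from .vector_io import read_geometries, read_points_csv, write_geometries, write_points_csv

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_prep_occ",
    "stage_fit_sdm",
    "stage_classify_habitat",
    "stage_build_siting",
    "stage_overlap",
    "stage_conflict",
    "stage_report",
]


@dataclass
class PipelineConfig:
    # grids: habitat modeling grid (1-km analog) and siting grid (300-m analog)
    extent_m: float = 100_000.0
    habitat_cell_m: float = 1000.0
    siting_cell_m: float = 300.0
    crs_id: str = "synthetic-lcc"

    # landscape
    autocorr_len: float = 6.0
    n_landcover_classes: int = 5
    n_seasons: int = 4
    shared_weight: float = 0.5
    truth_coefficients: dict = field(
        default_factory=lambda: dict(L.DEFAULT_TRUTH.coefficients))

    # occurrence simulation and cleaning
    n_raw_per_season: int = 150
    year_min: int = 1970
    year_max: int = 2020
    basis: str = "PreservedSpecimen"
    thin_window_km: float = 10.0

    # modeling
    background_size: int = 10000
    rm_grid: tuple = M.DEFAULT_RM_GRID
    cv_folds: int = 5
    omission_rates: tuple = (0.10, 0.50)
    collinearity_threshold: float = 0.7

    # siting and overlap
    weights: dict = field(default_factory=lambda: dict(S.DEFAULT_WEIGHTS))
    siting_bounds: tuple = (16, 32)
    airport_buffer_m: float = 1000.0
    n_turbines: int = 400
    turbine_bias: float = 0.8
    n_roosts: int = 3
    buffer_km: float = 100.0
    min_capacity_kw: float = 65.0
    min_rotor_m: float = 30.0

    # per-stage seeds
    seed_landscape: int = 101
    seed_occurrences: int = 202
    seed_thin: int = 303
    seed_background: int = 404
    seed_cv: int = 505
    seed_criteria: int = 606
    seed_turbines: int = 707
    seed_roosts: int = 808
    seed_contrib: int = 909

    def habitat_grid(self) -> GridSpec:
        n = int(round(self.extent_m / self.habitat_cell_m))
        return GridSpec(0.0, self.extent_m, self.habitat_cell_m, n, n, self.crs_id)

    def siting_grid(self) -> GridSpec:
        n = int(round(self.extent_m / self.siting_cell_m))
        return GridSpec(0.0, self.extent_m, self.siting_cell_m, n, n, self.crs_id)

    @property
    def seasons(self) -> tuple[str, ...]:
        return L.SEASONS[: self.n_seasons]

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Derive all stage seeds deterministically from one master seed."""
        rng = np.random.default_rng(seed)
        kwargs = asdict(self)
        for f in fields(self):
            if f.name.startswith("seed_"):
                kwargs[f.name] = int(rng.integers(0, 2**31 - 1))
        return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Read a TOML config; unknown keys are an error naming the key."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    for key in ("rm_grid", "omission_rates", "siting_bounds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _json_dump(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=1, default=str))


def _season_kinds(variables) -> dict[str, str]:
    return {v: ("categorical" if v == "landcover" else "continuous")
            for v in variables}


# ---------------------------------------------------------------------------
# Stage 1: synthetic scene
# ---------------------------------------------------------------------------

def simulate_occurrences(config: PipelineConfig,
                         truths: dict[str, RasterLayer]) -> pd.DataFrame:
    """Raw Darwin-Core-like records with duplicates, bad bases, bad years.

    Roughly 80% preserved specimens within the year window; the rest exercise
    the cleaning funnel (human observations, out-of-window years, missing
    months).
    """
    rng = np.random.default_rng(config.seed_occurrences)
    frames = []
    for season, truth in truths.items():
        pts = L.sample_presences(truth, config.n_raw_per_season,
                                 seed=int(rng.integers(2**31 - 1)))
        months = rng.choice(O.SEASON_MONTHS[season], size=len(pts))
        years = rng.integers(config.year_min - 8, config.year_max + 4,
                             size=len(pts))
        basis = rng.choice(
            ["PreservedSpecimen", "PRESERVED_SPECIMEN", "HumanObservation"],
            size=len(pts), p=[0.65, 0.2, 0.15])
        month_col = months.astype(object)
        missing = rng.random(len(pts)) < 0.04
        month_col[missing] = None
        frames.append(pd.DataFrame({
            "longitude": pts.data["x"], "latitude": pts.data["y"],
            "year": years, "month": month_col, "basis_of_record": basis,
        }))
    return pd.concat(frames, ignore_index=True)


def stage_simulate(config: PipelineConfig, outdir) -> dict:
    """Generate and write the full synthetic scene under <outdir>/scene."""
    out = Path(outdir) / "scene"
    out.mkdir(parents=True, exist_ok=True)
    land_cfg = L.LandscapeConfig(
        grid=config.habitat_grid(), seed=config.seed_landscape,
        autocorr_len=config.autocorr_len,
        n_landcover_classes=config.n_landcover_classes,
        n_seasons=config.n_seasons, shared_weight=config.shared_weight)
    env_stacks = L.generate_env_stack(land_cfg)
    truth_model = L.TruthModel(coefficients=dict(config.truth_coefficients))
    truths = {s: L.compute_truth_suitability(env, truth_model)
              for s, env in env_stacks.items()}
    variables = list(next(iter(env_stacks.values())))
    for season, env in env_stacks.items():
        for var, layer in env.items():
            write_raster(layer, out / f"env_{season}_{var}.tif")
        write_raster(truths[season], out / f"truth_{season}.tif")
    raw_occ = simulate_occurrences(config, truths)
    raw_occ.to_csv(out / "occurrences_raw.csv", index=False)

    sit_cfg = L.LandscapeConfig(
        grid=config.siting_grid(), seed=config.seed_criteria,
        autocorr_len=config.autocorr_len * config.habitat_cell_m / config.siting_cell_m,
        n_landcover_classes=config.n_landcover_classes)
    criteria = L.generate_siting_criteria(sit_cfg, seed=config.seed_criteria)
    for name in ("wind_power_class", "slope", "population_density", "landcover"):
        write_raster(getattr(criteria, name), out / f"criterion_{name}.tif")
    write_geometries(criteria.roads, out / "roads.geojson", config.crs_id)
    write_geometries(criteria.transmission_lines, out / "transmission.geojson",
                     config.crs_id)
    write_geometries(criteria.military, out / "military.geojson", config.crs_id)
    write_geometries(criteria.protected, out / "protected.geojson", config.crs_id)
    write_points_csv(criteria.airports, out / "airports.csv")
    turbines = L.generate_turbines(config.n_turbines, criteria.wind_power_class,
                                   config.turbine_bias, seed=config.seed_turbines)
    write_points_csv(turbines, out / "turbines.csv")
    write_points_csv(L.generate_roosts(config.n_roosts, config.habitat_grid(),
                                       seed=config.seed_roosts),
                     out / "roosts.csv")
    _json_dump({"coefficients": truth_model.coefficients, "tau": truth_model.tau,
                "seasons": list(env_stacks), "variables": variables,
                "seed_landscape": config.seed_landscape},
               out / "truth_manifest.json")
    return {"n_raw_occurrences": int(len(raw_occ)),
            "n_turbines": int(len(turbines)), "variables": variables}


def _read_env(config: PipelineConfig, outdir, season: str) -> dict[str, RasterLayer]:
    scene = Path(outdir) / "scene"
    manifest = json.loads((scene / "truth_manifest.json").read_text())
    return {v: read_raster(scene / f"env_{season}_{v}.tif")
            for v in manifest["variables"]}


# ---------------------------------------------------------------------------
# Stage 2: occurrence cleaning
# ---------------------------------------------------------------------------

def stage_prep_occ(config: PipelineConfig, outdir) -> dict:
    """Filter, season-split, dedupe and thin raw occurrences."""
    outdir = Path(outdir)
    (outdir / "occurrences").mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(outdir / "scene" / "occurrences_raw.csv")
    filtered = O.filter_occurrences(raw, config.year_min, config.year_max,
                                    config.basis)
    funnel: dict = {"raw": int(len(raw)), "filtered": int(len(filtered))}
    for season, frame in O.split_by_season(filtered).items():
        deduped = O.dedupe_exact(frame)
        thinned = O.thin_spatial(deduped, config.thin_window_km,
                                 seed=config.seed_thin, metric="euclidean")
        thinned.to_csv(outdir / "occurrences" / f"occ_{season}.csv", index=False)
        funnel[season] = {"split": int(len(frame)), "deduped": int(len(deduped)),
                          "thinned": int(len(thinned))}
    _json_dump(funnel, outdir / "occurrences" / "funnel.json")
    return funnel


# ---------------------------------------------------------------------------
# Stage 3: seasonal niche models
# ---------------------------------------------------------------------------

def stage_fit_sdm(config: PipelineConfig, outdir) -> dict:
    """Per season: background, features, AICc rm selection, final fit, CV,
    response curves, contributions, collinearity screen, suitability raster."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    (outdir / "habitat").mkdir(parents=True, exist_ok=True)
    hab_grid = config.habitat_grid()
    info: dict = {}
    for season in config.seasons:
        env = _read_env(config, outdir, season)
        kinds = _season_kinds(env)
        occ = pd.read_csv(outdir / "occurrences" / f"occ_{season}.csv")
        bg = M.sample_background(env, B=config.background_size,
                                 seed=config.seed_background)
        row, col, inside = hab_grid.index_of(
            occ["longitude"].to_numpy(), occ["latitude"].to_numpy())
        pvals = {v: env[v].values[row[inside], col[inside]] for v in env}
        bvals = {v: bg[v].to_numpy() for v in env}
        train = {v: np.concatenate([pvals[v], bvals[v]]) for v in env}
        _, specs = M.build_features(train, kinds)
        Xp = M.design_from_specs(pvals, specs)
        Xb = M.design_from_specs(bvals, specs)

        screen = M.collinearity_screen(
            bg[[v for v in env if kinds[v] == "continuous"]],
            threshold=config.collinearity_threshold)
        screen.correlations.to_csv(outdir / "models" / f"collinearity_{season}.csv")

        best_rm, rm_table, best_fit = M.select_rm(
            Xp, Xb, specs, candidates=tuple(config.rm_grid))
        rm_table.to_csv(outdir / "models" / f"rm_table_{season}.csv", index=False)
        M.save_fit(best_fit, outdir / "models" / f"fit_{season}.json")

        report = M.cross_validate(Xp, Xb, specs, k=config.cv_folds,
                                  seed=config.seed_cv, schema=best_fit.schema)
        contrib = M.variable_contribution(best_fit, Xp, Xb,
                                          seed=config.seed_contrib)
        curves = M.response_curves(pvals, bvals, kinds)
        pd.DataFrame([
            {"variable": v, "value": float(val), "logistic": float(p)}
            for v, curve in curves.items()
            for val, p in zip(curve.values, curve.logistic)
        ]).to_csv(outdir / "models" / f"response_curves_{season}.csv", index=False)

        tab = M.raster_stack_table(env)
        Xall = M.design_from_specs({v: tab[v].to_numpy() for v in env}, specs)
        logi = M.logistic_at(best_fit, Xall)
        suit_vals = np.full(hab_grid.shape, -9999.0)
        suit_vals[tab["row"], tab["col"]] = logi
        write_raster(RasterLayer(hab_grid, suit_vals, nodata=-9999.0,
                                 kind="continuous"),
                     outdir / "habitat" / f"suitability_{season}.tif")
        # training suitabilities feed the omission thresholds downstream
        pd.DataFrame({"suitability": M.logistic_at(best_fit, Xp)}).to_csv(
            outdir / "models" / f"train_suitability_{season}.csv", index=False)

        info[season] = {
            "m": int(Xp.shape[0]), "B": int(Xb.shape[0]),
            "rm_selected": best_rm,
            "cv_auc_mean": round(report.mean, 6),
            "cv_auc_sd": round(report.sd, 6),
            "contributions": {k: round(v, 3)
                              for k, v in contrib.percentages.items()},
            "flagged_pairs": [[a, b, round(r, 3)] for a, b, r in screen.flagged],
        }
        _json_dump(info[season], outdir / "models" / f"summary_{season}.json")
    return info


# ---------------------------------------------------------------------------
# Stage 4: habitat classes
# ---------------------------------------------------------------------------

def stage_classify_habitat(config: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    rate_low, rate_high = config.omission_rates
    info: dict = {}
    for season in config.seasons:
        suit = read_raster(outdir / "habitat" / f"suitability_{season}.tif")
        train_suit = pd.read_csv(
            outdir / "models" / f"train_suitability_{season}.csv"
        )["suitability"].to_numpy()
        thresholds = H.thresholds_from_training(train_suit, rate_low, rate_high)
        hmap = H.classify_habitat(suit, thresholds, season=season)
        write_raster(hmap.classes, outdir / "habitat" / f"habitat_{season}.tif")
        payload = {"season": season, "t_low": thresholds.t_low,
                   "t_high": thresholds.t_high, "m": thresholds.m,
                   "rate_low": rate_low, "rate_high": rate_high}
        _json_dump(payload, outdir / "habitat" / f"thresholds_{season}.json")
        info[season] = payload
    return info


def _read_habitat_maps(config: PipelineConfig, outdir) -> dict[str, H.HabitatClassMap]:
    outdir = Path(outdir)
    maps = {}
    for season in config.seasons:
        layer = read_raster(outdir / "habitat" / f"habitat_{season}.tif")
        t = json.loads((outdir / "habitat" / f"thresholds_{season}.json").read_text())
        thresholds = H.OmissionThresholds(t["t_low"], t["t_high"], t["m"],
                                          t["rate_low"], t["rate_high"])
        maps[season] = H.HabitatClassMap(layer, thresholds, season)
    return maps


# ---------------------------------------------------------------------------
# Stage 5: siting MCDA
# ---------------------------------------------------------------------------

def stage_build_siting(config: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    (outdir / "siting").mkdir(parents=True, exist_ok=True)
    scene = outdir / "scene"
    sit_grid = config.siting_grid()
    wind = read_raster(scene / "criterion_wind_power_class.tif")
    slope = read_raster(scene / "criterion_slope.tif")
    pop = read_raster(scene / "criterion_population_density.tif")
    landcover = read_raster(scene / "criterion_landcover.tif")
    roads, _ = read_geometries(scene / "roads.geojson")
    lines, _ = read_geometries(scene / "transmission.geojson")
    military, _ = read_geometries(scene / "military.geojson")
    protected, _ = read_geometries(scene / "protected.geojson")
    airports = read_points_csv(scene / "airports.csv", crs_id=config.crs_id)

    crit_specs = S.default_criteria(
        np.unique(landcover.values[landcover.valid_mask()]))
    scored = {
        "wind_power_class": S.reclassify(wind, crit_specs["wind_power_class"]),
        "distance_to_roads": S.reclassify(
            S.distance_to_features(roads, sit_grid),
            crit_specs["distance_to_roads"]),
        "distance_to_transmission": S.reclassify(
            S.distance_to_features(lines, sit_grid),
            crit_specs["distance_to_transmission"]),
        "landcover": S.reclassify(landcover, crit_specs["landcover"]),
        "slope": S.reclassify(slope, crit_specs["slope"]),
        "population_density": S.reclassify(pop, crit_specs["population_density"]),
    }
    mask = S.build_exclusion_mask(sit_grid, military, protected, airports,
                                  config.airport_buffer_m)
    score_map = S.weighted_overlay(scored, config.weights, mask)
    class_map = S.classify_siting(score_map, tuple(config.siting_bounds))
    write_raster(score_map.score, outdir / "siting" / "score.tif")
    write_raster(class_map.classes, outdir / "siting" / "classes.tif")

    turbines = C.load_turbines(scene / "turbines.csv", config.min_capacity_kw,
                               config.min_rotor_m, crs_id=config.crs_id)
    write_points_csv(turbines, outdir / "siting" / "turbines_kept.csv")
    frac_below, n_nodata = S.turbine_score_quantile(
        turbines, score_map, cutoff=config.siting_bounds[1])
    payload = {"cutoff": int(config.siting_bounds[1]),
               "fraction_below": frac_below, "n_nodata": n_nodata,
               "n_turbines_kept": int(len(turbines)),
               "score_min": int(score_map.score.masked().min()),
               "score_max": int(score_map.score.masked().max())}
    _json_dump(payload, outdir / "siting" / "turbine_quantile.json")
    return payload


def _read_siting_classes(config: PipelineConfig, outdir) -> S.SitingClassMap:
    layer = read_raster(Path(outdir) / "siting" / "classes.tif")
    return S.SitingClassMap(layer, tuple(config.siting_bounds))


# ---------------------------------------------------------------------------
# Stage 6: overlap, conflict, report
# ---------------------------------------------------------------------------

def stage_overlap(config: PipelineConfig, outdir) -> dict:
    """Turbine impact table (season × habitat class counts and percentages)."""
    outdir = Path(outdir)
    (outdir / "conflict").mkdir(parents=True, exist_ok=True)
    turbines = read_points_csv(outdir / "siting" / "turbines_kept.csv",
                               crs_id=config.crs_id)
    impact = C.turbine_impact_table(turbines, _read_habitat_maps(config, outdir))
    impact.to_csv(outdir / "conflict" / "impact_table.csv")
    payload = {
        "n_turbines": impact.n_turbines,
        "counts": impact.counts.to_dict(orient="index"),
        "percentages": {s: {k: round(v, 4) for k, v in r.items()}
                        for s, r in impact.percentages.to_dict(orient="index").items()},
    }
    _json_dump(payload, outdir / "conflict" / "impact_table.json")
    return payload


def stage_conflict(config: PipelineConfig, outdir) -> dict:
    """Seasonal conflict maps on high-siting cells."""
    outdir = Path(outdir)
    (outdir / "conflict").mkdir(parents=True, exist_ok=True)
    class_map = _read_siting_classes(config, outdir)
    counts: dict = {}
    for season, hmap in _read_habitat_maps(config, outdir).items():
        cmap = C.conflict_map(class_map, hmap)
        write_raster(cmap.classes, outdir / "conflict" / f"conflict_{season}.tif")
        vals = cmap.classes.values[cmap.classes.valid_mask()]
        counts[season] = {name: int((vals == code).sum())
                          for code, name in C.CONFLICT_CLASS_NAMES.items()}
    _json_dump(counts, outdir / "conflict" / "conflict_cell_counts.json")
    return counts


def stage_report(config: PipelineConfig, outdir) -> dict:
    """Roost-buffer report and the provenance manifest."""
    outdir = Path(outdir)
    turbines = read_points_csv(outdir / "siting" / "turbines_kept.csv",
                               crs_id=config.crs_id)
    roosts = read_points_csv(outdir / "scene" / "roosts.csv",
                             crs_id=config.crs_id)
    report = C.roost_buffer_overlap(roosts, turbines,
                                    _read_siting_classes(config, outdir),
                                    config.buffer_km)
    _json_dump(report.to_dict(), outdir / "conflict" / "roost_report.json")
    return report.to_dict()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; any stage failure aborts with a named error."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "config": asdict(config), "stages": {}}
    stages = [
        ("simulate", stage_simulate),
        ("prep_occ", stage_prep_occ),
        ("fit_sdm", stage_fit_sdm),
        ("classify_habitat", stage_classify_habitat),
        ("build_siting", stage_build_siting),
        ("overlap", stage_overlap),
        ("conflict", stage_conflict),
        ("report", stage_report),
    ]
    for name, func in stages:
        log.info("pipeline stage: %s", name)
        try:
            manifest["stages"][name] = func(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    _json_dump(manifest, outdir / "manifest.json")
    return manifest
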