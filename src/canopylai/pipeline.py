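"""End-to-end orchestration: simulate -> extract -> select -> train ->
evaluate -> map, reproducible from a config + master seed alone.

Every stage writes re-loadable artifacts (ENVI rasters, GeoJSON, CSV,
JSON) into the configured output directory, so the pipeline can resume
from any stage; the CLI in :mod:`canopylai.cli` exposes each stage as a
subcommand.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import io as cio
from .containers import FeatureTable, ReflectanceCube
from .models import (METHODS, ModelSpec, fit, reports_to_frame,
                     run_experiment)
from .selection import correlation_screen, spa_select
from .spectra import (build_spectral_features, fdsr, plot_mean_spectrum,
                      vi_image)
from .synth import (STAGES, make_layout, simulate_cube, simulate_lai,
                    wavelength_grid)
from .textures import (TEXTURE_NAMES, pca_first_component,
                       texture_feature_maps, texture_feature_table)

log = logging.getLogger("canopylai")


@dataclass
class RunConfig:
    """Fully serializable run description; a run is reproducible from
    the config plus its master seed alone."""
    seed: int = 0
    out_dir: str = "canopylai_run"
    stages: tuple = STAGES
    # wavelength grid
    wavelength_start: float = 450.0
    wavelength_step: float = 4.0
    n_bands: int = 125
    # generator
    k_ext: float = 0.5
    k_ext_sd: float = 0.3
    noise_sigma: float = 0.004
    roughness0: float = 0.9
    roughness_noise: float = 0.3
    soil_brightness_sd: float = 0.10
    chlorophyll_sd: float = 0.15
    nir_sd: float = 0.02
    illumination_sd: float = 0.03
    # spectra
    fdsr_convention: str = "printed"
    # textures
    gray_levels: int = 32
    window: int = 5
    offset: tuple = (-1, 1)
    # SPA
    kmax: int | None = None
    folds: int = 5
    # mapping
    map_feature_set: str = "ALL"
    map_method: str = "GPR"

    def wavelengths(self) -> np.ndarray:
        return wavelength_grid(self.wavelength_start, self.wavelength_step,
                               self.n_bands)

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["offset"] = list(d["offset"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", STAGES))
        d["offset"] = tuple(d.get("offset", (-1, 1)))
        return cls(**d)


def _timed(stage_name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            out = fn(*a, **kw)
            log.info("stage %-9s done in %.1f s", stage_name,
                     time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def _out(config) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


@_timed("simulate")
def stage_simulate(config: RunConfig):
    """Generate layout, ground truth and per-stage cubes; write all."""
    out = _out(config)
    layout = make_layout(config.seed)
    cio.write_layout_geojson(out / "layout.geojson", layout)
    truth, cubes = [], {}
    wl = config.wavelengths()
    for stage in config.stages:
        t = simulate_lai(layout, stage, config.seed)
        truth.extend(t)
        cube = simulate_cube(layout, t, stage, config.seed,
                             k_ext=config.k_ext,
                             k_ext_sd=config.k_ext_sd,
                             noise_sigma=config.noise_sigma,
                             roughness0=config.roughness0,
                             roughness_noise=config.roughness_noise,
                             soil_brightness_sd=config.soil_brightness_sd,
                             chlorophyll_sd=config.chlorophyll_sd,
                             nir_sd=config.nir_sd,
                             illumination_sd=config.illumination_sd,
                             wavelengths=wl)
        cio.write_cube(out / f"cube_{stage}.bsq", cube)
        cubes[stage] = cube
    cio.write_truth_csv(out / "truth.csv", truth)
    return layout, truth, cubes


def _load_simulated(config: RunConfig):
    out = _out(config)
    layout = cio.read_layout_geojson(out / "layout.geojson")
    truth = cio.read_truth_csv(out / "truth.csv")
    cubes = {stage: cio.read_cube(out / f"cube_{stage}.bsq")
             for stage in config.stages}
    return layout, truth, cubes


@_timed("extract")
def stage_extract(config: RunConfig, layout=None, truth=None, cubes=None):
    """Spectral + texture feature extraction -> one combined table."""
    if layout is None:
        layout, truth, cubes = _load_simulated(config)
    out = _out(config)
    per_stage = []
    for stage in config.stages:
        cube = cubes[stage]
        records = plot_mean_spectrum(cube, layout, stage)
        spec_tab = build_spectral_features(
            records, fdsr_convention=config.fdsr_convention)
        pc1 = pca_first_component(cube)
        tex_tab = texture_feature_table(pc1, layout, stage,
                                        G=config.gray_levels,
                                        window=config.window,
                                        offset=config.offset)
        per_stage.append(spec_tab.join(tex_tab))
    data = pd.concat([t.data for t in per_stage], axis=0)
    combined = FeatureTable(data.sort_index(), per_stage[0].families)
    combined.to_csv(out / "features.csv")
    return combined


@_timed("select")
def stage_select(config: RunConfig, combined=None, truth=None):
    """Correlation screen + per-family SPA selection on calibration."""
    out = _out(config)
    if combined is None:
        combined = FeatureTable.from_csv(out / "features.csv")
    if truth is None:
        truth = cio.read_truth_csv(out / "truth.csv")
    lai_by_key = {(t.plot_id, t.stage): t.lai for t in truth}
    lai = np.array([lai_by_key[tuple(k)] for k in combined.data.index])
    screen = correlation_screen(combined, lai)
    screen.table.to_csv(out / "correlation.csv")

    train_keys = {(t.plot_id, t.stage) for t in truth if t.replicate != 1}
    train_idx = [k for k in combined.data.index if tuple(k) in train_keys]
    y_train = np.array([lai_by_key[tuple(k)] for k in train_idx])
    selections = {}
    fams = {"OSR": combined.columns_of("OSR"),
            "FDSR": combined.columns_of("FDSR"),
            "VI": combined.columns_of("VI"),
            "TEX": combined.columns_of("TEX"),
            "ALL": list(combined.data.columns)}
    for fs, cols in fams.items():
        sub = combined.subset(cols)
        sub_train = FeatureTable(sub.data.loc[train_idx], sub.families)
        selections[fs] = spa_select(sub_train, y_train, kmax=config.kmax,
                                    folds=config.folds, seed=config.seed)
    payload = {fs: {"start_column": r.start_column, "chain": r.chain,
                    "rmsecv_path": list(map(float, r.rmsecv_path)),
                    "chosen_k": r.chosen_k,
                    "chosen_columns": r.chosen_columns}
               for fs, r in selections.items()}
    (out / "selections.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame([{"feature_set": fs,
                   "features": ", ".join(r.chosen_columns)}
                  for fs, r in selections.items()]
                 ).to_csv(out / "selected_features.csv", index=False)
    return screen, selections


@_timed("train")
def stage_train(config: RunConfig, combined=None, truth=None,
                selections=None):
    """Fit and evaluate the 5 x 3 x 2 report grid."""
    out = _out(config)
    if combined is None:
        combined = FeatureTable.from_csv(out / "features.csv")
    if truth is None:
        truth = cio.read_truth_csv(out / "truth.csv")
    if selections is None:
        sel_path = out / "selections.json"
        if sel_path.exists():
            payload = json.loads(sel_path.read_text())
            selections = {fs: d["chosen_columns"]
                          for fs, d in payload.items()}
    result = run_experiment(combined, truth, selections=selections,
                            kmax=config.kmax, folds=config.folds,
                            seed=config.seed)
    reports_to_frame(result["reports"]).to_csv(out / "reports.csv",
                                               index=False)
    rows = []
    for (fs, method, stage), rep in result["per_stage"].items():
        rows.append({"feature_set": fs, "method": method, "stage": stage,
                     "r2": rep.r2, "rmse": rep.rmse,
                     "nrmse_percent": rep.nrmse_percent, "n": rep.n})
    pd.DataFrame(rows).to_csv(out / "reports_per_stage.csv", index=False)
    # measured-vs-estimated scatter data for the mapped model
    key = (config.map_feature_set, config.map_method, "validation")
    rep = result["reports"][key]
    pd.DataFrame({"measured": rep.measured, "estimated": rep.predicted}
                 ).to_csv(out / "scatter_validation.csv", index=False)
    return result


def pixel_feature_planes(cube: ReflectanceCube, columns, config: RunConfig,
                         texture_maps: dict | None = None) -> np.ndarray:
    """Per-pixel planes for a list of feature columns.

    OSR columns read the band plane, FDSR columns the per-pixel
    finite-difference transform, VI columns the registry formula on
    each pixel spectrum, TEX columns the sliding-window texture maps.
    """
    H, W, _ = cube.values.shape
    planes = np.full((len(columns), H, W), np.nan)
    tex_needed = [c for c in columns if c in TEXTURE_NAMES]
    if tex_needed and texture_maps is None:
        pc1 = pca_first_component(cube)
        texture_maps = texture_feature_maps(pc1, G=config.gray_levels,
                                            window=config.window,
                                            offset=config.offset)
    wl = cube.wavelengths
    dl = cube.delta_lambda
    for k, col in enumerate(columns):
        if col in TEXTURE_NAMES:
            planes[k] = texture_maps[col]
        elif col.startswith("R") and col[1:].isdigit():
            planes[k] = cube.values[:, :, cube.band_index(float(col[1:]))]
        elif col.startswith("D") and col[1:].isdigit():
            i = cube.band_index(float(col[1:]))
            lo = max(1, min(i, cube.n_bands - 2))
            if config.fdsr_convention == "printed":
                planes[k] = (cube.values[:, :, lo - 1]
                             - cube.values[:, :, lo + 1]) / dl
            else:
                planes[k] = (cube.values[:, :, lo + 1]
                             - cube.values[:, :, lo - 1]) / (2 * dl)
        else:
            try:
                planes[k] = vi_image(cube, col)
            except KeyError:
                raise ValueError(
                    f"feature {col!r} cannot be computed per pixel")
    return planes


@_timed("map")
def write_lai_map(model, cube: ReflectanceCube, layout, stage: str,
                  config: RunConfig, path=None) -> np.ndarray:
    """Pixel-wise LAI prediction raster, masked outside the plots.

    The plot-level model is applied to per-pixel features: spectral
    features from the pixel spectrum, texture features from the 5x5
    window centred on the pixel.
    """
    planes = pixel_feature_planes(cube, model.columns, config)
    H, W = cube.mask.shape
    xx, yy = cube.pixel_centers()
    in_plot = np.zeros((H, W), dtype=bool)
    for plot in layout:
        in_plot |= shapely.contains_xy(
            plot.polygon, xx.ravel(), yy.ravel()).reshape(H, W)
    valid = in_plot & cube.mask & np.isfinite(planes).all(axis=0)
    lai_map = np.full((H, W), np.nan)
    if valid.any():
        X = planes[:, valid].T
        lai_map[valid] = model.predict(X)
    if path is not None:
        cio.write_envi(path, lai_map, pixel_size=cube.pixel_size,
                       nodata=float("nan"))
    return lai_map


def stage_map(config: RunConfig, result=None, cubes=None, layout=None):
    """Refit the configured mapping model and write per-stage LAI maps."""
    out = _out(config)
    if layout is None or cubes is None:
        layout, truth, cubes = _load_simulated(config)
    else:
        truth = cio.read_truth_csv(out / "truth.csv")
    if result is not None:
        model = result["models"][(config.map_feature_set, config.map_method)]
    else:
        combined = FeatureTable.from_csv(out / "features.csv")
        payload = json.loads((out / "selections.json").read_text())
        cols = payload[config.map_feature_set]["chosen_columns"]
        lai_by_key = {(t.plot_id, t.stage): t.lai for t in truth}
        train_keys = {(t.plot_id, t.stage) for t in truth
                      if t.replicate != 1}
        idx = [k for k in combined.data.index if tuple(k) in train_keys]
        y = np.array([lai_by_key[tuple(k)] for k in idx])
        model = fit(ModelSpec(config.map_method, seed=config.seed),
                    combined.data.loc[idx, cols], y)
    maps = {}
    for stage in config.stages:
        maps[stage] = write_lai_map(model, cubes[stage], layout, stage,
                                    config, path=out / f"lai_map_{stage}.bsq")
    return maps


def run_all(config: RunConfig) -> dict:
    """The whole workflow; returns the in-memory artifact bundle."""
    out = _out(config)
    config.to_yaml(out / "config.yaml")
    layout, truth, cubes = stage_simulate(config)
    combined = stage_extract(config, layout, truth, cubes)
    screen, selections = stage_select(config, combined, truth)
    result = stage_train(config, combined, truth,
                         {fs: r.chosen_columns
                          for fs, r in selections.items()})
    maps = stage_map(config, result=result, cubes=cubes, layout=layout)
    return {"layout": layout, "truth": truth, "cubes": cubes,
            "features": combined, "screen": screen,
            "selections": selections, "result": result, "maps": maps,
            "out_dir": out}
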