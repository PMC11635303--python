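"""Serialization: ENVI-style rasters, GeoJSON plot layouts, truth CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .containers import ReflectanceCube
from .synth import GroundTruthLAI, PlotLayout


def write_envi(path, values: np.ndarray, wavelengths=None,
               pixel_size: float = 1.0, nodata: float | None = None):
    """Write an array as ENVI BSQ (raw float32 + text header).

    ``values`` may be H x W (single band) or H x W x B.
    """
    path = Path(path)
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w, b = arr.shape
    np.transpose(arr, (2, 0, 1)).tofile(path)
    lines = ["ENVI",
             f"samples = {w}", f"lines = {h}", f"bands = {b}",
             "header offset = 0", "file type = ENVI Standard",
             "data type = 4", "interleave = bsq", "byte order = 0",
             f"pixel size = {{{pixel_size}, {pixel_size}}}"]
    if wavelengths is not None:
        wl = ", ".join(f"{x:g}" for x in np.asarray(wavelengths))
        lines.append("wavelength units = Nanometers")
        lines.append(f"wavelength = {{{wl}}}")
    if nodata is not None:
        lines.append(f"data ignore value = {nodata}")
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(lines) + "\n")


def read_envi(path) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Read an ENVI BSQ raster written by :func:`write_envi`.

    Returns (values H x W x B, wavelengths or None, pixel_size).
    """
    path = Path(path)
    hdr = path.with_suffix(path.suffix + ".hdr").read_text()
    meta = {}
    for line in hdr.splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    h, w, b = int(meta["lines"]), int(meta["samples"]), int(meta["bands"])
    arr = np.fromfile(path, dtype=np.float32).reshape(b, h, w)
    wl = None
    if "wavelength" in meta:
        wl = np.array([float(x) for x in
                       meta["wavelength"].strip("{} ").split(",")])
    ps = 1.0
    if "pixel size" in meta:
        ps = float(meta["pixel size"].strip("{} ").split(",")[0])
    return np.transpose(arr, (1, 2, 0)).astype(float), wl, ps


def write_cube(path, cube: ReflectanceCube):
    write_envi(path, cube.values, wavelengths=cube.wavelengths,
               pixel_size=cube.pixel_size)


def read_cube(path) -> ReflectanceCube:
    values, wl, ps = read_envi(path)
    return ReflectanceCube(values, wl, pixel_size=ps)


def write_layout_geojson(path, layout: list[PlotLayout]):
    features = []
    for p in layout:
        features.append({
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {"plot_id": p.plot_id, "variety": p.variety,
                           "density_level": p.density_level,
                           "n_level": p.n_level, "k_level": p.k_level,
                           "replicate": p.replicate}})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_layout_geojson(path) -> list[PlotLayout]:
    gj = json.loads(Path(path).read_text())
    out = []
    for feat in gj["features"]:
        pr = feat["properties"]
        out.append(PlotLayout(pr["plot_id"], pr["variety"],
                              pr["density_level"], pr["n_level"],
                              pr["k_level"], pr["replicate"],
                              shape(feat["geometry"])))
    return out


def write_truth_csv(path, truth: list[GroundTruthLAI]):
    pd.DataFrame([{"plot_id": t.plot_id, "stage": t.stage, "W1": t.W1,
                   "W2": t.W2, "S": t.S, "M": t.M, "lai": t.lai,
                   "replicate": t.replicate} for t in truth]
                 ).to_csv(path, index=False)


def read_truth_csv(path) -> list[GroundTruthLAI]:
    df = pd.read_csv(path)
    return [GroundTruthLAI(int(r.plot_id), r.stage, r.W1, r.W2, r.S, r.M,
                           r.lai, replicate=int(r.replicate))
            for r in df.itertuples()]
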