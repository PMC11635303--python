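"""Spectral feature families: plot-mean reflectance, first-order
differential spectra, and the 30-entry vegetation-index registry.

Per sample (plot x stage) the default configuration yields 125 OSR
columns (band reflectances), 125 FDSR columns and 30 VI columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .containers import FeatureTable, ReflectanceCube


@dataclass
class SpectrumRecord:
    plot_id: int
    stage: str
    reflectance: np.ndarray
    wavelengths: np.ndarray


def plot_mean_spectrum(cube: ReflectanceCube, layout, stage: str
                       ) -> list[SpectrumRecord]:
    """Unweighted mean spectrum over masked-in pixels whose centres fall
    inside each plot polygon."""
    xx, yy = cube.pixel_centers()
    out = []
    for plot in layout:
        inside = shapely.contains_xy(plot.polygon, xx.ravel(), yy.ravel())
        sel = inside.reshape(cube.mask.shape) & cube.mask
        if not sel.any():
            raise ValueError(f"plot {plot.plot_id} has no valid pixels")
        mean = cube.values[sel].mean(axis=0)
        out.append(SpectrumRecord(plot.plot_id, stage, mean,
                                  cube.wavelengths))
    return out


def fdsr(spectrum: np.ndarray, delta_lambda: float,
         convention: str = "printed") -> np.ndarray:
    """First-order differential spectral reflectance.

    With ``convention='printed'`` the transform at interior channel i is
    ``(R(i-1) - R(i+1)) / delta_lambda`` — note this equals -2x the
    conventional central difference, which ``convention='central'``
    gives instead ((R(i+1) - R(i-1)) / (2 delta_lambda)). Endpoints are
    replicated from the nearest interior value; output length equals
    input length.
    """
    r = np.asarray(spectrum, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise ValueError("spectrum must be a vector of length >= 3")
    out = np.empty_like(r)
    if convention == "printed":
        out[1:-1] = (r[:-2] - r[2:]) / delta_lambda
    elif convention == "central":
        out[1:-1] = (r[2:] - r[:-2]) / (2.0 * delta_lambda)
    else:
        raise ValueError(f"unknown fdsr convention {convention!r}")
    out[0] = out[1]
    out[-1] = out[-2]
    return out


# ---------------------------------------------------------------------------
# Vegetation-index registry. Each formula is written against a band
# accessor b(wavelength_nm) that resolves to the nearest grid channel,
# so the same registry serves plot-mean spectra (scalars) and whole
# images (arrays).

VI_REGISTRY = {
    "DVI": lambda b: b(890) - b(670),
    "EVI": lambda b: 2.5 * (b(800) - b(670))
    / (b(800) + 6 * b(670) - 7.5 * b(450) + 1),
    "EVI2": lambda b: 2.5 * (b(800) - b(670)) / (b(800) + 2.4 * b(670) + 1),
    "GNDVI": lambda b: (b(750) - b(550)) / (b(750) + b(550)),
    "GI": lambda b: b(554) / b(677),
    "LCI": lambda b: (b(850) - b(710)) / (b(850) + b(670)) ** 0.5,
    "MCARI": lambda b: ((b(700) - b(670)) - 0.2 * (b(700) - b(550)))
    * (b(700) / b(670)),
    "MSR": lambda b: (b(800) / b(670) - 1) / (b(800) / b(670) + 1) ** 0.5,
    "MSAVI": lambda b: 0.5 * (2 * b(800) + 1 - ((2 * b(800) + 1) ** 2
                                                - 8 * (b(800) - b(670))) ** 0.5),
    "MTVI1": lambda b: 1.2 * (1.2 * (b(800) - b(550))
                              - 2.5 * (b(670) - b(550))),
    # first term uses R500 as tabulated in the source register
    "MTVI2": lambda b: 1.5 * (1.2 * (b(800) - b(500))
                              - 2.5 * (b(670) - b(550)))
    / (2 * (b(800) + 1) ** 2 - (6 * b(800) - 5 * b(670) ** 0.5) - 0.5) ** 0.5,
    "NDVI": lambda b: (b(800) - b(680)) / (b(800) + b(680)),
    "NDRE": lambda b: (b(790) - b(720)) / (b(790) + b(720)),
    "NPCI": lambda b: (b(670) - b(460)) / (b(670) + b(460)),
    "NDI": lambda b: (b(850) - b(710)) / (b(850) + b(680)),
    "NRI": lambda b: (b(570) - b(670)) / (b(570) + b(670)),
    "OSAVI": lambda b: 1.16 * (b(800) - b(670)) / (b(800) + b(670) + 0.16),
    "PSRI": lambda b: (b(680) - b(500)) / b(750),
    "PSND": lambda b: (b(800) - b(470)) / (b(800) + b(470)),
    "PBI": lambda b: b(810) / b(560),
    "RVI": lambda b: b(810) / b(660),
    "RDVI": lambda b: (b(800) - b(670)) / (b(800) + b(670)) ** 0.5,
    "RASI": lambda b: b(760) / b(500),
    "RVSI": lambda b: (b(712) + b(752)) / 2 - b(732),
    "SAVI": lambda b: 1.5 * (b(800) - b(670)) / (b(800) + b(670) + 0.5),
    "SPVI": lambda b: 0.4 * (3.7 * (b(800) - b(670))
                             - 1.2 * abs(b(550) - b(670))),
    "TVI": lambda b: 0.5 * (120 * (b(750) - b(550))
                            - 200 * (b(670) - b(550))),
    "TCARI": lambda b: 3 * ((b(710) - b(680))
                            - 0.2 * (b(700) - b(560)) * (b(710) / b(680))),
    "VARI": lambda b: (b(555) - b(680)) / (b(555) + b(680) - b(480)),
    "WDRVI": lambda b: (0.1 * b(800) - b(670)) / (0.1 * b(800) + b(670)),
}

VI_NAMES = tuple(VI_REGISTRY)


def _band_accessor(reflectance, wavelengths):
    wl = np.asarray(wavelengths, dtype=float)

    def b(target):
        idx = int(np.argmin(np.abs(wl - target)))
        return reflectance[..., idx] if np.ndim(reflectance) > 1 \
            else reflectance[idx]
    return b


def compute_vi(record: SpectrumRecord, vi_name: str) -> float:
    """Evaluate one registry formula on a plot-mean spectrum; referenced
    wavelengths resolve to the nearest grid channel (ties toward the
    lower wavelength)."""
    if vi_name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {vi_name!r}")
    b = _band_accessor(record.reflectance, record.wavelengths)
    with np.errstate(divide="raise", invalid="raise"):
        try:
            return float(VI_REGISTRY[vi_name](b))
        except FloatingPointError as exc:
            raise ValueError(
                f"{vi_name} undefined for this spectrum (division by zero "
                f"or invalid operation)") from exc


def vi_image(cube: ReflectanceCube, vi_name: str) -> np.ndarray:
    """Per-pixel VI plane over a whole cube (used for LAI mapping)."""
    if vi_name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {vi_name!r}")
    b = _band_accessor(cube.values, cube.wavelengths)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(VI_REGISTRY[vi_name](b), dtype=float)


def osr_column(wavelength: float) -> str:
    return f"R{int(round(wavelength))}"


def fdsr_column(wavelength: float) -> str:
    return f"D{int(round(wavelength))}"


def build_spectral_features(records: list[SpectrumRecord],
                            vi_names=VI_NAMES,
                            fdsr_convention: str = "printed") -> FeatureTable:
    """Assemble the OSR + FDSR + VI table for a set of samples."""
    if not records:
        raise ValueError("no spectrum records")
    wl = records[0].wavelengths
    dl = float(wl[1] - wl[0])
    osr_cols = [osr_column(w) for w in wl]
    fdsr_cols = [fdsr_column(w) for w in wl]
    rows, index = [], []
    for rec in records:
        d = fdsr(rec.reflectance, dl, convention=fdsr_convention)
        vis = [compute_vi(rec, name) for name in vi_names]
        rows.append(np.concatenate([rec.reflectance, d, vis]))
        index.append((rec.plot_id, rec.stage))
    cols = osr_cols + fdsr_cols + list(vi_names)
    data = pd.DataFrame(rows, columns=cols,
                        index=pd.MultiIndex.from_tuples(
                            index, names=["plot_id", "stage"]))
    families = {c: "OSR" for c in osr_cols}
    families.update({c: "FDSR" for c in fdsr_cols})
    families.update({c: "VI" for c in vi_names})
    return FeatureTable(data, families)
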