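"""Synthetic potato field experiment: layout, ground-truth LAI, imagery.

Emulates a density/nitrogen/potash trial on two early-maturing potato
varieties: 16 treatments x 3 replicates = 48 plots of 32.5 m^2, observed
at three growth stages (BBCH41 tuber formation, BBCH44 tuber growth,
BBCH47 starch accumulation). Ground-truth LAI comes from the destructive
leaf-disc weighing protocol; canopy imagery is a 125-band hyperspectral
cube in which per-pixel spectra follow a gap-fraction (Beer-law) mixture
of a leaf and a soil spectrum, and within-plot spatial structure
(planting-row stripes plus a correlated random field whose roughness
decreases with canopy closure) carries an independent texture signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

STAGES = ("BBCH41", "BBCH44", "BBCH47")
#: Per-stage target mean LAI of the generated population.
STAGE_MEAN_LAI = {"BBCH41": 1.50, "BBCH44": 1.32, "BBCH47": 1.28}
LAI_RANGE = (0.29, 3.75)

DENSITY_LEVELS = (60000, 72000, 84000)        # tubers per hectare
N_LEVELS = (0.0, 112.5, 225.0, 337.5)         # kg pure N per hectare
K_LEVELS = (0.0, 495.0, 990.0)                # kg K2O per hectare
VARIETIES = ("Z3", "Z5")

#: Total one-sided area of the 60 leaf discs punched with a 0.8 cm
#: diameter punch, in m^2.
DISC_AREA_TOTAL = 60 * math.pi * 0.004 ** 2

# Scene geometry (metres / pixels). 48 plots of 6.5 m x 5 m = 32.5 m^2
# on an 8 x 6 grid with 1 m alleys, sampled at 0.25 m GSD.
PIXEL_SIZE = 0.25
PLOT_W_PX, PLOT_H_PX = 26, 20
GAP_PX, MARGIN_PX = 4, 2
GRID_COLS, GRID_ROWS = 8, 6
SCENE_W_PX = 2 * MARGIN_PX + GRID_COLS * PLOT_W_PX + (GRID_COLS - 1) * GAP_PX
SCENE_H_PX = 2 * MARGIN_PX + GRID_ROWS * PLOT_H_PX + (GRID_ROWS - 1) * GAP_PX

#: 125 channels at 4 nm from 450 nm (450-946 nm). The sensor's printed
#: range would imply one extra channel; the channel count wins and the
#: origin is configurable where it matters.
WAVELENGTH_START, WAVELENGTH_STEP, N_BANDS = 450.0, 4.0, 125


def wavelength_grid(start: float = WAVELENGTH_START,
                    step: float = WAVELENGTH_STEP,
                    n: int = N_BANDS) -> np.ndarray:
    return start + step * np.arange(n)


# Multiplicative treatment response factors. LAI increases with planting
# density and with nitrogen up to N2 (plateau at N3); potash and variety
# effects are mild.
_DENSITY_EFFECT = {60000: 0.85, 72000: 1.00, 84000: 1.12}
_N_EFFECT = {0.0: 0.55, 112.5: 0.85, 225.0: 1.15, 337.5: 1.18}
_K_EFFECT = {0.0: 0.90, 495.0: 1.00, 990.0: 1.05}
_VARIETY_EFFECT = {"Z3": 0.95, "Z5": 1.05}


@dataclass
class PlotLayout:
    """One experimental plot with its treatment and footprint."""
    plot_id: int
    variety: str
    density_level: int       # plants per hectare
    n_level: float           # kg pure N per hectare
    k_level: float           # kg K2O per hectare
    replicate: int           # 1..3
    polygon: Polygon         # scene coordinates, area 32.5 m^2

    @property
    def plants_per_m2(self) -> float:
        return self.density_level / 10_000.0


@dataclass
class GroundTruthLAI:
    """Destructive LAI record for one plot at one stage.

    W1/W2 are the wet weights (g) of the 60 punched discs and of the
    remaining leaves of the 3 sampled plants; S the total one-sided
    disc area (m^2); M the stand density (plants per m^2).
    """
    plot_id: int
    stage: str
    W1: float
    W2: float
    S: float
    M: float
    lai: float
    replicate: int = 0


def compute_lai_eq1(W1: float, W2: float, S: float, M: float) -> float:
    """LAI from the disc-weighing bookkeeping.

    LAI = (W1 + W2) / (3 * W1) * S * M: the disc-to-total weight ratio
    scales the known disc area up to whole-plant leaf area per plant
    (the factor 3 is the number of sampled plants), and M converts to
    area per unit ground area.
    """
    W1 = np.asarray(W1, dtype=float)
    S = np.asarray(S, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(W1 <= 0) or np.any(S <= 0) or np.any(M <= 0):
        raise ValueError("W1, S and M must be positive")
    W2 = np.asarray(W2, dtype=float)
    out = (W1 + W2) / (3.0 * W1) * S * M
    return float(out) if out.ndim == 0 else out


def _treatments():
    """The 16 unique treatments: per variety, a density trial
    {P1,P3} at N2/K1, a nitrogen trial {N0,N1,N3} at P2/K1, the shared
    P2/N2/K1 plot, and a potash trial {K0,K2} at P2/N2."""
    out = []
    for v in VARIETIES:
        out.append((v, 60000, 225.0, 495.0))
        out.append((v, 84000, 225.0, 495.0))
        out.append((v, 72000, 225.0, 495.0))
        out.append((v, 72000, 0.0, 495.0))
        out.append((v, 72000, 112.5, 495.0))
        out.append((v, 72000, 337.5, 495.0))
        out.append((v, 72000, 225.0, 0.0))
        out.append((v, 72000, 225.0, 990.0))
    return out


def make_layout(seed: int) -> list[PlotLayout]:
    """48 plots on an 8 x 6 grid, treatments x 3 replicates randomly
    placed (seeded); polygons are disjoint 6.5 m x 5 m rectangles."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    assignments = [(t, r) for t in _treatments() for r in (1, 2, 3)]
    order = rng.permutation(len(assignments))
    plots = []
    for pid, k in enumerate(order, start=1):
        (variety, dens, n, kk), rep = assignments[k]
        gi = pid - 1
        gc, gr = gi % GRID_COLS, gi // GRID_COLS
        c0 = MARGIN_PX + gc * (PLOT_W_PX + GAP_PX)
        r0 = MARGIN_PX + gr * (PLOT_H_PX + GAP_PX)
        poly = box(c0 * PIXEL_SIZE, r0 * PIXEL_SIZE,
                   (c0 + PLOT_W_PX) * PIXEL_SIZE,
                   (r0 + PLOT_H_PX) * PIXEL_SIZE)
        plots.append(PlotLayout(pid, variety, dens, n, kk, rep, poly))
    return plots


def treatment_response(plot: PlotLayout, stage: str) -> float:
    """Deterministic (noise-free) LAI response for a plot at a stage."""
    g = (_DENSITY_EFFECT[plot.density_level] * _N_EFFECT[plot.n_level]
         * _K_EFFECT[plot.k_level] * _VARIETY_EFFECT[plot.variety])
    mean_g = np.mean([_DENSITY_EFFECT[d] * _N_EFFECT[n] * _K_EFFECT[k]
                      * _VARIETY_EFFECT[v] for v, d, n, k in _treatments()])
    return STAGE_MEAN_LAI[stage] * g / mean_g


def simulate_lai(layout: list[PlotLayout], stage: str, seed: int,
                 noise_sigma: float = 0.35) -> list[GroundTruthLAI]:
    """Ground-truth LAI for every plot at one stage.

    LAI = treatment response x mean-one lognormal plot noise, truncated
    to the observed field range; the disc weights W1/W2 are then
    back-computed so the weighing formula reproduces lai exactly.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    sidx = STAGES.index(stage)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, sidx]))
    out = []
    for plot in layout:
        base = treatment_response(plot, stage)
        noise = math.exp(rng.normal(0.0, noise_sigma)
                         - 0.5 * noise_sigma ** 2) if noise_sigma > 0 else 1.0
        lai = float(np.clip(base * noise, *LAI_RANGE))
        W1 = float(np.clip(rng.normal(1.5, 0.15), 0.5, None))
        S, M = DISC_AREA_TOTAL, plot.plants_per_m2
        # invert the weighing formula: (W1+W2)/(3 W1) * S * M = lai
        W2 = W1 * (3.0 * lai / (S * M) - 1.0)
        out.append(GroundTruthLAI(plot.plot_id, stage, W1, W2, S, M, lai,
                                  replicate=plot.replicate))
    return out


# ---------------------------------------------------------------------------
# Hyperspectral scene synthesis


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


#: Stage-dependent leaf optics: NIR plateau level and senescence lift of
#: red reflectance (leaves yellow toward starch accumulation).
_STAGE_LEAF = {"BBCH41": (0.46, 0.00),
               "BBCH44": (0.44, 0.05),
               "BBCH47": (0.42, 0.15)}


def leaf_spectrum(wavelengths: np.ndarray, stage: str,
                  chlorophyll: float = 1.0, nir: float | None = None
                  ) -> np.ndarray:
    """Parametric green-leaf reflectance: green peak near 550 nm, red
    absorption trough, red-edge ramp near 715 nm, NIR plateau."""
    wl = np.asarray(wavelengths, dtype=float)
    nir_base, senescence = _STAGE_LEAF[stage]
    if nir is None:
        nir = nir_base
    green = (0.055 / max(chlorophyll, 0.2)) * np.exp(
        -0.5 * ((wl - 550.0) / 30.0) ** 2)
    red_lift = senescence * 0.2 * np.exp(
        -0.5 * ((wl - 640.0) / 45.0) ** 2)
    vis = 0.03 + green + red_lift
    edge = _sigmoid((wl - 715.0) / 13.0)
    return vis * (1.0 - edge) + nir * edge


def soil_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Dry-soil reflectance, linearly increasing with wavelength."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.10 + 0.10 * (wl - 450.0) / 500.0


def _unit_field(rng, shape, smooth_sigma):
    """Zero-mean, unit-variance correlated random field."""
    f = gaussian_filter(rng.standard_normal(shape), smooth_sigma,
                        mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_cube(layout: list[PlotLayout], truth: list[GroundTruthLAI],
                  stage: str, seed: int, *,
                  k_ext: float = 0.5,
                  k_ext_sd: float = 0.3,
                  noise_sigma: float = 0.004,
                  roughness0: float = 0.9,
                  roughness_noise: float = 0.3,
                  soil_brightness_sd: float = 0.10,
                  chlorophyll_sd: float = 0.15,
                  nir_sd: float = 0.02,
                  illumination_sd: float = 0.03,
                  wavelengths: np.ndarray | None = None):
    """Synthesize the stage's hyperspectral cube over the whole scene.

    Each pixel is a vegetation-fraction mixture
    ``R = f * R_leaf + (1 - f) * R_soil`` with ``f = 1 - exp(-k_ext *
    LAI_local)``. ``LAI_local`` varies within a plot as planting-row
    stripes plus a correlated random field; the relative amplitude of
    that variation (the plot's *roughness*) decreases as plot LAI grows,
    so canopy closure smooths the image and textures carry an LAI
    signal that is statistically independent of the spectral nuisances.

    The per-plot nuisances emulate the spectral confounding of real
    field imagery, all uncorrelated with LAI: a lognormal jitter of the
    extinction coefficient (canopy-architecture variation, which caps
    how well any spectral feature can invert the gap fraction back to
    LAI while leaving the leaf-soil mixing axis as the single dominant
    spectral direction), plus milder soil-brightness, chlorophyll,
    NIR-plateau and illumination jitters. Their default magnitudes are
    calibrated so single-family regressions land in the accuracy range
    typical of plot trials rather than recovering LAI exactly.
    """
    from .containers import ReflectanceCube

    if wavelengths is None:
        wavelengths = wavelength_grid()
    truth_by_plot = {t.plot_id: t for t in truth if t.stage == stage}
    missing = [p.plot_id for p in layout if p.plot_id not in truth_by_plot]
    if missing:
        raise ValueError(f"no ground truth for plots {missing[:5]} at {stage}")

    sidx = STAGES.index(stage)
    root = np.random.SeedSequence([int(seed), 23, sidx])
    rng_scene = np.random.default_rng(root.spawn(1)[0])

    H, W, B = SCENE_H_PX, SCENE_W_PX, wavelengths.size
    roughness_by_plot = {}
    soil = soil_spectrum(wavelengths)
    # background: bare soil with a gentle scene-scale brightness field
    bg_bright = 1.0 + 0.05 * _unit_field(rng_scene, (H, W), 8.0)
    values = bg_bright[:, :, None] * soil[None, None, :]

    for plot in layout:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 23, sidx, plot.plot_id]))
        lai = truth_by_plot[plot.plot_id].lai
        # per-plot nuisances, uncorrelated with LAI
        b_soil = math.exp(rng.normal(0.0, soil_brightness_sd))
        chl = math.exp(rng.normal(0.0, chlorophyll_sd))
        nir = _STAGE_LEAF[stage][0] + rng.normal(0.0, nir_sd)
        illum = math.exp(rng.normal(0.0, illumination_sd))
        k_plot = k_ext * math.exp(rng.normal(0.0, k_ext_sd))
        rough = (roughness0 / (1.0 + lai)
                 * math.exp(rng.normal(0.0, roughness_noise)))
        roughness_by_plot[plot.plot_id] = rough

        x0, y0, x1, y1 = plot.polygon.bounds
        c0, c1 = int(round(x0 / PIXEL_SIZE)), int(round(x1 / PIXEL_SIZE))
        r0, r1 = int(round(y0 / PIXEL_SIZE)), int(round(y1 / PIXEL_SIZE))
        ph, pw = r1 - r0, c1 - c0

        rows = np.arange(ph)[:, None]
        stripe = np.cos(2.0 * np.pi * rows / 4.0) * np.ones((1, pw))
        field = _unit_field(rng, (ph, pw), 1.5)
        rel = np.clip(1.0 + rough * (0.55 * stripe + 0.8 * field), 0.05, None)
        lai_local = lai * rel
        f = 1.0 - np.exp(-k_plot * lai_local)

        leaf = leaf_spectrum(wavelengths, stage, chlorophyll=chl, nir=nir)
        patch = (f[:, :, None] * leaf[None, None, :]
                 + (1.0 - f)[:, :, None] * (b_soil * soil)[None, None, :])
        values[r0:r1, c0:c1, :] = illum * patch

    if noise_sigma > 0:
        values = values + rng_scene.normal(0.0, noise_sigma, size=values.shape)
    values = np.clip(values, 0.0, 1.2)
    return ReflectanceCube(values.astype(np.float64), wavelengths,
                           mask=np.ones((H, W), dtype=bool),
                           pixel_size=PIXEL_SIZE,
                           meta={"roughness": roughness_by_plot})


def simulate_experiment(seed: int, stages=STAGES, **cube_kwargs):
    """Convenience wrapper: layout, per-stage truth and cubes.

    Returns ``(layout, truth, cubes)`` with ``truth`` a flat list over
    all stages and ``cubes`` a dict stage -> ReflectanceCube.
    """
    layout = make_layout(seed)
    truth, cubes = [], {}
    for stage in stages:
        t = simulate_lai(layout, stage, seed)
        truth.extend(t)
        cubes[stage] = simulate_cube(layout, t, stage, seed, **cube_kwargs)
    return layout, truth, cubes
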