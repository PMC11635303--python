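# Methods

This note documents the models, conventions and design choices behind
`canopylai`, in the order the pipeline runs them.

## Synthetic field trial

The generator stands in for a real plot experiment; it is first-class,
tested code, and its defaults define the study conditions used
throughout the tests and examples.

**Design.** Two early-maturing varieties (Z3, Z5) × 8 treatments × 3
replicates = 48 plots of 6.5 m × 5 m (32.5 m²) on an 8 × 6 grid with
1 m alleys. The published description of such trials (3 planting
densities, 4 nitrogen levels, potash levels, 48 plots, 3 replicates)
does not pin down the 16 unique treatments; we resolve them as, per
variety: a density trial {60 000, 84 000 tubers/ha} at N2/K1, a
nitrogen trial {0, 112.5, 337.5 kg N/ha} at P2/K1, the shared
P2/N2/K1 plot, and a potash trial {0, 990 kg K₂O/ha} at P2/N2 — the
overlap of the density and nitrogen control plots makes the arithmetic
close (2 + 3 + 1 + 2 = 8).

**Ground truth.** Plot LAI is a multiplicative treatment response
(increasing in density; increasing in nitrogen up to N2 with a plateau
at N3; mild potash and variety effects) times a stage multiplier
calibrated so the population means are ≈ 1.50 / 1.32 / 1.28 at
BBCH 41/44/47, times mean-one lognormal plot noise (σ = 0.35),
truncated to the observed field range [0.29, 3.75]. The disc-weighing
weights are then back-computed so `(W1+W2)/(3·W1)·S·M` reproduces the
drawn LAI to machine precision: W1 ~ N(1.5 g, 0.15 g), S is the total
one-sided area of 60 discs punched with a 0.8 cm punch
(60·π·0.004² ≈ 3.016×10⁻³ m²), and M is the density level divided by
10⁴ (plants/m²). We read S as the *total* disc area — the alternative
(one disc) yields LAI off by 60× from observed magnitudes.

**Scene.** 125 channels at 450 + 4k nm (k = 0…124). The sensor
literature quotes "450–950 nm at 4 nm", which would imply 126 points;
the stated channel count (125) wins and the grid origin is exposed in
`RunConfig`. Pixels are 0.25 m; each pixel mixes a parametric leaf
spectrum (green peak at 550 nm, red absorption, red edge at ~715 nm,
stage-dependent NIR plateau and senescence lift) with a linear dry-soil
spectrum through the gap fraction `f = 1 − exp(−k·LAI_local)`,
k = 0.5 by default. Within a plot, `LAI_local` varies as planting-row
stripes (4-pixel pitch) plus a Gaussian-smoothed random field; the
relative amplitude ("roughness") is `0.9/(1 + LAI)` times lognormal
plot noise, so canopy closure smooths the image and textures carry an
LAI signal. Additive sensor noise is N(0, 0.004).

**Nuisances and calibration.** Per-plot nuisances, all independent of
LAI, emulate the confounding of real imagery: a lognormal jitter of
the extinction coefficient (σ = 0.3; canopy-architecture variation
that caps how well any spectral feature can invert the gap fraction,
while keeping all spectral variance on the leaf–soil mixing axis),
soil brightness (σ = 0.10), chlorophyll (σ = 0.15), NIR plateau
(σ = 0.02) and illumination (σ = 0.03) jitters, and roughness noise
(σ = 0.3). These magnitudes were chosen so that (i) the first
principal component keeps ≥ 95% of spectral variance at every stage,
(ii) single-family regressions land in the accuracy range typical of
plot trials (validation R² ≈ 0.6–0.85) instead of recovering LAI
exactly, and (iii) the spectral and texture channels err independently,
so fusing them helps — the qualitative behaviour the pipeline is meant
to exhibit. What passing tests show is therefore that the *method*
recovers a planted, realistically-confounded signal; they say nothing
about absolute accuracy on real fields, where atmospheric effects,
BRDF, registration error and phenology are not modelled (no radiative
transfer, no illumination geometry, no stitching artefacts).

## Spectral features

Plot spectra are unweighted means over valid pixels whose centres fall
inside the plot polygon. The differential transform is implemented
exactly as the source register prints it,
`FDSR(i) = (R(i−1) − R(i+1))/Δλ` — note this equals −2× the
conventional central difference; `fdsr_convention="central"` switches
to the textbook form, and endpoints replicate the nearest interior
value. The 30-entry VI registry is transcribed verbatim, including its
oddities (MTVI2's first term uses R500 as printed; SPVI keeps an
absolute value; RVSI its bracket structure). A referenced wavelength
resolves to the nearest grid channel, ties toward the lower wavelength.
Division by zero in a VI raises an explicit error rather than emitting
NaN.

## Haralick textures

PCA is covariance PCA on per-pixel spectra (bands mean-centred, no
variance scaling); the PC1 loading sign is fixed so its
largest-magnitude element is positive. The score image is quantized to
G = 32 levels by a linear 2–98 percentile stretch (G and the stretch
are config-exposed; 32 levels keep 5×5-window co-occurrence matrices
non-degenerate). The GLCM uses offset (−1, +1) — one step up-right,
the 45° direction — accumulated symmetrically and normalized.
Windows are 5×5; windows touching the image edge or any masked pixel
are skipped (no padding). Per-plot values are the means of the
per-window feature maps inside the polygon.

Feature conventions: natural logarithms everywhere with 0·ln 0 = 0;
gray levels are 0…G−1 in GLCM statistics; the Haralick-correlation
feature uses the Orfeo Toolbox form `(Σ i·j·p − μ_t²)/σ_t²` with
moments from the row marginal; degenerate (zero-variance) windows
report correlation features as 0. Run lengths are maximal runs along
the 45° anti-diagonals of the window; the ten Galloway statistics use
gray level + 1 in the gray-weighted features so level 0 cannot divide
by zero. Exactly the 28 named features are produced — canonical
extensions such as long-run high gray-level emphasis are deliberately
out of scope.

Two implementations coexist: readable per-window reference functions
and a vectorized sliding-window path (batched bincount co-occurrence
counting, cumulative-product run-length decomposition). The suite
holds them to each other to 10⁻⁹, and to independent brute-force
oracles and `skimage.feature.graycomatrix` (whose row-down axis makes
its 3π/4 equal this package's 45°).

## Feature selection

`correlation_screen` reports Pearson r with two-sided p per column
(scipy), flags at 0.05/0.01, and per-family mean |r|. `spa_select`
standardizes columns, grows a projection chain from *every* candidate
start column (removing the textbook algorithm's random initialization),
and scores every chain prefix by the cross-validated RMSE of an
intercept + prefix multiple linear regression (classic SPA-MLR). The
CV pools squared errors over 3 seeded repetitions of a 5-fold
partition — a single partition made the prefix-length choice unstable
on 300-column tables. The global (start, length) minimum wins, first
minimum on ties; `kmax` defaults to min(30, ⌊n/3⌋). Selection is run
on the calibration replicates only, so the validation set never
influences which features the models see.

## Regression and evaluation

All models standardize inputs inside a sklearn Pipeline. PLSR picks
its component count (≤ 10) by internal 5-fold CV; RFR fixes
ntree = 500 and mtry = max(1, ⌊p/3⌋); GPR uses a constant × RBF +
white-noise kernel, normalized targets, and marginal-likelihood
optimization with 2 restarts, seeded. The printed renderings of the
accuracy formulas in the source register are typographically garbled,
so the standard forms are used: R² = 1 − SS_res/SS_tot,
RMSE = √(mean squared error), NRMSE = 100·RMSE/ȳ. The replicate-based
96/48 split is deterministic. `run_experiment` produces the
5 feature-sets × 3 methods × 2 splits grid plus a per-stage validation
breakdown.

## LAI mapping

How plot-level models should be applied to pixels is genuinely open;
the package applies the fitted model pixel-wise: band and differential
features from each pixel's spectrum, VI formulas evaluated per pixel,
texture features from the 5×5 window centred on the pixel, predictions
masked outside plot polygons and wherever a window is incomputable.
For linear models this commutes with plot averaging almost exactly;
for nonlinear models the tests require agreement of plot-mean map
values with plot-level predictions within 10%.

## Problem sizes and determinism

Default scenes are 144 × 240 px (34 560 pixels, ~35k texture windows
per stage), chosen so a complete three-stage run — simulation,
extraction, selection, training and mapping — finishes in about a
minute on one core while every plot still contains ≈ 480 pixels and
≈ 150 texture windows. All randomness flows from one master seed
through `numpy.random.SeedSequence` children per stage and plot; equal
seeds give bit-identical layouts, truths, cubes and downstream tables.

## Known limitations

* The leaf/soil spectra are parametric sketches, not radiative
  transfer; absolute reflectance values and VI magnitudes should not
  be compared against field spectra.
* The texture signal is planted through a single scalar roughness law;
  real canopies express structure through row orientation, leaf
  angle and shadowing that a 5×5 gray-level window only partially
  captures.
* SPA's internal scorer is linear; features whose LAI information is
  purely nonlinear can be under-selected even when the downstream GPR
  could exploit them.
* With 48 validation samples, differences of ≲ 0.05 in validation R²
  between feature sets are within seed-to-seed variation.
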