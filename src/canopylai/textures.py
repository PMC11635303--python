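"""Haralick textures from the first principal-component image.

The cube is reduced to its PC1 score image (covariance PCA over
per-pixel spectra), quantized to G gray levels, and 28 texture features
are extracted with a 5 x 5 sliding window in the 45-degree direction:

* 8 *simple* GLCM features (energy ... Haralick correlation),
* 10 *advanced* GLCM features (mean ... information measures of
  correlation IC1/IC2),
* 10 *higher-order* features from the gray-level run-length matrix
  (short run emphasis ... long run low gray-level emphasis, Galloway
  conventions with gray levels shifted by +1).

Two code paths exist on purpose: per-window reference functions
(:func:`glcm_window`, :func:`haralick_simple`, ...) written as plain
summations, and a vectorized whole-scene path
(:func:`texture_feature_maps`) used by the pipeline. The test suite
holds them to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from numpy.lib.stride_tricks import sliding_window_view

from .containers import FeatureTable, ReflectanceCube

SIMPLE_NAMES = ("energy", "entropy", "correlation",
                "inverse_difference_moment", "inertia", "cluster_shade",
                "cluster_prominence", "haralick_correlation")
ADVANCED_NAMES = ("mean", "variance", "dissimilarity", "sum_average",
                  "sum_variance", "sum_entropy", "difference_variance",
                  "difference_entropy", "ic1", "ic2")
RUNLENGTH_NAMES = ("short_run_emphasis", "long_run_emphasis",
                   "grey_level_nonuniformity", "run_length_nonuniformity",
                   "run_percentage", "low_grey_level_run_emphasis",
                   "high_grey_level_run_emphasis",
                   "short_run_low_grey_level_emphasis",
                   "short_run_high_grey_level_emphasis",
                   "long_run_low_grey_level_emphasis")
TEXTURE_NAMES = SIMPLE_NAMES + ADVANCED_NAMES + RUNLENGTH_NAMES


@dataclass
class PrincipalComponentImage:
    values: np.ndarray
    explained_variance_ratio: float
    mask: np.ndarray
    loading: np.ndarray = None
    pixel_size: float = 1.0


@dataclass
class GLCMatrix:
    """Normalized gray-level co-occurrence probabilities for one window."""
    p: np.ndarray
    levels: int
    offset: tuple = (-1, 1)
    symmetric: bool = True


@dataclass
class RunLengthMatrix:
    """Run-length counts r[g, l-1] for one window (direction 45 deg)."""
    r: np.ndarray
    levels: int
    n_pixels: int
    degenerate: bool = False

    @property
    def n_runs(self) -> int:
        return int(self.r.sum())


def pca_first_component(cube: ReflectanceCube) -> PrincipalComponentImage:
    """PC1 score image of the per-pixel spectra.

    Covariance PCA: bands are mean-centred over valid pixels, no
    variance scaling. The loading sign is fixed so its
    largest-magnitude element is positive.
    """
    X = cube.values[cube.mask]
    if cube.n_bands < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 bands and 2 valid pixels")
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = (Xc.T @ Xc) / (Xc.shape[0] - 1)
    trace = np.trace(cov)
    if trace <= 0:
        raise ValueError("degenerate cube: zero spectral variance")
    w, V = np.linalg.eigh(cov)
    v1 = V[:, -1]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    ratio = float(w[-1] / trace)
    scores = np.full(cube.mask.shape, np.nan)
    scores[cube.mask] = Xc @ v1
    return PrincipalComponentImage(scores, ratio, cube.mask.copy(), v1,
                                   pixel_size=cube.pixel_size)


def quantize(image: np.ndarray, G: int, mask: np.ndarray | None = None,
             stretch=(2.0, 98.0)) -> np.ndarray:
    """Linear 2-98 percentile stretch of valid pixels to levels 0..G-1.

    A constant image maps to level 0 everywhere. Invalid pixels get -1.
    """
    if G < 2:
        raise ValueError("need at least 2 gray levels")
    img = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.isfinite(img)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(img)
    q = np.full(img.shape, -1, dtype=np.int64)
    vals = img[mask]
    if vals.size == 0:
        return q
    lo, hi = np.percentile(vals, stretch)
    if hi <= lo:
        q[mask] = 0
        return q
    lev = np.floor((img[mask] - lo) / (hi - lo) * G)
    q[mask] = np.clip(lev, 0, G - 1).astype(np.int64)
    return q


# ---------------------------------------------------------------------------
# Per-window reference path


def glcm_window(q: np.ndarray, G: int, offset=(-1, 1),
                symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence probabilities of one quantized window.

    Counts pairs (q[r, c], q[r + dr, c + dc]) for every in-window
    position, optionally symmetrized, normalized to sum to 1.
    """
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("window contains masked pixels")
    dr, dc = offset
    h, w = q.shape
    counts = np.zeros((G, G), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("window too small for the offset")
    return GLCMatrix(counts / total, G, offset, symmetric)


def _marginals(p):
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    return px, py


def _xlogx(v):
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    nz = v > 0
    out[nz] = v[nz] * np.log(v[nz])
    return out


def haralick_simple(m: GLCMatrix) -> dict:
    """The eight simple GLCM statistics.

    Haralick correlation follows the Orfeo Toolbox convention
    ``(sum_ij i*j*p - mu_t^2) / sigma_t^2`` with the moments taken from
    the row marginal. Degenerate (zero-variance) windows report both
    correlations as 0.
    """
    p = m.p
    G = m.levels
    i = np.arange(G)[:, None] * np.ones((1, G))
    j = np.ones((G, 1)) * np.arange(G)[None, :]
    px, py = _marginals(p)
    mx = float((i * p).sum())
    my = float((j * p).sum())
    sx = float(np.sqrt(((i - mx) ** 2 * p).sum()))
    sy = float(np.sqrt(((j - my) ** 2 * p).sum()))
    out = {
        "energy": float((p ** 2).sum()),
        "entropy": float(-_xlogx(p).sum()),
        "inverse_difference_moment": float((p / (1 + (i - j) ** 2)).sum()),
        "inertia": float(((i - j) ** 2 * p).sum()),
        "cluster_shade": float(((i + j - mx - my) ** 3 * p).sum()),
        "cluster_prominence": float(((i + j - mx - my) ** 4 * p).sum()),
    }
    if sx > 0 and sy > 0:
        out["correlation"] = float((((i - mx) * (j - my) * p).sum())
                                   / (sx * sy))
    else:
        out["correlation"] = 0.0
    mu_t = float((np.arange(G) * px).sum())
    var_t = float(((np.arange(G) - mu_t) ** 2 * px).sum())
    if var_t > 0:
        out["haralick_correlation"] = float(((i * j * p).sum() - mu_t ** 2)
                                            / var_t)
    else:
        out["haralick_correlation"] = 0.0
    return {k: out[k] for k in SIMPLE_NAMES}


def haralick_advanced(m: GLCMatrix) -> dict:
    """The ten advanced GLCM statistics (marginal-based)."""
    p = m.p
    G = m.levels
    i = np.arange(G)[:, None] * np.ones((1, G))
    j = np.ones((G, 1)) * np.arange(G)[None, :]
    px, py = _marginals(p)
    mean = float((i * p).sum())
    # diagonal marginals p_{x+y}, p_{x-y}
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    for a in range(G):
        for b in range(G):
            psum[a + b] += p[a, b]
            pdiff[abs(a - b)] += p[a, b]
    k_sum = np.arange(2 * G - 1)
    k_diff = np.arange(G)
    sum_avg = float((k_sum * psum).sum())
    mu_d = float((k_diff * pdiff).sum())
    hxy = float(-_xlogx(p).sum())
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    # HXY1 = -sum p log(px py); HXY2 = -sum px py log(px py)
    outer = px[:, None] * py[None, :]
    lo = np.zeros_like(outer)
    nz = outer > 0
    lo[nz] = np.log(outer[nz])
    hxy1 = float(-(p * lo).sum())
    hxy2 = float(-_xlogx(outer).sum())
    denom = max(hx, hy)
    ic1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    ic2 = float(np.sqrt(max(arg, 0.0)))
    return {
        "mean": mean,
        "variance": float(((i - mean) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((k_sum - sum_avg) ** 2 * psum).sum()),
        "sum_entropy": float(-_xlogx(psum).sum()),
        "difference_variance": float(((k_diff - mu_d) ** 2 * pdiff).sum()),
        "difference_entropy": float(-_xlogx(pdiff).sum()),
        "ic1": ic1,
        "ic2": ic2,
    }


def _window_diagonals(h, w):
    """Anti-diagonal index paths (direction (-1, +1)) through an h x w
    window, each as a list of (row, col) from bottom-left to top-right."""
    paths = []
    for s in range(h + w - 1):
        path = [(r, s - r) for r in range(h - 1, -1, -1) if 0 <= s - r < w]
        paths.append(path)
    return paths


def glrlm_window(q: np.ndarray, G: int) -> RunLengthMatrix:
    """Gray-level run-length matrix of one window, 45-degree direction.

    Maximal runs of equal level are traced along every anti-diagonal;
    r[g, l-1] counts runs of level g and length l.
    """
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("window contains masked pixels")
    h, w = q.shape
    lmax = min(h, w)
    r = np.zeros((G, lmax), dtype=np.int64)
    for path in _window_diagonals(h, w):
        vals = [q[rc] for rc in path]
        k = 0
        while k < len(vals):
            length = 1
            while k + length < len(vals) and vals[k + length] == vals[k]:
                length += 1
            r[vals[k], length - 1] += 1
            k += length
    return RunLengthMatrix(r, G, h * w)


def runlength_features(rlm: RunLengthMatrix) -> dict:
    """The ten Galloway run-length statistics.

    Gray levels are shifted by +1 in the gray-weighted features so
    level 0 does not divide by zero.
    """
    r = rlm.r.astype(float)
    nr = r.sum()
    if nr == 0:
        raise ValueError("run-length matrix is empty")
    G, lmax = r.shape
    g = (np.arange(G) + 1.0)[:, None]
    l = np.arange(1, lmax + 1, dtype=float)[None, :]
    return {
        "short_run_emphasis": float((r / l ** 2).sum() / nr),
        "long_run_emphasis": float((r * l ** 2).sum() / nr),
        "grey_level_nonuniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "run_length_nonuniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "run_percentage": float(nr / rlm.n_pixels),
        "low_grey_level_run_emphasis": float((r / g ** 2).sum() / nr),
        "high_grey_level_run_emphasis": float((r * g ** 2).sum() / nr),
        "short_run_low_grey_level_emphasis":
            float((r / (g ** 2 * l ** 2)).sum() / nr),
        "short_run_high_grey_level_emphasis":
            float((r * g ** 2 / l ** 2).sum() / nr),
        "long_run_low_grey_level_emphasis":
            float((r * l ** 2 / g ** 2).sum() / nr),
    }


def window_features(q: np.ndarray, G: int, offset=(-1, 1)) -> dict:
    """All 28 texture features of one quantized window (reference path)."""
    m = glcm_window(q, G, offset=offset)
    out = haralick_simple(m)
    out.update(haralick_advanced(m))
    out.update(runlength_features(glrlm_window(q, G)))
    return out


# ---------------------------------------------------------------------------
# Vectorized whole-scene path


def _glcm_probabilities(qw, G):
    """Symmetric GLCM probabilities for a batch of 5x5 windows.

    qw: (N, win, win) int windows with no masked pixels.
    Returns (N, G, G).
    """
    n, win, _ = qw.shape
    a = qw[:, 1:, :-1]          # anchor q[r, c], r >= 1, c <= win-2
    b = qw[:, :-1, 1:]          # neighbour q[r-1, c+1]
    codes_ij = (a * G + b).reshape(n, -1)
    codes_ji = (b * G + a).reshape(n, -1)
    codes = np.concatenate([codes_ij, codes_ji], axis=1)
    offs = (np.arange(n) * G * G)[:, None]
    flat = (codes + offs).ravel()
    counts = np.bincount(flat, minlength=n * G * G).astype(float)
    P = counts.reshape(n, G, G)
    P /= P.sum(axis=(1, 2), keepdims=True)
    return P


def _glcm_features_batch(P):
    """All 18 GLCM features for a batch of probability matrices."""
    n, G, _ = P.shape
    i = np.arange(G)[:, None] * np.ones((1, G))
    j = i.T
    lev = np.arange(G, dtype=float)
    px = P.sum(axis=2)
    py = P.sum(axis=1)
    mx = px @ lev
    my = py @ lev
    sx2 = ((lev[None, :] - mx[:, None]) ** 2 * px).sum(axis=1)
    sy2 = ((lev[None, :] - my[:, None]) ** 2 * py).sum(axis=1)
    sx, sy = np.sqrt(sx2), np.sqrt(sy2)

    def s(weight):
        return (P * weight).sum(axis=(1, 2))

    logP = np.zeros_like(P)
    nz = P > 0
    logP[nz] = np.log(P[nz])
    feats = {}
    feats["energy"] = (P ** 2).sum(axis=(1, 2))
    feats["entropy"] = -(P * logP).sum(axis=(1, 2))
    sij = s(i * j)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (sij - mx * my) / (sx * sy)
    feats["correlation"] = np.where((sx > 0) & (sy > 0), corr, 0.0)
    feats["inverse_difference_moment"] = s(1.0 / (1 + (i - j) ** 2))
    feats["inertia"] = s((i - j) ** 2)
    ipj = (i + j)[None, :, :] - (mx + my)[:, None, None]
    feats["cluster_shade"] = (P * ipj ** 3).sum(axis=(1, 2))
    feats["cluster_prominence"] = (P * ipj ** 4).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        hc = (sij - mx ** 2) / sx2
    feats["haralick_correlation"] = np.where(sx2 > 0, hc, 0.0)

    feats["mean"] = mx
    feats["variance"] = ((i[None] - mx[:, None, None]) ** 2 * P
                         ).sum(axis=(1, 2))
    feats["dissimilarity"] = s(np.abs(i - j))
    # diagonal marginals via one-hot matmuls over the flattened GLCM
    M_sum = np.zeros((G * G, 2 * G - 1))
    M_diff = np.zeros((G * G, G))
    ii, jj = np.divmod(np.arange(G * G), G)
    M_sum[np.arange(G * G), ii + jj] = 1.0
    M_diff[np.arange(G * G), np.abs(ii - jj)] = 1.0
    P2 = P.reshape(n, -1)
    psum = P2 @ M_sum
    pdiff = P2 @ M_diff
    k_sum = np.arange(2 * G - 1, dtype=float)
    k_diff = lev
    sa = psum @ k_sum
    feats["sum_average"] = sa
    feats["sum_variance"] = ((k_sum[None, :] - sa[:, None]) ** 2
                             * psum).sum(axis=1)
    feats["sum_entropy"] = -_xlogx(psum).sum(axis=1)
    mu_d = pdiff @ k_diff
    feats["difference_variance"] = ((k_diff[None, :] - mu_d[:, None]) ** 2
                                    * pdiff).sum(axis=1)
    feats["difference_entropy"] = -_xlogx(pdiff).sum(axis=1)
    hxy = feats["entropy"]
    hx = -_xlogx(px).sum(axis=1)
    hy = -_xlogx(py).sum(axis=1)
    outer = px[:, :, None] * py[:, None, :]
    lout = np.zeros_like(outer)
    nzo = outer > 0
    lout[nzo] = np.log(outer[nzo])
    hxy1 = -(P * lout).sum(axis=(1, 2))
    hxy2 = -_xlogx(outer).sum(axis=(1, 2))
    denom = np.maximum(hx, hy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ic1 = (hxy - hxy1) / denom
    feats["ic1"] = np.where(denom > 0, ic1, 0.0)
    feats["ic2"] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)),
                                   0.0, None))
    return feats


def _runlength_features_batch(qw, G):
    """All 10 run-length features for a batch of windows (45 degrees)."""
    n, win, _ = qw.shape
    npix = win * win
    paths = _window_diagonals(win, win)
    feats = {name: np.zeros(n) for name in RUNLENGTH_NAMES}
    nr = np.zeros(n)
    gl_counts = np.zeros((n, G))
    rl_counts = np.zeros((n, win))
    idx = np.arange(n)
    for path in paths:
        L = len(path)
        vals = np.stack([qw[:, r, c] for (r, c) in path], axis=1)  # (n, L)
        eq = vals[:, 1:] == vals[:, :-1] if L > 1 else \
            np.zeros((n, 0), dtype=bool)
        for k in range(L):
            start = np.ones(n, dtype=bool) if k == 0 else ~eq[:, k - 1]
            # run length from k: 1 + cumulative product of equalities
            runlen = np.ones(n)
            prod = np.ones(n)
            for m in range(k, L - 1):
                prod = prod * eq[:, m]
                runlen = runlen + prod
            g = vals[:, k] + 1.0
            w = start.astype(float)
            feats["short_run_emphasis"] += w / runlen ** 2
            feats["long_run_emphasis"] += w * runlen ** 2
            feats["low_grey_level_run_emphasis"] += w / g ** 2
            feats["high_grey_level_run_emphasis"] += w * g ** 2
            feats["short_run_low_grey_level_emphasis"] += \
                w / (g ** 2 * runlen ** 2)
            feats["short_run_high_grey_level_emphasis"] += \
                w * g ** 2 / runlen ** 2
            feats["long_run_low_grey_level_emphasis"] += \
                w * runlen ** 2 / g ** 2
            nr += w
            np.add.at(gl_counts, (idx[start], vals[start, k]), 1.0)
            np.add.at(rl_counts,
                      (idx[start], runlen[start].astype(int) - 1), 1.0)
    for name in ("short_run_emphasis", "long_run_emphasis",
                 "low_grey_level_run_emphasis",
                 "high_grey_level_run_emphasis",
                 "short_run_low_grey_level_emphasis",
                 "short_run_high_grey_level_emphasis",
                 "long_run_low_grey_level_emphasis"):
        feats[name] /= nr
    feats["grey_level_nonuniformity"] = (gl_counts ** 2).sum(axis=1) / nr
    feats["run_length_nonuniformity"] = (rl_counts ** 2).sum(axis=1) / nr
    feats["run_percentage"] = nr / npix
    return feats


def texture_feature_maps(pc1: PrincipalComponentImage, G: int = 32,
                         window: int = 5, offset=(-1, 1),
                         chunk: int = 4096) -> dict:
    """Sliding-window texture feature maps over the whole PC1 image.

    Returns a dict feature name -> H x W array, NaN where the window is
    not fully inside the image/valid mask. Windows containing any
    masked pixel are skipped (no padding).
    """
    q = quantize(pc1.values, G, mask=pc1.mask)
    H, W = q.shape
    half = window // 2
    maps = {name: np.full((H, W), np.nan) for name in TEXTURE_NAMES}
    if H < window or W < window:
        return maps
    qv = sliding_window_view(q, (window, window))    # (H-w+1, W-w+1, w, w)
    valid = (qv >= 0).all(axis=(2, 3))
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        return maps
    for s in range(0, rows.size, chunk):
        rs, cs = rows[s:s + chunk], cols[s:s + chunk]
        qw = qv[rs, cs]
        P = _glcm_probabilities(qw, G)
        feats = _glcm_features_batch(P)
        feats.update(_runlength_features_batch(qw, G))
        for name in TEXTURE_NAMES:
            maps[name][rs + half, cs + half] = feats[name]
    return maps


def texture_feature_table(pc1: PrincipalComponentImage, layout, stage: str,
                          G: int = 32, window: int = 5,
                          offset=(-1, 1),
                          maps: dict | None = None) -> FeatureTable:
    """Per-plot means of the 28 sliding-window texture features."""
    if maps is None:
        maps = texture_feature_maps(pc1, G=G, window=window, offset=offset)
    H, W = pc1.values.shape
    ps = pc1.pixel_size
    x = (np.arange(W) + 0.5) * ps
    y = (np.arange(H) + 0.5) * ps
    xx, yy = np.meshgrid(x, y)
    computable = np.isfinite(maps[TEXTURE_NAMES[0]])
    rows, index = [], []
    for plot in layout:
        inside = shapely.contains_xy(plot.polygon, xx.ravel(), yy.ravel())
        sel = inside.reshape(H, W) & computable
        if not sel.any():
            raise ValueError(f"plot {plot.plot_id}: no computable windows")
        rows.append([maps[name][sel].mean() for name in TEXTURE_NAMES])
        index.append((plot.plot_id, stage))
    data = pd.DataFrame(rows, columns=list(TEXTURE_NAMES),
                        index=pd.MultiIndex.from_tuples(
                            index, names=["plot_id", "stage"]))
    return FeatureTable(data, {c: "TEX" for c in TEXTURE_NAMES})
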