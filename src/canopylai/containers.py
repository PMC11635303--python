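"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of objects around: hyperspectral
reflectance cubes, per-plot/per-stage feature tables with a
feature-family taxonomy, and small record collections (plot layouts,
ground-truth LAI) that are plain dataclasses defined next to their
generators in :mod:`canopylai.synth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Feature families used throughout: original spectral reflectance,
#: first-order differential spectral reflectance, vegetation indices,
#: Haralick textures.
FAMILIES = ("OSR", "FDSR", "VI", "TEX")


@dataclass
class ReflectanceCube:
    """An H x W x B reflectance image with its wavelength grid.

    Parameters
    ----------
    values : ndarray, shape (H, W, B)
        Per-pixel reflectance, expected in [0, 1.2].
    wavelengths : ndarray, shape (B,)
        Band-center wavelengths in nm; strictly increasing with a
        uniform step.
    mask : ndarray of bool, shape (H, W)
        True where the pixel is valid (canopy or soil); masked-out
        pixels are excluded from every plot statistic.
    pixel_size : float
        Ground sampling distance in metres; pixel (row, col) maps to
        scene coordinates (x, y) = (col * pixel_size, row * pixel_size)
        at the pixel centre offset by half a pixel.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    mask: np.ndarray = None
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be H x W x B")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength grid")
        steps = np.diff(self.wavelengths)
        if self.wavelengths.size > 1:
            if np.any(steps <= 0):
                raise ValueError("wavelengths must be strictly increasing")
            if np.ptp(steps) > 1e-9:
                raise ValueError("wavelength step must be uniform")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match cube H x W")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def delta_lambda(self) -> float:
        """Sampling interval in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def band_index(self, wavelength: float) -> int:
        """Index of the grid channel nearest to ``wavelength``.

        Ties are broken toward the lower wavelength.
        """
        d = np.abs(self.wavelengths - wavelength)
        # argmin returns the first (lower-wavelength) index on exact ties
        return int(np.argmin(d))

    def pixel_centers(self):
        """Scene (x, y) coordinates of every pixel centre."""
        h, w = self.values.shape[:2]
        x = (np.arange(w) + 0.5) * self.pixel_size
        y = (np.arange(h) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass
class FeatureTable:
    """Sample-by-feature matrix with a family tag per column.

    ``data`` is indexed by (plot_id, stage); ``families`` maps each
    column name to one of :data:`FAMILIES`.
    """

    data: pd.DataFrame
    families: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValueError("feature column names must be unique")
        missing = [c for c in self.data.columns if c not in self.families]
        if missing:
            raise ValueError(f"columns without a family tag: {missing[:5]}")
        bad = {f for f in self.families.values()} - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown feature families: {sorted(bad)}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def columns_of(self, family: str) -> list:
        return [c for c in self.data.columns if self.families[c] == family]

    def family_counts(self) -> dict:
        out = {f: 0 for f in FAMILIES}
        for c in self.data.columns:
            out[self.families[c]] += 1
        return {k: v for k, v in out.items() if v}

    def join(self, other: "FeatureTable") -> "FeatureTable":
        """Column-wise concatenation on a shared sample index."""
        if not self.data.index.equals(other.data.index):
            other_data = other.data.reindex(self.data.index)
        else:
            other_data = other.data
        merged = pd.concat([self.data, other_data], axis=1)
        fams = dict(self.families)
        fams.update(other.families)
        return FeatureTable(merged, fams)

    def subset(self, columns) -> "FeatureTable":
        cols = list(columns)
        return FeatureTable(self.data[cols].copy(),
                            {c: self.families[c] for c in cols})

    def to_csv(self, path):
        """Write the table as CSV with a sidecar JSON of column families."""
        path = Path(path)
        self.data.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".families.json")
        sidecar.write_text(json.dumps(self.families, indent=1))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path, index_col=[0, 1])
        sidecar = path.with_suffix(path.suffix + ".families.json")
        families = json.loads(sidecar.read_text())
        return cls(data, families)
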