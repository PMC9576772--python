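"""Shared in-memory containers for the axon-morphometry pipeline.

Physical coordinates are micrometres (μm) throughout.  Raster grids carry
their own spacing so that anisotropic FIB-SEM stacks (fine in-plane pixels,
coarse slice spacing) are handled without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Image2D",
    "BinaryImage",
    "LabelVolume",
    "Centerline",
    "CrossSection",
    "AxonRecord",
    "TractStats",
]


@dataclass
class Image2D:
    """A 2D greyscale raster with a physical pixel size.

    Parameters
    ----------
    pixels
        2D array of intensities.  Stored as float64 in [0, 1] internally by
        the processing pipeline; 8/16-bit integer input is accepted and
        rescaled by the readers.
    pixel_size
        Edge length of one pixel in μm (isotropic in-plane).
    """

    pixels: np.ndarray
    pixel_size: float = 0.020

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image2D requires a non-empty 2D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """A 2D boolean raster, same footprint as its source image."""

    pixels: np.ndarray
    pixel_size: float = 0.020

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BinaryImage requires a non-empty 2D raster")


@dataclass
class LabelVolume:
    """A 3D integer-labelled voxel grid with anisotropic spacing.

    ``labels`` is indexed ``[z, y, x]``; 0 is background (extra-cellular
    matrix), ``k > 0`` marks the voxels of axon ``k``.  ``voxel_size`` is
    ``(dx, dy, dz)`` in μm; dz is typically much coarser than dx = dy
    (150 nm slices vs 20 nm pixels).  Voxel centers sit at
    ``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.020, 0.020, 0.150)
    periodic_xy: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def box_volume(self) -> float:
        """Physical volume of the scanned box in μm³."""
        return self.labels.size * self.voxel_volume

    def axon_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class Centerline:
    """An ordered 3D polyline (μm) through the middle of one axon."""

    points: np.ndarray  # (n, 3) array, columns x, y, z in μm

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("Centerline requires at least two 3D points")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class CrossSection:
    """Measurements taken on one centerline-perpendicular plane."""

    station_arclength: float  # μm along the centerline
    area: float  # μm²
    best_fit_diameter: float  # μm, equivalent-area circle
    semi_axis_major: float  # μm
    semi_axis_minor: float  # μm
    ellipticity: float  # a/b - 1, dimensionless
    flagged: bool = False  # True when the station had multiple contours

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("cross-section area must be positive")
        if not self.semi_axis_major >= self.semi_axis_minor > 0:
            raise ValueError("require semi_axis_major >= semi_axis_minor > 0")


@dataclass
class AxonRecord:
    """One axon's centerline plus its per-station measurement database."""

    axon_id: int
    centerline: Centerline
    sections: list[CrossSection]
    tortuosity: float
    mean_area: float
    mean_diameter: float
    mean_ellipticity: float
    volume: float  # μm³, sum of station area × station spacing


@dataclass
class TractStats:
    """Tract-level summary used both as a measurement output and as the
    input parameter set for in-silico RVE generation.

    ``area_mu``/``area_sigma`` (and the diameter pair) are the log-scale
    lognormal parameters: mode = exp(μ − σ²), median = exp(μ).
    ``axonal_density`` is axons/mm³; ``volume_fraction`` is the summed axon
    volume over the box volume.  The interlayer fields describe
    slice-to-slice variability of a single axon: the coefficient of
    variation of its per-station area and the largest admissible
    station-to-station change of a semi-axis (μm).
    """

    tract: str
    area_mu: float
    area_sigma: float
    diameter_mu: float
    diameter_sigma: float
    ellipticity_min: float
    ellipticity_max: float
    tortuosity_mean: float
    tortuosity_sd: float
    axonal_density: float
    volume_fraction: float
    volume_fraction_sd: float
    interlayer_area_cv: float = 0.10
    interlayer_semiaxis_delta: float = 0.05
    axonal_density_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.volume_fraction < 1:
            raise ValueError("volume_fraction must lie in (0, 1)")
        if self.axonal_density <= 0:
            raise ValueError("axonal_density must be positive")
        if self.area_sigma <= 0 or self.diameter_sigma <= 0:
            raise ValueError("lognormal sigmas must be positive")
        if not 0 <= self.ellipticity_min <= self.ellipticity_max:
            raise ValueError("require 0 <= ellipticity_min <= ellipticity_max")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "TractStats":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)
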