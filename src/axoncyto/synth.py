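"""Synthetic FIB-SEM phantoms with known ground truth.

Two generators stand in for real acquisitions so that every downstream
stage is testable without data downloads:

* :func:`generate_phantom_image` — a 16-bit greyscale 2D image emulating an
  osmium-stained white-matter face: bright annular myelin rings, dimmer
  glial blobs, a smooth uneven illumination field and impulse
  ("salt and pepper") noise, together with the exact clean myelin mask.
* :func:`generate_phantom_volume` — a 3D labelled voxel volume of tubular
  axons (anisotropic voxels: fine in-plane, coarse slices) built from the
  same geometric kernel as the RVE generator, with the full per-axon
  ground truth returned alongside.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import Image2D, LabelVolume, TractStats
from . import rve as _rve

__all__ = [
    "Phantom2DConfig",
    "Phantom2DTruth",
    "Phantom3DConfig",
    "generate_phantom_image",
    "generate_phantom_volume",
    "voxelize_tubes",
]

# intensity conventions, as fractions of the 16-bit dynamic range
BACKGROUND_LEVEL = 0.30
MYELIN_LEVEL = 0.75
GLIA_LEVEL = 0.45
TEXTURE_SD = 0.015  # mild Gaussian grain so median filtering has work to do


@dataclass(frozen=True)
class Phantom2DConfig:
    width: int = 764
    height: int = 1024
    pixel_size: float = 0.020
    myelin_fraction: float = 0.40
    ring_count: int = 1200  # upper bound on placed rings
    ring_outer_diameter_range: tuple[float, float] = (0.6, 1.6)  # μm
    ring_thickness_range: tuple[float, float] = (0.12, 0.35)  # μm
    glia_blob_count: int = 8
    impulse_noise_fraction: float = 0.0
    illumination_gradient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.myelin_fraction <= 1):
            raise ValueError("myelin_fraction must lie in [0, 1]")
        if not (0 <= self.impulse_noise_fraction <= 1):
            raise ValueError("impulse_noise_fraction must lie in [0, 1]")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")


@dataclass(frozen=True)
class Phantom2DTruth:
    myelin_mask: np.ndarray
    true_white_fraction: float


def _raster_annulus(shape, cy, cx, r_out, r_in, pad=0.0):
    """Boolean raster of an annulus (pixel units), within its bounding box.

    Returns (mask, (y0, y1, x0, x1)); ``pad`` widens the annulus for
    separation tests.
    """
    h, w = shape
    r = r_out + pad
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2
    mask = (d2 <= (r_out + pad) ** 2) & (d2 > max(r_in - pad, 0.0) ** 2)
    return mask, (y0, y1, x0, x1)


def generate_phantom_image(config: Phantom2DConfig) -> tuple[Image2D, Phantom2DTruth]:
    """Generate one 2D phantom and its clean ground-truth myelin mask.

    Rings are placed by rejection sampling, largest first, with pixelwise
    disjointness (annuli never overlap each other; they may overlap glial
    blobs).  Placement stops when the mask fraction reaches the configured
    myelin fraction; if the geometry bounds make the target unreachable the
    failure names the achieved fraction.  The truth mask and fraction are
    captured BEFORE the illumination field and impulse noise are applied.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    px = config.pixel_size
    mask = np.zeros((h, w), dtype=bool)
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)

    # glial blobs first; rings may overwrite them
    for _ in range(config.glia_blob_count):
        r_um = rng.uniform(0.25, 0.6)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        blob, (y0, y1, x0, x1) = _raster_annulus(
            (h, w), cy, cx, r_um / px, 0.0
        )
        img[y0:y1, x0:x1][blob] = GLIA_LEVEL

    target = config.myelin_fraction
    if target > 0:
        d_lo, d_hi = config.ring_outer_diameter_range
        t_lo, t_hi = config.ring_thickness_range
        mean_r = (d_lo + d_hi) / 4
        mean_t = min((t_lo + t_hi) / 2, 0.9 * mean_r)
        mean_area_px = math.pi * (mean_r**2 - (mean_r - mean_t) ** 2) / px**2
        est = int(math.ceil(target * h * w / mean_area_px))
        n_rings = min(config.ring_count, 3 * est + 8)
        radii = rng.uniform(d_lo / 2, d_hi / 2, size=n_rings)
        thick = np.minimum(rng.uniform(t_lo, t_hi, size=n_rings), 0.9 * radii)
        # descending sizes pack best; late refill batches use the small end
        # of the range to fill residual gaps
        queue = list(np.argsort(radii)[::-1])
        for _ in range(3):
            if len(radii) >= config.ring_count:
                break
            extra = min(config.ring_count - len(radii), est)
            r_new = rng.uniform(d_lo / 2, (d_lo + (d_hi - d_lo) / 4) / 2, size=extra)
            t_new = np.minimum(rng.uniform(t_lo, t_hi, size=extra), 0.9 * r_new)
            queue.extend(range(len(radii), len(radii) + extra))
            radii = np.concatenate([radii, r_new])
            thick = np.concatenate([thick, t_new])
        total = h * w
        placed = 0
        white = 0
        for i in queue:
            if white / total >= target - 0.005:
                break
            r_out = radii[i] / px
            r_in = (radii[i] - thick[i]) / px
            # skip rings that would overshoot the target band
            ring_px = math.pi * (r_out**2 - r_in**2)
            if (white + ring_px) / total > target + 0.015:
                continue
            # ring centers snap to pixel centers so the raster template is
            # built once per ring, not once per attempt
            half = int(math.ceil(r_out + 1.0)) + 1
            n = 2 * half + 1
            yy, xx = np.mgrid[0:n, 0:n]
            d2 = (yy - half) ** 2 + (xx - half) ** 2
            ring_tpl = (d2 <= r_out**2) & (d2 > r_in**2)
            pad_tpl = (d2 <= (r_out + 1.0) ** 2) & (d2 > max(r_in - 1.0, 0.0) ** 2)
            for _ in range(1000):
                iy, ix = int(rng.integers(0, h)), int(rng.integers(0, w))
                y0, y1 = max(0, iy - half), min(h, iy + half + 1)
                x0, x1 = max(0, ix - half), min(w, ix + half + 1)
                ty0, tx0 = y0 - (iy - half), x0 - (ix - half)
                twin = pad_tpl[ty0 : ty0 + (y1 - y0), tx0 : tx0 + (x1 - x0)]
                if not (mask[y0:y1, x0:x1] & twin).any():
                    rwin = ring_tpl[ty0 : ty0 + (y1 - y0), tx0 : tx0 + (x1 - x0)]
                    sub = mask[y0:y1, x0:x1]
                    white += int(rwin.sum()) - int((sub & rwin).sum())
                    sub |= rwin
                    img[y0:y1, x0:x1][rwin] = MYELIN_LEVEL
                    placed += 1
                    break
            # an unplaceable ring is simply skipped: the remaining (smaller)
            # rings may still fit into the gaps
        achieved = mask.sum() / total
        if abs(achieved - target) > 0.02:
            raise ValueError(
                f"myelin_fraction {target} unreachable with the configured ring "
                f"geometry: achieved {achieved:.3f} after {placed} rings "
                f"(achievable range ≈ [0, {achieved:.3f}])"
            )

    truth = Phantom2DTruth(
        myelin_mask=mask, true_white_fraction=float(mask.sum()) / (h * w)
    )

    # corruption applied AFTER truth capture
    img = img + rng.normal(0.0, TEXTURE_SD, size=img.shape)
    if config.illumination_gradient_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        xn, yn = xx / (w - 1 if w > 1 else 1), yy / (h - 1 if h > 1 else 1)
        coef = rng.uniform(-1.0, 1.0, size=5)
        pfield = (
            coef[0] * xn + coef[1] * yn + coef[2] * xn**2
            + coef[3] * xn * yn + coef[4] * yn**2
        )
        span = pfield.max() - pfield.min()
        if span > 0:
            pfield = (pfield - pfield.min()) / span - 0.5
            img = img + config.illumination_gradient_amplitude * pfield
    if config.impulse_noise_fraction > 0:
        n_noise = int(round(config.impulse_noise_fraction * h * w))
        idx = rng.choice(h * w, size=n_noise, replace=False)
        vals = rng.integers(0, 2, size=n_noise).astype(float)  # 0 = pepper, 1 = salt
        img.ravel()[idx] = vals

    img16 = (np.clip(img, 0.0, 1.0) * np.iinfo(np.uint16).max).round().astype(np.uint16)
    return Image2D(img16, px), truth


@dataclass(frozen=True)
class Phantom3DConfig:
    tract_params: TractStats
    box_size: tuple[float, float, float] = (15.0, 15.0, 15.0)
    voxel_size: tuple[float, float, float] = (0.020, 0.020, 0.150)
    station_spacing: float = 0.150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.station_spacing <= 0:
            raise ValueError("station_spacing must be positive")


def generate_phantom_volume(
    config: Phantom3DConfig,
) -> tuple[LabelVolume, list[_rve.AxonTube]]:
    """Labelled tubular-axon volume with exact per-axon ground truth.

    Delegates tube generation to the RVE kernel (so the phantom and the in
    silico RVEs share one geometric model) and voxelises with the
    center-inside rule.  The returned tubes carry the true centerlines and
    per-station semi-axes/areas for oracle comparisons.
    """
    cfg = _rve.RVEConfig(
        tract_params=config.tract_params,
        box=config.box_size,
        station_spacing=config.station_spacing,
        seed=config.seed,
    )
    r = _rve.generate_rve(cfg)
    vol = voxelize_tubes(r.tubes, config.box_size, config.voxel_size, periodic_xy=True)
    return vol, r.tubes


def voxelize_tubes(
    tubes,
    box: tuple[float, float, float],
    voxel_size: tuple[float, float, float] = (0.020, 0.020, 0.150),
    periodic_xy: bool = True,
) -> LabelVolume:
    """Rasterise elliptical tubes into a labelled voxel grid.

    A voxel belongs to an axon iff its center lies inside (or exactly on)
    the tube surface at the voxel's z; station geometry is interpolated
    linearly in z.  With ``periodic_xy`` the in-plane indices wrap.  Earlier
    labels win on (rare) conflicts.
    """
    bx, by, bz = box
    dx, dy, dz = voxel_size
    nx, ny, nz = round(bx / dx), round(by / dy), round(bz / dz)
    labels = np.zeros((nz, ny, nx), dtype=np.int16 if len(tubes) < 3e4 else np.int32)
    for k in range(nz):
        zc = (k + 0.5) * dz
        for tube in tubes:
            cx, cy, a, b, th = _interp_station(tube, zc)
            if a <= 0:
                continue
            rad = a
            i_lo = int(math.floor((cx - rad) / dx - 0.5))
            i_hi = int(math.ceil((cx + rad) / dx + 0.5))
            j_lo = int(math.floor((cy - rad) / dy - 0.5))
            j_hi = int(math.ceil((cy + rad) / dy + 0.5))
            if not periodic_xy:
                i_lo, i_hi = max(i_lo, 0), min(i_hi, nx - 1)
                j_lo, j_hi = max(j_lo, 0), min(j_hi, ny - 1)
                if i_lo > i_hi or j_lo > j_hi:
                    continue
            ii = np.arange(i_lo, i_hi + 1)
            jj = np.arange(j_lo, j_hi + 1)
            xw = (ii + 0.5) * dx - cx
            yw = (jj + 0.5) * dy - cy
            xg, yg = np.meshgrid(xw, yw, indexing="xy")
            ct, st = math.cos(th), math.sin(th)
            u = xg * ct + yg * st
            v = -xg * st + yg * ct
            # <= with a float-rounding allowance: exactly-on-surface → inside
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-9
            if not inside.any():
                continue
            jj_idx, ii_idx = np.nonzero(inside)
            gi, gj = ii[ii_idx], jj[jj_idx]
            if periodic_xy:
                gi, gj = gi % nx, gj % ny
            sl = labels[k]
            free = sl[gj, gi] == 0
            sl[gj[free], gi[free]] = tube.axon_id
    return LabelVolume(labels, voxel_size, periodic_xy=periodic_xy)


def _interp_station(tube, zc: float):
    """Linear interpolation of tube center, semi-axes and orientation at zc."""
    z = tube.z
    if zc <= z[0]:
        k0, k1, t = 0, 0, 0.0
    elif zc >= z[-1]:
        k0, k1, t = len(z) - 1, len(z) - 1, 0.0
    else:
        k1 = int(np.searchsorted(z, zc))
        k0 = k1 - 1
        t = (zc - z[k0]) / (z[k1] - z[k0])
    cx = (1 - t) * tube.centers[k0, 0] + t * tube.centers[k1, 0]
    cy = (1 - t) * tube.centers[k0, 1] + t * tube.centers[k1, 1]
    a = (1 - t) * tube.a[k0] + t * tube.a[k1]
    b = (1 - t) * tube.b[k0] + t * tube.b[k1]
    thetas = np.atleast_1d(np.asarray(tube.theta, dtype=float))
    if thetas.size == 1:
        th = float(thetas[0])
    else:
        th = (1 - t) * thetas[k0] + t * thetas[k1]
    return cx, cy, a, b, th
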