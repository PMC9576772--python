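"""In silico periodic Representative Volume Elements of white-matter tracts.

Given a tract parameter set (lognormal cross-sectional-area distribution,
ellipticity range, axonal density, volume fraction, tortuosity and the
interlayer variability terms), the generator builds a box of non-overlapping
elliptical tubular "axons" spanning the z extent, periodic in x-y, whose
realised statistics match the inputs:

1. per-axon mean (perpendicular-plane) area drawn from the truncated
   lognormal, ellipticity uniform on the tract range, random in-plane
   orientation;
2. lateral sway drawn as a bundle-coherent path shared by all axons (real
   fibre bundles undulate together — inter-axon gaps are tens of
   nanometres while tortuosity implies sub-micrometre lateral structure)
   plus a smaller per-axon component, slope-capped, with the amplitude
   calibrated by bisection so the realised mean tortuosity — measured
   exactly as the morphometry stage measures it — hits the target;
3. axon count chosen jointly from the density ± SD and volume-fraction
   ± SD bands (the published values are not exactly mutually consistent
   with the area distribution);
4. seed cross-sections placed by random sequential addition (largest
   first) with periodic wrap and an inter-surface clearance reserving
   room for downstream per-station variability;
5. stations every ``station_spacing`` in z: the z-plane section is the
   drawn perpendicular ellipse — with multiplicative lognormal area
   jitter (configured CV, station-to-station semi-axis changes capped at
   ``interlayer_semiaxis_delta``, growth above the placed footprint
   capped) — stretched by sec α along the local tilt azimuth so that
   perpendicular cuts recover the drawn area and ellipticity;
6. residual collisions (checked at every station against periodic
   neighbours) resolved by rebuilding offenders on the pure shared sway,
   then by shrinking sections at still-violating stations;
7. an outer loop that rescales all areas and re-places if the achieved
   volume fraction leaves the target ± SD band, failing loudly if the
   configuration is infeasible.

Every stochastic choice derives from the config seed; the same config and
seed reproduce the RVE bit-for-bit.  ``export_stl`` writes watertight
lofted surface meshes (one per axon plus a combined file), clipping tubes
that cross the periodic x-y boundary into in-box shells.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .containers import TractStats
from .morpho3d import smooth_polyline
from .statsfit import mode_median_to_params

__all__ = [
    "AxonTube",
    "RVEConfig",
    "RVE",
    "InfeasibleRVEError",
    "tract_preset",
    "available_presets",
    "generate_rve",
    "validate_rve",
    "export_stl",
]

#: smallest resolvable outer diameter (μm); areas are truncated below this
MIN_DIAMETER = 0.2
MIN_AREA = math.pi * (MIN_DIAMETER / 2) ** 2

_AR1_CORR_LEN = 3.0  # stations; correlation length of the area jitter
_SWAY_CORR_LEN = 25.0  # stations; lateral sway correlation (long-wavelength
#   undulation keeps the curvature low so oblique sections stay clean)
_IND_SWAY_FRACTION = 0.10  # per-axon sway amplitude relative to shared sway
_MAX_SLOPE = 0.85  # cap on lateral path slope (≈40° tilt); bounds sec α
_SEC_CAP = math.sqrt(1.0 + _MAX_SLOPE**2)  # matching cap on the section stretch
_GROW_CAP = 0.01  # μm; admissible semi-axis growth above the placed ellipse


class InfeasibleRVEError(RuntimeError):
    """Raised when no RVE can satisfy the parameter set; the message names
    the binding constraint."""


@dataclass
class AxonTube:
    """One tubular axon: per-station center, semi-axes and orientation.

    Stations are equally spaced in z (``z``); ``centers`` are x-y positions
    in μm, unwrapped (they may leave [0, box) laterally — apply the
    periodic wrap when rasterising).  ``theta`` is the per-station in-plane
    orientation of the major axis (it drifts slowly along z because the
    z-plane section is the drawn perpendicular ellipse stretched along the
    local tilt azimuth); the principal direction is +z.
    """

    axon_id: int
    z: np.ndarray
    centers: np.ndarray  # (n, 2)
    a: np.ndarray  # (n,) semi-axis major, μm
    b: np.ndarray  # (n,) semi-axis minor, μm
    theta: np.ndarray  # (n,) orientation of the major axis, rad
    ellipticity: float  # drawn perpendicular-plane ellipticity
    seed_center: np.ndarray | None = None  # x-y of the placed seed axis
    shared_index: int | None = None
    a_perp: np.ndarray | None = None  # (n,) perpendicular-plane semi-axes
    b_perp: np.ndarray | None = None  # (before the z-plane tilt stretch)

    @property
    def centerline_points(self) -> np.ndarray:
        return np.column_stack([self.centers, self.z])

    @property
    def areas(self) -> np.ndarray:
        return math.pi * self.a * self.b

    @property
    def mean_area(self) -> float:
        return float(self.areas.mean())


@dataclass
class RVEConfig:
    tract_params: TractStats
    box: tuple[float, float, float] = (15.0, 15.0, 15.0)
    station_spacing: float = 0.150
    seed: int = 0
    max_outer_iterations: int = 5
    min_gap: float = 0.02
    placement_attempts: int = 20000
    calibrate_tortuosity: bool = True

    def __post_init__(self) -> None:
        if min(self.box) <= 0:
            raise ValueError("box dimensions must be positive")
        if self.min_gap < 0:
            raise ValueError("min_gap must be non-negative")
        if self.station_spacing <= 0:
            raise ValueError("station_spacing must be positive")


@dataclass
class RVE:
    tubes: list[AxonTube]
    box: tuple[float, float, float]
    achieved_stats: TractStats
    periodic_xy: bool = True
    config: RVEConfig | None = None


# ---------------------------------------------------------------------------
# tract presets (built from published tract-level summary values)


def available_presets() -> list[str]:
    return ["cc", "cr", "fo"]


def tract_preset(name: str) -> TractStats:
    """Load a bundled tract parameter set (cc, cr or fo).

    The JSON files store the published summary primitives (lognormal mode
    and median of area and diameter, ellipticity range, tortuosity,
    density, volume fraction); the log-scale (μ, σ) are derived here via
    ``mode_median_to_params``.
    """
    name = name.lower()
    if name not in available_presets():
        raise ValueError(f"unknown tract preset {name!r}; choose from {available_presets()}")
    ref = importlib.resources.files("axoncyto") / "presets" / f"{name}.json"
    raw = json.loads(ref.read_text())
    area_mu, area_sigma = mode_median_to_params(raw["area_mode"], raw["area_median"])
    diam_mu, diam_sigma = mode_median_to_params(raw["diameter_mode"], raw["diameter_median"])
    return TractStats(
        tract=raw["tract"],
        area_mu=area_mu,
        area_sigma=area_sigma,
        diameter_mu=diam_mu,
        diameter_sigma=diam_sigma,
        ellipticity_min=raw["ellipticity_min"],
        ellipticity_max=raw["ellipticity_max"],
        tortuosity_mean=raw["tortuosity_mean"],
        tortuosity_sd=raw["tortuosity_sd"],
        axonal_density=raw["axonal_density"],
        volume_fraction=raw["volume_fraction"],
        volume_fraction_sd=raw["volume_fraction_sd"],
        interlayer_area_cv=raw.get("interlayer_area_cv", 0.10),
        interlayer_semiaxis_delta=raw.get("interlayer_semiaxis_delta", 0.05),
        axonal_density_sd=raw.get("axonal_density_sd"),
    )


# ---------------------------------------------------------------------------
# internal geometry helpers


def _ellipse_polygon(cx, cy, a, b, theta, n=32) -> Polygon:
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    ct, st = math.cos(theta), math.sin(theta)
    ex, ey = a * np.cos(t), b * np.sin(t)
    return Polygon(np.column_stack([cx + ex * ct - ey * st, cy + ex * st + ey * ct]))


def _nearest_image(delta: np.ndarray, period: np.ndarray) -> np.ndarray:
    """Minimum-image convention for x-y displacement(s)."""
    return delta - period * np.round(delta / period)


def _ar1(rng: np.random.Generator, n: int, corr_len: float = _AR1_CORR_LEN) -> np.ndarray:
    """Stationary unit-variance AR(1) series with correlation length ``corr_len``."""
    rho = math.exp(-1.0 / corr_len)
    innov = math.sqrt(1 - rho * rho)
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]  # start in the stationary distribution
    for k in range(1, n):
        x[k] = rho * x[k - 1] + innov * e[k]
    return x


def _semi_axes(area: float, ellipticity: float) -> tuple[float, float]:
    a = math.sqrt(area * (1 + ellipticity) / math.pi)
    return a, a / (1 + ellipticity)


def _tube_tau(points: np.ndarray) -> float:
    """Tortuosity of a tube centerline as the morphometry stage measures it.

    Slice centroids sample the lateral path at slice midpoints (one linear
    interpolation), and the centroid chain is smoothed with a 5-station
    moving average before τ = 1 − chord/arc is taken; both are reproduced
    here so the generator's calibration target equals the measured value.
    """
    mid = 0.5 * (points[:-1] + points[1:])
    sm = smooth_polyline(mid, 5)
    arc = float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())
    chord = float(np.linalg.norm(sm[-1] - sm[0]))
    return max(0.0, 1.0 - chord / arc) if arc > 0 else 0.0


def _tilt_secant(points: np.ndarray) -> float:
    """Mean sec(α) of the smoothed midpoint-sampled path: the factor by
    which a z-plane section exceeds the perpendicular-plane section."""
    mid = 0.5 * (points[:-1] + points[1:])
    sm = smooth_polyline(mid, 5)
    d = np.diff(sm, axis=0)
    seg = np.linalg.norm(d, axis=1)
    dz = d[:, 2]
    good = dz > 0
    if not good.any():
        return 1.0
    return float(np.mean(seg[good] / dz[good]))


# ---------------------------------------------------------------------------
# generation


def _draw_axon_population(rng, tp: TractStats, box, max_n: int):
    """Draw candidate mean areas (truncated), ellipticities and orientations."""
    cap_area = math.pi * (min(box[0], box[1]) / 4) ** 2
    areas = np.empty(max_n)
    filled = 0
    for _ in range(200):
        need = max_n - filled
        if need == 0:
            break
        draw = rng.lognormal(tp.area_mu, tp.area_sigma, size=2 * need)
        draw = draw[(draw >= MIN_AREA) & (draw <= cap_area)][:need]
        areas[filled : filled + draw.size] = draw
        filled += draw.size
    if filled < max_n:
        raise InfeasibleRVEError("could not draw admissible areas (truncation too tight)")
    ells = rng.uniform(tp.ellipticity_min, tp.ellipticity_max, size=max_n)
    thetas = rng.uniform(0.0, 2 * math.pi, size=max_n)
    return areas, ells, thetas


def _choose_count(areas: np.ndarray, tp: TractStats, box, tilt_factor: float = 1.0) -> int:
    """Pick the axon count N from the joint density/volume-fraction bands.

    The published density and volume-fraction means are not exactly
    mutually consistent with the area distribution (density × mean area ×
    length generally over-predicts the volume fraction), so N is the value
    inside the density ± SD band whose cumulative drawn area (including the
    tilt inflation of z-plane sections) lands closest to the target volume
    fraction.
    """
    bx, by, bz = box
    vol_mm3 = bx * by * bz * 1e-9
    n0 = tp.axonal_density * vol_mm3
    if n0 < 1:
        raise InfeasibleRVEError(
            f"box too small: expected axon count {n0:.2f} < 1 at density "
            f"{tp.axonal_density:.3g}/mm³"
        )
    dens_sd = tp.axonal_density_sd if tp.axonal_density_sd else 0.25 * tp.axonal_density
    lo = max(1, math.ceil((tp.axonal_density - dens_sd) * vol_mm3))
    hi = max(lo, math.floor((tp.axonal_density + dens_sd) * vol_mm3))
    hi = min(hi, areas.size)
    cum = np.cumsum(areas) * tilt_factor
    vf = cum[lo - 1 : hi] / (bx * by)
    best = int(np.argmin(np.abs(vf - tp.volume_fraction)))
    return lo + best


def _place_seeds(
    rng, areas, ells, thetas, box, clearance: float, attempts: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential addition of ellipse seeds, largest first, periodic.

    Returns (centers, placed_index) where placed_index maps back into the
    drawn population; axons that could not be placed are dropped.
    """
    from shapely.affinity import translate

    bx, by = box[0], box[1]
    period = np.array([bx, by])
    order = np.argsort(areas)[::-1]
    centers: list[np.ndarray] = []
    placed: list[int] = []
    polys: list[Polygon] = []
    radii: list[float] = []
    for i in order:
        a, b = _semi_axes(areas[i], ells[i])
        base = _ellipse_polygon(0.0, 0.0, a, b, thetas[i])
        for _ in range(attempts):
            c = rng.uniform([0.0, 0.0], [bx, by])
            ok = True
            for k in range(len(centers)):
                d = _nearest_image(centers[k] - c, period)
                if math.hypot(d[0], d[1]) > a + radii[k] + clearance:
                    continue  # bounding-circle quick reject
                moved = translate(polys[k], xoff=float(d[0]), yoff=float(d[1]))
                if base.distance(moved) < clearance:
                    ok = False
                    break
            if ok:
                centers.append(c)
                placed.append(int(i))
                polys.append(base)
                radii.append(a)
                break
        # unplaceable axon: dropped; caller checks the resulting VF band
    return np.array(centers).reshape(-1, 2), np.array(placed, dtype=int)


def _smooth_sway(rng, n_st: int) -> np.ndarray:
    """One lateral sway path (n_st, 2): low-frequency AR(1) noise smoothed
    once more, so its structure survives the measurement-side smoothing."""
    raw = np.column_stack([
        _ar1(rng, n_st, corr_len=_SWAY_CORR_LEN),
        _ar1(rng, n_st, corr_len=_SWAY_CORR_LEN),
    ])
    return smooth_polyline(raw, 5)


def _limit_slope(path2: np.ndarray, z: np.ndarray, max_slope: float = _MAX_SLOPE) -> np.ndarray:
    """Clip the lateral step norms of a sway path to ``max_slope``·Δz.

    The tortuosity targets can demand steep undulation in short boxes;
    beyond ≈40° tilt the tubular model (and any slice-wise measurement of
    it) stops being meaningful, so the slope is bounded here and the
    amplitude calibration works against the bounded path.
    """
    d = np.diff(path2, axis=0)
    dz = np.diff(z)
    norms = np.linalg.norm(d, axis=1)
    cap = max_slope * dz
    over = norms > cap
    if over.any():
        d[over] *= (cap[over] / norms[over])[:, None]
    out = np.empty_like(path2)
    out[0] = path2[0]
    out[1:] = path2[0] + np.cumsum(d, axis=0)
    return out


def _calibrate_sway(rng, n_ax: int, z, config, tp):
    """Draw the bundle-shared and per-axon sway paths and bisect the sway
    amplitude until the realised mean tortuosity — measured exactly as the
    morphometry stage measures it — matches the target."""
    n_st = z.size
    shared = _smooth_sway(rng, n_st)
    ind = np.stack([_smooth_sway(rng, n_st) for _ in range(n_ax)])

    def tau_mean(sigma: float) -> float:
        taus = [
            _tube_tau(np.column_stack([
                _limit_slope(sigma * (shared + _IND_SWAY_FRACTION * ind[i]), z), z
            ]))
            for i in range(n_ax)
        ]
        return float(np.mean(taus))

    sigma = 0.0
    if config.calibrate_tortuosity and tp.tortuosity_mean > 0:
        lo, hi = 0.0, 0.5
        while tau_mean(hi) < tp.tortuosity_mean and hi < 16.0:
            hi *= 2
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if tau_mean(mid) < tp.tortuosity_mean:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-4:
                break
        sigma = 0.5 * (lo + hi)
    return sigma, shared, ind


def _ellipse_cov(a: float, b: float, theta: float) -> np.ndarray:
    """Symmetric matrix M with ellipse {x : xᵀ M⁻¹ x ≤ 1}."""
    c, s = math.cos(theta), math.sin(theta)
    r = np.array([[c, -s], [s, c]])
    return r @ np.diag([a * a, b * b]) @ r.T


def _cov_ellipse(m: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`_ellipse_cov`: (a, b, theta) with a ≥ b."""
    w, v = np.linalg.eigh(m)
    a, b = math.sqrt(w[1]), math.sqrt(w[0])
    theta = math.atan2(v[1, 1], v[0, 1])
    return a, b, theta


def _path_tilt(path3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-station tilt secant and lateral azimuth unit vector of a path."""
    n = path3.shape[0]
    d = np.empty((n, 3))
    d[1:-1] = path3[2:] - path3[:-2]
    d[0] = path3[1] - path3[0]
    d[-1] = path3[-1] - path3[-2]
    dz = d[:, 2]
    lat = np.linalg.norm(d[:, :2], axis=1)
    sec = np.sqrt(lat**2 + dz**2) / np.where(dz > 0, dz, 1.0)
    sec = np.clip(sec, 1.0, _SEC_CAP)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(lat[:, None] > 1e-12, d[:, :2] / np.maximum(lat, 1e-12)[:, None],
                     np.array([1.0, 0.0]))
    return sec, u


class _TubeFactory:
    """Builds AxonTube station geometry for a given lateral path.

    The drawn (perpendicular-plane) ellipse, with its per-station area
    jitter, is stretched by sec α along the local tilt azimuth to give the
    z-plane section, so that cutting the lofted tube perpendicular to its
    (smoothed) centerline recovers the drawn area and ellipticity.  Kept as
    a factory so overlap resolution can rebuild a tube on a new path.
    """

    def __init__(self, rng, areas, ells, thetas, z, tp: TractStats):
        self.z = z
        self.ells = ells
        self.thetas = thetas
        n_st = z.size
        self.perp_axes = []
        for i in range(areas.size):
            a0, _ = _semi_axes(areas[i], ells[i])
            a, b = _station_semi_axes(rng, a0, ells[i], n_st, tp)
            self.perp_axes.append((a, b))

    def build(self, i: int, axon_id: int, path2: np.ndarray) -> AxonTube:
        z = self.z
        n_st = z.size
        # tilt taken from the measurement-convention path (midpoint-sampled,
        # 5-station smoothed): perpendicular cuts are made along THAT
        # tangent, so the stretch must compensate exactly that tilt
        p3 = np.column_stack([path2, z])
        mid = smooth_polyline(0.5 * (p3[:-1] + p3[1:]), 5)
        sec_m, u_m = _path_tilt(mid)
        sec = np.interp(z, mid[:, 2], sec_m)
        u = np.column_stack([
            np.interp(z, mid[:, 2], u_m[:, 0]), np.interp(z, mid[:, 2], u_m[:, 1])
        ])
        norm = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
        u = u / norm[:, None]
        ap, bp = self.perp_axes[i]
        a_out = np.empty(n_st)
        b_out = np.empty(n_st)
        th_out = np.empty(n_st)
        prev_th = None
        for k in range(n_st):
            m = _ellipse_cov(ap[k], bp[k], self.thetas[i])
            stretch = np.eye(2) + (sec[k] - 1.0) * np.outer(u[k], u[k])
            a, b, th = _cov_ellipse(stretch @ m @ stretch.T)
            if prev_th is not None:  # orientation is mod π; keep it continuous
                while th - prev_th > math.pi / 2:
                    th -= math.pi
                while th - prev_th < -math.pi / 2:
                    th += math.pi
            a_out[k], b_out[k], th_out[k] = a, b, th
            prev_th = th
        return AxonTube(
            axon_id=axon_id,
            z=z.copy(),
            centers=path2.copy(),
            a=a_out,
            b=b_out,
            theta=th_out,
            ellipticity=float(self.ells[i]),
            seed_center=None,
            a_perp=ap.copy(),
            b_perp=bp.copy(),
        )


def _station_semi_axes(rng, a0: float, ellip: float, n_st: int, tp: TractStats):
    """Per-station perpendicular-plane major semi-axis with lognormal area
    jitter, capped station-to-station changes, and capped growth above the
    placed size (so the placement clearance is never consumed)."""
    cv = tp.interlayer_area_cv
    if cv <= 0:
        a = np.full(n_st, a0)
        return a, a / (1 + ellip)
    s = math.sqrt(math.log(1 + cv**2))
    g = _ar1(rng, n_st)
    factor = np.exp(s * g - s**2 / 2)
    a_raw = a0 * np.sqrt(factor)
    delta = tp.interlayer_semiaxis_delta
    a = np.empty(n_st)
    a[0] = min(a_raw[0], a0 + _GROW_CAP)
    for j in range(1, n_st):
        a[j] = np.clip(a_raw[j], a[j - 1] - delta, a[j - 1] + delta)
        a[j] = min(a[j], a0 + _GROW_CAP)
        a[j] = max(a[j], 0.5 * a0, MIN_DIAMETER / 2)
    return a, a / (1 + ellip)


def generate_rve(config: RVEConfig) -> RVE:
    """Generate a periodic RVE matching a tract parameter set.

    See the module docstring for the algorithm.  Deterministic given the
    config seed; raises :class:`InfeasibleRVEError` when the density /
    volume-fraction / clearance constraints cannot be met jointly.
    """
    tp = config.tract_params
    rng = np.random.default_rng(config.seed)
    bx, by, bz = config.box
    n_st = int(round(bz / config.station_spacing)) + 1
    z = np.arange(n_st) * config.station_spacing
    clearance = config.min_gap + 2 * _GROW_CAP
    vf_lo = tp.volume_fraction - tp.volume_fraction_sd
    vf_hi = tp.volume_fraction + tp.volume_fraction_sd

    vol_mm3 = bx * by * bz * 1e-9
    max_n = int(math.ceil((tp.axonal_density * 1.6) * vol_mm3)) + 8
    areas, ells, thetas = _draw_axon_population(rng, tp, config.box, max_n)

    # lateral sway is independent of seed placement: calibrate once
    sigma, shared, ind = _calibrate_sway(rng, max_n, z, config, tp)
    sways = np.stack([
        _limit_slope(sigma * (shared + _IND_SWAY_FRACTION * ind[i]), z)
        for i in range(max_n)
    ])
    tilt = np.array([
        _tilt_secant(np.column_stack([sways[i], z])) for i in range(max_n)
    ])
    mean_tilt = float(tilt.mean())

    n = _choose_count(areas, tp, config.box, tilt_factor=mean_tilt)
    # pull the cumulative drawn area toward the target VF if it left the
    # band — only as far as the nearest band edge, to distort the drawn
    # area distribution as little as possible
    vf0 = areas[:n].sum() * mean_tilt / (bx * by)
    vf_pull = min(max(vf0, vf_lo + 0.1 * tp.volume_fraction_sd),
                  vf_hi - 0.1 * tp.volume_fraction_sd)
    if vf_pull != vf0:
        areas = areas * (vf_pull / vf0)

    scale = 1.0
    best_tubes = None
    best_err = math.inf
    for outer in range(config.max_outer_iterations):
        sub = np.random.default_rng([config.seed % (2**31), outer])
        eff_areas = areas[:n] * scale**2
        centers, placed = _place_seeds(
            sub, eff_areas, ells[:n], thetas[:n], config.box, clearance,
            config.placement_attempts,
        )
        if placed.size == 0:
            raise InfeasibleRVEError("no axon could be placed (clearance too large?)")
        factory = _TubeFactory(
            sub, eff_areas[placed], ells[placed], thetas[placed], z, tp
        )
        tubes = []
        for rank, i in enumerate(placed):
            t = factory.build(rank, rank + 1, centers[rank] + sways[i])
            t.seed_center = centers[rank].copy()
            t.shared_index = int(i)
            tubes.append(t)
        # resolve collisions BEFORE the volume-fraction check: the shrink
        # phase removes material, and the rescale must see the final state
        _enforce_no_overlap(tubes, config, _limit_slope(sigma * shared, z), factory)
        vf = sum(np.trapezoid(t.areas, t.z) for t in tubes) / (bx * by * bz)
        if abs(vf - tp.volume_fraction) < best_err:
            best_tubes, best_err = tubes, abs(vf - tp.volume_fraction)
        # iterate toward the target while iterations remain (collision
        # shrinkage systematically pulls below it); the best realisation
        # seen is kept, so a failed pull never makes the result worse
        if best_err <= 0.5 * tp.volume_fraction_sd:
            break
        scale *= math.sqrt(tp.volume_fraction / vf)
    if best_err > tp.volume_fraction_sd:
        raise InfeasibleRVEError(
            f"volume fraction off target by {best_err:.3f} > sd "
            f"{tp.volume_fraction_sd:.3f} after "
            f"{config.max_outer_iterations} iterations (packing-bound)"
        )

    achieved = _achieved_stats(best_tubes, config)
    return RVE(tubes=best_tubes, box=config.box, achieved_stats=achieved, config=config)


def _pair_violates(ti: AxonTube, tj: AxonTube, period, gap: float) -> bool:
    """Sampled distance check at every station, periodic nearest image."""
    d = _nearest_image(tj.centers - ti.centers, period)
    dist = np.hypot(d[:, 0], d[:, 1])
    close = np.nonzero(dist < ti.a + tj.a + gap)[0]
    for k in close:
        pi = _ellipse_polygon(0, 0, ti.a[k], ti.b[k], ti.theta[k])
        pj = _ellipse_polygon(d[k, 0], d[k, 1], tj.a[k], tj.b[k], tj.theta[k])
        if pi.distance(pj) < gap * 0.999:
            return True
    return False


def _shrink_pair_at_station(ti: AxonTube, tj: AxonTube, k: int, d, gap: float) -> None:
    """Scale both tubes' section semi-axes at station ``k`` (about their own
    centers) until the inter-surface distance reaches ``gap``."""
    lo, hi = 0.3, 1.0
    for _ in range(12):
        f = 0.5 * (lo + hi)
        pi = _ellipse_polygon(0, 0, f * ti.a[k], f * ti.b[k], ti.theta[k])
        pj = _ellipse_polygon(d[0], d[1], f * tj.a[k], f * tj.b[k], tj.theta[k])
        if pi.distance(pj) < gap:
            hi = f
        else:
            lo = f
    for tube in (ti, tj):
        for arr in (tube.a, tube.b, tube.a_perp, tube.b_perp):
            if arr is not None:
                arr[k] *= lo


def _enforce_no_overlap(tubes, config: RVEConfig, shared_path, factory) -> None:
    """Resolve residual collisions (sampled distance checks at every
    station against periodic neighbours), in two phases.

    Phase 1: any tube involved in a violation is rebuilt on the
    bundle-coherent sway (seed axis + shared path), removing the per-axon
    sway that broke the placement clearance.  Phase 2: the shared tilt
    stretches sections toward each other faster than their separations
    grow, so residual contacts at high-tilt stations are resolved by
    shrinking both sections at the offending station until the minimum gap
    holds — shrinking never creates new contacts, so this terminates with
    the non-overlap invariant satisfied.
    """
    period = np.array(config.box[:2])
    gap = config.min_gap
    n = len(tubes)
    for _ in range(3):  # phase 1
        bad_ids: set[int] = set()
        for i in range(n):
            for j in range(i + 1, n):
                if _pair_violates(tubes[i], tubes[j], period, gap):
                    bad_ids.update((i, j))
        if not bad_ids:
            return
        for i in bad_ids:
            old = tubes[i]
            rebuilt = factory.build(i, old.axon_id, old.seed_center + shared_path)
            rebuilt.seed_center = old.seed_center
            tubes[i] = rebuilt
    shrunk: set[int] = set()
    for i in range(n):  # phase 2
        for j in range(i + 1, n):
            ti, tj = tubes[i], tubes[j]
            d = _nearest_image(tj.centers - ti.centers, period)
            dist = np.hypot(d[:, 0], d[:, 1])
            close = np.nonzero(dist < ti.a + tj.a + gap)[0]
            for k in close:
                pi = _ellipse_polygon(0, 0, ti.a[k], ti.b[k], ti.theta[k])
                pj = _ellipse_polygon(d[k, 0], d[k, 1], tj.a[k], tj.b[k], tj.theta[k])
                if pi.distance(pj) < gap * 0.999:
                    _shrink_pair_at_station(ti, tj, k, d[k], gap * 1.001)
                    shrunk.update((i, j))
    for i in shrunk:
        _relimit_steps(tubes[i], config.tract_params.interlayer_semiaxis_delta)


def _relimit_steps(tube: AxonTube, delta: float) -> None:
    """Re-impose the station-to-station semi-axis cap after local shrinks by
    lowering neighbours (lowering a section can never create an overlap)."""
    for arr in (tube.a, tube.b, tube.a_perp, tube.b_perp):
        if arr is None:
            continue
        for k in range(1, arr.size):  # forward pass
            arr[k] = min(arr[k], arr[k - 1] + delta)
        for k in range(arr.size - 2, -1, -1):  # backward pass
            arr[k] = min(arr[k], arr[k + 1] + delta)


def _achieved_stats(tubes: list[AxonTube], config: RVEConfig) -> TractStats:
    tp = config.tract_params
    bx, by, bz = config.box
    mean_areas = np.array([t.mean_area for t in tubes])
    mean_diams = 2 * np.sqrt(mean_areas / math.pi)
    taus = np.array([_tube_tau(t.centerline_points) for t in tubes])
    ells = np.array([t.ellipticity for t in tubes])
    vf = float(sum(np.trapezoid(t.areas, t.z) for t in tubes) / (bx * by * bz))
    la, ld = np.log(mean_areas), np.log(mean_diams)
    cvs = [float(t.areas.std() / t.areas.mean()) for t in tubes]
    max_step = max(float(np.abs(np.diff(t.a)).max()) if t.a.size > 1 else 0.0 for t in tubes)
    return TractStats(
        tract=tp.tract,
        area_mu=float(la.mean()),
        area_sigma=max(float(la.std()), 1e-9),
        diameter_mu=float(ld.mean()),
        diameter_sigma=max(float(ld.std()), 1e-9),
        ellipticity_min=float(ells.min()),
        ellipticity_max=float(ells.max()),
        tortuosity_mean=float(taus.mean()),
        tortuosity_sd=float(taus.std()),
        axonal_density=len(tubes) / (bx * by * bz) * 1e9,
        volume_fraction=vf,
        volume_fraction_sd=tp.volume_fraction_sd,
        interlayer_area_cv=float(np.mean(cvs)),
        interlayer_semiaxis_delta=max_step,
    )
def _achieved_stats(tubes: list[AxonTube], config: RVEConfig) -> TractStats:
    tp = config.tract_params
    bx, by, bz = config.box
    mean_areas = np.array([t.mean_area for t in tubes])
    mean_diams = 2 * np.sqrt(mean_areas / math.pi)
    taus = np.array([_tube_tau(t.centerline_points) for t in tubes])
    ells = np.array([t.ellipticity for t in tubes])
    vf = float(sum(np.trapezoid(t.areas, t.z) for t in tubes) / (bx * by * bz))
    la, ld = np.log(mean_areas), np.log(mean_diams)
    cvs = [float(t.areas.std() / t.areas.mean()) for t in tubes]
    max_step = max(float(np.abs(np.diff(t.a)).max()) if t.a.size > 1 else 0.0 for t in tubes)
    return TractStats(
        tract=tp.tract,
        area_mu=float(la.mean()),
        area_sigma=max(float(la.std()), 1e-9),
        diameter_mu=float(ld.mean()),
        diameter_sigma=max(float(ld.std()), 1e-9),
        ellipticity_min=float(ells.min()),
        ellipticity_max=float(ells.max()),
        tortuosity_mean=float(taus.mean()),
        tortuosity_sd=float(taus.std()),
        axonal_density=len(tubes) / (bx * by * bz) * 1e9,
        volume_fraction=vf,
        volume_fraction_sd=tp.volume_fraction_sd,
        interlayer_area_cv=float(np.mean(cvs)),
        interlayer_semiaxis_delta=max_step,
    )


def validate_rve(
    r: RVE,
    voxel_size: tuple[float, float, float] = (0.020, 0.020, 0.150),
    station_stride: int = 1,
) -> TractStats:
    """Round-trip self-validation: voxelise the RVE and measure it with the
    morphometry stage, returning the measured tract statistics."""
    from . import morpho3d, synth

    vol = synth.voxelize_tubes(r.tubes, r.box, voxel_size, periodic_xy=r.periodic_xy)
    res = morpho3d.measure_volume(
        vol, spacing=r.config.station_spacing if r.config else 0.150,
        station_stride=station_stride,
    )
    mean_areas = np.array([rec.mean_area for rec in res.records])
    mean_diams = np.array([rec.mean_diameter for rec in res.records])
    taus = np.array([rec.tortuosity for rec in res.records])
    ells = np.array([rec.mean_ellipticity for rec in res.records])
    la, ld = np.log(mean_areas), np.log(mean_diams)
    tp = r.achieved_stats
    return TractStats(
        tract=tp.tract,
        area_mu=float(la.mean()),
        area_sigma=max(float(la.std()), 1e-9),
        diameter_mu=float(ld.mean()),
        diameter_sigma=max(float(ld.std()), 1e-9),
        ellipticity_min=float(ells.min()),
        ellipticity_max=float(ells.max()),
        tortuosity_mean=float(taus.mean()),
        tortuosity_sd=float(taus.std()),
        axonal_density=res.density,
        volume_fraction=res.volume_fraction,
        volume_fraction_sd=tp.volume_fraction_sd,
        interlayer_area_cv=tp.interlayer_area_cv,
        interlayer_semiaxis_delta=tp.interlayer_semiaxis_delta,
    )


# ---------------------------------------------------------------------------
# STL export


def _loft_tube(tube: AxonTube, n_ring: int = 32) -> trimesh.Trimesh:
    """Closed, outward-oriented triangulation of one tube: consecutive
    station ellipses (fixed ring of 32 vertices) lofted and end-capped."""
    t = np.linspace(0.0, 2 * math.pi, n_ring, endpoint=False)
    n_st = tube.z.size
    thetas = np.atleast_1d(np.asarray(tube.theta, dtype=float))
    if thetas.size == 1:
        thetas = np.full(n_st, thetas[0])
    rings = np.empty((n_st, n_ring, 3))
    for k in range(n_st):
        ct, st = math.cos(thetas[k]), math.sin(thetas[k])
        ex, ey = tube.a[k] * np.cos(t), tube.b[k] * np.sin(t)
        rings[k, :, 0] = tube.centers[k, 0] + ex * ct - ey * st
        rings[k, :, 1] = tube.centers[k, 1] + ex * st + ey * ct
        rings[k, :, 2] = tube.z[k]
    verts = rings.reshape(-1, 3)
    faces = []
    for k in range(n_st - 1):
        base0, base1 = k * n_ring, (k + 1) * n_ring
        for m in range(n_ring):
            m1 = (m + 1) % n_ring
            faces.append([base0 + m, base0 + m1, base1 + m])
            faces.append([base0 + m1, base1 + m1, base1 + m])
    # end caps as fans around the section centroids
    c0 = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    c1 = c0 + 1
    last = (n_st - 1) * n_ring
    for m in range(n_ring):
        m1 = (m + 1) % n_ring
        faces.append([c0, m1, m])  # bottom cap, normal -z
        faces.append([c1, last + m, last + m1])  # top cap, normal +z
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
    mesh.fix_normals()
    return mesh


def _point_in_tri(p, a, b, c) -> bool:
    d1 = (p[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (p[1] - b[1])
    d2 = (p[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (p[1] - c[1])
    d3 = (p[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[1] - a[1])
    neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (neg and pos)


def _ear_clip(poly: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple 2D polygon by ear clipping (CCW output)."""
    n = poly.shape[0]
    area2 = float(np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                         - np.roll(poly[:, 0], -1) * poly[:, 1]))
    order = list(range(n)) if area2 > 0 else list(range(n - 1, -1, -1))
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(order) > 3 and guard < 10 * n:
        guard += 1
        clipped = False
        for pos in range(len(order)):
            i0 = order[pos - 1]
            i1 = order[pos]
            i2 = order[(pos + 1) % len(order)]
            a, b, c = poly[i0], poly[i1], poly[i2]
            if (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0]) <= 1e-14:
                continue  # reflex or degenerate corner
            if any(
                _point_in_tri(poly[j], a, b, c)
                for j in order
                if j not in (i0, i1, i2)
            ):
                continue
            tris.append((i0, i1, i2))
            order.pop(pos)
            clipped = True
            break
        if not clipped:
            break
    if len(order) >= 3:  # remainder (convex or numerical leftovers): fan
        for k in range(1, len(order) - 1):
            tris.append((order[0], order[k], order[k + 1]))
    return tris


def _clean_loop(pts: np.ndarray) -> np.ndarray | None:
    """Drop exactly duplicated loop vertices; None if degenerate.

    Collinear vertices are kept: the cap triangulation must reference every
    boundary vertex of the open mesh for its edges to pair up.
    """
    keep = np.linalg.norm(pts - np.roll(pts, 1, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    return pts if pts.shape[0] >= 3 else None


def _slice_cap(mesh: trimesh.Trimesh, origin, normal) -> trimesh.Trimesh | None:
    """Slice a watertight mesh with a plane (keeping the normal side) and
    cap the cut with ear-clipped boundary loops."""
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    m = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=origin, cap=False
    )
    if m is None or m.is_empty or len(m.faces) == 0:
        return None
    m.merge_vertices()  # the cut duplicates vertices per face
    if m.is_watertight:  # plane did not actually cut the solid
        return m
    # in-plane orthonormal basis (e1, e2) with e1 × e2 = normal
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, normal)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    cap_meshes = [m]
    for loop in m.outline().discrete:
        pts = np.asarray(loop)
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        pts = _clean_loop(pts)
        if pts is None:
            continue
        uv = np.column_stack([(pts - origin) @ e1, (pts - origin) @ e2])
        tris = _ear_clip(uv)
        # CCW in (e1, e2) faces +normal; the cap must face outward (−normal)
        faces = np.array([(t[0], t[2], t[1]) for t in tris])
        cap_meshes.append(trimesh.Trimesh(vertices=pts, faces=faces, process=False))
    out = trimesh.util.concatenate(cap_meshes)
    out.merge_vertices()
    # no validate pass: it would strip zero-area cap triangles that are
    # topologically required for a closed surface
    out.fix_normals()
    if not out.is_watertight:
        # thin grazing slivers can defeat the ear-clip capping; fill any
        # remaining holes triangle-by-triangle before giving up
        trimesh.repair.fill_holes(out)
        out.fix_normals()
    return out


def _clip_to_box(mesh: trimesh.Trimesh, box) -> trimesh.Trimesh | None:
    """Intersect a watertight mesh with the x-y extent of the box, capping
    the cut faces.  Returns None when nothing remains."""
    bx, by, _ = box
    planes = [
        ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ((bx, 0.0, 0.0), (-1.0, 0.0, 0.0)),
        ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
        ((0.0, by, 0.0), (0.0, -1.0, 0.0)),
    ]
    m = mesh
    for origin, normal in planes:
        if m is None or m.is_empty or len(m.faces) == 0:
            return None
        m = _slice_cap(m, origin, normal)
    if m is None or m.is_empty or len(m.faces) == 0 or m.volume < 1e-9:
        return None
    return m


def tube_meshes(r: RVE, n_ring: int = 32) -> dict[int, list[trimesh.Trimesh]]:
    """Watertight shells per axon, clipped to the box with periodic wrap.

    A tube crossing the x-y boundary yields its in-box part plus the
    wrapped remainder(s) as separate closed shells.
    """
    bx, by, _ = r.box
    out: dict[int, list[trimesh.Trimesh]] = {}
    for tube in r.tubes:
        full = _loft_tube(tube, n_ring)
        xmin, ymin = full.bounds[0][:2]
        xmax, ymax = full.bounds[1][:2]
        crosses = xmin < 0 or ymin < 0 or xmax > bx or ymax > by
        shells: list[trimesh.Trimesh] = []
        if not crosses or not r.periodic_xy:
            shells.append(full)
        else:
            for ox in (0.0, bx, -bx):
                for oy in (0.0, by, -by):
                    moved = full.copy()
                    moved.apply_translation([ox, oy, 0.0])
                    piece = _clip_to_box(moved, r.box)
                    if piece is not None:
                        shells.append(piece)
        for s in shells:
            if not s.is_watertight:
                raise RuntimeError(
                    f"axon {tube.axon_id}: non-watertight shell produced"
                )
        out[tube.axon_id] = shells
    return out


def export_stl(r: RVE, out_dir, n_ring: int = 32) -> list:
    """Write one binary STL per axon plus a combined ``rve.stl``.

    Units are μm.  Every emitted shell is verified watertight before
    writing; a non-watertight shell raises instead of being written.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meshes = tube_meshes(r, n_ring)
    written = []
    combined = []
    for axon_id, shells in meshes.items():
        merged = trimesh.util.concatenate(shells)
        path = out_dir / f"axon_{axon_id:03d}.stl"
        merged.export(path)
        written.append(path)
        combined.append(merged)
    all_path = out_dir / "rve.stl"
    trimesh.util.concatenate(combined).export(all_path)
    written.append(all_path)
    return written
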