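"""RVE generation: presets, packing, calibration, periodicity, STL export."""

import math

import numpy as np
import pytest
import trimesh

from axoncyto import rve, statsfit, synth
from axoncyto.containers import TractStats
from axoncyto.rve import (
    AxonTube,
    InfeasibleRVEError,
    RVE,
    RVEConfig,
    _nearest_image,
    _pair_violates,
    _tube_tau,
)

from conftest import straight_tube


def degenerate_params(**over) -> TractStats:
    """One straight circular axon, no interlayer variability."""
    base = dict(
        tract="TEST", area_mu=math.log(1.0), area_sigma=0.3,
        diameter_mu=0.0, diameter_sigma=0.3,
        ellipticity_min=0.0, ellipticity_max=0.0,
        tortuosity_mean=0.0, tortuosity_sd=0.0,
        axonal_density=1.0 / (5.0**3) * 1e9,  # exactly one axon in a 5 μm box
        volume_fraction=0.04, volume_fraction_sd=0.03,
        interlayer_area_cv=0.0, interlayer_semiaxis_delta=0.05,
    )
    base.update(over)
    return TractStats(**base)


class TestPresets:
    def test_cc_log_params_derive_from_mode_median(self, cc_params):
        mu, sigma = statsfit.mode_median_to_params(0.63, 1.42)
        assert cc_params.area_mu == pytest.approx(mu)
        assert cc_params.area_sigma == pytest.approx(sigma)
        assert cc_params.tract == "CC"

    def test_all_presets_load_and_validate(self):
        for name in rve.available_presets():
            tp = rve.tract_preset(name)
            assert 0 < tp.volume_fraction < 1
            assert tp.ellipticity_min < tp.ellipticity_max

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown tract"):
            rve.tract_preset("hippocampus")


class TestGenerate:
    def test_degenerate_single_straight_axon(self):
        cfg = RVEConfig(tract_params=degenerate_params(), box=(5.0, 5.0, 5.0),
                        seed=1, calibrate_tortuosity=True)
        r = rve.generate_rve(cfg)
        assert len(r.tubes) == 1
        t = r.tubes[0]
        assert _tube_tau(t.centerline_points) == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t.a, t.a[0]) and np.allclose(t.a, t.b)  # circular, constant

    def test_same_seed_identical_different_seed_differs(self, cc_params):
        cfg = lambda s: RVEConfig(tract_params=cc_params, box=(6.0, 6.0, 6.0), seed=s)
        r1, r2, r3 = (rve.generate_rve(cfg(s)) for s in (7, 7, 8))
        assert len(r1.tubes) == len(r2.tubes)
        for a, b in zip(r1.tubes, r2.tubes):
            assert np.array_equal(a.centers, b.centers)
            assert np.array_equal(a.a, b.a)
        assert not all(
            np.allclose(a.seed_center, b.seed_center)
            for a, b in zip(r1.tubes, r3.tubes)
        )

    def test_achieved_stats_in_band(self, small_rve, cc_params):
        st = small_rve.achieved_stats
        assert abs(st.volume_fraction - cc_params.volume_fraction) <= cc_params.volume_fraction_sd
        assert st.ellipticity_min >= cc_params.ellipticity_min - 1e-9
        assert st.ellipticity_max <= cc_params.ellipticity_max + 1e-9

    def test_no_overlap_at_any_station_incl_periodic_images(self, small_rve):
        period = np.array(small_rve.box[:2])
        tubes = small_rve.tubes
        for i in range(len(tubes)):
            for j in range(i + 1, len(tubes)):
                assert not _pair_violates(tubes[i], tubes[j], period,
                                          small_rve.config.min_gap)

    def test_every_tube_spans_full_z(self, small_rve):
        for t in small_rve.tubes:
            assert t.z[0] == 0.0
            assert t.z[-1] == pytest.approx(small_rve.box[2])

    def test_interlayer_semiaxis_step_capped(self, small_rve, cc_params):
        # the cap applies to the perpendicular-plane ellipse (the measured
        # quantity); the z-plane raster adds the tilt stretch on top
        for t in small_rve.tubes:
            assert np.all(
                np.abs(np.diff(t.a_perp)) <= cc_params.interlayer_semiaxis_delta + 1e-9
            )

    def test_infeasible_volume_fraction_fails_loudly(self):
        tp = degenerate_params(
            axonal_density=80 / (5.0**3) * 1e9, volume_fraction=0.85,
            volume_fraction_sd=0.01, area_mu=math.log(0.3),
        )
        cfg = RVEConfig(tract_params=tp, box=(5.0, 5.0, 5.0), seed=0,
                        placement_attempts=200, max_outer_iterations=2)
        with pytest.raises(InfeasibleRVEError):
            rve.generate_rve(cfg)

    def test_box_too_small_for_one_axon(self):
        tp = degenerate_params(axonal_density=1e3)  # ~0 axons expected
        with pytest.raises(InfeasibleRVEError, match="box too small"):
            rve.generate_rve(RVEConfig(tract_params=tp, box=(5.0, 5.0, 5.0)))

    def test_tortuosity_calibration_hits_target(self, cc_params):
        r = rve.generate_rve(RVEConfig(tract_params=cc_params, box=(8.0, 8.0, 8.0), seed=5))
        taus = [_tube_tau(t.centerline_points) for t in r.tubes]
        assert np.mean(taus) == pytest.approx(cc_params.tortuosity_mean, abs=0.02)


class TestDistributionMatching:
    def test_area_mode_median_match_input_lognormal(self, cc_params):
        # pooled per-axon mean perpendicular areas over seeds, fitted and
        # compared with the input lognormal's mode and median.  (The
        # arithmetic mean is not checked: the published density and volume
        # fraction jointly truncate the heavy upper tail, which the robust
        # mode/median barely feel.)
        pooled = []
        for seed in range(4):
            r = rve.generate_rve(
                RVEConfig(tract_params=cc_params, box=(10.0, 10.0, 10.0), seed=seed)
            )
            tilt = np.array([rve._tilt_secant(t.centerline_points) for t in r.tubes])
            pooled.extend(np.array([t.mean_area for t in r.tubes]) / tilt)
        fit = statsfit.fit_lognormal(np.array(pooled))
        assert fit.median == pytest.approx(math.exp(cc_params.area_mu), rel=0.15)
        assert fit.mode == pytest.approx(
            math.exp(cc_params.area_mu - cc_params.area_sigma**2), rel=0.35
        )  # the mode of a broad lognormal is noisy at n ≈ 90


class TestValidateRVE:
    def test_axon_count_round_trips_exactly(self, small_rve):
        stats = rve.validate_rve(small_rve, station_stride=4)
        vol = synth.voxelize_tubes(small_rve.tubes, small_rve.box)
        n_measured = stats.axonal_density * np.prod(small_rve.box) * 1e-9
        assert round(n_measured) == len(small_rve.tubes)
        assert stats.volume_fraction == pytest.approx(
            small_rve.achieved_stats.volume_fraction, abs=0.02
        )


class TestSTL:
    def test_cylinder_stl_volume_within_1pct(self, tmp_path):
        tube = straight_tube(radius=0.5, length=6.0, center=(3.0, 3.0))
        r = RVE(tubes=[tube], box=(6.0, 6.0, 6.0), achieved_stats=None)
        files = rve.export_stl(r, tmp_path)
        mesh = trimesh.load(tmp_path / "axon_001.stl")
        assert abs(mesh.volume / (math.pi * 0.25 * 6.0) - 1) < 0.01

    def test_shells_watertight_euler_2_and_partition_volume(self, tmp_path):
        z = np.arange(0, 6.0 + 1e-9, 0.15)
        n = z.size
        mk = lambda i, c: AxonTube(i, z, np.tile(c, (n, 1)), np.full(n, 0.5),
                                   np.full(n, 0.5), np.zeros(n), 0.0)
        r = RVE(tubes=[mk(1, [3.0, 3.0]), mk(2, [0.1, 3.0]), mk(3, [0.05, 0.1])],
                box=(6.0, 6.0, 6.0), achieved_stats=None)
        meshes = rve.tube_meshes(r)
        vol_exp = math.pi * 0.25 * 6.0
        assert [len(s) for s in meshes.values()] == [1, 2, 4]
        for shells in meshes.values():
            for s in shells:
                assert s.is_watertight and s.euler_number == 2
            assert sum(s.volume for s in shells) == pytest.approx(vol_exp, rel=0.01)

    def test_periodic_images_of_clipped_parts_coincide(self):
        z = np.arange(0, 3.0 + 1e-9, 0.15)
        n = z.size
        tube = AxonTube(1, z, np.tile([0.1, 1.5], (n, 1)), np.full(n, 0.4),
                        np.full(n, 0.4), np.zeros(n), 0.0)
        r = RVE(tubes=[tube], box=(3.0, 3.0, 3.0), achieved_stats=None)
        shells = rve.tube_meshes(r)[1]
        assert len(shells) == 2
        # translating the wrapped shell by ±box_x must reassemble the tube:
        # the union then matches the unclipped loft volume
        full = rve._loft_tube(tube)
        assert sum(s.volume for s in shells) == pytest.approx(full.volume, rel=1e-6)
        # x-extents of the two shells together tile [0, box] boundary-to-boundary
        spans = sorted((s.bounds[0][0], s.bounds[1][0]) for s in shells)
        assert spans[0][0] == pytest.approx(0.0, abs=1e-6)
        assert spans[1][1] == pytest.approx(3.0, abs=1e-6)

    def test_rve_stl_round_trip_volume_fraction(self, small_rve, tmp_path):
        files = rve.export_stl(small_rve, tmp_path)
        combined = trimesh.load(tmp_path / "rve.stl")
        vf = combined.volume / np.prod(small_rve.box)
        assert vf == pytest.approx(small_rve.achieved_stats.volume_fraction, rel=0.02)


class TestGeometryHelpers:
    def test_nearest_image_convention(self):
        period = np.array([10.0, 10.0])
        d = _nearest_image(np.array([9.0, -9.0]), period)
        assert np.allclose(d, [-1.0, 1.0])

    def test_tilt_secant_straight_line_is_one(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 3, 20)])
        assert rve._tilt_secant(pts) == pytest.approx(1.0)
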