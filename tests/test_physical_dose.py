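"""Dose engine: ray tracing, lateral kernel, splitting, scoring, MU."""

import numpy as np
import pytest

import carbonpb.physical_dose as pd
from carbonpb.beam_data import idd_at_depth
from carbonpb.physical_dose import (DoseEngineError, Spot, build_slab_phantom,
                                    compute_dose, compute_field_dose_water,
                                    dose_components, effective_depth,
                                    heterogeneous_slab_phantom,
                                    lateral_gaussian, sequence_control_points,
                                    sigma_at_depth, split_beam, transit_dose,
                                    water_box)


class TestEffectiveDepth:
    def test_uniform_water_equals_geometric_depth(self, water_ph):
        top = water_ph.z_top_face
        d = effective_depth(water_ph, (0, 0, top), (0, 0, -1),
                            (0, 0, top - 50.0))
        assert d == pytest.approx(50.0, abs=0.2)

    def test_high_rsp_slab_adds_excess(self):
        ph = build_slab_phantom(
            regions=[(-40, 40, -40, 40, 30, 40, 2.0),
                     (-40, 40, -40, 40, -60, 30, 1.0)],
            bounds=((-40, 40), (-40, 40), (-60, 40)), spacing=2.0)
        d = effective_depth(ph, (0, 0, 40.0), (0, 0, -1), (0, 0, -20.0))
        # 10 mm of RSP 2 plus 50 mm of water
        assert d == pytest.approx(70.0, abs=0.3)

    @pytest.mark.parametrize("x,slab_rsp", [(-30.0, 0.11), (0.0, 1.16),
                                            (30.0, 1.37)])
    def test_three_column_phantom_hand_sum(self, x, slab_rsp):
        ph = heterogeneous_slab_phantom()
        d = effective_depth(ph, (x, 0, 60.0), (0, 0, -1), (x, 0, -50.0))
        expected = 20.0 * slab_rsp + 40.0 * pd.AIR_RSP + 50.0
        assert d == pytest.approx(expected, abs=0.3)

    def test_zero_direction_rejected(self, water_ph):
        with pytest.raises(DoseEngineError):
            effective_depth(water_ph, (0, 0, 0), (0, 0, 0), (0, 0, -10))


class TestLateralGaussian:
    def test_peak_value(self):
        s = 3.0
        assert lateral_gaussian(0, 0, 0, 0, s, s) == pytest.approx(
            1.0 / (2 * np.pi * s * s), rel=1e-12)

    def test_one_sigma_offset(self):
        s = 4.0
        peak = lateral_gaussian(0, 0, 0, 0, s, s)
        assert lateral_gaussian(s, 0, 0, 0, s, s) == pytest.approx(
            peak * np.exp(-0.5), rel=1e-12)

    def test_plane_integral_is_unity(self):
        x = np.linspace(-40, 40, 801)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        g = lateral_gaussian(xx, yy, 1.0, -2.0, 3.0, 5.0)
        integral = np.trapezoid(np.trapezoid(g, x, axis=1), x)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DoseEngineError):
            lateral_gaussian(0, 0, 0, 0, -1.0, 1.0)


class TestSigmaAtDepth:
    def test_waist_value_at_isocenter(self, small_lib):
        k = small_lib.kernels[0]
        sx, sy = sigma_at_depth(k, 1, 0.0, 0.0)
        assert sx == pytest.approx(k.sigma_optics["sigma_x"], rel=1e-12)
        assert sy == pytest.approx(k.sigma_optics["sigma_y"], rel=1e-12)

    @pytest.mark.parametrize("n", [2, 3])
    def test_fragment_components_isotropic(self, small_lib, n):
        sx, sy = sigma_at_depth(small_lib.kernels[1], n, -50.0, 80.0)
        assert sx == sy

    def test_monotone_growth_with_depth(self, small_lib):
        k = small_lib.kernels[2]
        weqs = np.array([0.0, 30.0, 60.0, 90.0])
        s1 = [sigma_at_depth(k, 1, -w, w)[0] for w in weqs]
        s2 = [sigma_at_depth(k, 2, -w, w)[0] for w in weqs]
        assert all(a < b for a, b in zip(s1, s1[1:]))
        assert all(a < b for a, b in zip(s2, s2[1:]))

    def test_invalid_component(self, small_lib):
        with pytest.raises(DoseEngineError):
            sigma_at_depth(small_lib.kernels[0], 0, 0.0, 0.0)


class TestSplitBeam:
    def test_default_yields_nine_sub_beams(self, small_lib):
        subs = split_beam(Spot(0, 0, 0, 0.01), small_lib.kernels[0])
        assert len(subs) == 9
        assert sum(s.weight for s in subs) == pytest.approx(1.0, abs=1e-12)

    def test_identity_for_single_sub_beam(self, small_lib):
        k = small_lib.kernels[0]
        subs = split_beam(Spot(1.0, -2.0, 0, 0.01), k, n_per_axis=1)
        assert len(subs) == 1
        sb = subs[0]
        assert sb.weight == 1.0
        assert sb.x0 == sb.y0 == sb.slope_x == sb.slope_y == 0.0
        assert sb.cov_x == pd._optics_cov(k, "x")

    @pytest.mark.parametrize("n", [3, 5, 9])
    @pytest.mark.parametrize("z_plane", [0.0, -150.0, 200.0])
    def test_mixture_reconstructs_parent_profile(self, small_lib, n,
                                                 z_plane):
        """Sub-beam mixture matches the parent Gaussian within 1% of peak
        at any plane in a homogeneous (here: empty) medium."""
        k = small_lib.kernels[1]
        spot = Spot(0, 0, 1, 0.01)
        subs = split_beam(spot, k, n_per_axis=n)
        x = np.linspace(-25, 25, 501)
        mix = np.zeros_like(x)
        for sb in subs:
            var = sb.optics_var_at(z_plane, "x")
            cx, _ = sb.center_at(z_plane)
            mix += sb.weight * np.exp(-(x - cx) ** 2 / (2 * var)) \
                / np.sqrt(2 * np.pi * var)
        parent_sigma, _ = sigma_at_depth(k, 1, z_plane, 0.0)
        parent = np.exp(-x ** 2 / (2 * parent_sigma ** 2)) \
            / np.sqrt(2 * np.pi * parent_sigma ** 2)
        assert np.max(np.abs(mix - parent)) <= 0.01 * parent.max()

    def test_invalid_split_count(self, small_lib):
        with pytest.raises(DoseEngineError):
            split_beam(Spot(0, 0, 0, 0.01), small_lib.kernels[0], 0)


class TestComputeDose:
    def test_zero_mu_plan_gives_zero_grid(self, small_lib, water_ph):
        grid = compute_dose([Spot(0, 0, 0, 0.0)], water_ph, small_lib)
        assert np.all(grid.physical == 0.0)

    def test_linearity_duplicated_spot(self, small_lib, water_ph):
        one = compute_dose([Spot(0, 0, 1, 0.01)], water_ph, small_lib)
        two = compute_dose([Spot(0, 0, 1, 0.01)] * 2, water_ph, small_lib)
        np.testing.assert_allclose(two.physical, 2 * one.physical,
                                   rtol=1e-12, atol=0.0)

    def test_transverse_integral_matches_idd(self, small_lib, water_ph):
        w = 0.01
        grid = compute_dose([Spot(0, 0, 2, w)], water_ph, small_lib,
                            n_split=1)
        k = small_lib.kernels[2]
        zc = water_ph.axis_centers(2)
        dz_area = water_ph.spacing[0] * water_ph.spacing[1]
        for iz in (20, 40, 60):
            weq = water_ph.z_top_face - zc[iz]
            expected = w * k.absolute_correction * sum(
                idd_at_depth(k, n, weq) for n in (1, 2, 3))
            got = grid.physical[:, :, iz].sum() * dz_area
            assert got == pytest.approx(expected, rel=0.02)

    def test_split_vs_unsplit_within_one_percent_of_peak(self, small_lib,
                                                         water_ph):
        plan = [Spot(0, 0, 2, 0.01)]
        g1 = compute_dose(plan, water_ph, small_lib, n_split=1)
        g3 = compute_dose(plan, water_ph, small_lib, n_split=3)
        peak = g1.physical.max()
        assert np.abs(g3.physical - g1.physical).max() <= 0.01 * peak

    def test_component_partition_conserves_total(self, small_lib,
                                                 water_ph):
        plan = [Spot(0, 0, 1, 0.01), Spot(6, 0, 2, 0.02)]
        plain = compute_dose(plan, water_ph, small_lib)
        tracked = compute_dose(plan, water_ph, small_lib,
                               track_components=True)
        total = tracked.carbon + tracked.fragment
        np.testing.assert_allclose(total, plain.physical, rtol=1e-9,
                                   atol=1e-9 * plain.physical.max())

    def test_fast_water_path_matches_engine(self, small_lib, water_ph):
        plan = [Spot(x, y, 2, 0.01) for x in (-6.0, 0.0)
                for y in (-6.0, 0.0)]
        ga = compute_dose(plan, water_ph, small_lib, n_split=1)
        gb = compute_field_dose_water(plan, water_ph, small_lib)
        assert np.abs(ga.physical - gb.physical).max() \
            <= 1e-4 * ga.physical.max()

    def test_spot_outside_field_rejected(self, small_lib, water_ph):
        with pytest.raises(DoseEngineError):
            compute_dose([Spot(150.0, 0, 0, 0.01)], water_ph, small_lib)

    def test_unknown_energy_rejected(self, small_lib, water_ph):
        with pytest.raises(Exception):
            compute_dose([Spot(0, 0, 99, 0.01)], water_ph, small_lib)

    def test_heterogeneity_range_ordering(self, small_lib):
        """Depth dose falls off deeper behind the lung column than behind
        acrylic, which in turn is deeper than behind bone."""
        from carbonpb.qa import DoseProfile, profile_metrics
        ph = heterogeneous_slab_phantom()
        plan = [Spot(x, 0.0, 3, 0.01) for x in (-30.0, 0.0, 30.0)]
        grid = compute_dose(plan, ph, small_lib, n_split=3)
        r90 = {}
        for x in (-30.0, 0.0, 30.0):
            dep, dose = pd.depth_dose_profile(grid, x, 0.0)
            r90[x] = profile_metrics(DoseProfile(dep, dose),
                                     kind="depth").r90
        assert r90[-30.0] > r90[0.0] > r90[30.0]

    def test_split_refinement_converges(self, small_lib):
        """Dose behind a lateral interface approaches the fine-split
        reference monotonically as the splitting number grows."""
        ph = heterogeneous_slab_phantom(water_depth=60.0)
        spot = [Spot(-15.0, 0.0, 1, 0.01)]  # straddles lung/acrylic edge
        probe = None
        vals = {}
        for n in (1, 3, 7, 15):
            grid = compute_dose(spot, ph, small_lib, n_split=n)
            if probe is None:
                xc = grid.axis_centers(0)
                zc = grid.axis_centers(2)
                ix = int(np.argmin(np.abs(xc - (-15.0))))
                iz = int(np.argmin(np.abs(zc - (-40.0))))
                iy = ph.shape[1] // 2
                probe = (ix, iy, iz)
            vals[n] = grid.physical[probe]
        ref = vals[15]
        errs = [abs(vals[n] - ref) for n in (1, 3, 7)]
        assert errs[0] >= errs[1] >= errs[2]


class TestDoseComponents:
    def test_pure_limits(self):
        d_c, d_f = dose_components(1.0, 2.0, 3.0, 0.0)
        assert (d_c, d_f) == (3.0, 3.0)
        d_c, d_f = dose_components(1.0, 2.0, 3.0, 1.0)
        assert (d_c, d_f) == (1.0, 5.0)

    def test_conservation_for_any_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f1, f2, f3 = rng.uniform(0, 5, 3)
            r = rng.uniform(0, 1)
            d_c, d_f = dose_components(f1, f2, f3, r)
            assert d_c + d_f == pytest.approx(f1 + f2 + f3, rel=1e-12)

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(DoseEngineError):
            dose_components(1.0, 1.0, 1.0, 1.5)


class TestTransitDose:
    def test_zero_length_segment(self):
        segs = transit_dose([(0, 0), (0, 0)], (10.0, 10.0), 0.5)
        assert segs == [[]]

    def test_current_times_period(self):
        segs = transit_dose([(0, 0), (10.0, 0)], (10.0, 10.0), 0.5)
        total = sum(d.mu for d in segs[0])
        assert total == pytest.approx(0.5, rel=1e-12)  # 1 s at 0.5 MU/s

    def test_linear_in_current(self):
        lo = transit_dose([(0, 0), (6, 0), (6, 6)], (20.0, 20.0), 1.0)
        hi = transit_dose([(0, 0), (6, 0), (6, 6)], (20.0, 20.0), 2.0)
        for a, b in zip(lo, hi):
            assert sum(d.mu for d in b) == pytest.approx(
                2 * sum(d.mu for d in a), rel=1e-12)

    def test_zero_speed_with_motion_rejected(self):
        with pytest.raises(DoseEngineError):
            transit_dose([(0, 0), (5, 0)], (0.0, 10.0), 1.0)


def _uniform_plan(machine, n=5, energy=0, spacing=6.0, current=2.0,
                  speed=2.0e4):
    # stationary MU chosen equal to the moving MU so the 1:1 rule holds
    w = current * (spacing / speed)
    return [Spot(i * spacing, 0.0, energy, w) for i in range(n)]


class TestControlPoints:
    def test_rule_satisfying_plan_single_control_point(self, small_lib):
        plan = _uniform_plan(small_lib.machine)
        cps = sequence_control_points(plan, small_lib.machine, current=2.0)
        assert len(cps) == 1
        assert cps[0].reason == "start"

    def test_energy_change_creates_range_change(self, small_lib):
        plan = _uniform_plan(small_lib.machine, energy=0) \
            + _uniform_plan(small_lib.machine, energy=1)
        cps = sequence_control_points(plan, small_lib.machine, current=2.0)
        assert "range_change" in {c.reason for c in cps}

    def test_tiny_segment_triggers_spm_rule(self, small_lib):
        plan = _uniform_plan(small_lib.machine)
        # insert a segment much shorter than the SPM-dose distance
        tiny = Spot(plan[-1].x + 0.1, 0.0, 0, plan[-1].w)
        cps = sequence_control_points(plan + [tiny], small_lib.machine,
                                      current=2.0)
        assert "spm_dose_low" in {c.reason for c in cps}

    def test_small_spot_dose_triggers_short_dose(self, small_lib):
        plan = _uniform_plan(small_lib.machine)
        plan.append(Spot(plan[-1].x + 6.0, 0.0, 0, 0.0001))
        cps = sequence_control_points(plan, small_lib.machine, current=2.0)
        assert "short_dose" in {c.reason for c in cps}

    def test_currents_within_machine_band(self, small_lib):
        plan = _uniform_plan(small_lib.machine)
        with pytest.raises(DoseEngineError):
            sequence_control_points(plan, small_lib.machine, current=25.0)

    def test_empty_plan_rejected(self, small_lib):
        with pytest.raises(DoseEngineError):
            sequence_control_points([], small_lib.machine)


class TestSlabPhantom:
    def test_all_water_spec_is_uniform(self):
        ph = build_slab_phantom(
            regions=[(-40, 40, -40, 40, -60, 40, 1.0)],
            bounds=((-40, 40), (-40, 40), (-60, 40)))
        assert ph.is_uniform() and ph.values.flat[0] == 1.0

    def test_preset_column_rsps(self):
        ph = heterogeneous_slab_phantom()
        xc = ph.axis_centers(0)
        zc = ph.axis_centers(2)
        iz = int(np.argmin(np.abs(zc - 50.0)))  # inside the slab
        iy = ph.shape[1] // 2
        get = lambda x: ph.values[int(np.argmin(np.abs(xc - x))), iy, iz]
        assert get(-30.0) == pd.LUNG_RSP
        assert get(0.0) == pd.ACRYLIC_RSP
        assert get(30.0) == pd.BONE_RSP
        assert get(-60.0) == pd.ACRYLIC_RSP

    def test_voxel_center_containment_rule(self):
        ph = build_slab_phantom(
            regions=[(0.0, 3.0, -10, 10, -10, 10, 2.0)],
            bounds=((-10, 10), (-10, 10), (-10, 10)), spacing=2.0,
            default_rsp=1.0)
        xc = ph.axis_centers(0)
        inside = ph.values[np.argmin(np.abs(xc - 1.0)), 0, 0]
        outside = ph.values[np.argmin(np.abs(xc - 3.0)), 0, 0]
        assert inside == 2.0 and outside == 1.0

    def test_overlapping_regions_rejected(self):
        with pytest.raises(DoseEngineError):
            build_slab_phantom(
                regions=[(-10, 10, -10, 10, -10, 10, 1.0),
                         (-5, 5, -5, 5, -5, 5, 2.0)],
                bounds=((-10, 10), (-10, 10), (-10, 10)))


class TestMUCalibration:
    def test_reference_delivers_one_cgy_per_mu(self, calib_lib):
        calibrated, record = pd.mu_calibration(calib_lib)
        assert record.scale > 0
        # recompute from scratch with the calibrated library
        mu = pd.mu_for_reference_dose(calibrated, dose_gy=0.01)
        assert mu == pytest.approx(1.0, rel=5e-3)

    def test_two_hundred_mu_for_two_hundred_cgy(self, calib_lib):
        calibrated, _ = pd.mu_calibration(calib_lib)
        mu = pd.mu_for_reference_dose(calibrated, dose_gy=2.0)
        assert mu == pytest.approx(200.0, rel=5e-3)

    def test_prescription_scaling_linearity(self, calib_lib):
        calibrated, _ = pd.mu_calibration(calib_lib)
        mu1 = pd.mu_for_reference_dose(calibrated, dose_gy=1.0)
        mu2 = pd.mu_for_reference_dose(calibrated, dose_gy=2.0)
        assert mu2 == pytest.approx(2 * mu1, rel=1e-9)

    def test_insufficient_range_rejected(self, small_lib):
        with pytest.raises(DoseEngineError):
            pd.mu_calibration(small_lib)
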