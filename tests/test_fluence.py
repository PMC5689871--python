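"""Fluence engine: accumulation physics, grids, composites, and export."""

import numpy as np
import pytest

from fluqa.geometry import BeamAngles, source_position
from fluqa.log_io import DeliverySegment
from fluqa.fluence import (
    FLAT_PROFILE,
    GridSpec,
    accumulate_fluence,
    composite_2d_fluence,
    compute_portal_bounds,
    compute_volume_bounds,
    export_volume,
    fluence_from_log,
    fluence_from_plan,
    load_volume,
)
from fluqa.plan_io import upsample_beam
from test_plan_io import make_beam


def static_segment(delta_mu=100.0, gantry=0.0, half=5.0, collimator=0.0):
    n = 60
    ang = BeamAngles(0.0, gantry, collimator)
    return DeliverySegment(
        angles=ang, jaws=(-half, half, -half, half),
        bank_a=np.full(n, -half), bank_b=np.full(n, half),
        delta_mu=delta_mu, source=source_position(ang),
    )


def odd_grid(n=21, voxel=0.3):
    """Grid with a voxel center exactly at the isocenter."""
    half = n * voxel / 2.0
    return GridSpec(origin=(-half, -half, -half), voxel_size=voxel, dims=(n, n, n))


class TestVolumeBounds:
    def test_symmetric_jaws_give_40_cube(self):
        beam = make_beam([0.0, 1.0], [0, 0], jaws=(-5, 5, -5, 5))
        grid = compute_volume_bounds([beam])
        assert grid.dims == (40, 40, 40)
        assert grid.origin == pytest.approx((-6.0, -6.0, -6.0))

    def test_asymmetric_jaws_use_largest_edge(self):
        beam = make_beam([0.0, 1.0], [0, 0], jaws=(-2, 6, -3, 3))
        grid = compute_volume_bounds([beam])
        half_extent = -grid.origin[0]
        assert half_extent == pytest.approx(7.0, abs=0.3)
        assert half_extent >= 7.0 - 1e-9  # margin honored: >= max edge + 1 cm

    def test_all_zero_jaws_degenerate_to_minimal_grid(self):
        beam = make_beam([0.0, 1.0], [0, 0], jaws=(0, 0, 0, 0))
        grid = compute_volume_bounds([beam])
        assert grid.dims == (3, 3, 3)

    def test_margin_covers_jaw_span(self, demo_beams):
        grid = compute_volume_bounds(demo_beams)
        span = grid.dims[0] * grid.voxel_size
        assert span >= 10.0 + 2.0  # field + 1 cm margin each side


class TestAccumulate:
    def test_isocenter_voxel_gets_full_mu(self):
        v = accumulate_fluence([static_segment(100.0)], odd_grid())
        center = tuple(d // 2 for d in v.grid.dims)
        assert v.values[center] == pytest.approx(100.0)

    def test_inverse_square_downstream(self):
        # on-axis voxel at y = +10 cm: 100 MU x (100/110)^2
        grid = GridSpec(origin=(-0.45, 9.55, -0.45), voxel_size=0.3, dims=(3, 3, 3))
        v = accumulate_fluence([static_segment(100.0)], grid)
        assert v.values[1, 1, 1] == pytest.approx(100.0 * (100.0 / 110.0) ** 2, rel=1e-12)

    def test_voxel_outside_field_stays_zero(self):
        v = accumulate_fluence([static_segment(100.0, half=2.0)], odd_grid())
        # corner voxel is outside the 4x4 field at gantry 0
        assert v.values[0, 10, 0] == 0.0

    def test_two_segments_superpose(self):
        g = odd_grid()
        s1 = static_segment(60.0, gantry=0.0)
        s2 = static_segment(40.0, gantry=90.0)
        both = accumulate_fluence([s1, s2], g)
        sep = accumulate_fluence([s1], g).values + accumulate_fluence([s2], g).values
        assert np.array_equal(both.values, sep)

    def test_mu_linearity(self):
        g = odd_grid()
        v1 = accumulate_fluence([static_segment(50.0)], g)
        v3 = accumulate_fluence([static_segment(150.0)], g)
        assert np.allclose(v3.values, 3.0 * v1.values, rtol=1e-13)

    def test_rotation_equivariance_about_gantry_axis(self, demo_beams):
        # shifting all gantry angles by +90 deg rotates the volume by 90 deg
        g = GridSpec(origin=(-3.0, -3.0, -0.9), voxel_size=0.3, dims=(20, 20, 6))
        segs = upsample_beam(demo_beams[0], step_deg=1.0)
        rot = []
        for s in segs:
            ang = BeamAngles(s.angles.couch_deg, s.angles.gantry_deg + 90.0,
                             s.angles.collimator_deg)
            rot.append(DeliverySegment(angles=ang, jaws=s.jaws, bank_a=s.bank_a,
                                       bank_b=s.bank_b, delta_mu=s.delta_mu,
                                       source=source_position(ang)))
        v = accumulate_fluence(segs, g).values
        vr = accumulate_fluence(rot, g).values
        expected = np.rot90(v, 1, axes=(0, 1))
        # voxel-center sampling of a binary mask: allow edge-voxel flips
        err = np.abs(vr - expected)
        assert np.quantile(err, 0.98) <= 0.02 * v.max()
        assert np.median(err) <= 0.005 * v.max()


class TestPlanAndLogPaths:
    def test_plan_fluence_matches_manual_accumulation(self):
        beam = make_beam([0.0, 1.0], [0.0, 0.0], total_mu=100.0)
        g = odd_grid(11)
        via_plan = fluence_from_plan(beam, g)
        manual = accumulate_fluence(upsample_beam(beam), g)
        assert np.array_equal(via_plan.values, manual.values)

    def test_two_beam_plan_superposes(self, demo_beams):
        beam = demo_beams[0]
        g = odd_grid(11)
        doubled = fluence_from_plan([beam, beam], g)
        single = fluence_from_plan([beam], g)
        assert np.allclose(doubled.values, 2.0 * single.values, rtol=1e-13)

    def test_empty_log_gives_zero_volume(self, grid20):
        v = fluence_from_log([], grid20)
        assert not np.any(v.values)

    def test_log_matches_plan_within_discretization(self, demo_plan_volume,
                                                    demo_log_volume):
        vp, vl = demo_plan_volume.values, demo_log_volume.values
        assert np.abs(vp - vl).max() <= 0.015 * vp.max()

    def test_mu_reparameterization_invariance(self, demo_beams, grid20):
        # doubling dose rate and halving duration delivers the same fluence
        from fluqa.synthetic import generate_matched_log

        fast = generate_matched_log(demo_beams[0], duration_s=60.0, dt=0.02)
        slow = generate_matched_log(demo_beams[0], duration_s=120.0, dt=0.04)
        assert len(fast) == len(slow)
        assert fast[100].dose_rate == pytest.approx(2 * slow[100].dose_rate)
        v_fast = fluence_from_log(fast, grid20).values
        v_slow = fluence_from_log(slow, grid20).values
        assert np.array_equal(v_fast, v_slow)

    def test_downsampling_error_below_qa_threshold(self, demo_log, grid20):
        v16 = fluence_from_log(demo_log, grid20, factor=16).values
        v1 = fluence_from_log(demo_log, grid20, factor=1).values
        assert np.abs(v16 - v1).max() < 0.03 * v1.max()


class TestComposite2D:
    def test_static_gantry_zero_matches_central_slice(self):
        from fluqa.fluence import PortalGrid

        beam = make_beam([0.0, 1.0], [0.0, 0.0], total_mu=100.0)
        n = 21
        g = odd_grid(n)
        v3d = fluence_from_plan(beam, g)
        portal = PortalGrid(origin=(g.origin[0], g.origin[2]), pixel_size=0.3,
                            dims=(n, n))
        m2d = composite_2d_fluence(beam, portal)
        # central y-slice of the 3D volume vs the 2D map, inside the field
        sl = v3d.values[:, n // 2, :]
        inside = m2d.values > 0
        assert np.any(inside)
        rel = np.abs(sl[inside] - m2d.values[inside]) / 100.0
        assert rel.max() < 0.01  # only the tiny lateral inverse-square term differs

    def test_gantry_perturbation_leaves_map_bit_identical(self, demo_beams):
        from fluqa.error_sim import ErrorSpec, inject_errors

        portal = compute_portal_bounds(demo_beams)
        base = composite_2d_fluence(demo_beams, portal)
        moved = inject_errors(demo_beams, ErrorSpec.within_tolerance("gantry", seed=5))
        pert = composite_2d_fluence(moved, portal)
        assert np.array_equal(base.values, pert.values)

    def test_mu_scaling_is_linear(self, demo_beams):
        from dataclasses import replace

        portal = compute_portal_bounds(demo_beams)
        base = composite_2d_fluence(demo_beams, portal)
        scaled_beams = [replace(b, total_mu=2.0 * b.total_mu) for b in demo_beams]
        scaled = composite_2d_fluence(scaled_beams, portal)
        assert np.allclose(scaled.values, 2.0 * base.values, rtol=1e-13)


class TestExport:
    def test_nrrd_round_trip(self, tmp_path, demo_plan_volume):
        path = tmp_path / "vol.nrrd"
        export_volume(demo_plan_volume, path)
        back = load_volume(path)
        assert np.array_equal(back.values, demo_plan_volume.values)
        assert back.grid.voxel_size == pytest.approx(0.3)
        assert back.grid.origin == pytest.approx(demo_plan_volume.grid.origin)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            GridSpec(origin=(0, 0, 0), voxel_size=0.0, dims=(3, 3, 3))
        with pytest.raises(ValueError):
            GridSpec(origin=(0, 0, 0), voxel_size=0.3, dims=(0, 3, 3))
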