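"""Tests for skeletonization, centerline ordering, plane fitting,
projection and effective-area measurement."""

import numpy as np
import pytest

from mvquant import geometry, phantom
from mvquant.errors import (
    DegeneratePathError,
    DegeneratePlaneError,
    EmptyProjectionError,
    MissingAnnulusError,
    OpenRingError,
)
from mvquant.geometry import (
    analyze_frame,
    effective_area,
    fit_valve_plane,
    order_centerline,
    project_to_plane,
    skeletonize_annulus,
    structure_areas,
)
from mvquant.types import LabelVolume, PlanarProjection, ValvePlane


def make_volume(labels, spacing=0.5):
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    aff[:3, 3] = -(np.asarray(labels.shape) - 1) / 2 * spacing
    return LabelVolume(labels.astype(np.uint8), aff)


def saddle_ring(n=200, radius=14.0, height=2.0):
    phi = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), height * np.cos(2 * phi)]
    )


class TestSkeletonize:
    def test_skeleton_contained_and_compressed(self, flat_ring_frame):
        mask = flat_ring_frame.voxels == 3
        pts = skeletonize_annulus(flat_ring_frame)
        assert all(mask[tuple(p)] for p in pts)
        assert len(pts) <= 0.15 * mask.sum()

    def test_skeleton_follows_analytic_circle(self, flat_ring_spec, flat_ring_frame):
        pts = skeletonize_annulus(flat_ring_frame)
        world = flat_ring_frame.index_to_world(pts)
        rho = np.hypot(world[:, 0], world[:, 1])
        tol = 1.5 * max(flat_ring_frame.spacing)
        assert np.all(np.abs(rho - flat_ring_spec.annulus_radius_mm) <= tol)
        assert np.all(np.abs(world[:, 2]) <= tol)

    def test_single_voxel_is_fixed_point(self):
        labels = np.zeros((9, 9, 9))
        labels[4, 4, 4] = 3
        pts = skeletonize_annulus(make_volume(labels))
        assert np.array_equal(pts, [[4, 4, 4]])

    def test_missing_annulus_raises(self):
        with pytest.raises(MissingAnnulusError):
            skeletonize_annulus(make_volume(np.zeros((9, 9, 9))))


class TestOrderCenterline:
    def test_circle_traversed_monotonically(self, rng):
        phi = np.sort(rng.uniform(0, 2 * np.pi, 80))
        pts = np.column_stack([20 + 10 * np.cos(phi), 20 + 10 * np.sin(phi), np.full(80, 5.0)])
        perm = rng.permutation(80)
        path = order_centerline(pts[perm], np.eye(4))
        ang = np.unwrap(np.arctan2(path.points[:, 1] - 20, path.points[:, 0] - 20))
        diffs = np.diff(ang)
        assert np.all(diffs > 0) or np.all(diffs < 0)
        assert path.n_backtracks == 0

    def test_uniform_circle_detected_closed(self):
        phi = 2 * np.pi * np.arange(60) / 60
        pts = np.column_stack([10 * np.cos(phi), 10 * np.sin(phi), np.zeros(60)])
        path = order_centerline(pts[::-1], np.eye(4))
        assert path.closed

    def test_collinear_points_ordered_end_to_end(self):
        pts = np.array([[5.0, 0, 0], [0.0, 0, 0], [9.0, 0, 0]])
        path = order_centerline(pts, np.eye(4))
        assert path.points[0, 0] == 0.0 and path.points[-1, 0] == 9.0

    def test_two_clusters_logged_not_crashed(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        b = a + [50.0, 50.0, 0.0]
        path = order_centerline(np.vstack([a, b[::-1]]), np.eye(4))
        assert len(path.points) == 10

    def test_too_few_points(self):
        with pytest.raises(DegeneratePathError):
            order_centerline(np.array([[0, 0, 0], [1, 1, 1]]), np.eye(4))


class TestFitValvePlane:
    def test_coplanar_ring_is_exact(self):
        pts = saddle_ring(height=0.0)
        plane = fit_valve_plane(pts)
        assert abs(plane.normal @ [0, 0, 1]) >= 1 - 1e-9
        residuals = (pts - plane.centroid) @ plane.normal
        assert np.max(np.abs(residuals)) <= 1e-9

    def test_saddle_ring_normal_close_to_axis(self):
        plane = fit_valve_plane(saddle_ring(height=2.0, radius=14.0))
        angle = np.degrees(np.arccos(np.clip(abs(plane.normal @ [0, 0, 1]), 0, 1)))
        assert angle <= 2.0

    def test_matches_least_squares_oracle(self, rng):
        # brute-force LS fit z = ax + by + c as an independent oracle on a
        # gently warped ring
        pts = saddle_ring(height=1.5) + rng.normal(0, 0.05, (200, 3))
        A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
        (a, b, _), *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
        n_ls = np.array([-a, -b, 1.0])
        n_ls /= np.linalg.norm(n_ls)
        plane = fit_valve_plane(pts)
        angle = np.degrees(np.arccos(np.clip(abs(plane.normal @ n_ls), 0, 1)))
        assert angle <= 0.5

    def test_invariant_to_point_permutation(self, rng):
        pts = saddle_ring()
        p1 = fit_valve_plane(pts)
        p2 = fit_valve_plane(pts[rng.permutation(len(pts))])
        assert abs(p1.normal @ p2.normal) >= 1 - 1e-12
        assert np.allclose(p1.centroid, p2.centroid)

    def test_orientation_reference_flips_normal(self):
        pts = saddle_ring(height=0.0)
        below = np.array([0.0, 0.0, -10.0])
        plane = fit_valve_plane(pts, orient_reference=below)
        assert (below - plane.centroid) @ plane.normal < 0

    def test_right_handed_basis(self):
        plane = fit_valve_plane(saddle_ring())
        triple = np.dot(np.cross(plane.basis_u, plane.basis_v), plane.normal)
        assert triple == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegeneratePlaneError):
            fit_valve_plane(pts)


class TestProjection:
    def test_disc_area_recovered(self):
        # flat disc of radius 8 mm, 1 voxel thick, axis-aligned plane
        shape = (64, 64, 64)
        labels = np.zeros(shape)
        aff_spacing = 0.5
        ii, jj = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        x = (ii - 31.5) * aff_spacing
        y = (jj - 31.5) * aff_spacing
        labels[:, :, 32][np.hypot(x, y) <= 8.0] = 1
        vol = make_volume(labels)
        plane = ValvePlane(np.zeros(3), np.array([0.0, 0, 1]),
                           np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))
        proj = project_to_plane(vol, plane, pixel_size_mm=0.5)
        area = structure_areas(proj)["anterior_leaflet"]
        assert area == pytest.approx(np.pi * 64.0, rel=0.05)

    def test_single_voxel_single_pixel_region(self):
        from skimage.measure import label as cc

        labels = np.zeros((16, 16, 16))
        labels[8, 8, 8] = 1
        vol = make_volume(labels)
        plane = ValvePlane(np.zeros(3), np.array([0.0, 0, 1]),
                           np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))
        proj = project_to_plane(vol, plane)
        assert cc(proj.rasters["anterior_leaflet"]).max() == 1

    def test_rasters_share_shape_and_calibration(self, small_frame):
        m = analyze_frame(small_frame)
        skel = skeletonize_annulus(small_frame)
        plane = fit_valve_plane(order_centerline(skel, small_frame.affine))
        proj = project_to_plane(small_frame, plane)
        shapes = {r.shape for r in proj.rasters.values()}
        assert len(shapes) == 1
        assert proj.pixel_area_mm2 == pytest.approx(
            proj.pixel_size_mm[0] * proj.pixel_size_mm[1]
        )
        assert set(m.structure_areas_mm2) == set(proj.rasters)

    def test_empty_volume_rejected(self):
        vol = make_volume(np.zeros((16, 16, 16)))
        plane = ValvePlane(np.zeros(3), np.array([0.0, 0, 1]),
                           np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))
        with pytest.raises(EmptyProjectionError):
            project_to_plane(vol, plane)


class TestStructureAreas:
    def test_pixel_count_arithmetic(self):
        r = np.zeros((20, 20), dtype=bool)
        r[:10, :10] = True  # 100 pixels at 0.25 x 0.25 mm
        proj = PlanarProjection({"annulus": r}, (0.25, 0.25), np.zeros(2))
        assert structure_areas(proj)["annulus"] == pytest.approx(6.25)

    def test_empty_raster_zero_area(self):
        proj = PlanarProjection({"annulus": np.zeros((5, 5), bool)}, (0.5, 0.5), np.zeros(2))
        assert structure_areas(proj)["annulus"] == 0.0

    def test_leaflet_band_matches_analytic(self, small_spec, small_frame):
        # anterior + posterior leaflet area ~ annulus ring minus orifice
        m = analyze_frame(small_frame)
        r_t = phantom.orifice_radius(small_spec, 2)
        analytic = np.pi * (small_spec.annulus_radius_mm**2 - r_t**2)
        measured = (
            m.structure_areas_mm2["anterior_leaflet"]
            + m.structure_areas_mm2["posterior_leaflet"]
        )
        assert measured == pytest.approx(analytic, rel=0.07)


class TestEffectiveArea:
    def test_phantom_orifice_8mm(self):
        # dedicated phantom whose mid-cycle orifice radius is exactly 8 mm
        spec = phantom.PhantomSpec(orifice_radius_min_mm=2.0,
                                   orifice_radius_max_mm=8.0, n_frames=4,
                                   grid_shape=(80, 80, 80))
        m = analyze_frame(phantom.make_phantom_frame(spec, 2))
        assert m.effective_area_mm2 == pytest.approx(np.pi * 64.0, rel=0.07)

    def test_fully_obstructed_orifice_is_zero(self):
        ring = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        r = np.hypot(yy - 20, xx - 20)
        ring[(r >= 12) & (r <= 15)] = True
        blocked = r < 12  # leaflets fill the whole enclosed region
        proj = PlanarProjection(
            {"annulus": ring, "anterior_leaflet": blocked}, (0.5, 0.5), np.zeros(2)
        )
        assert effective_area(proj) <= 2 * proj.pixel_area_mm2

    def test_monotone_under_leaflet_erosion(self):
        from scipy.ndimage import binary_erosion
        from skimage.morphology import disk

        yy, xx = np.mgrid[:80, :80]
        r = np.hypot(yy - 40, xx - 40)
        ring = (r >= 30) & (r <= 34)
        leaf = (r >= 12) & (r < 30)
        ea_values = []
        for _ in range(3):
            proj = PlanarProjection(
                {"annulus": ring, "anterior_leaflet": leaf}, (0.5, 0.5), np.zeros(2)
            )
            ea_values.append(effective_area(proj))
            leaf = binary_erosion(leaf, structure=disk(2))
        assert ea_values == sorted(ea_values)

    def test_open_ring_raises_with_gap(self):
        yy, xx = np.mgrid[:80, :80]
        r = np.hypot(yy - 40, xx - 40)
        ang = np.arctan2(yy - 40, xx - 40)
        ring = (r >= 30) & (r <= 33) & ~((ang > 0) & (ang < 1.2))  # big arc missing
        proj = PlanarProjection({"annulus": ring}, (0.5, 0.5), np.zeros(2))
        with pytest.raises(OpenRingError):
            effective_area(proj, closing_radius_mm=2.0)

    def test_ring_with_small_gap_closed_and_measured(self):
        yy, xx = np.mgrid[:80, :80]
        r = np.hypot(yy - 40, xx - 40)
        ang = np.arctan2(yy - 40, xx - 40)
        ring = (r >= 30) & (r <= 33) & ~((ang > 0) & (ang < 0.1))
        proj = PlanarProjection({"annulus": ring}, (0.5, 0.5), np.zeros(2))
        # interior radius 30 px at 0.5 mm/px = 15 mm
        ea = effective_area(proj, closing_radius_mm=4.5)
        assert ea == pytest.approx(np.pi * 15.0**2, rel=0.15)


class TestRotationInvariance:
    def test_areas_stable_under_30_degree_tilt(self):
        specs = {
            t: phantom.PhantomSpec(tilt_deg=t, n_frames=4) for t in (0.0, 30.0)
        }
        results = {
            t: analyze_frame(phantom.make_phantom_frame(s, 2))
            for t, s in specs.items()
        }
        for key in results[0.0].structure_areas_mm2:
            a = results[0.0].structure_areas_mm2[key]
            b = results[30.0].structure_areas_mm2[key]
            assert abs(a - b) / a <= 0.05
        ea0 = results[0.0].effective_area_mm2
        ea30 = results[30.0].effective_area_mm2
        assert abs(ea0 - ea30) / ea0 <= 0.05
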