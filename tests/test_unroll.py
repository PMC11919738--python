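"""Cylindrical projection against the analytic lattice oracle."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from vippgeom.core_lattice import HelicalSymmetry, start_family, subunit_spacing_at_radius
from vippgeom.errors import InvalidArgumentError
from vippgeom.unroll import (
    UnrolledLattice,
    line_family_spacings,
    reroll_points,
    synthetic_lattice_map,
    unroll_map,
    unroll_points,
)


class TestUnrollPoints:
    def test_nearest_neighbour_distances_match_lattice_vectors(self, l3):
        ul = unroll_points(l3, 200, 92.75)
        d, _ = cKDTree(ul.points).query(ul.points, k=3)
        nn = np.round(d[:, 1:], 1).ravel()
        # interior points see both principal directions
        assert (np.abs(nn - 30.4) < 0.1).any()
        assert (np.abs(nn - 42.6) < 0.1).any()
        interior = d[5:-25, 1]
        assert np.allclose(
            np.sort(np.unique(np.round(interior, 1)))[:1], [30.4], atol=0.1
        )

    def test_single_subunit(self, l3):
        ul = unroll_points(l3, 1, 92.75)
        assert ul.points.shape == (1, 2)
        assert ul.points[0, 1] == 0.0

    def test_square_like_lattice(self):
        # circumference 40 Å, twist 90°, rise 10 Å: a 45°-rotated square
        # lattice (side 10*sqrt(2)) with 10 Å axial rows at x = 0,10,20,30
        r = 40.0 / (2 * math.pi)
        ul = unroll_points(HelicalSymmetry(10.0, 90.0), 60, r)
        d, _ = cKDTree(ul.points).query(ul.points, k=2)
        assert np.median(d[:, 1]) == pytest.approx(10.0 * math.sqrt(2.0), rel=1e-9)
        assert np.allclose(np.sort(np.unique(np.round(ul.points[:, 0], 6))),
                           [0.0, 10.0, 20.0, 30.0])
        assert np.allclose(np.diff(np.unique(ul.points[:, 1])), 10.0)

    def test_round_trip_identity(self, l3):
        ul = unroll_points(l3, 100, 92.75)
        xyz = reroll_points(ul)
        assert np.allclose(np.hypot(xyz[:, 0], xyz[:, 1]), 92.75)
        assert np.allclose(xyz[:, 2], ul.points[:, 1])
        phi = np.mod(np.arctan2(xyz[:, 1], xyz[:, 0]), 2 * math.pi)
        assert np.allclose(92.75 * phi, ul.points[:, 0], atol=1e-9)

    def test_argument_checks(self, l3):
        with pytest.raises(InvalidArgumentError):
            unroll_points(l3, 0, 92.75)
        with pytest.raises(InvalidArgumentError):
            unroll_points(l3, 10, 0.0)


class TestUnrollMap:
    def test_lattice_map_peaks_match_analytic_points(self, l3):
        voxel = 2.5
        radius = 60.0
        vol = synthetic_lattice_map(l3, radius, box_px=96, voxel_A=voxel, sigma_A=4.0)
        raster, px_x, px_y = unroll_map(vol, voxel, radius, shell_dr_A=5.0)
        n_sub = int(96 * voxel / l3.rise_A) + 1
        ul = unroll_points(l3, n_sub, radius)
        peaks = peak_local_max(raster, min_distance=3, threshold_rel=0.3)
        assert len(peaks) > 30
        tree = cKDTree(ul.points)
        margin = 3 * px_y
        checked = 0
        for row, col in peaks:
            # sub-pixel refinement: intensity-weighted centroid of a 5x5 patch
            r0, r1 = max(0, row - 2), min(raster.shape[0], row + 3)
            c0, c1 = max(0, col - 2), min(raster.shape[1], col + 3)
            patch = raster[r0:r1, c0:c1]
            w = patch.sum()
            rr = (patch.sum(axis=1) @ np.arange(r0, r1)) / w
            cc = (patch.sum(axis=0) @ np.arange(c0, c1)) / w
            y = rr * px_y
            x = cc * px_x
            if y < margin or y > raster.shape[0] * px_y - margin:
                continue
            dist, _ = tree.query([x, y])
            # allow azimuthal wrap at x = 0 / circumference
            dist_wrap, _ = tree.query([x - 2 * math.pi * radius, y])
            assert min(dist, dist_wrap) < 0.5 * max(px_x, px_y, voxel)
            checked += 1
        assert checked > 20

    def test_uniform_cylinder_gives_constant_raster(self):
        n = 64
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
        rr = np.hypot(yy - c, xx - c) * 2.0
        vol = np.exp(-((rr - 40.0) ** 2) / (2 * 8.0**2)).astype(np.float32)
        raster, _, _ = unroll_map(vol, 2.0, 40.0, shell_dr_A=4.0)
        inner = raster[5:-5]
        assert inner.std() / inner.mean() < 1e-3

    def test_radius_out_of_bounds(self):
        vol = np.zeros((32, 32, 32), dtype=np.float32)
        with pytest.raises(InvalidArgumentError):
            unroll_map(vol, 2.0, 40.0)


class TestLineFamilySpacings:
    def test_published_families(self, l3):
        ul = unroll_points(l3, 400, 92.75)
        df = line_family_spacings(ul, [4, 17, 21]).set_index("k")
        for k in (4, 17):
            expected = start_family(l3, k).axial_spacing_A
            assert df.loc[k, "axial_spacing_A"] == pytest.approx(expected, rel=0.005)
            tilt = math.radians(df.loc[k, "tilt_deg"])
            assert df.loc[k, "perpendicular_spacing_A"] == pytest.approx(
                df.loc[k, "axial_spacing_A"] * math.cos(tilt), rel=1e-6
            )
        # the 21-start family runs nearly parallel to the axis
        assert df.loc[21, "tilt_deg"] > 75.0

    def test_square_lattice_fixture(self):
        # hand-built row-major 10 Å square grid wrapped at 40 Å
        pts = np.array([[10.0 * (j % 4), 10.0 * (j // 4)] for j in range(40)])
        ul = UnrolledLattice(points=pts, radius_A=40.0 / (2 * math.pi), extent=((0, 30), (0, 90)))
        df = line_family_spacings(ul, [1, 4]).set_index("k")
        # k = 1 runs along the rows: horizontal lines, perpendicular == axial
        assert df.loc[1, "tilt_deg"] == pytest.approx(0.0)
        assert df.loc[1, "perpendicular_spacing_A"] == pytest.approx(10.0)
        assert df.loc[1, "axial_spacing_A"] == pytest.approx(10.0)
        # k = 4 runs along the columns: vertical lines
        assert df.loc[4, "tilt_deg"] == pytest.approx(90.0)
        assert df.loc[4, "perpendicular_spacing_A"] == pytest.approx(10.0)

    def test_degenerate_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 30, 20)])
        ul = UnrolledLattice(points=pts, radius_A=50.0, extent=((0, 10), (0, 30)))
        with pytest.raises(InvalidArgumentError):
            line_family_spacings(ul, [1])

    def test_too_few_points_rejected(self, l3):
        ul = unroll_points(l3, 5, 92.75)
        with pytest.raises(InvalidArgumentError):
            line_family_spacings(ul, [1])
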