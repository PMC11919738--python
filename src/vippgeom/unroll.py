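"""Cylindrical projection: unrolling helical lattices into planar lattices.

A point at azimuth phi (radians) and height z on a cylinder of radius r
maps to the plane as (x, y) = (r * phi, z).  Applied to a helical
lattice this produces the geometrically equivalent 2D lattice: the
k-start strand families become families of parallel lines whose axial
spacing equals ``360 * rise / |step(k)|`` from the real-space geometry.

Conventions: azimuth origin on the +x axis, wrap interval [0, 2*pi),
y increases with z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_lattice import HelicalSymmetry, reduce_angle
from .errors import InvalidArgumentError


@dataclass(frozen=True)
class UnrolledLattice:
    """Planar image of a helical lattice at a fixed radius.

    ``points`` is an (N, 2) array of (x_A, y_A) in subunit order
    (row j is subunit j), with x wrapped into [0, 2*pi*radius).
    """

    points: np.ndarray
    radius_A: float
    extent: tuple[tuple[float, float], tuple[float, float]]

    @property
    def circumference_A(self) -> float:
        return 2.0 * math.pi * self.radius_A


def unroll_points(
    sym: HelicalSymmetry, n_subunits: int, radius_A: float, phi0_deg: float = 0.0
) -> UnrolledLattice:
    """Unroll the first ``n_subunits`` of the helix at a given radius."""
    if n_subunits < 1:
        raise InvalidArgumentError(f"n_subunits must be >= 1, got {n_subunits!r}")
    if not (radius_A > 0):
        raise InvalidArgumentError(f"radius_A must be > 0, got {radius_A!r}")
    j = np.arange(n_subunits)
    phi = np.deg2rad(phi0_deg + j * sym.twist_deg) % (2.0 * math.pi)
    x = radius_A * phi
    y = j * sym.rise_A
    pts = np.column_stack([x, y])
    extent = ((float(x.min()), float(x.max())), (float(y.min()), float(y.max())))
    return UnrolledLattice(points=pts, radius_A=radius_A, extent=extent)


def reroll_points(unrolled: UnrolledLattice) -> np.ndarray:
    """Map unrolled (x, y) points back to 3D cylinder coordinates.

    Inverse of the cylindrical projection; used to assert the round-trip
    identity.  Returns an (N, 3) array of (X, Y, Z) in Å.
    """
    phi = unrolled.points[:, 0] / unrolled.radius_A
    return np.column_stack(
        [
            unrolled.radius_A * np.cos(phi),
            unrolled.radius_A * np.sin(phi),
            unrolled.points[:, 1],
        ]
    )


def synthetic_lattice_map(
    sym: HelicalSymmetry,
    radius_A: float,
    box_px: int = 96,
    voxel_A: float = 2.5,
    sigma_A: float = 3.5,
    n_subunits: int | None = None,
) -> np.ndarray:
    """Synthetic density raster: Gaussian blobs at the helical lattice points.

    Fixture builder for testing :func:`unroll_map` against the analytic
    lattice.  The raster is indexed [z, y, x] with the helix axis along z
    through the box centre.
    """
    if n_subunits is None:
        n_subunits = int(box_px * voxel_A / sym.rise_A) + 1
    c = (box_px - 1) / 2.0
    vol = np.zeros((box_px, box_px, box_px), dtype=np.float32)
    half = max(2, int(math.ceil(3 * sigma_A / voxel_A)))
    s2 = 2.0 * (sigma_A / voxel_A) ** 2
    for j in range(n_subunits):
        phi = math.radians(j * sym.twist_deg)
        xp = c + radius_A * math.cos(phi) / voxel_A
        yp = c + radius_A * math.sin(phi) / voxel_A
        zp = j * sym.rise_A / voxel_A
        iz, iy, ix = int(round(zp)), int(round(yp)), int(round(xp))
        z0, z1 = max(0, iz - half), min(box_px, iz + half + 1)
        y0, y1 = max(0, iy - half), min(box_px, iy + half + 1)
        x0, x1 = max(0, ix - half), min(box_px, ix + half + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        gz = np.arange(z0, z1) - zp
        gy = np.arange(y0, y1) - yp
        gx = np.arange(x0, x1) - xp
        vol[z0:z1, y0:y1, x0:x1] += np.exp(
            -(gz[:, None, None] ** 2 + gy[None, :, None] ** 2 + gx[None, None, :] ** 2) / s2
        ).astype(np.float32)
    return vol


def unroll_map(
    map3d: np.ndarray,
    voxel_A: float | tuple[float, float, float],
    radius_A: float,
    shell_dr_A: float | None = None,
    n_shells: int = 5,
) -> tuple[np.ndarray, float, float]:
    """Cylindrical projection of a 3D density raster.

    The raster is indexed [z, y, x]; the cylinder axis runs along z
    through the lateral box centre.  Output pixel (z, theta) is the mean
    trilinearly-interpolated density over ``n_shells`` radial samples in
    [radius - dr/2, radius + dr/2].  Azimuthal sampling is at least
    Nyquist for the voxel size (arc step <= voxel/2).

    Returns ``(raster, pixel_x_A, pixel_y_A)`` where pixel_x is the
    azimuthal arc length per column and pixel_y the axial step per row.
    """
    if isinstance(voxel_A, (tuple, list, np.ndarray)):
        vx, vy, vz = (float(v) for v in voxel_A)
    else:
        vx = vy = vz = float(voxel_A)
    if shell_dr_A is None:
        shell_dr_A = 2.0 * vx
    if shell_dr_A <= 0:
        raise InvalidArgumentError(f"shell_dr_A must be > 0, got {shell_dr_A!r}")
    nz, ny, nx = map3d.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    max_r_A = min(cx * vx, cy * vy)
    if not (0 < radius_A and radius_A + shell_dr_A / 2.0 <= max_r_A):
        raise InvalidArgumentError(
            f"radius {radius_A} Å (+ dr/2) outside raster bounds ({max_r_A:.1f} Å)"
        )

    n_theta = int(math.ceil(2.0 * math.pi * radius_A / (min(vx, vy) / 2.0)))
    theta = np.arange(n_theta) * (2.0 * math.pi / n_theta)
    radii = radius_A + np.linspace(-shell_dr_A / 2.0, shell_dr_A / 2.0, n_shells)
    z_idx = np.arange(nz, dtype=np.float64)

    out = np.zeros((nz, n_theta), dtype=np.float64)
    for r in radii:
        xs = cx + (r / vx) * np.cos(theta)
        ys = cy + (r / vy) * np.sin(theta)
        coords = np.stack(
            [
                np.broadcast_to(z_idx[:, None], (nz, n_theta)).ravel(),
                np.broadcast_to(ys[None, :], (nz, n_theta)).ravel(),
                np.broadcast_to(xs[None, :], (nz, n_theta)).ravel(),
            ]
        )
        out += ndimage.map_coordinates(
            map3d.astype(np.float64), coords, order=1, mode="nearest"
        ).reshape(nz, n_theta)
    out /= n_shells
    return out.astype(np.float32), 2.0 * math.pi * radius_A / n_theta, vz


def _wrap_dx(dx: np.ndarray, circumference: float) -> np.ndarray:
    """Wrap circumferential displacements into (-C/2, C/2]."""
    return dx - circumference * np.round(dx / circumference)


def line_family_spacings(
    unrolled: UnrolledLattice, k_families: list[int]
) -> pd.DataFrame:
    """Spacings and tilts of k-connected line families of an unrolled lattice.

    For each k the points are grouped into the lines joining subunits
    (j, j+k, j+2k, ...); the common line direction is estimated from the
    median wrapped k-step displacement, points are projected on the unit
    normal and clustered, and the median gap between adjacent clusters is
    the perpendicular inter-line spacing.  The axial spacing follows as
    ``perpendicular / cos(tilt)`` (infinite for near-vertical families).

    Returns a DataFrame with columns
    ``k, perpendicular_spacing_A, axial_spacing_A, tilt_deg``.
    """
    pts = np.asarray(unrolled.points, dtype=float)
    if len(pts) < 10:
        raise InvalidArgumentError("need >= 10 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise InvalidArgumentError("degenerate (collinear) point set")
    circ = unrolled.circumference_A

    rows = []
    for k in k_families:
        if k < 1 or k >= len(pts):
            raise InvalidArgumentError(f"invalid family k={k} for {len(pts)} points")
        d = pts[k:] - pts[:-k]
        d[:, 0] = _wrap_dx(d[:, 0], circ)
        ux = float(np.median(d[:, 0]))
        uz = float(np.median(d[:, 1]))
        norm = math.hypot(ux, uz)
        tilt = math.degrees(math.atan2(abs(uz), abs(ux)))
        # unit normal to the line direction
        nvec = np.array([-uz, ux]) / norm
        proj = np.sort(pts @ nvec)
        gaps = np.diff(proj)
        # expected adjacent-line gap ~ unit-cell area / |u|; estimate the
        # cell area from the areal point density of the unrolled patch
        y_span = float(pts[:, 1].max() - pts[:, 1].min())
        cell_area = circ * y_span / max(1, len(pts) - 1)
        thr = 0.3 * cell_area / norm
        centers = []
        start = 0
        for i, g in enumerate(gaps):
            if g > thr:
                centers.append(proj[start : i + 1].mean())
                start = i + 1
        centers.append(proj[start:].mean())
        if len(centers) < 2:
            perp = math.nan
        else:
            perp = float(np.median(np.diff(centers)))
        cos_t = abs(ux) / norm
        axial = perp / cos_t if cos_t > 1e-9 else math.inf
        rows.append(
            {
                "k": k,
                "perpendicular_spacing_A": perp,
                "axial_spacing_A": axial,
                "tilt_deg": tilt,
            }
        )
    return pd.DataFrame(rows)
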