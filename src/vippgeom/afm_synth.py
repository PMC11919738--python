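"""Synthetic AFM height images of membrane-bound planar polymers.

Physically parameterised generator emulating the measured statistics of
Vipp1 sheets, spiral filaments and rings on supported lipid bilayers:
5.5 nm plateau height above the membrane, 54 Å surface ridges with
122 Å seams, 13.4 ± 0.9 nm filament width, 82.7 ± 37.8 nm spiral
diameters, ~1 nm central-ring protrusion, 35.5 ± 2.9 nm (9.6 ± 2.2 nm
high) pre-assembled rings, and 24 ± 19.6 nm/s filament growth.

Every generator returns ``(AFMImage, truth)`` where ``truth`` is a
pandas DataFrame with exactly one record per rendered object, so
measurement operators can be validated by recovery against ground
truth.  Generators are deterministic per (seed, parameters); each
object class draws from its own named substream, so adding objects of
one class does not perturb another.

Distribution floors ("diameter >= 30 nm", "velocity >= 0") are applied
by *clipping* draws to the floor rather than resampling; resampling
would inflate the configured means (by ~7% for diameters and ~17% for
velocities), breaking the stated mean statistics the generator is
supposed to reproduce.  Tip convolution and scanner drift are not
simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import presets
from .errors import InvalidArgumentError, PlacementError

DEFAULT_NOISE_SD_NM = 0.1
DEFAULT_RIDGE_AMPLITUDE_NM = 0.3
DEFAULT_SEAM_AMPLITUDE_NM = 0.15
DEFAULT_TURN_GAP_NM = 10.0
DEFAULT_PIXEL_NM = 1.0
MAX_PLACEMENT_ATTEMPTS = 10_000

_SUBSTREAMS = {"sheet": 0, "spiral": 1, "ring": 2, "filament": 3, "noise": 4, "placement": 5}


@dataclass
class AFMImage:
    """Physical-unit height raster: heights in nm above the membrane."""

    heights: np.ndarray
    pixel_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixel_nm > 0:
            raise InvalidArgumentError(f"pixel_nm must be > 0, got {self.pixel_nm!r}")
        if not np.all(np.isfinite(self.heights)):
            raise InvalidArgumentError("heights must be finite everywhere")

    @property
    def field_nm(self) -> tuple[float, float]:
        return (self.heights.shape[0] * self.pixel_nm, self.heights.shape[1] * self.pixel_nm)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_SUBSTREAMS[stream], int(seed)])


def clipped_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, floor: float | None = None
) -> np.ndarray:
    """Normal draws clipped (not resampled) to an optional floor."""
    x = rng.normal(mean, sd, size)
    if floor is not None:
        np.clip(x, floor, None, out=x)
    return x


def _add_noise(heights: np.ndarray, noise_sd_nm: float, seed: int) -> None:
    if noise_sd_nm > 0:
        heights += _rng(seed, "noise").normal(0.0, noise_sd_nm, heights.shape)


def _stamp_polyline(
    heights: np.ndarray,
    pixel_nm: float,
    samples_nm: np.ndarray,
    half_width_nm: float,
    level_nm: float,
) -> None:
    """Raise all pixels within half_width of a sampled centerline to level."""
    lo = samples_nm.min(axis=0) - half_width_nm - 2 * pixel_nm
    hi = samples_nm.max(axis=0) + half_width_nm + 2 * pixel_nm
    ny, nx = heights.shape
    x0 = max(0, int(lo[0] / pixel_nm))
    y0 = max(0, int(lo[1] / pixel_nm))
    x1 = min(nx, int(math.ceil(hi[0] / pixel_nm)) + 1)
    y1 = min(ny, int(math.ceil(hi[1] / pixel_nm)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx = (np.arange(x0, x1) + 0.5) * pixel_nm
    gy = (np.arange(y0, y1) + 0.5) * pixel_nm
    pix = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    dist, _ = cKDTree(samples_nm).query(pix, workers=1)
    mask = (dist <= half_width_nm).reshape(y1 - y0, x1 - x0)
    region = heights[y0:y1, x0:x1]
    region[mask] = np.maximum(region[mask], level_nm)


def _stamp_annulus(
    heights: np.ndarray,
    pixel_nm: float,
    center_nm: tuple[float, float],
    r_centerline_nm: float,
    half_width_nm: float,
    level_nm: float,
) -> None:
    """Raise an annulus |r - r_c| <= half_width around a centre to level."""
    cx, cy = center_nm
    r_hi = r_centerline_nm + half_width_nm
    ny, nx = heights.shape
    x0 = max(0, int((cx - r_hi) / pixel_nm) - 1)
    y0 = max(0, int((cy - r_hi) / pixel_nm) - 1)
    x1 = min(nx, int(math.ceil((cx + r_hi) / pixel_nm)) + 2)
    y1 = min(ny, int(math.ceil((cy + r_hi) / pixel_nm)) + 2)
    gx = (np.arange(x0, x1) + 0.5) * pixel_nm - cx
    gy = (np.arange(y0, y1) + 0.5) * pixel_nm - cy
    rr = np.hypot(gx[None, :], gy[:, None])
    mask = np.abs(rr - r_centerline_nm) <= half_width_nm
    region = heights[y0:y1, x0:x1]
    region[mask] = np.maximum(region[mask], level_nm)


def _place_circles(
    radii_nm: np.ndarray, field_nm: float, clearance_nm: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample non-overlapping circle centres in a square field."""
    centers: list[np.ndarray] = []
    for i, r in enumerate(radii_nm):
        lo, hi = r + clearance_nm, field_nm - r - clearance_nm
        if hi <= lo:
            raise PlacementError(f"object {i} (radius {r:.1f} nm) larger than field")
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            c = rng.uniform(lo, hi, 2)
            if all(
                np.hypot(*(c - cj)) >= r + rj + clearance_nm
                for cj, rj in zip(centers, radii_nm[: len(centers)])
            ):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place object {i} in {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return np.array(centers)


def _auto_field(radii_nm: np.ndarray, clearance_nm: float, fill: float = 0.22) -> float:
    area = float(np.sum(math.pi * (radii_nm + clearance_nm) ** 2))
    side = math.sqrt(area / fill)
    return max(side, 2.0 * float(radii_nm.max() + clearance_nm) * 2.2)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def synth_sheet(
    field_nm: float = 1000.0,
    pixel_nm: float = 0.7,
    ridge_period_A: float = presets.RIDGE_PERIOD_A,
    height_nm: float = presets.MEMBRANE_OFFSET_NM,
    seam_period_A: float = presets.SEAM_PERIOD_A,
    ridge_amplitude_nm: float = DEFAULT_RIDGE_AMPLITUDE_NM,
    seam_amplitude_nm: float = DEFAULT_SEAM_AMPLITUDE_NM,
    noise_sd_nm: float = DEFAULT_NOISE_SD_NM,
    seed: int = 0,
    sheet_fraction: float = 0.8,
) -> tuple[AFMImage, pd.DataFrame]:
    """Planar crystalline sheet: plateau with sinusoidal ridges and seams.

    Membrane background at 0 nm; a centred square sheet plateau at
    ``height_nm`` carries a ridge modulation of the stated period along
    x and a fainter orthogonal seam modulation along y.
    """
    if pixel_nm > ridge_period_A / 10.0 / 2.0:
        raise InvalidArgumentError(
            f"pixel {pixel_nm} nm violates Nyquist for a {ridge_period_A} Å ridge period"
        )
    n = int(round(field_nm / pixel_nm))
    heights = np.zeros((n, n), dtype=np.float64)
    half = sheet_fraction / 2.0
    i0, i1 = int(n * (0.5 - half)), int(n * (0.5 + half))
    x = (np.arange(i0, i1) + 0.5) * pixel_nm
    y = (np.arange(i0, i1) + 0.5) * pixel_nm
    ridge = ridge_amplitude_nm * np.sin(2.0 * math.pi * x / (ridge_period_A / 10.0))
    seam = seam_amplitude_nm * np.sin(2.0 * math.pi * y / (seam_period_A / 10.0))
    heights[i0:i1, i0:i1] = height_nm + ridge[None, :] + seam[:, None]
    _add_noise(heights, noise_sd_nm, seed)
    img = AFMImage(
        heights=heights.astype(np.float32),
        pixel_nm=pixel_nm,
        metadata={"seed": seed, "preset": "sheet", "noise_sd_nm": noise_sd_nm},
    )
    truth = pd.DataFrame(
        [
            {
                "kind": "sheet",
                "center_x_nm": field_nm / 2.0,
                "center_y_nm": field_nm / 2.0,
                "diameter_nm": sheet_fraction * field_nm,
                "width_nm": sheet_fraction * field_nm,
                "height_nm": height_nm,
                "ridge_period_A": ridge_period_A,
                "seam_period_A": seam_period_A,
            }
        ]
    )
    return img, truth


def _spiral_centerline(
    r_out_c: float,
    r_in_min: float,
    width_nm: float,
    gap_nm: float,
    min_gap_nm: float = 4.0,
    min_winding: float = 0.92,
) -> tuple[float, float, float]:
    """(theta_max_rad, pitch_nm, r_out_render_nm) for an inward-curling spiral.

    A decaying Archimedean centerline touches its nominal outer radius
    at a single angle, so its maximal chord is ``2*r_out - pitch/2``;
    rendering from ``r_out + pitch/4`` makes the object's enclosing
    diameter match the drawn diameter.  Large spirals use the default
    pitch (filament width + membrane gap); spirals too small to
    complete ``min_winding`` turns at that pitch shrink the pitch
    instead, rendering as maximally curled open curls (their cores fill
    in, as in the AFM fields, where tightly curled objects show no
    resolvable lumen).  A shrunk pitch that would leave an unresolvable
    (< ``min_gap_nm``) membrane channel between turns snaps to slight
    overlap: a filament curled past self-contact merges with itself.
    """
    pitch_default = width_nm + gap_nm
    span = max(r_out_c - r_in_min, 0.0)
    w0 = span / pitch_default if pitch_default > 0 else 0.0
    merged = False
    if w0 < min_winding:
        pitch = span / min_winding if span > 0 else 0.0
        if pitch < width_nm + min_gap_nm:
            pitch = 0.9 * width_nm  # merged turns: solid maximal curl
            merged = True
    else:
        pitch = pitch_default
    r_out_render = r_out_c + pitch / 4.0
    if merged:
        # overlapping arms: curl to the very centre so the core fills in
        # completely (every point lies within half a pitch of an arm)
        r_end = 0.0
    else:
        r_end = r_in_min
    winding = (r_out_render - r_end) / pitch if pitch > 0 else min_winding
    winding = max(winding, min_winding)
    return winding * 2.0 * math.pi, pitch, r_out_render


def synth_spiral_field(
    n_spirals: int,
    field_nm: float | None = None,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    diameter_mean_nm: float = presets.SPIRAL_DIAMETER_NM[0],
    diameter_sd_nm: float = presets.SPIRAL_DIAMETER_NM[1],
    diameter_floor_nm: float = presets.SPIRAL_DIAMETER_FLOOR_NM,
    width_mean_nm: float = presets.FILAMENT_WIDTH_NM[0],
    width_sd_nm: float = presets.FILAMENT_WIDTH_NM[1],
    height_nm: float = presets.MEMBRANE_OFFSET_NM,
    turn_gap_nm: float = DEFAULT_TURN_GAP_NM,
    ring_fraction: float = 0.2,
    ring_protrusion_nm: float = presets.RING_PROTRUSION_NM[0],
    ring_diameter_nm: float = presets.RING_LS_DIAMETER_NM[0],
    noise_sd_nm: float = DEFAULT_NOISE_SD_NM,
    seed: int = 0,
) -> tuple[AFMImage, pd.DataFrame]:
    """Field of Archimedean spiral filaments, optionally with central rings.

    Spirals curl anticlockwise with a turn pitch of filament width plus
    a membrane gap; diameters and widths are drawn from the configured
    (clipped) normal laws.  Central rings sit detached inside a fraction
    of the sufficiently large spirals and protrude above the spiral
    plateau.  Rejection sampling guarantees non-overlapping objects.
    """
    if n_spirals < 1:
        raise InvalidArgumentError("n_spirals must be >= 1")
    rng = _rng(seed, "spiral")
    diameters = clipped_normal(rng, diameter_mean_nm, diameter_sd_nm, n_spirals,
                               floor=diameter_floor_nm)
    widths = clipped_normal(rng, width_mean_nm, width_sd_nm, n_spirals, floor=1.0)
    ring_draw = rng.random(n_spirals)

    # placement circles allow for the pitch/4 rendering overshoot
    radii = diameters / 2.0 + (widths + turn_gap_nm) / 4.0 + 1.0
    clearance = 12.0
    if field_nm is None:
        field_nm = _auto_field(radii, clearance)
    centers = _place_circles(radii, field_nm, clearance, _rng(seed, "placement"))

    n = int(round(field_nm / pixel_nm))
    heights = np.zeros((n, n), dtype=np.float64)
    records = []
    for i in range(n_spirals):
        d, w = float(diameters[i]), float(widths[i])
        cx, cy = (float(c) for c in centers[i])
        r_out_c = d / 2.0 - w / 2.0
        ring_min_d = ring_diameter_nm + 2.0 * (turn_gap_nm / 2.0 + w) + 30.0
        has_ring = bool(ring_draw[i] < ring_fraction and d >= ring_min_d)
        if has_ring:
            r_in_min = ring_diameter_nm / 2.0 + turn_gap_nm / 2.0 + w / 2.0
        else:
            # curl all the way to a filled core: a membrane island smaller
            # than the filament width is not resolvable as a lumen anyway
            r_in_min = w / 2.0
        theta_max, pitch, r_out_render = _spiral_centerline(r_out_c, r_in_min, w, turn_gap_nm)
        theta0 = rng.uniform(0.0, 2.0 * math.pi)
        arc = theta_max * max(r_out_render, 1.0)
        m = max(64, int(arc / (0.3 * pixel_nm)))
        t = np.linspace(0.0, theta_max, m)
        r_c = r_out_render - (pitch / (2.0 * math.pi)) * t
        # never curl into the central ring's clearance zone (or below 0)
        r_c = np.maximum(r_c, r_in_min if has_ring else 0.0)
        if not has_ring:
            r_c = np.maximum(r_c, 0.0)
        samples = np.column_stack(
            [cx + r_c * np.cos(theta0 + t), cy + r_c * np.sin(theta0 + t)]
        )
        _stamp_polyline(heights, pixel_nm, samples, w / 2.0, height_nm)
        if has_ring:
            ring_w = w
            r_ring_c = ring_diameter_nm / 2.0 - ring_w / 2.0
            _stamp_annulus(
                heights, pixel_nm, (cx, cy), r_ring_c, ring_w / 2.0,
                height_nm + ring_protrusion_nm,
            )
        records.append(
            {
                "kind": "spiral",
                "center_x_nm": cx,
                "center_y_nm": cy,
                "diameter_nm": d,
                "width_nm": w,
                "height_nm": height_nm,
                "spiral_model": "archimedean",
                "spiral_a_nm": float(r_c[-1]),
                "spiral_b_nm_per_rad": pitch / (2.0 * math.pi),
                "winding_turns": theta_max / (2.0 * math.pi),
                "has_ring": has_ring,
                "ring_diameter_nm": ring_diameter_nm if has_ring else np.nan,
                "ring_protrusion_nm": ring_protrusion_nm if has_ring else np.nan,
            }
        )
    _add_noise(heights, noise_sd_nm, seed)
    img = AFMImage(
        heights=heights.astype(np.float32),
        pixel_nm=pixel_nm,
        metadata={"seed": seed, "preset": "spiral-field", "noise_sd_nm": noise_sd_nm},
    )
    return img, pd.DataFrame(records)


def synth_ring_field(
    n_rings: int,
    field_nm: float | None = None,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    diameter_mean_nm: float = presets.RING_HS_DIAMETER_NM[0],
    diameter_sd_nm: float = presets.RING_HS_DIAMETER_NM[1],
    height_mean_nm: float = presets.RING_HS_HEIGHT_NM[0],
    height_sd_nm: float = presets.RING_HS_HEIGHT_NM[1],
    ring_width_nm: float = presets.FILAMENT_WIDTH_NM[0],
    noise_sd_nm: float = DEFAULT_NOISE_SD_NM,
    seed: int = 0,
) -> tuple[AFMImage, pd.DataFrame]:
    """Field of annular rings (pre-assembled high-salt rings by default)."""
    if n_rings < 1:
        raise InvalidArgumentError("n_rings must be >= 1")
    rng = _rng(seed, "ring")
    diameters = clipped_normal(rng, diameter_mean_nm, diameter_sd_nm, n_rings,
                               floor=2.0 * ring_width_nm + 6.0)
    ring_heights = clipped_normal(rng, height_mean_nm, height_sd_nm, n_rings, floor=3.0)

    radii = diameters / 2.0
    clearance = 12.0
    if field_nm is None:
        field_nm = _auto_field(radii, clearance)
    centers = _place_circles(radii, field_nm, clearance, _rng(seed, "placement"))

    n = int(round(field_nm / pixel_nm))
    heights = np.zeros((n, n), dtype=np.float64)
    records = []
    for i in range(n_rings):
        d, h = float(diameters[i]), float(ring_heights[i])
        cx, cy = (float(c) for c in centers[i])
        _stamp_annulus(
            heights, pixel_nm, (cx, cy), d / 2.0 - ring_width_nm / 2.0,
            ring_width_nm / 2.0, h,
        )
        records.append(
            {
                "kind": "ring",
                "center_x_nm": cx,
                "center_y_nm": cy,
                "diameter_nm": d,
                "width_nm": ring_width_nm,
                "height_nm": h,
            }
        )
    _add_noise(heights, noise_sd_nm, seed)
    img = AFMImage(
        heights=heights.astype(np.float32),
        pixel_nm=pixel_nm,
        metadata={"seed": seed, "preset": "ring-field", "noise_sd_nm": noise_sd_nm},
    )
    return img, pd.DataFrame(records)


def synth_filament_field(
    n_filaments: int = 13,
    field_nm: float | None = None,
    pixel_nm: float = 0.7,
    width_mean_nm: float = presets.FILAMENT_WIDTH_NM[0],
    width_sd_nm: float = presets.FILAMENT_WIDTH_NM[1],
    length_range_nm: tuple[float, float] = (150.0, 400.0),
    height_nm: float = presets.MEMBRANE_OFFSET_NM,
    noise_sd_nm: float = DEFAULT_NOISE_SD_NM,
    seed: int = 0,
) -> tuple[AFMImage, pd.DataFrame]:
    """Field of straight filaments with the measured width distribution."""
    if n_filaments < 1:
        raise InvalidArgumentError("n_filaments must be >= 1")
    rng = _rng(seed, "filament")
    widths = clipped_normal(rng, width_mean_nm, width_sd_nm, n_filaments, floor=1.0)
    lengths = rng.uniform(*length_range_nm, n_filaments)
    angles = rng.uniform(0.0, math.pi, n_filaments)

    radii = lengths / 2.0 + widths
    clearance = 15.0
    if field_nm is None:
        field_nm = _auto_field(radii, clearance)
    centers = _place_circles(radii, field_nm, clearance, _rng(seed, "placement"))

    n = int(round(field_nm / pixel_nm))
    heights = np.zeros((n, n), dtype=np.float64)
    records = []
    for i in range(n_filaments):
        w, L, a = float(widths[i]), float(lengths[i]), float(angles[i])
        cx, cy = (float(c) for c in centers[i])
        u = np.array([math.cos(a), math.sin(a)])
        t = np.linspace(-L / 2.0, L / 2.0, max(32, int(L / (0.3 * pixel_nm))))
        samples = np.array([cx, cy]) + t[:, None] * u[None, :]
        _stamp_polyline(heights, pixel_nm, samples, w / 2.0, height_nm)
        records.append(
            {
                "kind": "filament",
                "center_x_nm": cx,
                "center_y_nm": cy,
                "length_nm": L,
                "width_nm": w,
                "height_nm": height_nm,
                "angle_rad": a,
            }
        )
    _add_noise(heights, noise_sd_nm, seed)
    img = AFMImage(
        heights=heights.astype(np.float32),
        pixel_nm=pixel_nm,
        metadata={"seed": seed, "preset": "filament-field", "noise_sd_nm": noise_sd_nm},
    )
    return img, pd.DataFrame(records)


def synth_growth_series(
    n_frames: int = 10,
    dt_s: float = 0.5,
    n_filaments: int = 11,
    velocity_mean_nm_s: float = presets.GROWTH_RATE_NM_S[0],
    velocity_sd_nm_s: float = presets.GROWTH_RATE_NM_S[1],
    initial_length_range_nm: tuple[float, float] = (40.0, 80.0),
    width_nm: float = presets.FILAMENT_WIDTH_NM[0],
    height_nm: float = presets.MEMBRANE_OFFSET_NM,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    noise_sd_nm: float = DEFAULT_NOISE_SD_NM,
    seed: int = 0,
) -> tuple[list[AFMImage], pd.DataFrame]:
    """Time series of filaments elongating at per-filament constant velocity.

    Each filament keeps a fixed base point and direction and grows from
    its tip; velocities are drawn once per filament from the configured
    law clipped at zero (stalled filaments are allowed).
    """
    if n_frames < 3:
        raise InvalidArgumentError("n_frames must be >= 3")
    rng = _rng(seed, "filament")
    velocities = clipped_normal(rng, velocity_mean_nm_s, velocity_sd_nm_s,
                                n_filaments, floor=0.0)
    lengths0 = rng.uniform(*initial_length_range_nm, n_filaments)
    angles = rng.uniform(0.0, 2.0 * math.pi, n_filaments)

    t_total = (n_frames - 1) * dt_s
    final_lengths = lengths0 + velocities * t_total
    radii = final_lengths + width_nm
    clearance = 20.0
    field_nm = _auto_field(radii, clearance, fill=0.15)
    bases = _place_circles(radii, field_nm, clearance, _rng(seed, "placement"))

    n = int(round(field_nm / pixel_nm))
    frames: list[AFMImage] = []
    for f in range(n_frames):
        heights = np.zeros((n, n), dtype=np.float64)
        for i in range(n_filaments):
            L = float(lengths0[i] + velocities[i] * f * dt_s)
            u = np.array([math.cos(angles[i]), math.sin(angles[i])])
            t = np.linspace(0.0, L, max(32, int(L / (0.3 * pixel_nm))))
            samples = bases[i] + t[:, None] * u[None, :]
            _stamp_polyline(heights, pixel_nm, samples, width_nm / 2.0, height_nm)
        _add_noise(heights, noise_sd_nm, (seed * 1009 + f) % 2**31)
        frames.append(
            AFMImage(
                heights=heights.astype(np.float32),
                pixel_nm=pixel_nm,
                metadata={
                    "seed": seed,
                    "preset": "growth",
                    "frame": f,
                    "dt_s": dt_s,
                    "noise_sd_nm": noise_sd_nm,
                },
            )
        )
    truth = pd.DataFrame(
        {
            "kind": "filament",
            "filament_id": np.arange(n_filaments),
            "base_x_nm": bases[:, 0],
            "base_y_nm": bases[:, 1],
            "angle_rad": angles,
            "length0_nm": lengths0,
            "velocity_nm_s": velocities,
            "width_nm": width_nm,
            "height_nm": height_nm,
        }
    )
    return frames, truth
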