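"""Reciprocal-space view of helical lattices.

The Fourier transform of a helical object is confined to layer lines.
With a single symmetry operator (rise, twist) the layer line carrying
Bessel order n and axial index m sits at reciprocal height

    Z = (n * twist/360 + m) / rise          [1/Å]

This is the selection rule used to index a filament transform: each
observed layer-line height plus an assigned Bessel order constrains
(rise, twist), and a pair of indexed reflections determines them
exactly for each choice of the integer pair (m_i, m_j).  Scanning a
small grid of m values therefore yields the grid of candidate
symmetries that is tested by helical refinement.

Only layer-line *positions* are modelled; amplitude modulation by the
Bessel functions depends on the subunit shape and is out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core_lattice import HelicalSymmetry, reduce_angle
from .errors import InvalidArgumentError, ResourceLimitError

#: Default reciprocal-height cap: Nyquist for a 1.1 Å pixel.
DEFAULT_Z_CAP_INVA = 1.0 / (2.0 * 1.1)

DEFAULT_M_SEARCH = (-6, 6)
DEFAULT_RISE_BOUNDS_A = (1.0, 10.0)
DEFAULT_TWIST_BOUNDS_DEG = (-180.0, 180.0)

MAX_SUBUNITS = 10**6


@dataclass(frozen=True)
class LayerLine:
    """A single helical layer line (n, m) at reciprocal height Z."""

    n: int
    m: int
    Z_invA: float


@dataclass(frozen=True)
class SymmetryCandidate:
    """One (rise, twist) solution of the selection rule for a reflection set."""

    rise_A: float
    twist_deg: float
    m_assignment: tuple[int, ...]
    residual: float


def layer_line_height(sym: HelicalSymmetry, n: int, m: int) -> float:
    """Reciprocal height Z = (n*twist/360 + m)/rise of layer line (n, m)."""
    return (n * sym.twist_deg / 360.0 + m) / sym.rise_A


def layer_lines(
    sym: HelicalSymmetry,
    n_range: tuple[int, int],
    m_range: tuple[int, int],
    z_cap_invA: float = DEFAULT_Z_CAP_INVA,
) -> list[LayerLine]:
    """All layer lines with n, m in the given inclusive ranges and Z in [0, cap].

    Sorted by Z.  The (n=0, m=1) line sits at 1/rise, the repeat of the
    1-start helix.
    """
    n_lo, n_hi = n_range
    m_lo, m_hi = m_range
    if n_lo > n_hi or m_lo > m_hi:
        raise InvalidArgumentError("n_range and m_range must be non-empty")
    lines = []
    for n in range(n_lo, n_hi + 1):
        for m in range(m_lo, m_hi + 1):
            z = layer_line_height(sym, n, m)
            if 0.0 <= z <= z_cap_invA:
                lines.append(LayerLine(n=n, m=m, Z_invA=z))
    lines.sort(key=lambda l: (l.Z_invA, l.n, l.m))
    return lines


def _residual(
    rise: float, twist: float, reflections, m_lo: int, m_hi: int
) -> tuple[float, tuple[int, ...]]:
    """RMS misfit of predicted vs observed Z, assigning each reflection its best m."""
    sq = 0.0
    ms = []
    for z_obs, n in reflections:
        # best integer m for this reflection under the candidate symmetry
        m_star = round(z_obs * rise - n * twist / 360.0)
        m_star = min(max(m_star, m_lo), m_hi)
        z_pred = (n * twist / 360.0 + m_star) / rise
        sq += (z_obs - z_pred) ** 2
        ms.append(int(m_star))
    return math.sqrt(sq / len(reflections)), tuple(ms)


def symmetry_candidates(
    reflections: list[tuple[float, int]],
    m_search: tuple[int, int] = DEFAULT_M_SEARCH,
    rise_bounds_A: tuple[float, float] = DEFAULT_RISE_BOUNDS_A,
    twist_bounds_deg: tuple[float, float] = DEFAULT_TWIST_BOUNDS_DEG,
    dedupe_tol: tuple[float, float] = (0.005, 0.01),
) -> list[SymmetryCandidate]:
    """Exhaustive grid of (rise, twist) candidates explaining indexed reflections.

    Parameters
    ----------
    reflections
        Sequence of ``(Z_invA, n)`` pairs: observed layer-line heights with
        assigned Bessel orders.  At least two reflections with distinct n
        are required.
    m_search
        Inclusive range of axial indices m scanned for every reflection.
    rise_bounds_A, twist_bounds_deg
        Physical bounds on the solutions; out-of-bounds solutions are
        dropped (an empty list is a valid result).
    dedupe_tol
        (Å, degrees) tolerance within which two solutions are considered
        the same candidate.

    Returns
    -------
    list of SymmetryCandidate, ranked by residual (best first).
    """
    refl = [(float(z), int(n)) for z, n in reflections]
    if len(refl) < 2 or len({n for _, n in refl}) < 2:
        raise InvalidArgumentError("need >= 2 reflections with distinct Bessel orders")
    m_lo, m_hi = m_search
    rise_lo, rise_hi = rise_bounds_A
    twist_lo, twist_hi = twist_bounds_deg

    raw: list[tuple[float, float]] = []
    for (zi, ni), (zj, nj) in itertools.combinations(refl, 2):
        if ni == nj:
            continue
        for mi in range(m_lo, m_hi + 1):
            for mj in range(m_lo, m_hi + 1):
                # zi*rise - ni*(twist/360) = mi ; zj*rise - nj*(twist/360) = mj
                det = -zi * nj + zj * ni
                if abs(det) < 1e-15:
                    continue
                rise = (-mi * nj + mj * ni) / det
                t360 = (zi * mj - zj * mi) / det
                twist = reduce_angle(t360 * 360.0) if math.isfinite(t360) else math.nan
                if not (math.isfinite(rise) and math.isfinite(twist)):
                    continue
                if not (rise_lo <= rise <= rise_hi):
                    continue
                if not (twist_lo < twist <= twist_hi) or twist == 0.0:
                    continue
                raw.append((rise, twist))

    # deduplicate within tolerance, keeping insertion order
    uniq: list[tuple[float, float]] = []
    for rise, twist in raw:
        if not any(
            abs(rise - r0) <= dedupe_tol[0] and abs(twist - t0) <= dedupe_tol[1]
            for r0, t0 in uniq
        ):
            uniq.append((rise, twist))

    cands = []
    for rise, twist in uniq:
        res, ms = _residual(rise, twist, refl, m_lo, m_hi)
        cands.append(SymmetryCandidate(rise_A=rise, twist_deg=twist, m_assignment=ms, residual=res))
    cands.sort(key=lambda c: (c.residual, c.rise_A, c.twist_deg))
    return cands


def simulate_power_spectrum(
    sym: HelicalSymmetry,
    radius_A: float,
    image_size_px: int = 512,
    pixel_A: float = 1.1,
    seed: int = 0,
    subunit_sigma_A: float = 4.0,
) -> np.ndarray:
    """Amplitude spectrum of a projected helix of Gaussian pseudo-subunits.

    Subunits are placed on the 1-start helix at the given radius over the
    full axial extent of the field, projected along the viewing direction
    onto the (x, z) plane, rendered as isotropic Gaussians, Hann-windowed
    and Fourier transformed.  The returned raster is the origin-centred
    amplitude |FFT|; its peak maxima lie on the predicted layer-line
    heights.  Deterministic for a fixed seed (the seed only randomises
    the azimuthal phase of the helix).
    """
    if pixel_A <= 0:
        raise InvalidArgumentError(f"pixel_A must be > 0, got {pixel_A!r}")
    if image_size_px < 64:
        raise InvalidArgumentError(f"image_size_px must be >= 64, got {image_size_px!r}")
    if radius_A < 0:
        raise InvalidArgumentError(f"radius_A must be >= 0, got {radius_A!r}")
    field_A = image_size_px * pixel_A
    n_sub = int(field_A / sym.rise_A) + 1
    if n_sub > MAX_SUBUNITS:
        raise ResourceLimitError(f"{n_sub} subunits exceed the {MAX_SUBUNITS} limit")
    if field_A < 3 * abs(360.0 / sym.twist_deg) * sym.rise_A:
        # fewer than three 1-start turns in the field: still renderable,
        # but layer lines will be poorly sampled.  Not an error.
        pass

    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * math.pi)

    j = np.arange(n_sub)
    phi = phi0 + np.deg2rad(sym.twist_deg) * j
    x_A = radius_A * np.cos(phi) + 0.5 * field_A
    z_A = j * sym.rise_A

    img = np.zeros((image_size_px, image_size_px), dtype=np.float64)
    half = max(3, int(math.ceil(4 * subunit_sigma_A / pixel_A)))
    xs = x_A / pixel_A
    zs = z_A / pixel_A
    s2 = 2.0 * (subunit_sigma_A / pixel_A) ** 2
    for xp, zp in zip(xs, zs):
        ix, iz = int(round(xp)), int(round(zp))
        x0, x1 = max(0, ix - half), min(image_size_px, ix + half + 1)
        z0, z1 = max(0, iz - half), min(image_size_px, iz + half + 1)
        if x0 >= x1 or z0 >= z1:
            continue
        gx = np.arange(x0, x1) - xp
        gz = np.arange(z0, z1) - zp
        img[z0:z1, x0:x1] += np.exp(-(gz[:, None] ** 2 + gx[None, :] ** 2) / s2)

    win = np.hanning(image_size_px)
    img = (img - img.mean()) * win[:, None] * win[None, :]
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    return spec


def spectrum_layer_line_heights(
    spectrum: np.ndarray, pixel_A: float, n_peaks: int = 2, exclude_px: int = 3
) -> list[float]:
    """Reciprocal heights |Z| (1/Å) of the strongest off-equator rows.

    Utility for cross-checking a simulated spectrum against
    :func:`layer_lines`: collapses the spectrum over the equatorial axis,
    masks rows within ``exclude_px`` of the equator and returns the
    heights of the ``n_peaks`` strongest local row maxima.
    """
    n = spectrum.shape[0]
    c = n // 2
    row_power = spectrum.sum(axis=1)
    freqs = (np.arange(n) - c) / (n * pixel_A)
    row_power[max(0, c - exclude_px): c + exclude_px + 1] = 0.0
    # local maxima only
    peaks = []
    for i in range(1, n - 1):
        if row_power[i] > row_power[i - 1] and row_power[i] >= row_power[i + 1]:
            peaks.append((row_power[i], abs(freqs[i])))
    peaks.sort(reverse=True)
    out: list[float] = []
    for _, z in peaks:
        if all(abs(z - z0) > 1.5 / (n * pixel_A) for z0 in out):
            out.append(z)
        if len(out) == n_peaks:
            break
    return out
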