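"""Pure geometry of helical lattices.

A helical polymer is generated by one symmetry operator: an axial rise
(Å per subunit) and an azimuthal twist (degrees per subunit).  Connecting
every k-th subunit yields the *k-start family*: k parallel helical
strands whose handedness follows the sign of the reduced azimuthal step
``k*twist mod 360`` in (−180, 180].  On the surface of a cylinder of
radius r the lattice can be treated as planar, with the k-connection
represented by the vector ``(r * step_in_radians, k * rise)``; the two
shortest such vectors are the nearest-neighbour directions of the
lattice and correspond to the dominant Bessel orders of the filament's
diffraction pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

#: Comparison tolerance for length/step ties (Å resp. degrees).
TIE_TOL = 1e-9

#: Default maximum start number searched.  The number of visible starts is
#: bounded by circumference / minimum subunit spacing; for the widest
#: filament considered here (outer radius 122 Å, spacing ~30 Å) that is
#: 2*pi*122/30 ~ 25.
DEFAULT_K_MAX = 25


def reduce_angle(angle_deg: float) -> float:
    """Reduce an angle in degrees to the interval (−180, 180].

    Parameters
    ----------
    angle_deg
        Any finite angle in degrees.

    Returns
    -------
    float
        The congruent angle modulo 360 lying in (−180, 180].
    """
    if not math.isfinite(angle_deg):
        raise InvalidArgumentError(f"angle must be finite, got {angle_deg!r}")
    r = math.fmod(angle_deg, 360.0)
    if r <= -180.0:
        r += 360.0
    elif r > 180.0:
        r -= 360.0
    # fmod(-x, 360) can return -0.0; normalise for cosmetic determinism
    return r + 0.0


@dataclass(frozen=True)
class HelicalSymmetry:
    """Refined helical symmetry of one filament lattice.

    Attributes
    ----------
    rise_A : float
        Axial rise per subunit, Å (> 0).
    twist_deg : float
        Azimuthal rotation per subunit, degrees; stored reduced to
        (−180, 180] and must be non-zero.
    r_lumen_A, r_outer_A : float, optional
        Inner (lumen) and outer wall radii, Å.
    label : str
        Free-text name of the lattice.
    """

    rise_A: float
    twist_deg: float
    r_lumen_A: float | None = None
    r_outer_A: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rise_A) and self.rise_A > 0):
            raise InvalidArgumentError(f"rise_A must be positive, got {self.rise_A!r}")
        reduced = reduce_angle(self.twist_deg)
        if reduced == 0.0:
            raise InvalidArgumentError("twist_deg must be non-zero modulo 360")
        object.__setattr__(self, "twist_deg", reduced)
        if (self.r_lumen_A is None) != (self.r_outer_A is None):
            # a single radius is allowed to be missing individually
            pass
        if self.r_lumen_A is not None and self.r_outer_A is not None:
            if not (0 < self.r_lumen_A < self.r_outer_A):
                raise InvalidArgumentError(
                    f"radii must satisfy 0 < r_lumen < r_outer, got "
                    f"({self.r_lumen_A!r}, {self.r_outer_A!r})"
                )

    @property
    def mid_wall_radius_A(self) -> float:
        """Mid-wall radius (r_lumen + r_outer)/2, the default evaluation radius."""
        if self.r_lumen_A is None or self.r_outer_A is None:
            raise InvalidArgumentError(f"{self.label or 'symmetry'} has no radii set")
        return 0.5 * (self.r_lumen_A + self.r_outer_A)


@dataclass(frozen=True)
class StartFamily:
    """One k-start helix family of a helical lattice."""

    k: int
    step_deg: float
    handedness: str  # "right", "left" or "axial"
    rise_per_step_A: float
    strand_pitch_A: float
    axial_spacing_A: float


@dataclass(frozen=True)
class LatticeVector:
    """The k-connection of the lattice unrolled at a given radius."""

    k: int
    dx_A: float
    dz_A: float
    length_A: float
    radius_A: float


def _check_k(k: int) -> int:
    if not isinstance(k, (int,)) or isinstance(k, bool) or k < 1:
        raise InvalidArgumentError(f"k must be a positive integer, got {k!r}")
    return k


def start_family(sym: HelicalSymmetry, k: int) -> StartFamily:
    """Describe the k-start helix family of a symmetry.

    The azimuthal step per connection is ``reduce_angle(k * twist)``.  A
    positive step is a right-handed family, a negative step left-handed.
    If the step is exactly zero the family is axial (k straight lines
    parallel to the axis) and the inter-strand axial spacing is reported
    as +infinity.
    """
    _check_k(k)
    step = reduce_angle(k * sym.twist_deg)
    rise_per_step = k * sym.rise_A
    if step == 0.0:
        return StartFamily(
            k=k,
            step_deg=0.0,
            handedness="axial",
            rise_per_step_A=rise_per_step,
            strand_pitch_A=math.inf,
            axial_spacing_A=math.inf,
        )
    axial_spacing = 360.0 * sym.rise_A / abs(step)
    return StartFamily(
        k=k,
        step_deg=step,
        handedness="right" if step > 0 else "left",
        rise_per_step_A=rise_per_step,
        strand_pitch_A=k * axial_spacing,
        axial_spacing_A=axial_spacing,
    )


def near_axial_family(sym: HelicalSymmetry, k_max: int = DEFAULT_K_MAX) -> int:
    """Start number k in [1, k_max] whose strands run closest to the axis.

    Minimises ``|reduce_angle(k * twist)|``; ties are broken toward the
    smaller k.
    """
    _check_k(k_max)
    best_k, best_abs = 1, math.inf
    for k in range(1, k_max + 1):
        a = abs(reduce_angle(k * sym.twist_deg))
        if a < best_abs - TIE_TOL:
            best_k, best_abs = k, a
    return best_k


def lattice_vector(sym: HelicalSymmetry, k: int, radius_A: float) -> LatticeVector:
    """Unrolled displacement of the k-connection at a given radius."""
    _check_k(k)
    if not (math.isfinite(radius_A) and radius_A >= 0):
        raise InvalidArgumentError(f"radius_A must be >= 0, got {radius_A!r}")
    step = reduce_angle(k * sym.twist_deg)
    dx = radius_A * math.radians(step)
    dz = k * sym.rise_A
    return LatticeVector(k=k, dx_A=dx, dz_A=dz, length_A=math.hypot(dx, dz), radius_A=radius_A)


def principal_vectors(
    sym: HelicalSymmetry, radius_A: float, k_max: int = DEFAULT_K_MAX
) -> tuple[int, int]:
    """Start numbers of the two shortest lattice vectors at a radius.

    Returns ``(k_short, k_long)`` ordered by unrolled length; ties are
    broken toward the smaller k.  These are the nearest-neighbour
    directions of the surface lattice, i.e. the dominant start families
    (and, up to sign, the dominant Bessel orders).
    """
    if not (math.isfinite(radius_A) and radius_A > 0):
        raise InvalidArgumentError(f"radius_A must be > 0, got {radius_A!r}")
    if k_max < 2:
        raise InvalidArgumentError(f"k_max must be >= 2, got {k_max!r}")
    vecs = [lattice_vector(sym, k, radius_A) for k in range(1, k_max + 1)]
    vecs.sort(key=lambda v: (round(v.length_A / TIE_TOL) * TIE_TOL, v.k))
    return (vecs[0].k, vecs[1].k)


def subunit_spacing_at_radius(sym: HelicalSymmetry, k: int, radius_A: float) -> float:
    """Distance (Å) between k-connected subunits on the unrolled surface.

    Monotone non-decreasing in radius for fixed k; at radius zero it
    reduces to the axial component ``k * rise``.
    """
    return lattice_vector(sym, k, radius_A).length_A
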