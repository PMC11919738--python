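"""Geometric model of planar ESCRT-III-like polymers.

Membrane-bound Vipp1 filaments are built from a rigid substructure of
parallel ridges (side-by-side hairpins) with a relaxed inter-ridge
spacing s0 ~ 54 Å.  When a filament of width w bends in the membrane
plane with centerline radius R, ridge elements stay rigid and the
spacing rescales with the local radius:

    s_inner = s0 * (R - w/2) / R,      s_outer = s0 * (R + w/2) / R

Measured rung geometry bounds the spacing between ~41 Å (compression)
and ~61 Å (stretch), which caps the achievable planar curvature at a
minimum centerline diameter of about 103 nm for a 13.4 nm filament.
Rings and spiral centres are far tighter than that, so filaments there
must tilt out of the membrane plane (or break) — the planar form alone
cannot supply the curvature.

The module also fits planar spiral traces (Archimedean r = a + b*theta
or exponential r = a*exp(b*theta)) and provides C_N ring geometry
(N subunits per circular rung).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import presets
from .errors import InsufficientArcError, InvalidArgumentError, TraceError

MIN_TURNS = 1.5


@dataclass(frozen=True)
class CurvatureModel:
    """Inter-ridge spacing bounds of the rigid filament substructure (Å)."""

    s0_A: float = presets.RIDGE_SPACING_RELAXED_A
    s_min_A: float = presets.RIDGE_SPACING_MIN_A
    s_max_A: float = presets.RIDGE_SPACING_MAX_A
    width_A: float = presets.FILAMENT_WIDTH_A

    def __post_init__(self) -> None:
        if not (0 < self.s_min_A < self.s0_A < self.s_max_A):
            raise InvalidArgumentError(
                f"need 0 < s_min < s0 < s_max, got "
                f"({self.s_min_A}, {self.s0_A}, {self.s_max_A})"
            )
        if not self.width_A > 0:
            raise InvalidArgumentError(f"width_A must be > 0, got {self.width_A!r}")


@dataclass(frozen=True)
class RingModel:
    """C_N ring rung geometry."""

    N: int
    diameter_A: float
    subunit_arc_A: float
    rung_spacing_A: float = presets.PROTOFILAMENT_SPACING_A
    n_rungs: int = 5


@dataclass(frozen=True)
class SpiralFit:
    """Least-squares fit of a planar spiral trace in polar coordinates."""

    model: str  # "archimedean" or "exponential"
    a: float  # nm
    b: float  # nm/rad (archimedean) or 1/rad (exponential)
    center: tuple[float, float]  # nm
    rms_residual_nm: float
    aic: float
    n_points: int


# --------------------------------------------------------------------------
# spiral fitting
# --------------------------------------------------------------------------

_N_FIT_PARAMS = 4  # a, b, cx, cy


def _polar(trace: np.ndarray, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = trace - center
    r = np.hypot(d[:, 0], d[:, 1])
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return r, theta


def _inner_fit(r: np.ndarray, theta: np.ndarray, model: str) -> tuple[float, float, np.ndarray]:
    """Fit (a, b) for fixed polar coordinates; residuals are in r."""
    A = np.column_stack([np.ones_like(theta), theta])
    if model == "archimedean":
        coef, *_ = np.linalg.lstsq(A, r, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        resid = r - (a + b * theta)
    elif model == "exponential":
        if np.any(r <= 0):
            return math.nan, math.nan, np.full_like(r, np.inf)
        coef, *_ = np.linalg.lstsq(A, np.log(r), rcond=None)
        a, b = float(math.exp(coef[0])), float(coef[1])
        resid = r - a * np.exp(b * theta)
    else:  # pragma: no cover - guarded by caller
        raise InvalidArgumentError(f"unknown spiral model {model!r}")
    return a, b, resid


def _fit_one_model(trace: np.ndarray, model: str) -> SpiralFit:
    centroid = trace.mean(axis=0)

    def residuals(c):
        r, theta = _polar(trace, c)
        _, _, resid = _inner_fit(r, theta, model)
        return resid

    sol = least_squares(
        residuals, centroid, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    center = sol.x
    r, theta = _polar(trace, center)
    a, b, resid = _inner_fit(r, theta, model)
    n = len(trace)
    rss = float(resid @ resid)
    rms = math.sqrt(rss / n)
    # Gaussian-likelihood AIC; both models share k = 4 free parameters
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * _N_FIT_PARAMS
    return SpiralFit(
        model=model,
        a=a,
        b=b,
        center=(float(center[0]), float(center[1])),
        rms_residual_nm=rms,
        aic=aic,
        n_points=n,
    )


def fit_spiral(trace, model: str = "auto") -> SpiralFit:
    """Fit a planar spiral to an ordered (x, y) trace in nm.

    Parameters
    ----------
    trace
        (N, 2) array-like of points ordered along the filament,
        N >= 20, spanning at least 1.5 turns about its centre.
    model
        "archimedean" (r = a + b*theta), "exponential"
        (r = a*exp(b*theta)) or "auto" (lower AIC wins; with equal
        parameter counts this reduces to the lower residual sum).

    The centre is optimised jointly with (a, b) by nested least squares,
    starting from the trace centroid; theta is unwrapped along the trace
    order and must be monotone.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2 or len(trace) < 20:
        raise InvalidArgumentError("trace must be an (N>=20, 2) point array")
    if model not in ("auto", "archimedean", "exponential"):
        raise InvalidArgumentError(f"unknown spiral model {model!r}")

    _, theta0 = _polar(trace, trace.mean(axis=0))
    span = theta0[-1] - theta0[0]
    if abs(span) < MIN_TURNS * 2.0 * math.pi:
        raise InsufficientArcError(
            f"trace spans {abs(span) / (2 * math.pi):.2f} turns; need >= {MIN_TURNS}"
        )
    dtheta = np.diff(theta0)
    wrong_way = np.sum(np.sign(dtheta) == -np.sign(span))
    if wrong_way > 0.1 * len(dtheta):
        raise TraceError("trace angle is not monotone after unwrapping")

    if model == "auto":
        fits = [_fit_one_model(trace, m) for m in ("archimedean", "exponential")]
        return min(fits, key=lambda f: f.aic)
    return _fit_one_model(trace, model)


def simulate_spiral_trace(
    model: str,
    a: float,
    b: float,
    n_points: int = 80,
    turns: float = 2.5,
    noise_sd_nm: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample an (N, 2) spiral trace with optional isotropic Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(0)
    theta = np.linspace(0.0, turns * 2.0 * math.pi, n_points)
    if model == "archimedean":
        r = a + b * theta
    elif model == "exponential":
        r = a * np.exp(b * theta)
    else:
        raise InvalidArgumentError(f"unknown spiral model {model!r}")
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)]) + np.asarray(center)
    if noise_sd_nm > 0:
        pts = pts + rng.normal(0.0, noise_sd_nm, size=pts.shape)
    return pts


# --------------------------------------------------------------------------
# curvature-limit model
# --------------------------------------------------------------------------


def spacing_across_bend(
    centerline_radius_A: float, model: CurvatureModel | None = None
) -> tuple[float, float]:
    """Inter-ridge spacing (inner edge, outer edge) of a bent filament.

    Ridge elements are rigid and the spacing is relaxed at the filament
    centerline, scaling with the local radius:
    ``s_edge = s0 * (R -/+ w/2) / R``.
    """
    model = model or CurvatureModel()
    R, w = centerline_radius_A, model.width_A
    if not R > w / 2.0:
        raise InvalidArgumentError(
            f"centerline radius {R} Å <= half-width {w / 2.0} Å: filament self-overlaps"
        )
    s_inner = model.s0_A * (R - w / 2.0) / R
    s_outer = model.s0_A * (R + w / 2.0) / R
    return s_inner, s_outer


def min_planar_diameter(model: CurvatureModel | None = None) -> float:
    """Smallest achievable planar centerline diameter, in nm.

    The stretch bound fixes ``R >= s0*(w/2)/(s_max - s0)`` and the
    compression bound ``R >= s0*(w/2)/(s0 - s_min)``; the larger of the
    two limits the curvature.  With the measured defaults this is
    ~103 nm — far wider than rings or spiral centres, hence the need for
    out-of-plane tilt.
    """
    model = model or CurvatureModel()
    half_w = model.width_A / 2.0
    r_outer_bound = model.s0_A * half_w / (model.s_max_A - model.s0_A)
    r_inner_bound = model.s0_A * half_w / (model.s0_A - model.s_min_A)
    return 2.0 * max(r_outer_bound, r_inner_bound) / 10.0  # Å -> nm


def requires_tilt(observed_diameter_nm: float, model: CurvatureModel | None = None) -> bool:
    """True if a planar filament cannot reach the observed (centerline) diameter.

    The boundary is inclusive-feasible: exactly the minimum planar
    diameter does not require tilt.
    """
    if not observed_diameter_nm > 0:
        raise InvalidArgumentError(
            f"observed_diameter_nm must be > 0, got {observed_diameter_nm!r}"
        )
    return observed_diameter_nm < min_planar_diameter(model)


# --------------------------------------------------------------------------
# rings and protofilaments
# --------------------------------------------------------------------------


def ring_geometry(
    N: int,
    diameter_A: float | None = None,
    subunit_arc_A: float | None = None,
    rung_spacing_A: float = presets.PROTOFILAMENT_SPACING_A,
    n_rungs: int = 5,
) -> RingModel:
    """C_N ring rung geometry from either the diameter or the subunit arc.

    The rung circumference is shared by N subunits: ``pi * D = N * s``.
    Exactly one of ``diameter_A`` / ``subunit_arc_A`` must be given.
    """
    if N < 3:
        raise InvalidArgumentError(f"N must be >= 3, got {N!r}")
    if (diameter_A is None) == (subunit_arc_A is None):
        raise InvalidArgumentError("give exactly one of diameter_A or subunit_arc_A")
    if diameter_A is not None:
        subunit_arc_A = math.pi * diameter_A / N
    else:
        diameter_A = N * subunit_arc_A / math.pi
    return RingModel(
        N=N,
        diameter_A=float(diameter_A),
        subunit_arc_A=float(subunit_arc_A),
        rung_spacing_A=rung_spacing_A,
        n_rungs=n_rungs,
    )


def ring_spacing_at_radius(ring: RingModel, radius_A: float) -> float:
    """Inter-subunit arc 2*pi*r/N of a C_N rung evaluated at radius r."""
    return 2.0 * math.pi * radius_A / ring.N


def protofilament_count(
    filament_width_A: float,
    proto_spacing_A: float = presets.PROTOFILAMENT_SPACING_A,
) -> int:
    """Number of parallel protofilaments in a filament of the given width.

    Nearest integer of width / lateral protofilament spacing, minimum 1.
    """
    if not (filament_width_A > 0 and proto_spacing_A > 0):
        raise InvalidArgumentError("width and spacing must be positive")
    return max(1, round(filament_width_A / proto_spacing_A))
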