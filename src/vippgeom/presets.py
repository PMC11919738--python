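"""Published parameter sets used as defaults throughout the toolkit.

Helical symmetries are the refined cryo-EM values for the four Vipp1
filament lattices; radii come from the printed filament diameters
(24.4 nm outer / 12.7 nm lumen for the Vipp1Δα6 L3 lattice, 21.0 /
10.5 nm for the constricted full-length L1 lattice and its interface-3
mutant, which shares its lattice).  AFM statistics are the measured
means ± s.d. of membrane-bound planar polymers.
"""

from __future__ import annotations

from .core_lattice import HelicalSymmetry

VIPP1_L1 = HelicalSymmetry(
    rise_A=2.372, twist_deg=-75.860, r_lumen_A=52.5, r_outer_A=105.0, label="Vipp1_L1"
)
VIPP1_F197K_L200K_L1 = HelicalSymmetry(
    rise_A=2.440, twist_deg=-75.835, r_lumen_A=52.5, r_outer_A=105.0,
    label="Vipp1_F197K/L200K_L1",
)
VIPP1_DA6_L2 = HelicalSymmetry(
    rise_A=2.155, twist_deg=68.507, label="Vipp1_da6_L2"
)
VIPP1_DA6_L3 = HelicalSymmetry(
    rise_A=2.159, twist_deg=85.495, r_lumen_A=63.5, r_outer_A=122.0, label="Vipp1_da6_L3"
)

#: All four refined lattices keyed by short name.
SYMMETRIES: dict[str, HelicalSymmetry] = {
    "L1": VIPP1_L1,
    "F197K_L200K_L1": VIPP1_F197K_L200K_L1,
    "da6_L2": VIPP1_DA6_L2,
    "da6_L3": VIPP1_DA6_L3,
}

# --- measured AFM / EM statistics (used as generator defaults) -------------

RIDGE_PERIOD_A = 54.0          # inter-ridge (hairpin) spacing in sheets/filaments
SEAM_PERIOD_A = 122.0          # seam repeat orthogonal to the ridges
FILAMENT_WIDTH_NM = (13.4, 0.9)       # mean, sd
SPIRAL_DIAMETER_NM = (82.7, 37.8)     # mean, sd (n = 278)
SPIRAL_DIAMETER_FLOOR_NM = 30.0
GROWTH_RATE_NM_S = (24.0, 19.6)       # mean, sd (n = 124 interval velocities)
MEMBRANE_OFFSET_NM = 5.5              # sheet/spiral height above membrane
RING_PROTRUSION_NM = (1.0, 0.2)       # central ring above surrounding spiral
RING_LS_DIAMETER_NM = (37.0, 3.9)     # low-salt rings formed in spiral centres
RING_NOSPIRAL_DIAMETER_NM = (49.1, 7.8)
RING_HS_DIAMETER_NM = (35.5, 2.9)     # pre-assembled high-salt rings on membrane
RING_HS_HEIGHT_NM = (9.6, 2.2)

# --- curvature-limit model constants ---------------------------------------

RIDGE_SPACING_RELAXED_A = 54.0
RIDGE_SPACING_MIN_A = 41.0     # maximum compression of the inter-ridge spacing
RIDGE_SPACING_MAX_A = 61.0     # maximum stretch
FILAMENT_WIDTH_A = 134.0
PROTOFILAMENT_SPACING_A = 32.5  # lateral spacing of ESCRT-III-like strands (32-33)
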