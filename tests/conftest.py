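import math

import numpy as np
import pytest

from vippgeom import presets
from vippgeom.core_lattice import HelicalSymmetry


@pytest.fixture(scope="session")
def l3() -> HelicalSymmetry:
    """The indexable Vipp1Δα6 L3 lattice (rise 2.159 Å, twist 85.495°)."""
    return presets.VIPP1_DA6_L3


@pytest.fixture(scope="session")
def l1() -> HelicalSymmetry:
    return presets.VIPP1_L1


@pytest.fixture(scope="session")
def l2() -> HelicalSymmetry:
    return presets.VIPP1_DA6_L2


@pytest.fixture(scope="session")
def f197k() -> HelicalSymmetry:
    return presets.VIPP1_F197K_L200K_L1


def random_symmetries(n: int, seed: int = 0) -> list[HelicalSymmetry]:
    """Random plausible helical symmetries for property tests."""
    rng = np.random.default_rng(seed)
    syms = []
    while len(syms) < n:
        rise = rng.uniform(1.0, 10.0)
        twist = rng.uniform(-180.0, 180.0)
        if abs(twist) < 1e-3 or abs(abs(twist) - 180.0) < 1e-3:
            continue
        syms.append(HelicalSymmetry(rise_A=rise, twist_deg=twist))
    return syms


def match_objects(objects, truth):
    """Pair each ground-truth record with the detected object it rendered.

    Candidates are objects whose centroid lies within the truth object's
    radius; a truth spiral with a central ring prefers its non-ring
    candidate (the detached ring sits at the same centre).
    """
    pairs = []
    for _, t in truth.iterrows():
        cands = [
            (math.hypot(o.centroid_nm[0] - t.center_x_nm, o.centroid_nm[1] - t.center_y_nm), o)
            for o in objects
        ]
        cands = [(d, o) for d, o in cands if d < t.diameter_nm / 2.0]
        cands.sort(key=lambda x: x[0])
        if bool(t.get("has_ring", False)):
            cands = [(d, o) for d, o in cands if o.kind != "ring"] or cands
        pairs.append((t, cands[0][1] if cands else None))
    return pairs
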