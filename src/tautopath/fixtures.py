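"""Synthetic labelled 3-D base-pair structures with exact observables.

The fixture is a minimal adenine-thymine pair: per base one pivot nitrogen
(the backbone-attachment site), the heavy atoms of the two hydrogen bonds
(B1 = N6(A)-H...O4(T), B2 = N3(T)-H...N1(A)) and the two bridging
hydrogens.  Sites are placed analytically so that the geometry module
recovers the requested separation, per-bond extensions and opening angle
exactly; the proton progress coordinates q1, q2 place each bridging
hydrogen between its donor (q = 0) and acceptor (q = 1) wells.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .geometry import HBondSpec, MolecularFrame

__all__ = ["synth_fixture_structures"]

#: Distance from pivot to pair midplane, A (sets the fixture footprint).
PIVOT_X = 5.45
#: Covalent X-H distance used to seat each bridging hydrogen, A.
COVALENT_XH = 1.0
#: Default heavy-atom equilibrium hydrogen-bond length, A.
EQ_LENGTH = 2.9
#: Default lever arm between the B1 and B2 attachment sites, A.
LEVER_ARM = 4.5

# site layout per frame (adenine then thymine)
_LABELS = ["N9", "N6", "N1", "H61", "N1'", "O4", "N3", "H3"]
_ELEMENTS = ["N", "N", "N", "H", "N", "O", "N", "H"]
_A_PIVOT, _A_N6, _A_N1, _A_H61 = 0, 1, 2, 3
_T_PIVOT, _T_O4, _T_N3, _T_H3 = 4, 5, 6, 7


def _build(d: float, q1: float, q2: float, theta_deg: float,
           eq_length: float, lever_arm: float) -> np.ndarray:
    w = lever_arm
    ext_diff = w * np.sin(np.radians(theta_deg))
    # equal per-bond allocation of the mean extension; theta splits them
    e1 = d - ext_diff / 2.0
    e2 = d + ext_diff / 2.0
    half1 = (eq_length + e1) / 2.0
    half2 = (eq_length + e2) / 2.0

    coords = np.zeros((8, 3))
    coords[_A_PIVOT] = (-PIVOT_X - d / 2.0, 0.0, 0.0)
    coords[_T_PIVOT] = (+PIVOT_X + d / 2.0, 0.0, 0.0)
    # B1 heavy atoms: donor N6 on adenine, acceptor O4 on thymine (upper rung)
    coords[_A_N6] = (-half1, +w / 2.0, 0.0)
    coords[_T_O4] = (+half1, +w / 2.0, 0.0)
    # B2 heavy atoms: donor N3 on thymine, acceptor N1 on adenine (lower rung)
    coords[_A_N1] = (-half2, -w / 2.0, 0.0)
    coords[_T_N3] = (+half2, -w / 2.0, 0.0)

    def place_h(donor, acceptor, q):
        u = coords[acceptor] - coords[donor]
        r = np.linalg.norm(u)
        u = u / r
        # q = 0: covalent distance from donor; q = 1: covalent from acceptor
        return coords[donor] + u * (COVALENT_XH + q * (r - 2.0 * COVALENT_XH))

    coords[_A_H61] = place_h(_A_N6, _T_O4, q1)
    coords[_T_H3] = place_h(_T_N3, _A_N1, q2)
    return coords


def synth_fixture_structures(d: float, q1: float = 0.0, q2: float = 0.0,
                             theta_deg: float = 0.0,
                             eq_length: float = EQ_LENGTH,
                             lever_arm: float = LEVER_ARM) -> MolecularFrame:
    """Labelled two-base fixture at separation ``d`` with protons at (q1, q2).

    ``theta_deg`` splits the separation unevenly between the two bonds so the
    arcsine opening angle of the frame equals the requested value; the default
    0 gives equal per-bond allocation.  The returned frame carries its own
    d = 0 configuration as the equilibrium reference.
    """
    if d < 0:
        raise DomainError(f"separation d={d} must be non-negative")
    for name, q in (("q1", q1), ("q2", q2)):
        if not -0.5 <= q <= 1.5:
            raise DomainError(f"proton coordinate {name}={q} outside [-0.5, 1.5]")
    coords = _build(d, q1, q2, theta_deg, eq_length, lever_arm)
    reference = _build(0.0, 0.0, 0.0, 0.0, eq_length, lever_arm)
    hbonds = [
        HBondSpec(donor=_A_N6, hydrogen=_A_H61, acceptor=_T_O4, label="B1",
                  eq_length=eq_length),
        HBondSpec(donor=_T_N3, hydrogen=_T_H3, acceptor=_A_N1, label="B2",
                  eq_length=eq_length),
    ]
    return MolecularFrame(
        labels=list(_LABELS),
        elements=list(_ELEMENTS),
        coords=coords,
        pivot_indices=(_A_PIVOT, _T_PIVOT),
        hbonds=hbonds,
        equilibrium_reference=reference,
        comment=f"synthetic A-T fixture d={d:.3f} q1={q1:.3f} q2={q2:.3f}",
    )
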