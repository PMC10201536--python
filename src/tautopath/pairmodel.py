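"""Mechanical two-base model used by the constrained separation scan.

Each base is a rigid body pivoting about its backbone nitrogen.  The state
vector is [px_A, py_A, phi_A, px_T, py_T, phi_T]: pivot coordinates (held
fixed during a scan) and a rotation angle per base (radians).  The bases
carry B1 and B2 attachment sites separated by the lever arm w; the pair is
held by two Morse hydrogen bonds, with B1 the deeper of the two, plus a
harmonic restraint on each rotation angle representing the stiffness of
the glycosidic linkage.

Because B1 resists stretching more strongly than B2, relaxation under
imposed pivot displacement rotates the bases to protect B1 at the expense
of B2, opening the pair at a positive angle; once both bonds are past the
reach of their Morse wells the rotational restraint wins and the angle
reverts toward zero.  This reproduces the rise-then-reversion of the
opening angle seen along a quantum-chemical separation scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .geometry import opening_angle

__all__ = ["PairModelParams", "BasePairModel", "PIVOT_IDX", "FREE_IDX"]

#: Indices of the pivot (constrained) components of the state vector.
PIVOT_IDX = (0, 1, 3, 4)
#: Indices of the rotational (free) components.
FREE_IDX = (2, 5)


@dataclass(frozen=True)
class PairModelParams:
    """Mechanical parameters of the two-base scan model."""

    morse_depth_B1: float = 0.28   # eV
    morse_depth_B2: float = 0.22   # eV
    morse_width: float = 2.0       # 1/A
    hbond_eq_length: float = 2.9   # A, canonical equilibrium length of both bonds
    lever_arm: float = 4.5         # A between the B1 and B2 sites of a base
    pivot_x: float = 5.45          # A, pivot distance from the pair midplane
    rotation_k: float = 0.8        # eV/rad^2, glycosidic rotation restraint
    #: tautomeric form: B1 deepens and its rest length contracts
    taut_B1_depth_scale: float = 1.3
    taut_B1_contraction: float = 0.10  # A

    def __post_init__(self):
        if self.morse_depth_B1 <= self.morse_depth_B2:
            raise DomainError("morse_depth_B1 must exceed morse_depth_B2")
        for name in ("morse_depth_B2", "morse_width", "hbond_eq_length",
                     "lever_arm", "pivot_x", "rotation_k"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


class BasePairModel:
    """Energy model over the 6-component pair state for one structural form.

    ``form`` is one of ``canonical``, ``tautomer`` or ``zwitterion``.  The
    tautomeric form deepens B1 and contracts its rest length (the tautomeric
    B1 bond is the stronger one and initially shortens); the zwitterionic
    form keeps canonical rest lengths with a mildly deepened B2 (the
    transferred proton strengthens the B2 contact).  Bond extensions are
    always reported against the canonical equilibrium length so the forms
    are directly comparable.
    """

    FORMS = ("canonical", "tautomer", "zwitterion")

    def __init__(self, params: PairModelParams = PairModelParams(),
                 form: str = "canonical"):
        if form not in self.FORMS:
            raise DomainError(f"form must be one of {self.FORMS}, got {form!r}")
        self.params = params
        self.form = form
        p = params
        self.d1, self.r01 = p.morse_depth_B1, p.hbond_eq_length
        self.d2, self.r02 = p.morse_depth_B2, p.hbond_eq_length
        if form == "tautomer":
            self.d1 *= p.taut_B1_depth_scale
            self.r01 -= p.taut_B1_contraction
        elif form == "zwitterion":
            self.d2 *= 1.1
        # offsets of the B1/B2 sites from the pivot in the unrotated base frame
        a = p.pivot_x - p.hbond_eq_length / 2.0
        self.off_b1 = np.array([a, +p.lever_arm / 2.0])
        self.off_b2 = np.array([a, -p.lever_arm / 2.0])

    # -- kinematics ---------------------------------------------------------

    @staticmethod
    def equilibrium_state(d: float = 0.0, pivot_x: float = 5.45) -> np.ndarray:
        """State with pivots displaced symmetrically by d/2 and no rotation."""
        return np.array([-pivot_x - d / 2.0, 0.0, 0.0,
                         +pivot_x + d / 2.0, 0.0, 0.0])

    def sites(self, x: np.ndarray) -> dict:
        """Cartesian positions of the four bonding sites for state ``x``."""
        pa = np.asarray(x[0:2], dtype=float)
        pt = np.asarray(x[3:5], dtype=float)
        ca, sa = np.cos(x[2]), np.sin(x[2])
        ct, st = np.cos(x[5]), np.sin(x[5])
        rot_a = np.array([[ca, -sa], [sa, ca]])
        rot_t = np.array([[ct, -st], [st, ct]])
        # the thymine base mirrors the adenine geometry across the midplane
        flip = np.array([-1.0, 1.0])
        return {
            ("A", "B1"): pa + rot_a @ self.off_b1,
            ("A", "B2"): pa + rot_a @ self.off_b2,
            ("T", "B1"): pt + rot_t @ (self.off_b1 * flip),
            ("T", "B2"): pt + rot_t @ (self.off_b2 * flip),
        }

    def bond_lengths(self, x: np.ndarray) -> tuple[float, float]:
        s = self.sites(x)
        r1 = float(np.linalg.norm(s[("T", "B1")] - s[("A", "B1")]))
        r2 = float(np.linalg.norm(s[("T", "B2")] - s[("A", "B2")]))
        return r1, r2

    def extensions(self, x: np.ndarray) -> tuple[float, float]:
        """(B1, B2) bond extensions against the canonical equilibrium length."""
        r1, r2 = self.bond_lengths(x)
        eq = self.params.hbond_eq_length
        return r1 - eq, r2 - eq

    def theta(self, x: np.ndarray) -> float:
        """Signed opening angle (degrees) from the arcsine lever formula."""
        e1, e2 = self.extensions(x)
        return opening_angle(e1, e2, self.params.lever_arm)

    # -- energetics ---------------------------------------------------------

    def _morse(self, r, depth, r0):
        e = np.exp(-self.params.morse_width * (r - r0))
        return depth * (1.0 - e) ** 2

    def energy(self, x: np.ndarray) -> float:
        """Potential energy (eV), zero at the form's own relaxed contact."""
        r1, r2 = self.bond_lengths(x)
        e = self._morse(r1, self.d1, self.r01) + self._morse(r2, self.d2, self.r02)
        e += 0.5 * self.params.rotation_k * (x[2] ** 2 + x[5] ** 2)
        return float(e)

    def gradient(self, x: np.ndarray, step: float = 1e-6) -> np.ndarray:
        """Central finite-difference gradient of :meth:`energy`."""
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += step
            xm[i] -= step
            g[i] = (self.energy(xp) - self.energy(xm)) / (2.0 * step)
        return g
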