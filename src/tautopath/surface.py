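"""Model double-proton-transfer energy surface for a separating base pair.

The surface is a two-coordinate landscape V(q1, q2; d).  q2 is the transfer
progress of the proton in hydrogen bond B2 (the thymine-donated proton that
moves first), q1 the progress of the B1 proton that follows, and d the
strand-separation distance in Angstrom.  (q1, q2) = (0, 0) is the canonical
Watson-Crick pair, (0, 1) the zwitterionic intermediate A+/T-, and (1, 1)
the neutral tautomeric pair A*/T*.

Each transfer step is a tilted quartic

    S(q; h, Delta) = 16 h q^2 (1 - q)^2 + Delta q,

whose (h, Delta) are root-solved at every separation so that the quartic's
own stationary analysis reproduces the requested forward and reverse
barriers exactly rather than to first order.  The steps are composed with a
smooth switch s(q2) = q2^2 (3 - 2 q2) and a sequential penalty that forbids
transferring the B1 proton before the B2 proton, which enforces the
asynchronous stepwise mechanism:

    V = S(q2; h1, D1) + s(q2) S(q1; h2, D2) + (1 - s(q2)) P q1^2.

The separation dependence enters through the barrier laws: the step-1
reverse barrier grows as a power of d; the single- and double-transfer
reaction asymmetries are linear in d; the step-2 reverse barrier grows
linearly past an onset separation d0 and is flagged unbound below it.
Below the onset the step-2 term degenerates to the bare sequential penalty,
so the tautomeric corner holds no minimum at all.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, asdict, replace
from importlib import resources

import numpy as np
import yaml
from scipy import optimize

from .errors import CalibrationError, DegenerateWellError, DomainError

__all__ = [
    "SurfaceState",
    "SurfaceParams",
    "BarrierTargets",
    "barrier_targets",
    "tilted_quartic",
    "tilted_quartic_grad",
    "quartic_stationary_points",
    "quartic_barriers",
    "calibrate_tilted_quartic",
    "CalibratedSurface",
    "get_surface",
    "potential_energy",
    "surface_gradient",
]

#: Physical window of the transfer-progress coordinates.
Q_MIN, Q_MAX = -0.2, 1.2
#: Hard envelope beyond which evaluation is a domain error.
Q_HARD_MIN, Q_HARD_MAX = -0.5, 1.5
#: Cubic confinement wall outside the physical window, eV per (unit excess)^3.
WALL_K = 20.0


@dataclass(frozen=True)
class SurfaceState:
    """A point on the transfer surface: progresses q1, q2 and separation d (A)."""

    q1: float
    q2: float
    d: float

    def __post_init__(self):
        for name in ("q1", "q2"):
            q = getattr(self, name)
            if not Q_HARD_MIN <= q <= Q_HARD_MAX:
                raise DomainError(
                    f"coordinate {name}={q:.4f} outside the admissible range "
                    f"[{Q_HARD_MIN}, {Q_HARD_MAX}]"
                )
        if self.d < 0:
            raise DomainError(f"separation d={self.d:.4f} must be non-negative")


@dataclass(frozen=True)
class SurfaceParams:
    """Full calibration of the transfer surface as functions of separation.

    The numeric defaults are artifact conventions chosen to satisfy the
    qualitative orderings of the landscape (zwitterion metastable at every
    separation, no tautomeric well below the onset, second barrier far below
    the first, quasi-linear asymmetries); only the power-law exponents carry
    preset-specific values (AT vs GC).
    """

    step1_reverse_base: float = 0.10       # eV, reverse barrier of step 1 at d = 0
    step1_reverse_prefactor: float = 0.70  # eV A^-p
    step1_exponent: float = 1.894          # dimensionless (AT preset; GC: 1.783)
    step2_slope: float = 0.50              # eV/A, growth of the step-2 reverse barrier
    step2_onset: float = 0.30              # A, onset separation d0 of the tautomer well
    spt_asymmetry_intercept: float = 0.55  # eV, zwitterion above canonical at d = 0
    spt_asymmetry_slope: float = 0.25      # eV/A
    dpt_asymmetry_intercept: float = 0.45  # eV, tautomer above canonical at d = 0
    dpt_asymmetry_slope: float = 0.35      # eV/A
    sequential_penalty: float = 3.0        # eV, cost of moving the B1 proton first
    stability_epsilon: float = 0.005       # eV, wells shallower than this are unbound
    preset_label: str = "AT"

    def __post_init__(self):
        if self.preset_label not in ("AT", "GC"):
            raise DomainError(f"preset_label must be 'AT' or 'GC', got {self.preset_label!r}")
        for name in (
            "step1_reverse_base",
            "step1_reverse_prefactor",
            "step1_exponent",
            "step2_slope",
            "sequential_penalty",
            "stability_epsilon",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.step2_onset < 0:
            raise DomainError("step2_onset must be non-negative")

    @classmethod
    def from_preset(cls, label: str) -> "SurfaceParams":
        """Load a packaged preset calibration ('AT' or 'GC')."""
        name = label.lower()
        try:
            text = resources.files("tautopath.data").joinpath(f"{name}.yaml").read_text()
        except FileNotFoundError as exc:
            raise DomainError(f"unknown preset {label!r}") from exc
        block = yaml.safe_load(text)["surface"]
        return cls.from_dict(block)

    @classmethod
    def from_dict(cls, block: dict) -> "SurfaceParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(block) - known
        if unknown:
            raise DomainError(f"unknown surface parameter(s): {sorted(unknown)}")
        return cls(**block)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SurfaceParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BarrierTargets:
    """Target barrier heights and asymmetries of the surface at one separation.

    Step 1 moves the B2 proton (canonical -> zwitterion), step 2 the B1
    proton (zwitterion -> tautomer).  When the tautomeric well is unbound
    (``dpt_bound`` is False) the step-2 barriers are reported as 0.
    """

    d: float
    Ef1: float
    Er1: float
    Ef2: float
    Er2: float
    A_spt: float
    A_dpt: float
    dpt_bound: bool


def barrier_targets(d: float, params: SurfaceParams) -> BarrierTargets:
    """Evaluate the calibration laws of the surface at separation ``d``.

    Er1(d) = base + prefactor * d^p, A_spt and A_dpt linear in d,
    Ef1 = A_spt + Er1, Er2(d) = slope * (d - d0), Ef2 = A_dpt + Er2 - A_spt.
    The tautomeric well is flagged unbound when Er2 <= epsilon (no depth) or
    Ef2 <= 0 (transition state below the intermediate), in which case the
    step-2 barriers are clamped to zero.
    """
    if d < 0:
        raise DomainError(f"separation d={d} must be non-negative")
    p = params
    er1 = p.step1_reverse_base + p.step1_reverse_prefactor * d**p.step1_exponent
    a_spt = p.spt_asymmetry_intercept + p.spt_asymmetry_slope * d
    a_dpt = p.dpt_asymmetry_intercept + p.dpt_asymmetry_slope * d
    ef1 = a_spt + er1
    er2_raw = p.step2_slope * (d - p.step2_onset)
    ef2_raw = a_dpt + er2_raw - a_spt
    bound = (er2_raw > p.stability_epsilon) and (ef2_raw > 0.0)
    er2 = er2_raw if bound else 0.0
    ef2 = ef2_raw if bound else 0.0
    return BarrierTargets(d=d, Ef1=ef1, Er1=er1, Ef2=ef2, Er2=er2,
                          A_spt=a_spt, A_dpt=a_dpt, dpt_bound=bound)


# ---------------------------------------------------------------------------
# Tilted-quartic step potential and its exact calibration
# ---------------------------------------------------------------------------

def tilted_quartic(q, h: float, delta: float):
    """S(q; h, Delta) = 16 h q^2 (1 - q)^2 + Delta q."""
    q = np.asarray(q, dtype=float)
    return 16.0 * h * q * q * (1.0 - q) ** 2 + delta * q


def tilted_quartic_grad(q, h: float, delta: float):
    """dS/dq = 32 h q (1 - q)(1 - 2q) + Delta."""
    q = np.asarray(q, dtype=float)
    return 32.0 * h * q * (1.0 - q) * (1.0 - 2.0 * q) + delta


def quartic_stationary_points(h: float, delta: float) -> np.ndarray:
    """The three real stationary points (reactant min, maximum, product min).

    Raises :class:`CalibrationError` when the tilt is too strong for a
    double-well structure.
    """
    if h <= 0:
        raise CalibrationError(f"quartic height h={h} must be positive")
    roots = np.roots([64.0 * h, -96.0 * h, 32.0 * h, delta])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    if len(real) != 3:
        raise CalibrationError(
            f"tilted quartic with h={h:.4g}, Delta={delta:.4g} has no double-well structure"
        )
    return real


def quartic_barriers(h: float, delta: float) -> tuple[float, float]:
    """(forward, reverse) barrier of the tilted quartic from its true extrema."""
    qa, qb, qc = quartic_stationary_points(h, delta)
    fa, fb, fc = (float(tilted_quartic(q, h, delta)) for q in (qa, qb, qc))
    return fb - fa, fb - fc


def calibrate_tilted_quartic(Ef: float, Er: float) -> tuple[float, float]:
    """Solve for (h, Delta) so the quartic's true barriers equal (Ef, Er).

    Initialised at the first-order estimate h = (Ef + Er)/2, Delta = Ef - Er
    and root-solved to 1e-8 eV.  Non-positive barriers are degenerate wells.
    """
    if Ef <= 0 or Er <= 0:
        raise DegenerateWellError(
            f"forward and reverse barriers must be positive, got Ef={Ef}, Er={Er}"
        )

    def residual(x):
        h, delta = x
        if h <= 0:
            return [1.0 + abs(h), 1.0 + abs(h)]
        try:
            ef, er = quartic_barriers(h, delta)
        except CalibrationError:
            return [1.0, 1.0]
        return [ef - Ef, er - Er]

    x0 = [(Ef + Er) / 2.0, Ef - Er]
    sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
    h, delta = sol.x
    ef, er = quartic_barriers(h, delta)
    if abs(ef - Ef) > 1e-8 or abs(er - Er) > 1e-8:
        raise CalibrationError(
            f"calibration failed for Ef={Ef}, Er={Er}: residual ({ef - Ef:.2e}, {er - Er:.2e})"
        )
    return float(h), float(delta)


# ---------------------------------------------------------------------------
# The composed two-coordinate surface at fixed separation
# ---------------------------------------------------------------------------

def _switch(q):
    return q * q * (3.0 - 2.0 * q)


def _switch_grad(q):
    return 6.0 * q * (1.0 - q)


def _wall(q):
    lo = np.clip(Q_MIN - q, 0.0, None)
    hi = np.clip(q - Q_MAX, 0.0, None)
    return WALL_K * (lo**3 + hi**3)


def _wall_grad(q):
    lo = np.clip(Q_MIN - q, 0.0, None)
    hi = np.clip(q - Q_MAX, 0.0, None)
    return WALL_K * (-3.0 * lo**2 + 3.0 * hi**2)


class CalibratedSurface:
    """The transfer surface at one separation, calibrated to its barrier laws.

    Exposes vectorised ``energy(q1, q2)`` / ``gradient(q1, q2)`` plus the
    array-of-coordinates interface (``energy_at(x)``, ``gradient_at(x)`` with
    x = [q1, q2]) used by the path-search and relaxation machinery.
    """

    def __init__(self, params: SurfaceParams, d: float):
        self.params = params
        self.d = float(d)
        self.targets = barrier_targets(d, params)
        t = self.targets
        self.h1, self.delta1 = calibrate_tilted_quartic(t.Ef1, t.Er1)
        if t.dpt_bound:
            self.h2, self.delta2 = calibrate_tilted_quartic(t.Ef2, t.Er2)
        else:
            self.h2 = self.delta2 = None

    @property
    def dpt_bound(self) -> bool:
        return self.targets.dpt_bound

    def _check(self, q1, q2):
        q1 = np.asarray(q1, dtype=float)
        q2 = np.asarray(q2, dtype=float)
        for name, q in (("q1", q1), ("q2", q2)):
            if np.any(q < Q_HARD_MIN) or np.any(q > Q_HARD_MAX):
                raise DomainError(
                    f"coordinate {name} outside the admissible range "
                    f"[{Q_HARD_MIN}, {Q_HARD_MAX}]"
                )
        return q1, q2

    def energy(self, q1, q2):
        """V(q1, q2) in eV relative to the canonical corner (0, 0)."""
        q1, q2 = self._check(q1, q2)
        p = self.params
        v = tilted_quartic(q2, self.h1, self.delta1)
        if self.dpt_bound:
            s = _switch(q2)
            v = v + s * tilted_quartic(q1, self.h2, self.delta2) \
                + (1.0 - s) * p.sequential_penalty * q1 * q1
        else:
            v = v + p.sequential_penalty * q1 * q1
        v = v + _wall(q1) + _wall(q2)
        return v if v.ndim else float(v)

    def gradient(self, q1, q2):
        """(dV/dq1, dV/dq2) in eV per unit coordinate."""
        q1, q2 = self._check(q1, q2)
        p = self.params
        g2 = tilted_quartic_grad(q2, self.h1, self.delta1)
        if self.dpt_bound:
            s = _switch(q2)
            ds = _switch_grad(q2)
            t2 = tilted_quartic(q1, self.h2, self.delta2)
            g1 = s * tilted_quartic_grad(q1, self.h2, self.delta2) \
                + (1.0 - s) * 2.0 * p.sequential_penalty * q1
            g2 = g2 + ds * (t2 - p.sequential_penalty * q1 * q1)
        else:
            g1 = 2.0 * p.sequential_penalty * q1
        g1 = g1 + _wall_grad(q1)
        g2 = g2 + _wall_grad(q2)
        if np.ndim(g1) == 0:
            return float(g1), float(g2)
        return np.asarray(g1), np.asarray(g2)

    # -- array-of-coordinates interface used by optimisers -------------------

    def energy_at(self, x) -> float:
        x = np.asarray(x, dtype=float)
        return float(self.energy(x[..., 0], x[..., 1]))

    def gradient_at(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g1, g2 = self.gradient(x[..., 0], x[..., 1])
        return np.stack([np.asarray(g1), np.asarray(g2)], axis=-1)

    def energy_batch(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.asarray(self.energy(X[:, 0], X[:, 1]))

    def gradient_batch(self, X) -> np.ndarray:
        return self.gradient_at(np.asarray(X, dtype=float))

    def minimize_from(self, x0, tol: float = 1e-10, max_step: float = 0.05) -> np.ndarray:
        """Local minimum of the surface from ``x0`` (gradient-norm tol in eV).

        Uses step-capped adaptive gradient descent so the iterate cannot
        jump out of its starting basin (an unconstrained line search can
        overshoot a low barrier into a deeper neighbouring well).
        """
        x = np.clip(np.asarray(x0, dtype=float), Q_HARD_MIN, Q_HARD_MAX)
        e = self.energy_at(x)
        alpha = 1e-2
        for _ in range(20000):
            g = self.gradient_at(x)
            gnorm = float(np.linalg.norm(g))
            if gnorm <= tol:
                break
            dx = -alpha * g
            dnorm = float(np.linalg.norm(dx))
            if dnorm > max_step:
                dx *= max_step / dnorm
            x_new = np.clip(x + dx, Q_HARD_MIN, Q_HARD_MAX)
            e_new = self.energy_at(x_new)
            if e_new <= e:
                x, e = x_new, e_new
                alpha = min(alpha * 1.2, 10.0)
            else:
                alpha *= 0.5
            if gnorm < 1e-3:
                break
        if float(np.linalg.norm(self.gradient_at(x))) > tol:
            # quasi-Newton polish; safe this close to the minimum
            res = optimize.minimize(
                self.energy_at, x, jac=self.gradient_at, method="L-BFGS-B",
                bounds=[(Q_HARD_MIN, Q_HARD_MAX)] * 2,
                options={"gtol": tol, "ftol": 0.0, "maxiter": 500},
            )
            x = res.x
        return x


@functools.lru_cache(maxsize=128)
def get_surface(params: SurfaceParams, d: float) -> CalibratedSurface:
    """Cached calibrated surface for (params, d)."""
    return CalibratedSurface(params, d)


def potential_energy(state: SurfaceState, params: SurfaceParams) -> float:
    """Energy of ``state`` in eV relative to the canonical corner at the same d."""
    return get_surface(params, state.d).energy(state.q1, state.q2)


def surface_gradient(state: SurfaceState, params: SurfaceParams) -> tuple[float, float]:
    """(dV/dq1, dV/dq2) at ``state`` in eV per unit coordinate."""
    return get_surface(params, state.d).gradient(state.q1, state.q2)
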