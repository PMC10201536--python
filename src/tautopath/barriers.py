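"""Barrier extraction, stability classification and scaling analytics.

Operates on energy profiles along a normalised reaction coordinate (as
produced by the path search): locates stationary points by cubic
interpolation, reads forward/reverse barriers and reaction asymmetries off
the admissible stationary patterns, classifies tautomer stability, detects
the onset separation, fits the power-law growth of the trapping barrier,
and provides the minimum-lifetime and temperature-equivalent calculators.

Conventions: step 1 is the B2 proton transfer (canonical -> zwitterion),
step 2 the B1 proton transfer (zwitterion -> tautomer).  The reverse
barrier of a step is transition-state energy minus product-well energy; a
reaction asymmetry is product energy minus reactant energy (positive means
the canonical state is the more stable).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import KB_EV_PER_K
from .errors import ClassificationError, DomainError, NoOnsetError
from .neb import MLNebConfig, PathImageSet, mlneb_run
from .surface import SurfaceParams, get_surface

__all__ = [
    "EnergyProfile",
    "BarrierSet",
    "find_stationary_points",
    "extract_barriers",
    "reaction_asymmetry",
    "classify_stability",
    "detect_onset",
    "fit_power_law",
    "min_lifetime",
    "barrier_temperature",
    "profile_from_path",
    "run_stability_pipeline",
    "METASTABILITY_THRESHOLD",
]

#: Wells shallower than ~2 kT at 310 K are not a meaningful thermal trap.
METASTABILITY_THRESHOLD = 0.05  # eV


@dataclass
class EnergyProfile:
    """Energies along a strictly increasing normalised reaction coordinate."""

    coordinate: np.ndarray
    energies: np.ndarray
    interpolation: str = "cubic"

    def __post_init__(self):
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coordinate.shape != self.energies.shape:
            raise DomainError("coordinate and energies must have equal length")
        if np.any(np.diff(self.coordinate) <= 0):
            raise DomainError("the reaction coordinate must be strictly increasing")
        if not np.all(np.isfinite(self.energies)):
            raise DomainError("profile energies must be finite")


@dataclass
class StationaryPoints:
    """Interior extrema of a profile plus its boundary minima candidates."""

    minima_x: np.ndarray
    minima_e: np.ndarray
    maxima_x: np.ndarray
    maxima_e: np.ndarray


@dataclass
class BarrierSet:
    """Per-separation barriers, asymmetries and the stability verdict."""

    d: float
    Ef1: float
    Er1: float
    Ef2: float
    Er2: float
    A_spt: float
    A_dpt: float
    dpt_bound: bool
    classification: str = ""

    def to_row(self) -> dict:
        return asdict(self)


def profile_from_path(path: PathImageSet) -> EnergyProfile:
    """Energy profile of a converged path over its normalised coordinate."""
    if path.energies is None:
        raise DomainError("the path carries no energies")
    e = path.energies - path.energies[0]
    return EnergyProfile(coordinate=path.coordinate(), energies=e)


def find_stationary_points(profile: EnergyProfile,
                           prominence: float = 0.005) -> StationaryPoints:
    """Interior extrema of the cubic-interpolated profile.

    Alternating maximum/minimum pairs whose energy gap is below
    ``prominence`` are discarded as interpolation wiggles.  The two
    endpoints are always reported as boundary minima candidates.
    """
    if len(profile.coordinate) < 5:
        raise DomainError("a profile needs at least 5 points")
    spline = CubicSpline(profile.coordinate, profile.energies)
    dspline = spline.derivative()
    roots = dspline.roots(extrapolate=False)
    lo, hi = profile.coordinate[0], profile.coordinate[-1]
    roots = np.array(sorted(r for r in np.atleast_1d(roots)
                            if lo + 1e-9 < r < hi - 1e-9))
    second = spline.derivative(2)
    # alternate extrema: (x, E, kind) with kind +1 for maxima, -1 for minima
    ext = []
    for r in roots:
        curv = float(second(r))
        if curv == 0.0:
            continue
        ext.append([float(r), float(spline(r)), -1 if curv > 0 else +1])
    # collapse duplicate same-kind neighbours (flat shoulders)
    cleaned = []
    for e in ext:
        if cleaned and cleaned[-1][2] == e[2]:
            keep = e if (e[1] > cleaned[-1][1]) == (e[2] == 1) else cleaned[-1]
            cleaned[-1] = keep
        else:
            cleaned.append(e)
    # iteratively drop the shallowest adjacent max/min pair below prominence
    changed = True
    while changed:
        changed = False
        for i in range(len(cleaned) - 1):
            if abs(cleaned[i][1] - cleaned[i + 1][1]) < prominence:
                del cleaned[i:i + 2]
                changed = True
                break
    minima = [(lo, float(profile.energies[0]))] + \
             [(x, e) for x, e, k in cleaned if k == -1] + \
             [(hi, float(profile.energies[-1]))]
    maxima = [(x, e) for x, e, k in cleaned if k == 1]
    minima.sort()
    return StationaryPoints(
        minima_x=np.array([x for x, _ in minima]),
        minima_e=np.array([e for _, e in minima]),
        maxima_x=np.array([x for x, _ in maxima]),
        maxima_e=np.array([e for _, e in maxima]),
    )


def extract_barriers(profile: EnergyProfile, points: StationaryPoints,
                     d: float) -> BarrierSet:
    """Read per-step barriers off an admissible stationary pattern.

    Admissible patterns: min-max-min (single transfer only) and
    min-max-min-max-min (both transfer steps; the third minimum is the
    bound tautomeric well).
    """
    n_min, n_max = len(points.minima_x), len(points.maxima_x)
    e_min, e_max = points.minima_e, points.maxima_e
    if n_min == 2 and n_max == 1:
        ef1 = float(e_max[0] - e_min[0])
        er1 = float(e_max[0] - e_min[1])
        return BarrierSet(d=d, Ef1=ef1, Er1=er1, Ef2=0.0, Er2=0.0,
                          A_spt=float(e_min[1] - e_min[0]),
                          A_dpt=float("nan"), dpt_bound=False)
    if n_min == 3 and n_max == 2:
        ef1 = float(e_max[0] - e_min[0])
        er1 = float(e_max[0] - e_min[1])
        ef2 = float(e_max[1] - e_min[1])
        er2 = float(e_max[1] - e_min[2])
        return BarrierSet(d=d, Ef1=ef1, Er1=er1, Ef2=ef2, Er2=er2,
                          A_spt=float(e_min[1] - e_min[0]),
                          A_dpt=float(e_min[2] - e_min[0]), dpt_bound=True)
    raise ClassificationError(
        f"unrecognised stationary pattern: {n_min} minima / {n_max} maxima"
    )


def reaction_asymmetry(e_reactant: float, e_product: float) -> float:
    """Product energy minus reactant energy, eV (positive: reactant more stable)."""
    return float(e_product) - float(e_reactant)


def classify_stability(b: BarrierSet, epsilon: float = 0.005,
                       metastability_threshold: float = METASTABILITY_THRESHOLD) -> str:
    """'unbound', 'metastable' or 'stable' for the tautomeric well of ``b``.

    Unbound when no tautomer minimum exists or its trapping barrier Er2 is
    at or below ``epsilon`` (the boundary is closed on the unbound side);
    metastable up to the metastability threshold; stable beyond.
    """
    if not b.dpt_bound or b.Er2 <= epsilon:
        return "unbound"
    if b.Er2 <= metastability_threshold:
        return "metastable"
    return "stable"


def detect_onset(barrier_sets: Sequence[BarrierSet], epsilon: float = 0.005) -> float:
    """Smallest scanned separation whose classification is not 'unbound'."""
    if len(barrier_sets) < 2:
        raise DomainError("onset detection needs at least 2 scanned separations")
    for b in sorted(barrier_sets, key=lambda b: b.d):
        if classify_stability(b, epsilon=epsilon) != "unbound":
            return b.d
    raise NoOnsetError("no scanned separation supports a bound tautomeric minimum")


def fit_power_law(d_values, barriers) -> tuple[float, float, float]:
    """Least-squares fit of y = A x^p in log-log space.

    Returns (exponent p, prefactor A, R^2).  Exact on noiseless power-law
    input.  All inputs must be strictly positive.
    """
    x = np.asarray(d_values, dtype=float)
    y = np.asarray(barriers, dtype=float)
    if len(x) < 3:
        raise DomainError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y < 0):
        raise DomainError("power-law fit requires positive separations and "
                          "non-negative barriers")
    if np.all(y == y[0]):
        return 0.0, float(y[0]), 1.0
    if np.any(y <= 0):
        raise DomainError("power-law fit requires positive barrier values")
    lx, ly = np.log(x), np.log(y)
    p, loga = np.polyfit(lx, ly, 1)
    pred = p * lx + loga
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - np.mean(ly)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(p), float(np.exp(loga)), r2


def min_lifetime(d_critical: float, separation_speed: float) -> float:
    """Minimum tautomer lifetime (ps) to outlive strand separation to d_critical.

    The tautomer must survive until the strands are too far apart for the
    reaction to reverse: t = d_critical / separation speed.
    """
    if separation_speed <= 0:
        raise DomainError("separation speed must be positive")
    if d_critical < 0:
        raise DomainError("critical separation must be non-negative")
    return d_critical / separation_speed


def barrier_temperature(energy_ev: float) -> float:
    """Temperature (K) whose thermal energy equals the barrier: T = E / k_B."""
    if energy_ev < 0:
        raise DomainError("barrier energy must be non-negative")
    return energy_ev / KB_EV_PER_K


# ---------------------------------------------------------------------------
# End-to-end stability pipeline
# ---------------------------------------------------------------------------

def run_stability_pipeline(params: SurfaceParams, d_grid,
                           neb_config: Optional[MLNebConfig] = None,
                           prominence: Optional[float] = None) -> list[BarrierSet]:
    """Scan separations, search the minimum-energy path and classify stability.

    At each separation the canonical well is relaxed, the tautomeric corner
    is probed by relaxation (a slide back to the zwitterion means the well
    is unbound there), the appropriate path is found with the surrogate-
    accelerated search, and barriers are read off the converged profile.
    """
    if neb_config is None:
        neb_config = MLNebConfig()
    if prominence is None:
        prominence = params.stability_epsilon
    results = []
    for d in np.asarray(d_grid, dtype=float):
        surface = get_surface(params, float(d))
        canonical = surface.minimize_from([0.0, 0.0])
        probe = surface.minimize_from([1.0, 1.0])
        bound = probe[0] > 0.5  # stayed in the tautomeric corner
        product = probe if bound else surface.minimize_from([0.0, 1.0])
        path, _ = mlneb_run(canonical, product, surface, neb_config)
        profile = profile_from_path(path)
        # surrogate-converged profiles can carry wiggles up to the path
        # search's uncertainty tolerance; escalate the prominence filter
        # until an admissible stationary pattern emerges
        b = None
        eps = prominence
        while True:
            points = find_stationary_points(profile, prominence=eps)
            try:
                b = extract_barriers(profile, points, d=float(d))
                break
            except ClassificationError:
                eps *= 2.0
                if eps > 0.05:
                    raise
        b.classification = classify_stability(b, epsilon=params.stability_epsilon)
        results.append(b)
    return results
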