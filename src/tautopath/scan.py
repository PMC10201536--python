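"""Constrained separation-scan protocol.

The scan imposes strand separation in uniform increments (default 0.222 A,
13 increments, i.e. 0.0 to 2.664 A), splitting each increment equally
between the two backbone pivots, and relaxes all unconstrained degrees of
freedom with L-BFGS to a force tolerance (default 0.01 eV/A).  Relaxation
is a continuation: each increment starts from the previous relaxed state,
so the scan follows a single branch of the landscape rather than hunting
for global minima.

Transition-state path searches downstream of the scan use only the first
``ts_scan_limit`` increments (default 8, up to 1.554 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DomainError
from .pairmodel import BasePairModel, PIVOT_IDX
from .surface import SurfaceParams, barrier_targets

__all__ = ["ScanConfig", "ScanRecord", "relax_constrained", "run_separation_scan"]


@dataclass(frozen=True)
class ScanConfig:
    """Separation-scan protocol parameters."""

    increment_spacing: float = 0.222  # A
    n_increments: int = 13
    ts_scan_limit: int = 8            # increments used for transition-state scans
    force_tolerance: float = 0.01     # eV/A
    max_steps: int = 500

    def __post_init__(self):
        if self.increment_spacing <= 0:
            raise DomainError("increment_spacing must be positive")
        if self.force_tolerance <= 0:
            raise DomainError("force_tolerance must be positive")
        if not 1 <= self.ts_scan_limit <= self.n_increments:
            raise DomainError("ts_scan_limit must lie in [1, n_increments]")

    @property
    def grid(self) -> np.ndarray:
        """Scanned separations d_k = k * spacing, k = 0..n_increments-1."""
        return self.increment_spacing * np.arange(self.n_increments)

    @property
    def ts_grid(self) -> np.ndarray:
        return self.grid[: self.ts_scan_limit]


@dataclass
class ScanRecord:
    """Relaxed configuration and observables at one scanned separation."""

    d: float
    state: np.ndarray
    B1_extension: float
    B2_extension: float
    theta: float              # degrees
    energy: float             # eV
    form: str
    bound: bool = True        # False: flagged placeholder (tautomer unbound here)
    gradient_norm: float = 0.0

    def to_row(self) -> dict:
        row = asdict(self)
        row["state"] = list(np.asarray(self.state, dtype=float))
        return row


def _as_model(model):
    """Accept either an object with .energy/.gradient or an (energy, grad) pair."""
    if hasattr(model, "energy") and hasattr(model, "gradient"):
        return model.energy, model.gradient
    energy, gradient = model
    return energy, gradient


def relax_constrained(x0: np.ndarray, fixed: Sequence[int], model,
                      tol: float = 0.01, max_steps: int = 500) -> np.ndarray:
    """Minimise ``model`` over the unconstrained components of ``x0``.

    The components listed in ``fixed`` are returned bit-identical to the
    input.  Convergence requires the 2-norm of the gradient over the free
    components to fall below ``tol``; failure raises
    :class:`ConvergenceError` carrying the last iterate.
    """
    energy, gradient = _as_model(model)
    x0 = np.asarray(x0, dtype=float).copy()
    fixed = sorted(set(int(i) for i in fixed))
    for i in fixed:
        if not 0 <= i < len(x0):
            raise DomainError(f"fixed index {i} out of range for a state of length {len(x0)}")
    free = np.array([i for i in range(len(x0)) if i not in fixed], dtype=int)
    if len(free) == 0:
        return x0

    def assemble(xf):
        x = x0.copy()
        x[free] = xf
        return x

    def fun(xf):
        x = assemble(xf)
        return energy(x), np.asarray(gradient(x))[free]

    xf = x0[free].copy()
    res = optimize.minimize(
        fun, xf, jac=True, method="L-BFGS-B",
        options={"gtol": tol * 1e-3, "ftol": 1e-14, "maxiter": max_steps},
    )
    x = assemble(res.x)
    gnorm = float(np.linalg.norm(np.asarray(gradient(x))[free]))
    if gnorm > tol:
        raise ConvergenceError(
            f"constrained relaxation did not reach |g| <= {tol} in {max_steps} steps "
            f"(residual {gnorm:.3e})",
            last_state=x,
        )
    return x


def run_separation_scan(config: ScanConfig, model: BasePairModel,
                        form: Optional[str] = None,
                        surface_params: Optional[SurfaceParams] = None) -> list[ScanRecord]:
    """Scan the two-base model over the separation grid of ``config``.

    ``form`` defaults to the model's own structural form.  For the
    tautomeric form, increments where the double-transfer well is unbound
    according to ``surface_params`` (default: the packaged A-T calibration)
    are emitted as flagged placeholder records relaxed in the zwitterionic
    form, since no tautomeric state exists there.
    """
    form = form or model.form
    if form != model.form:
        model = BasePairModel(model.params, form=form)
    if surface_params is None:
        surface_params = SurfaceParams()
    zwit = BasePairModel(model.params, form="zwitterion") if form == "tautomer" else None

    records: list[ScanRecord] = []
    prev = BasePairModel.equilibrium_state(0.0, model.params.pivot_x)
    for k, d in enumerate(config.grid):
        active = model
        bound = True
        if form == "tautomer" and not barrier_targets(d, surface_params).dpt_bound:
            active, bound = zwit, False
        x0 = prev.copy()
        x0[0] = -model.params.pivot_x - d / 2.0
        x0[3] = +model.params.pivot_x + d / 2.0
        try:
            x = relax_constrained(x0, PIVOT_IDX, active,
                                  tol=config.force_tolerance,
                                  max_steps=config.max_steps)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"separation scan failed to relax at d={d:.3f} A (increment {k})",
                last_state=exc.last_state,
            ) from exc
        e1, e2 = active.extensions(x)
        gnorm = float(np.linalg.norm(active.gradient(x)[list(set(range(6)) - set(PIVOT_IDX))]))
        records.append(ScanRecord(
            d=float(d), state=x, B1_extension=e1, B2_extension=e2,
            theta=active.theta(x), energy=active.energy(x), form=form,
            bound=bound, gradient_norm=gnorm,
        ))
        prev = x
    return records
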