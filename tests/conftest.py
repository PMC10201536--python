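"""Shared fixtures.

The expensive objects (converged path searches, steered-dynamics
ensembles) are session-scoped and shared between the module test files
and the acceptance suite so each study condition is simulated once.
"""

import warnings

import numpy as np
import pytest

from tautopath.barriers import run_stability_pipeline
from tautopath.duplex import DuplexModelParams, build_duplex
from tautopath.dynamics import (TEST_PROTOCOL, equilibrate, run_steered)
from tautopath.neb import MLNebConfig
from tautopath.scan import ScanConfig
from tautopath.surface import SurfaceParams, get_surface

warnings.filterwarnings("ignore", category=Warning,
                        module="sklearn.gaussian_process")


@pytest.fixture(scope="session")
def at_params():
    return SurfaceParams.from_preset("AT")


@pytest.fixture(scope="session")
def gc_params():
    return SurfaceParams.from_preset("GC")


@pytest.fixture(scope="session")
def default_grid():
    return ScanConfig().grid


@pytest.fixture(scope="session")
def surface_at(at_params):
    def factory(d):
        return get_surface(at_params, d)
    return factory


@pytest.fixture(scope="session")
def stability_results(at_params):
    """Full scan -> path search -> barrier extraction over the
    transition-state grid (first 8 increments of the default spacing)."""
    grid = ScanConfig().ts_grid
    return run_stability_pipeline(at_params, grid, MLNebConfig(seed=1))


# ---------------------------------------------------------------------------
# Steered-dynamics ensembles (shared study conditions)
# ---------------------------------------------------------------------------

FORCE_LADDER = (25.0, 50.0, 75.0, 100.0, 125.0)


@pytest.fixture(scope="session")
def equilibrated_duplex():
    duplex = build_duplex(DuplexModelParams())
    proto = TEST_PROTOCOL.with_(seed=2026)
    state, temperature = equilibrate(duplex, proto, return_temperature=True)
    return duplex, proto, state, temperature


@pytest.fixture(scope="session")
def ladder_ensembles(equilibrated_duplex):
    """One production ensemble per steering force of the ladder."""
    duplex, proto, state, _ = equilibrated_duplex
    out = {}
    for force in FORCE_LADDER:
        n = 10 if force == FORCE_LADDER[-1] else 6
        out[force] = run_steered(
            state, duplex,
            proto.with_(force=force, production_ps=200.0, n_replicas=n))
    return out


@pytest.fixture(scope="session")
def pooled_angle_histogram(ladder_ensembles):
    """Cumulative opening-angle histogram over the whole force ladder
    (occurrences summed across all steered simulations, as for a
    whole-campaign ensemble)."""
    from tautopath.dynamics import angle_histogram
    counts = None
    edges = None
    total = 0
    for force in sorted(ladder_ensembles):
        h = angle_histogram(ladder_ensembles[force])
        edges = h.bin_edges
        total += h.total_samples
        if counts is None:
            counts = {k: v.copy() for k, v in h.counts.items()}
        else:
            for k in counts:
                counts[k] += h.counts[k]
    from tautopath.dynamics import AngleHistogram
    return AngleHistogram(bin_edges=edges, counts=counts, total_samples=total)


@pytest.fixture(scope="session")
def zero_force_ensemble(equilibrated_duplex):
    duplex, proto, state, _ = equilibrated_duplex
    return run_steered(state, duplex,
                       proto.with_(force=0.0, production_ps=20.0, n_replicas=4))


@pytest.fixture(scope="session")
def mirror_ensembles():
    """Default-depth and depth-swapped ensembles with identical seeds."""
    out = {}
    for tag, (d1, d2) in (("default", (0.28, 0.22)), ("swapped", (0.22, 0.28))):
        params = DuplexModelParams(morse_depth_B1=d1, morse_depth_B2=d2)
        duplex = build_duplex(params)
        proto = TEST_PROTOCOL.with_(seed=7, force=125.0,
                                    production_ps=100.0, n_replicas=4)
        state = equilibrate(duplex, proto)
        out[tag] = run_steered(state, duplex, proto)
    return out


@pytest.fixture(scope="session")
def speed_pool():
    """64-replica pool on a short duplex for standard-error scaling checks."""
    params = DuplexModelParams(n_pairs=4)
    duplex = build_duplex(params)
    proto = TEST_PROTOCOL.with_(seed=11, force=125.0,
                                production_ps=60.0, n_replicas=64)
    state = equilibrate(duplex, proto)
    return run_steered(state, duplex, proto)
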