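"""Steered Langevin dynamics: integrator, protocol stages and analysis."""

import numpy as np
import pytest

from tautopath.constants import EV_IN_AMU_A2_PS2
from tautopath.duplex import DuplexModelParams, build_duplex
from tautopath.dynamics import (
    MDState,
    ReplicaTrajectory,
    SteeringProtocol,
    TEST_PROTOCOL,
    TrajectoryEnsemble,
    angle_histogram,
    classify_opening_scenario,
    equilibrate,
    run_steered,
    separation_speed,
    steering_force_ev_per_a,
    total_energy,
)
from tautopath.dynamics import _integrate
from tautopath.errors import DomainError


def make_replica(t, e1, e2, sep):
    from tautopath.geometry import opening_angle_or_nan
    e1, e2 = np.asarray(e1, float), np.asarray(e2, float)
    return ReplicaTrajectory(time=np.asarray(t, float), ext_b1=e1, ext_b2=e2,
                             theta=opening_angle_or_nan(e1, e2, 4.5),
                             separation=np.asarray(sep, float))


class TestUnits:
    def test_steering_force_conversion(self):
        # 25 kJ mol^-1 nm^-1 in eV/A via CODATA constants
        assert steering_force_ev_per_a(25.0) == pytest.approx(0.025911, abs=1e-6)


class TestIntegrator:
    def test_deterministic_limit_energy_drift(self):
        # friction -> 0, noise -> 0: the BAOAB core reduces to velocity
        # Verlet and conserves energy over 10^4 steps
        duplex = build_duplex(DuplexModelParams(n_pairs=4))
        pos = duplex.positions.copy()
        pos[0] += [0.01, 0.005, -0.008]  # small perturbation to set it moving
        state = MDState(positions=pos, velocities=np.zeros_like(pos))
        e0 = total_energy(duplex, state)
        final = _integrate(duplex, state, 10_000, rng=None, friction=0.0)
        e1 = total_energy(duplex, final)
        assert abs(e1 - e0) < 1e-4

    def test_momentum_conservation_without_thermostat(self):
        duplex = build_duplex(DuplexModelParams(n_pairs=3))
        rng = np.random.default_rng(8)
        vel = 0.1 * rng.standard_normal(duplex.positions.shape)
        state = MDState(duplex.positions.copy(), vel)
        p0 = (duplex.masses[:, None] * state.velocities).sum(axis=0)
        final = _integrate(duplex, state, 2000, rng=None, friction=0.0)
        p1 = (duplex.masses[:, None] * final.velocities).sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-10)

    def test_steering_forces_equal_and_opposite(self):
        duplex = build_duplex(DuplexModelParams(n_pairs=3))
        proto = TEST_PROTOCOL.with_(force=100.0)
        from tautopath.dynamics import _steering
        a, b, mag = _steering(duplex, proto)
        pos = duplex.positions
        u = pos[b] - pos[a]
        u /= np.linalg.norm(u)
        fa, fb = -mag * u, +mag * u
        assert np.allclose(fa, -fb)
        assert np.linalg.norm(fb) == pytest.approx(proto.force_ev_a)


class TestEquilibration:
    def test_kinetic_temperature_near_target(self, equilibrated_duplex):
        _, _, _, temperature = equilibrated_duplex
        assert temperature == pytest.approx(310.0, rel=0.10)

    def test_identical_seeds_identical_states(self):
        duplex = build_duplex(DuplexModelParams(n_pairs=3))
        proto = TEST_PROTOCOL.with_(seed=5, equilibration_ps=2.0)
        a = equilibrate(duplex, proto)
        b = equilibrate(duplex, proto)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


class TestScenarioClassification:
    def test_b1_crosses_first(self):
        r = make_replica(t=np.arange(6.0),
                         e1=[0.0, 0.2, 0.6, 0.8, 1.0, 1.2],
                         e2=[0.0, 0.1, 0.2, 0.3, 0.6, 0.9],
                         sep=np.zeros(6))
        assert classify_opening_scenario(r) == "B1-first"

    def test_neither_crosses(self):
        r = make_replica(t=np.arange(4.0), e1=np.full(4, 0.1),
                         e2=np.full(4, 0.2), sep=np.zeros(4))
        assert classify_opening_scenario(r) == "none"

    def test_tie_broken_toward_b2(self):
        r = make_replica(t=np.arange(3.0), e1=[0.0, 0.6, 0.7],
                         e2=[0.0, 0.6, 0.7], sep=np.zeros(3))
        assert classify_opening_scenario(r) == "B2-first"


class TestAngleHistogram:
    def ensemble_of(self, replicas):
        return TrajectoryEnsemble(replicas=replicas, protocol=TEST_PROTOCOL,
                                  duplex_params=DuplexModelParams(),
                                  sampling_ps=0.1)

    def test_all_zero_angles_in_zero_bin(self):
        n = 200
        sep = np.linspace(0.0, 1.9, n)
        e = sep.copy()
        r = make_replica(np.arange(n, dtype=float), e + 0.6, e, sep)
        hist = angle_histogram(self.ensemble_of([r]))
        mids = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        summed = hist.summed()
        assert summed.sum() == hist.total_samples
        # constant extension difference -> a single occupied bin
        assert (summed > 0).sum() == 1

    def test_counts_conserved(self, ladder_ensembles):
        hist = angle_histogram(ladder_ensembles[125.0])
        assert int(hist.summed().sum()) == hist.total_samples

    def test_bimodal_with_negative_mode_dominant(self, pooled_angle_histogram):
        # with the stronger B1 bond on the fork side, unzipping prefers to
        # start at B1: cumulated over the whole force ladder the negative
        # mode carries the global maximum, while a positive mode from
        # B2-led openings coexists
        hist = pooled_angle_histogram
        mids = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        summed = hist.summed()
        neg, pos = summed[mids < 0], summed[mids > 0]
        assert neg.max() == summed.max()
        assert pos.max() > 0

    def test_depth_swap_mirrors_exactly(self, mirror_ensembles):
        # swapping the Morse depths relabels the duplex into its mirror
        # image, so with identical seeds the histograms mirror bin-by-bin
        h_def = angle_histogram(mirror_ensembles["default"])
        h_swp = angle_histogram(mirror_ensembles["swapped"])
        assert np.array_equal(h_def.counts["B1-first"],
                              h_swp.counts["B2-first"][::-1])
        assert np.array_equal(h_def.counts["B2-first"],
                              h_swp.counts["B1-first"][::-1])


class TestSeparationSpeed:
    def ensemble_of(self, replicas):
        return TrajectoryEnsemble(replicas=replicas, protocol=TEST_PROTOCOL,
                                  duplex_params=DuplexModelParams(),
                                  sampling_ps=0.1)

    def test_linear_trajectory_exact(self):
        t = np.linspace(0.0, 4.0, 400)
        sep = 1.25 * t
        r = make_replica(t, sep, sep, sep)
        est = separation_speed(self.ensemble_of([r]))
        assert est.mean == pytest.approx(1.25, abs=1e-9)

    def test_constant_trajectory_excluded(self):
        t = np.linspace(0.0, 4.0, 100)
        flat = make_replica(t, np.zeros_like(t), np.zeros_like(t),
                            np.zeros_like(t))
        moving = make_replica(t, 1.0 * t, 1.0 * t, 1.0 * t)
        est = separation_speed(self.ensemble_of([flat, moving]))
        assert est.n_excluded == 1
        with pytest.raises(DomainError):
            separation_speed(self.ensemble_of([flat]))

    def test_standard_error_definition(self):
        t = np.linspace(0.0, 4.0, 400)
        reps = [make_replica(t, v * t, v * t, v * t) for v in (1.0, 1.5, 2.0, 2.5)]
        est = separation_speed(self.ensemble_of(reps))
        assert est.standard_error == pytest.approx(
            np.std(est.speeds, ddof=1) / 2.0)

    def test_standard_error_scales_inverse_sqrt_n(self, speed_pool):
        # nested subsets of one fixed-parameter pool: SE ~ 1/sqrt(n)
        def se_of(n):
            sub = TrajectoryEnsemble(replicas=speed_pool.replicas[:n],
                                     protocol=speed_pool.protocol,
                                     duplex_params=speed_pool.duplex_params,
                                     sampling_ps=speed_pool.sampling_ps)
            return separation_speed(sub, d_start=0.1, d_end=0.5).standard_error

        se4, se16, se64 = se_of(4), se_of(16), se_of(64)
        for se_small, se_big, factor in ((se4, se16, 2.0), (se16, se64, 2.0)):
            ratio = se_small / se_big
            assert factor / 1.5 < ratio < factor * 1.5


class TestSteeredEnsembles:
    def test_zero_force_duplex_stays_closed(self, zero_force_ensemble):
        # ensemble statistic: no spontaneous unzipping without steering
        peak = np.mean([rep.separation.max()
                        for rep in zero_force_ensemble.replicas])
        assert peak < 0.5
        assert all(not (rep.separation >= 2.0).any()
                   for rep in zero_force_ensemble.replicas)

    def test_high_force_opens_terminal_pair(self, ladder_ensembles):
        ens = ladder_ensembles[125.0]
        opened = sum(1 for r in ens.replicas if (r.separation >= 2.0).any())
        assert opened >= 0.9 * len(ens.replicas)

    def test_stronger_force_drives_further_opening(self, ladder_ensembles):
        # the qualitative force effect at desk scale: the strongest pull
        # opens the terminal pair far beyond what the weakest achieves
        reach = {f: np.mean([r.separation.max() for r in ens.replicas])
                 for f, ens in ladder_ensembles.items()}
        assert reach[125.0] > reach[25.0]
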