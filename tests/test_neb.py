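"""Path search: plain NEB, the GP surrogate and the accelerated loop.

The independent oracle for saddle energies is a dense-grid flood-fill
("watershed") search: grid cells are activated in order of increasing
energy and the saddle between two basins is the level at which their
components first connect.
"""

import numpy as np
import pytest

from tautopath.errors import DomainError
from tautopath.neb import (
    CountingModel,
    GaussianSurrogate,
    MLNebConfig,
    PathImageSet,
    gp_fit,
    gp_predict,
    interpolate_path,
    mlneb_run,
    neb_relax,
)
from tautopath.surface import get_surface, tilted_quartic, tilted_quartic_grad


def grid_saddle_energy(surface, start, goal, step=0.002):
    """Watershed oracle: minimal barrier between the basins of two points."""
    q = np.arange(-0.2, 1.2 + step / 2, step)
    Q1, Q2 = np.meshgrid(q, q, indexing="ij")
    V = surface.energy(Q1, Q2)
    n1, n2 = V.shape
    order = np.argsort(V, axis=None)
    parent = np.full(n1 * n2, -1, dtype=np.int64)

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def cell(x):
        return (int(round((x[0] + 0.2) / step)) * n2
                + int(round((x[1] + 0.2) / step)))

    ca, cb = cell(start), cell(goal)
    flat = V.ravel()
    for idx in order:
        parent[idx] = idx
        i, j = divmod(int(idx), n2)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n1 and 0 <= nj < n2:
                nidx = ni * n2 + nj
                if parent[nidx] != -1:
                    ra, rb = find(idx), find(nidx)
                    if ra != rb:
                        parent[ra] = rb
        if parent[ca] != -1 and parent[cb] != -1 and find(ca) == find(cb):
            return float(flat[idx]) - float(flat[ca])
    raise AssertionError("basins never connected")


class Quartic1D:
    def __init__(self, h, delta=0.0):
        self.h, self.delta = h, delta

    def energy(self, x):
        return float(tilted_quartic(x[0], self.h, self.delta))

    def gradient(self, x):
        return np.array([float(tilted_quartic_grad(x[0], self.h, self.delta))])


class TestInterpolatePath:
    def test_midpoint_of_three(self):
        path = interpolate_path([0.0, 0.0], [1.0, 1.0], 3)
        assert np.allclose(path.images[1], [0.5, 0.5])

    def test_endpoints_preserved(self):
        r, p = np.array([0.1, -0.04]), np.array([1.03, 0.98])
        path = interpolate_path(r, p, 9)
        assert np.array_equal(path.images[0], r)
        assert np.array_equal(path.images[-1], p)

    def test_image_count(self):
        assert interpolate_path([0.0], [1.0], 15).n_images == 15

    def test_identical_endpoints_rejected(self):
        with pytest.raises(DomainError):
            interpolate_path([0.3, 0.3], [0.3, 0.3], 5)


class TestNebRelax:
    def test_symmetric_quartic_barrier(self):
        # for the untilted double well the saddle is exactly h at q = 1/2
        model = Quartic1D(h=0.4)
        path = neb_relax(interpolate_path([0.0], [1.0], 15), model)
        assert path.energies.max() == pytest.approx(0.4, abs=1e-3)

    def test_first_leg_matches_watershed_oracle(self, surface_at):
        s = surface_at(0.444)
        can = s.minimize_from([0.0, 0.0])
        zw = s.minimize_from([0.0, 1.0])
        path = neb_relax(interpolate_path(can, zw, 15), s)
        neb_barrier = float(path.energies.max() - path.energies[0])
        oracle = grid_saddle_energy(s, can, zw)
        assert neb_barrier == pytest.approx(oracle, abs=1e-3)

    def test_converged_path_is_stable(self, surface_at):
        s = surface_at(0.444)
        can = s.minimize_from([0.0, 0.0])
        zw = s.minimize_from([0.0, 1.0])
        path = neb_relax(interpolate_path(can, zw, 15), s)
        again = neb_relax(path, s)
        # residual motion is bounded by the force tolerance of the band
        assert np.allclose(again.images, path.images, atol=5e-3)
        assert np.allclose(again.energies, path.energies, atol=1e-3)

    def test_profile_reversal_symmetry(self, surface_at):
        s = surface_at(0.888)
        can = s.minimize_from([0.0, 0.0])
        taut = s.minimize_from([1.0, 1.0])
        fwd = neb_relax(interpolate_path(can, taut, 15), s)
        rev = neb_relax(interpolate_path(taut, can, 15), s)
        assert fwd.energies.max() == pytest.approx(rev.energies.max(), abs=2e-3)


class TestGaussianSurrogate:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = rng.uniform(0, 1, size=(12, 2))
        self.y = np.sin(3 * self.X[:, 0]) + self.X[:, 1] ** 2

    def test_interpolates_training_points(self):
        gp = gp_fit(list(zip(self.X, self.y)), seed=0)
        for x, y in zip(self.X, self.y):
            mean, sd = gp_predict(gp, x)
            assert mean == pytest.approx(y, abs=1e-4)
            assert sd <= 1e-4

    def test_constant_data_constant_mean(self):
        X = np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 0.0]])
        gp = gp_fit(list(zip(X, [2.0, 2.0, 2.0])), seed=0)
        mean, _ = gp_predict(gp, [0.25, 0.7])
        assert mean == pytest.approx(2.0, abs=1e-6)

    def test_prior_sd_far_from_data(self):
        gp = gp_fit(list(zip(self.X, self.y)), seed=0)
        far = np.array([50.0, -50.0])  # >> 5 length scales away
        _, sd = gp_predict(gp, far)
        assert sd >= 0.9 * gp.prior_sd

    def test_analytic_gradient_matches_fd(self):
        gp = gp_fit(list(zip(self.X, self.y)), seed=0)
        x = np.array([0.4, 0.6])
        g = gp.gradient(x)
        h = 1e-6
        for k in range(2):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fd = (gp.energy(xp) - gp.energy(xm)) / (2 * h)
            assert g[k] == pytest.approx(fd, abs=1e-5)


class TestMLNeb:
    @pytest.fixture(scope="class")
    def full_path_comparison(self, surface_at):
        s = surface_at(0.888)
        can = s.minimize_from([0.0, 0.0])
        taut = s.minimize_from([1.0, 1.0])
        plain_counter = CountingModel(s)
        plain = neb_relax(interpolate_path(can, taut, 15), plain_counter)
        ml_counter = CountingModel(s)
        ml_path, log = mlneb_run(can, taut, ml_counter, MLNebConfig(seed=1))
        return plain, plain_counter, ml_path, ml_counter, log

    def test_barriers_within_uncertainty_tolerance(self, full_path_comparison):
        plain, _, ml_path, _, _ = full_path_comparison
        p_prof = plain.energies - plain.energies[0]
        m_prof = ml_path.energies - ml_path.energies[0]
        # step-1 barrier: global maximum
        assert m_prof.max() == pytest.approx(p_prof.max(), abs=0.02)
        # step-2 barrier: second maximum relative to the intermediate well
        def second_step(prof):
            peak = int(np.argmax(prof))
            tail = prof[peak:]
            well = int(np.argmin(tail))
            return float(tail[well:].max() - tail[well])
        assert second_step(m_prof) == pytest.approx(second_step(p_prof), abs=0.02)

    def test_fewer_true_evaluations_than_plain_neb(self, full_path_comparison):
        _, plain_counter, _, ml_counter, log = full_path_comparison
        assert len(log) < plain_counter.total_calls
        assert ml_counter.total_calls < plain_counter.total_calls

    def test_identical_seeds_identical_logs(self, surface_at):
        s = surface_at(0.444)
        can = s.minimize_from([0.0, 0.0])
        zw = s.minimize_from([0.0, 1.0])
        _, log_a = mlneb_run(can, zw, s, MLNebConfig(seed=9, n_images=9))
        _, log_b = mlneb_run(can, zw, s, MLNebConfig(seed=9, n_images=9))
        assert log_a == log_b


class TestProfileStationaryStructure:
    @pytest.mark.parametrize("d,n_max,n_min", [(0.222, 1, 2), (0.888, 2, 3)])
    def test_counts_match_surface_structure(self, surface_at, d, n_max, n_min):
        from tautopath.barriers import find_stationary_points, profile_from_path
        s = surface_at(d)
        can = s.minimize_from([0.0, 0.0])
        if s.dpt_bound:
            product = s.minimize_from([1.0, 1.0])
        else:
            product = s.minimize_from([0.0, 1.0])
        path, _ = mlneb_run(can, product, s, MLNebConfig(seed=1))
        pts = find_stationary_points(profile_from_path(path), prominence=0.005)
        assert len(pts.maxima_x) == n_max
        assert len(pts.minima_x) == n_min
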