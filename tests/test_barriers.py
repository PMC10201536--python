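"""Barrier extraction, classification, onset and scaling analytics."""

import numpy as np
import pytest

from tautopath.barriers import (
    BarrierSet,
    EnergyProfile,
    barrier_temperature,
    classify_stability,
    detect_onset,
    extract_barriers,
    find_stationary_points,
    fit_power_law,
    min_lifetime,
    reaction_asymmetry,
)
from tautopath.constants import KB_EV_PER_K
from tautopath.errors import (ClassificationError, DomainError, NoOnsetError)
from tautopath.surface import barrier_targets


def profile_from_function(f, n=101):
    x = np.linspace(0.0, 1.0, n)
    return EnergyProfile(coordinate=x, energies=f(x))


class TestFindStationaryPoints:
    def test_single_hump(self):
        p = profile_from_function(lambda x: np.sin(np.pi * x))
        pts = find_stationary_points(p, prominence=0.01)
        assert len(pts.maxima_x) == 1
        assert len(pts.minima_x) == 2  # the two boundary candidates
        assert pts.maxima_x[0] == pytest.approx(0.5, abs=1e-3)

    def test_two_step_profile(self):
        # min - max - min - max - min shape
        p = profile_from_function(
            lambda x: np.sin(np.pi * x) + 0.35 * np.sin(3 * np.pi * x))
        pts = find_stationary_points(p, prominence=0.01)
        assert len(pts.maxima_x) == 2
        assert len(pts.minima_x) == 3

    def test_monotone_profile_no_interior_extrema(self):
        p = profile_from_function(lambda x: 2.0 * x)
        pts = find_stationary_points(p, prominence=0.01)
        assert len(pts.maxima_x) == 0
        assert len(pts.minima_x) == 2

    def test_prominence_filters_wiggles(self):
        p = profile_from_function(
            lambda x: np.sin(np.pi * x) + 0.002 * np.sin(12 * np.pi * x))
        pts = find_stationary_points(p, prominence=0.01)
        assert len(pts.maxima_x) == 1

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            find_stationary_points(
                EnergyProfile(np.linspace(0, 1, 4), np.zeros(4)))


class TestExtractBarriers:
    def test_two_step_fixture_arithmetic(self):
        # extrema energies (0, 0.9, 0.65, 0.67, 0.6)
        x = np.linspace(0.0, 1.0, 201)
        pts = find_stationary_points(profile_from_function(
            lambda x: np.interp(x, [0, 0.25, 0.5, 0.75, 1.0],
                                [0, 0.9, 0.65, 0.67, 0.6])), prominence=0.001)
        b = extract_barriers(
            EnergyProfile(np.array([0, 0.25, 0.5, 0.75, 1.0]),
                          np.array([0, 0.9, 0.65, 0.67, 0.6])),
            type(pts)(minima_x=np.array([0.0, 0.5, 1.0]),
                      minima_e=np.array([0.0, 0.65, 0.6]),
                      maxima_x=np.array([0.25, 0.75]),
                      maxima_e=np.array([0.9, 0.67])),
            d=0.444)
        assert b.Ef1 == pytest.approx(0.9)
        assert b.Er1 == pytest.approx(0.25)
        assert b.Ef2 == pytest.approx(0.02)
        assert b.Er2 == pytest.approx(0.07)
        assert b.dpt_bound

    def test_single_hump_no_second_step(self):
        p = profile_from_function(lambda x: 0.6 * np.sin(np.pi * x) + 0.3 * x)
        pts = find_stationary_points(p, prominence=0.01)
        b = extract_barriers(p, pts, d=0.222)
        assert not b.dpt_bound
        assert b.Ef2 == 0.0 and b.Er2 == 0.0
        assert b.Ef1 > b.Er1  # tilted uphill profile

    def test_unrecognised_pattern(self):
        # three humps: not an admissible one- or two-step profile
        p = profile_from_function(lambda x: np.sin(5 * np.pi * x))
        pts = find_stationary_points(p, prominence=0.01)
        with pytest.raises(ClassificationError):
            extract_barriers(p, pts, d=0.0)


class TestReactionAsymmetry:
    def test_values(self):
        assert reaction_asymmetry(0.2, 0.2) == 0.0
        assert reaction_asymmetry(0.0, 0.55) == pytest.approx(0.55)
        # positive sign: the canonical reactant is the more stable state
        assert reaction_asymmetry(0.0, 0.45) > 0


class TestClassifyStability:
    def make(self, er2, bound=True):
        return BarrierSet(d=1.0, Ef1=1.0, Er1=0.5, Ef2=0.1, Er2=er2,
                          A_spt=0.5, A_dpt=0.4, dpt_bound=bound)

    def test_unbound_when_no_minimum(self):
        assert classify_stability(self.make(0.0, bound=False)) == "unbound"

    def test_boundary_closed_on_unbound_side(self):
        assert classify_stability(self.make(0.005), epsilon=0.005) == "unbound"

    def test_metastable_band(self):
        assert classify_stability(self.make(0.03)) == "metastable"

    def test_stable_beyond_threshold(self):
        assert classify_stability(self.make(0.072)) == "stable"


class TestDetectOnset:
    def make(self, d, er2):
        bound = er2 > 0.005
        return BarrierSet(d=d, Ef1=1.0, Er1=0.5, Ef2=0.1 if bound else 0.0,
                          Er2=er2 if bound else 0.0, A_spt=0.5, A_dpt=0.4,
                          dpt_bound=bound)

    def test_first_bound_entry(self):
        sets = [self.make(0.0, 0.0), self.make(0.222, 0.0),
                self.make(0.444, 0.072), self.make(0.666, 0.18)]
        assert detect_onset(sets) == pytest.approx(0.444)

    def test_all_bound_returns_first(self):
        sets = [self.make(0.1, 0.1), self.make(0.2, 0.2)]
        assert detect_onset(sets) == pytest.approx(0.1)

    def test_all_unbound_errors(self):
        sets = [self.make(0.0, 0.0), self.make(0.222, 0.0)]
        with pytest.raises(NoOnsetError):
            detect_onset(sets)


class TestFitPowerLaw:
    def test_exact_recovery(self):
        d = 0.222 * np.arange(1, 10)
        p, a, r2 = fit_power_law(d, 2.0 * d**1.894)
        assert p == pytest.approx(1.894, abs=1e-10)
        assert a == pytest.approx(2.0, abs=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_constant_series(self):
        p, a, _ = fit_power_law([0.5, 1.0, 1.5], [0.3, 0.3, 0.3])
        assert p == 0.0
        assert a == pytest.approx(0.3)

    @pytest.mark.parametrize("preset,expected", [("AT", 1.894), ("GC", 1.783)])
    def test_generator_consistency(self, preset, expected, at_params, gc_params):
        # baseline-subtracted step-1 reverse barriers recover the
        # configured exponent exactly
        params = at_params if preset == "AT" else gc_params
        d = 0.222 * np.arange(1, 10)
        series = np.array([barrier_targets(x, params).Er1 for x in d])
        baseline = barrier_targets(0.0, params).Er1
        p, _, _ = fit_power_law(d, series - baseline)
        assert p == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            fit_power_law([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestLifetimeAndTemperature:
    def test_lifetime_values(self):
        assert min_lifetime(2.0, 1.25) == pytest.approx(1.6)
        assert min_lifetime(0.0, 3.0) == 0.0
        assert min_lifetime(1.0, 1.0) == pytest.approx(1.0)

    def test_lifetime_errors(self):
        with pytest.raises(DomainError):
            min_lifetime(2.0, 0.0)

    def test_temperature_unit_conversion(self):
        assert barrier_temperature(KB_EV_PER_K) == pytest.approx(1.0)
        assert barrier_temperature(0.02672) == pytest.approx(310.0, rel=1e-2)
        # a reverse barrier of ~3 eV corresponds to tens of thousands of K
        assert barrier_temperature(3.016) == pytest.approx(3.5e4, rel=1e-2)

    def test_negative_energy_rejected(self):
        with pytest.raises(DomainError):
            barrier_temperature(-0.1)


class TestPipelineResults:
    """Properties of the full scan -> path search -> extraction pipeline."""

    def test_onset_at_third_increment(self, stability_results):
        assert detect_onset(stability_results) == pytest.approx(0.444)

    def test_barriers_match_calibration(self, stability_results, at_params):
        for b in stability_results:
            t = barrier_targets(b.d, at_params)
            assert b.dpt_bound == t.dpt_bound
            assert b.Ef1 == pytest.approx(t.Ef1, abs=0.02)
            assert b.Er1 == pytest.approx(t.Er1, abs=0.02)
            if b.dpt_bound:
                assert b.Ef2 == pytest.approx(t.Ef2, abs=0.02)
                assert b.Er2 == pytest.approx(t.Er2, abs=0.02)

    def test_path_independence_of_state_energies(self, stability_results):
        # (Ef1 - Er1) + (Ef2 - Er2) must equal the double-transfer asymmetry
        for b in stability_results:
            if b.dpt_bound:
                assert (b.Ef1 - b.Er1) + (b.Ef2 - b.Er2) == pytest.approx(
                    b.A_dpt, abs=1e-4)

    def test_er1_strictly_increasing(self, stability_results):
        er1 = [b.Er1 for b in sorted(stability_results, key=lambda b: b.d)]
        assert np.all(np.diff(er1) > 0)

    def test_classification_monotone(self, stability_results):
        # stability never reverts to unbound as separation grows
        states = [classify_stability(b) != "unbound"
                  for b in sorted(stability_results, key=lambda b: b.d)]
        seen_bound = False
        for bound in states:
            if seen_bound:
                assert bound
            seen_bound = seen_bound or bound
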