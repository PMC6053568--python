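import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metapred import (
    SimulationParams,
    expected_local_change,
    functional_response,
    herbivore_emigration_rate,
    local_event_rates,
    predator_emigration_rate,
    settlement_distribution,
    settlement_matrix,
    build_fractal_layout,
)


class TestFunctionalResponse:
    def test_half_saturation_and_limits(self, params):
        assert functional_response(0.0, params) == 0.0
        assert functional_response(params.H_0, params) == pytest.approx(params.e_P / 2)
        h = np.geomspace(1, 1e6, 50)
        vals = functional_response(h, params)
        assert np.all(np.diff(vals) > 0)  # monotone increasing
        assert np.all(vals < params.e_P)  # saturates from below
        assert vals[-1] == pytest.approx(params.e_P, rel=1e-4)

    def test_negative_prey_rejected(self, params):
        with pytest.raises(ValueError):
            functional_response(-1.0, params)


class TestLocalRates:
    def test_carrying_capacity_fixed_point(self, params):
        r = local_event_rates(params.k_H, 0.0, params)
        assert r.herbivore_birth == pytest.approx(r.herbivore_crowding_death)

    def test_no_predators_no_predation(self, params):
        r = local_event_rates(30.0, 0.0, params)
        assert r.predation == 0.0
        assert r.predator_birth == 0.0

    def test_empty_patch_is_absorbing(self, params):
        r = local_event_rates(0.0, 0.0, params)
        assert r.total() == 0.0

    def test_scenario_i_disables_predator_demography(self, params):
        p1 = params.with_(scenario="i")
        p2 = params.with_(scenario="ii")
        r1 = local_event_rates(30.0, 2.0, p1)
        r2 = local_event_rates(30.0, 2.0, p2)
        assert r1.predator_birth == 0.0 and r1.predator_background_death == 0.0
        assert r2.predator_birth > 0.0 and r2.predator_background_death > 0.0

    @given(h=st.floats(0, 1e4), p=st.floats(0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_rates_nonnegative_for_any_state(self, h, p):
        r = local_event_rates(h, p, SimulationParams(scenario="ii"))
        assert all(
            getattr(r, f) >= 0
            for f in (
                "herbivore_birth", "herbivore_crowding_death",
                "herbivore_background_death", "predation", "predator_birth",
                "predator_background_death", "herbivore_emigration",
                "predator_emigration",
            )
        )


class TestEmigration:
    def test_logistic_midpoints(self, params):
        assert herbivore_emigration_rate(params.tau_H, params) == pytest.approx(
            params.d_H_max / 2
        )
        assert predator_emigration_rate(params.tau_P, params) == pytest.approx(
            params.d_P_max / 2
        )

    def test_asymptotes(self, params):
        assert herbivore_emigration_rate(1e6, params) == pytest.approx(params.d_H_max)
        assert predator_emigration_rate(1e6, params) == pytest.approx(0.0, abs=1e-12)
        # predators on an empty patch leave at nearly the maximal rate
        assert predator_emigration_rate(0.0, params) == pytest.approx(
            params.d_P_max / (1 + np.exp(-params.s_P * params.tau_P))
        )

    def test_monotone_shapes(self, params):
        h = np.linspace(0, 200, 400)
        assert np.all(np.diff(herbivore_emigration_rate(h, params)) >= 0)
        assert np.all(np.diff(predator_emigration_rate(h, params)) <= 0)

    def test_zero_steepness_is_constant(self, params):
        p = params.with_(s_H=0.0)
        h = np.array([0.0, 10.0, 1000.0])
        assert np.allclose(herbivore_emigration_rate(h, p), p.d_H_max / 2)


class TestSettlement:
    def test_probabilities_normalised_closed_system(self, layout81, params):
        probs = settlement_distribution(layout81, 5, params)
        assert probs.shape == (82,)
        assert probs[5] == 0.0  # no self-settlement
        assert probs[-1] == 0.0  # closed system: no outside mass
        assert probs.sum() == pytest.approx(1.0)

    def test_equidistant_destinations_equal_probability(self, layout9, params):
        # patches 1 and 2 complete patch 0's first-level triangle
        probs = settlement_distribution(layout9, 0, params)
        assert probs[1] == pytest.approx(probs[2])

    def test_flat_kernel_is_uniform(self, layout9):
        p = SimulationParams(alpha=0.0, w_out=0.0)
        probs = settlement_distribution(layout9, 4, p)
        others = np.delete(probs[:-1], 4)
        assert np.allclose(others, 1.0 / 8.0)

    def test_outside_weight_adds_sink_mass(self, layout9, params):
        p = params.with_(w_out=5.0)
        probs = settlement_distribution(layout9, 0, p)
        assert probs[-1] > 0
        assert probs.sum() == pytest.approx(1.0)

    def test_invalid_source_rejected(self, layout9, params):
        with pytest.raises(ValueError):
            settlement_distribution(layout9, 9, params)

    def test_single_closed_patch_rejected(self, params):
        lay = build_fractal_layout(0)
        with pytest.raises(ValueError):
            settlement_distribution(lay, 0, params)

    def test_matrix_rows_match_vector(self, layout9, params):
        mat = settlement_matrix(layout9, params)
        for src in (0, 4, 8):
            assert np.allclose(mat[src], settlement_distribution(layout9, src, params))


class TestDeterministicSkeleton:
    def test_one_step_change_matches_difference_equations(self):
        """Summed rate contributions reproduce the mean-field difference
        equations for prey and predator over a parameter and state grid."""
        grid = [
            dict(g_H=g, k_H=k, e_P=e, H_0=h0, a_P=a, m_H=mh, m_P=mp_)
            for g in (0.1, 0.6)
            for k in (20.0, 60.0)
            for e in (5.0, 20.0)
            for h0 in (5.0, 15.0)
            for a in (0.0, 0.05)
            for mh in (0.0, 0.1)
            for mp_ in (0.0, 0.2)
        ]
        states = [(0, 0), (1, 0), (10, 2), (60, 1), (200, 5)]
        for kw in grid:
            p = SimulationParams(scenario="ii", **kw)
            for h, pr in states:
                dh, dp = expected_local_change(h, pr, p)
                fr = p.e_P * h / (h + p.H_0) if h else 0.0
                dh_eq = p.g_H * h * (p.k_H - h) / p.k_H - fr * pr - p.m_H * h
                dp_eq = p.a_P * fr * pr - p.m_P * pr
                assert dh == pytest.approx(dh_eq, abs=1e-12)
                assert dp == pytest.approx(dp_eq, abs=1e-12)
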