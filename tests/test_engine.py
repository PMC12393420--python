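"""Normalized-Hill math, gate algebra, integration, steady-state detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyrknet import (
    ReactionRule,
    generate_cascade,
    generate_feedback,
    hill_activation,
    hill_constants,
    node_input,
    rhs,
    rule_flux,
    run_to_steady_state,
    simulate,
)
from dyrknet.model import NetworkModel, Species


class TestHillConstants:
    def test_default_parameters(self):
        p = hill_constants(1.4, 0.5)
        assert p.B == pytest.approx(2.5649064800633354, abs=1e-9)
        assert p.K == pytest.approx(1.3769566816515924, abs=1e-9)

    def test_hand_computable_case(self):
        # n=1, ec50=0.25: B = (0.25-1)/(0.5-1) = 1.5, K = (B-1)^1 = 0.5
        p = hill_constants(1.0, 0.25)
        assert p.B == pytest.approx(1.5)
        assert p.K == pytest.approx(0.5)
        assert hill_activation(0.25, p) == pytest.approx(0.5)

    def test_ec50_outside_admissible_region_rejected(self):
        with pytest.raises(ValueError):
            hill_constants(1.4, 0.7)  # 0.7 > 0.5^(1/1.4) ~ 0.6095
        with pytest.raises(ValueError):
            hill_constants(1.4, 0.0)
        with pytest.raises(ValueError):
            hill_constants(-1.0, 0.3)

    @settings(max_examples=150, deadline=None)
    @given(
        n=st.floats(0.5, 6.0),
        frac=st.floats(0.01, 0.99),
    )
    def test_normalization_triple(self, n, frac):
        """f(0)=0, f(ec50)=0.5, f(1)=1 everywhere in the admissible region."""
        ec50 = frac * 0.5 ** (1.0 / n)
        p = hill_constants(n, ec50)
        assert hill_activation(0.0, p) == pytest.approx(0.0, abs=1e-9)
        assert hill_activation(ec50, p) == pytest.approx(0.5, abs=1e-9)
        assert hill_activation(1.0, p) == pytest.approx(1.0, abs=1e-9)

    def test_monotonicity_and_frozen_value(self):
        p = hill_constants(1.4, 0.5)
        xs = np.linspace(0, 1.5, 200)
        ys = hill_activation(xs, p)
        assert np.all(np.diff(ys) > 0)
        assert hill_activation(0.9, p) == pytest.approx(0.9116002377869303, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(-0.1, hill_constants(1.4, 0.5))


class TestGateAlgebra:
    def test_source_rule_flux_is_weight(self):
        rule = ReactionRule((), "A", w=0.7)
        assert rule_flux(rule, {}) == pytest.approx(0.7)

    def test_inhibition_at_zero_input_is_full_flux(self):
        rule = ReactionRule((("X", -1),), "A")
        assert rule_flux(rule, {"X": 0.0}) == pytest.approx(1.0)

    def test_and_is_product_of_terms(self):
        rule = ReactionRule((("X", 1), ("Y", 1)), "A")
        p = hill_constants(1.4, 0.5)
        x, y = 0.4, 0.6
        expected = hill_activation(x, p) * hill_activation(y, p)
        assert rule_flux(rule, {"X": x, "Y": y}) == pytest.approx(expected)

    def test_flux_clamped_under_overexpression(self):
        # f(10) > 1, but the gate term saturates at 1
        rule = ReactionRule((("X", 1),), "A")
        assert rule_flux(rule, {"X": 10.0}) == pytest.approx(1.0)

    def test_or_fold(self):
        r1 = ReactionRule((("X", 1),), "A", w=0.5)
        r2 = ReactionRule((("Y", 1),), "A", w=0.5)
        state = {"X": 1.0, "Y": 1.0}  # both terms = 1, fluxes = weights
        assert node_input("A", [r1, r2], state) == pytest.approx(0.75)
        r3 = ReactionRule((("X", 1),), "A", w=1.0)
        assert node_input("A", [r3, r2], state) == pytest.approx(1.0)  # absorbing
        assert node_input("A", [], state) == 0.0


class TestRhs:
    def test_isolated_species_decays(self):
        m = NetworkModel((Species("A", role="intermediate", y_init=0.3),), ())
        assert rhs(m, [0.3]) == pytest.approx([-0.3])

    def test_input_fixed_point(self):
        m = NetworkModel(
            (Species("A", role="input", y_max=0.9),), (ReactionRule((), "A"),)
        )
        assert rhs(m, [0.9]) == pytest.approx([0.0], abs=1e-12)

    def test_derivative_sign_at_box_faces(self):
        """At Y=0 the derivative is >=0, at Y=y_max it is <=0 (gates in [0,1])."""
        model, _ = generate_cascade(3, input_level=0.8)
        ymax = np.array([s.y_max for s in model.species])
        assert np.all(rhs(model, np.zeros(len(ymax))) >= 0)
        assert np.all(rhs(model, ymax) <= 1e-12)


class TestSimulate:
    def test_fixed_point_initial_condition_stays_constant(self):
        m = NetworkModel(
            (Species("A", role="input", y_init=0.9, y_max=0.9),),
            (ReactionRule((), "A"),),
        )
        res = simulate(m, t_end=10.0)
        assert np.allclose(res.activities["A"], 0.9, atol=1e-7)

    def test_cascade_saturates_at_one_for_full_input(self):
        model, _ = generate_cascade(2, input_level=1.0)
        res = simulate(model, t_end=60.0)
        assert res.final_state == pytest.approx([1.0, 1.0, 1.0], abs=1e-6)

    def test_cascade_steady_state_matches_closed_form(self):
        model, expected = generate_cascade(1, input_level=0.9)
        res = run_to_steady_state(model, rel_change=1e-9, abs_change=1e-12)
        assert res.converged
        assert res.state["A1"] == pytest.approx(0.9116002377869303, abs=1e-6)
        assert res.state["A1"] == pytest.approx(expected["A1"], abs=1e-6)

    def test_tolerance_contract_against_reference_solution(self):
        """The reporting-grid activities are integrator-tolerance converged."""
        from dyrknet import engine

        model, _ = generate_cascade(3, input_level=0.7)
        a = simulate(model, t_end=20.0).activities.to_numpy()
        old = engine.REL_TOL, engine.ABS_TOL
        try:
            engine.REL_TOL, engine.ABS_TOL = old[0] / 2, old[1] / 2
            b = simulate(model, t_end=20.0).activities.to_numpy()
        finally:
            engine.REL_TOL, engine.ABS_TOL = old
        assert np.max(np.abs(a - b)) < 1e-6

    def test_rejects_nonpositive_horizon(self):
        model, _ = generate_cascade(1)
        with pytest.raises(ValueError):
            simulate(model, t_end=0.0)


class TestSteadyState:
    def test_fixed_point_converges_at_first_check(self):
        m = NetworkModel(
            (Species("A", role="input", y_init=0.9, y_max=0.9),),
            (ReactionRule((), "A"),),
        )
        res = run_to_steady_state(m)
        assert res.converged and res.t_reached == pytest.approx(1.0)

    def test_nonconvergence_reported_when_horizon_too_short(self):
        model, _ = generate_cascade(4, input_level=0.9)
        res = run_to_steady_state(model, max_time=2.0)
        assert not res.converged
        assert np.all(np.isfinite(res.state.to_numpy()))

    def test_repressilator_never_settles(self):
        """A 3-node inhibitory ring with steep Hill oscillates indefinitely."""
        res = run_to_steady_state(generate_feedback(3, n=4.0, ec50=0.35), max_time=150.0)
        assert not res.converged
        assert res.max_rel_change > 0.01  # genuine oscillation, not slow drift

    def test_two_node_ring_always_converges(self):
        """Planar logic-ODE systems cannot sustain limit cycles."""
        res = run_to_steady_state(generate_feedback(2, n=4.0, ec50=0.35))
        assert res.converged
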