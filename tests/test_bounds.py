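"""Mismatch cost, periodicity bounds, jump distributions, speed limits, TURs."""

import math

import numpy as np
import pytest

import cothermo as ct
from cothermo import bounds as B
from cothermo import fixtures as fx
from cothermo.dynamics import (
    Distribution,
    PropagatorKernel,
    period_propagator,
    steady_state,
)
from cothermo.process_model import StateSpace, ValidationError
from cothermo.thermo import CurrentSpec, integrated_ep

from conftest import random_distribution


def _kernel(space, cols):
    return PropagatorKernel(space, np.array(cols).T)  # cols given row-wise per source


class TestMismatchCost:
    def setup_method(self):
        self.space = StateSpace(("X",), {"X": ("0", "1")})

    def test_equal_distributions_cost_nothing(self):
        P = PropagatorKernel(self.space, np.array([[0.9, 0.5], [0.1, 0.5]]))
        p = np.array([0.2, 0.8])
        assert B.mismatch_cost(P, p, p) == pytest.approx(0.0, abs=1e-14)

    def test_identity_kernel_costs_nothing(self):
        P = PropagatorKernel(self.space, np.eye(2))
        assert B.mismatch_cost(P, [0.3, 0.7], [0.6, 0.4]) == pytest.approx(0.0, abs=1e-14)

    def test_hand_evaluated_example(self):
        # columns (per source): (0.9, 0.1) and (0.5, 0.5); p = (1,0), q = (1/2,1/2)
        P = PropagatorKernel(self.space, np.array([[0.9, 0.5], [0.1, 0.5]]))
        expected = math.log(2) - (
            0.9 * math.log(0.9 / 0.7) + 0.1 * math.log(0.1 / 0.3)
        )
        got = B.mismatch_cost(P, np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.5768, abs=1e-4)

    def test_unsupported_prior_flags_infinity(self):
        P = PropagatorKernel(self.space, np.eye(2))
        assert math.isinf(B.mismatch_cost(P, [0.5, 0.5], [1.0, 0.0]))

    def test_data_processing_nonnegativity(self):
        rng = np.random.default_rng(0)
        space = StateSpace(("X",), {"X": ("0", "1", "2")})
        for _ in range(50):
            P = PropagatorKernel(space, rng.dirichlet(np.ones(3), size=3).T)
            p, q = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3)) + 1e-6
            q = q / q.sum()
            assert B.mismatch_cost(P, p, q) >= -1e-12


class TestJensenShannonDrop:
    def test_identical_members_drop_nothing(self):
        space = StateSpace(("X",), {"X": ("0", "1")})
        P = PropagatorKernel(space, np.array([[0.8, 0.3], [0.2, 0.7]]))
        p = np.array([0.4, 0.6])
        assert B.jensen_shannon_drop(P, [p, p, p]) == pytest.approx(0.0, abs=1e-14)

    def test_identity_kernel_drops_nothing(self):
        space = StateSpace(("X",), {"X": ("0", "1")})
        P = PropagatorKernel(space, np.eye(2))
        members = [np.array([0.9, 0.1]), np.array([0.2, 0.8])]
        assert B.jensen_shannon_drop(P, members) == pytest.approx(0.0, abs=1e-14)

    def test_matches_numeric_prior_minimization(self):
        """ΔJS equals the minimum over priors of the expected mismatch cost."""
        rng = np.random.default_rng(3)
        space = StateSpace(("X",), {"X": ("0", "1", "2")})
        for _ in range(5):
            P = PropagatorKernel(space, rng.dirichlet(np.ones(3) * 2, size=3).T)
            members = np.stack([rng.dirichlet(np.ones(3)) for _ in range(3)])
            djs = B.jensen_shannon_drop(P, members)
            numeric, _ = B._minimize_over_prior(P.P, members)
            assert numeric / len(members) == pytest.approx(djs, abs=1e-6)

    def test_nonnegative_for_valid_kernels(self):
        rng = np.random.default_rng(9)
        space = StateSpace(("X",), {"X": ("0", "1", "2")})
        for _ in range(30):
            P = PropagatorKernel(space, rng.dirichlet(np.ones(3), size=3).T)
            members = [rng.dirichlet(np.ones(3)) for _ in range(4)]
            assert B.jensen_shannon_drop(P, members) >= -1e-12


class TestPeriodicityBound:
    def test_single_period_bound_is_zero(self, ring):
        P = period_propagator(ring, 0.4)
        p0 = Distribution(ring.state_space, [0.7, 0.2, 0.1])
        rep = B.periodicity_ep_bound(P, p0, 1)
        assert rep.components["bound_closed_form"] == pytest.approx(0.0, abs=1e-12)

    def test_stationary_start_bound_is_zero(self, ring):
        P = period_propagator(ring, 0.4)
        pi = steady_state(ring.full_generator(), ring.state_space)
        rep = B.periodicity_ep_bound(P, pi, 10)
        assert rep.components["bound_closed_form"] == pytest.approx(0.0, abs=1e-12)

    def test_numeric_infimum_agrees_with_closed_form(self, ring):
        P = period_propagator(ring, 0.4)
        p0 = Distribution(ring.state_space, [0.7, 0.2, 0.1])
        rep = B.periodicity_ep_bound(P, p0, 8)
        assert rep.components["agreement"] < 1e-6

    def test_bound_below_integrated_ep_of_realizing_ctmc(self, ring):
        """The λ-kernel of a CTMC realizes P; the bound must sit below the
        CTMC's directly integrated EP over N periods."""
        lam, N = 0.3, 10
        P = period_propagator(ring, lam)
        p0 = Distribution(ring.state_space, [0.9, 0.05, 0.05])
        rep = B.periodicity_ep_bound(P, p0, N)
        sigma, _ = integrated_ep(ring, {"R"}, p0, N * lam)
        assert 0 < rep.bound <= sigma


class TestNestedPeriodicBound:
    def test_bound_components_and_ordering(self):
        inst = fx.build_nested_periodic(3, 4, 1.0, seed=0)
        rep = B.nested_periodic_bound(inst)
        assert rep.components["minus_delta_inex_information"] >= -1e-10
        assert rep.components["djs_AB"] >= -1e-12
        assert rep.components["djs_AC"] >= -1e-12
        assert rep.bound > 0  # nondegenerate kernels, non-stationary start
        assert rep.bound <= rep.sigma + 1e-8

    def test_structural_violation_is_named(self):
        inst = fx.build_nested_periodic(3, 4, 1.0, seed=0)
        broken = fx.biased_ring()

        class Fake:
            process = broken
            p0 = Distribution.uniform(broken.state_space)
            lam_B, lam_C, m, n, tau = inst.lam_B, inst.lam_C, 3, 4, inst.tau

        with pytest.raises(ValidationError):
            B.nested_periodic_bound(Fake())

    def test_builder_rejects_bad_arithmetic(self):
        with pytest.raises(ValueError, match="coprime"):
            fx.build_nested_periodic(4, 6, 1.0, 0)
        with pytest.raises(ValueError, match="m must exceed 2"):
            fx.build_nested_periodic(2, 5, 1.0, 0)
        with pytest.raises(ValueError, match="n > m"):
            fx.build_nested_periodic(5, 4, 1.0, 0)

    def test_period_relations(self):
        inst = fx.build_nested_periodic(3, 4, 0.8, seed=1)
        assert inst.lam_B == pytest.approx(3 * 0.8 / 4, abs=1e-15)
        assert inst.tau == pytest.approx(4 * inst.lam_B, rel=1e-12)
        assert inst.tau == pytest.approx(3 * inst.lam_C, rel=1e-12)


class TestJumpDistributions:
    def test_equilibrium_jump_distributions_coincide(self, two_state):
        pi = np.array([1 / 3, 2 / 3])  # detailed balance for rates (2, 1)
        jd = B.jump_distributions(two_state, {"S"}, "m", pi)
        assert jd.d_tv == pytest.approx(0.0, abs=1e-12)
        assert jd.kl == pytest.approx(0.0, abs=1e-12)

    def test_zero_activity_flagged(self):
        from cothermo.process_model import (
            CompositeProcess,
            DependencyNetwork,
            Mechanism,
            StateSpace,
        )

        space = StateSpace(("S",), {"S": ("0", "1")})
        m = Mechanism(
            id="m",
            puppets=frozenset({"S"}),
            entries=(({"S": "0"}, {"S": "1"}, 0.0), ({"S": "1"}, {"S": "0"}, 0.0)),
        )
        proc = CompositeProcess(space, DependencyNetwork(), (m,))
        jd = B.jump_distributions(proc, {"S"}, "m", np.array([0.5, 0.5]))
        assert not jd.defined

    def test_ep_identity_and_pinsker_on_random_instances(self):
        """ζ̇ = A·D_KL(W‖W̃) exactly, and d_TV ≤ sqrt(D_KL/2) always."""
        from cothermo.thermo import ep_rate

        for s in range(10):
            proc = fx.random_composite_process(seed=s)
            p0 = random_distribution(proc, 700 + s)
            _, per = ep_rate(proc, proc.subsystem_set, p0.p)
            for m in proc.mechanisms:
                jd = B.jump_distributions(proc, proc.subsystem_set, m.id, p0.p)
                assert jd.defined
                assert jd.activity * jd.kl == pytest.approx(per[m.id], abs=1e-10)
                assert jd.d_tv <= B.PINSKER(jd.kl) + 1e-12


class TestGFunction:
    def test_pinsker_values(self):
        assert B.PINSKER(0.0) == 0.0
        assert B.PINSKER(2.0) == pytest.approx(1.0)

    def test_invalid_g_rejected(self):
        with pytest.raises(ValidationError, match="concave"):
            B.GFunction("convex", lambda x: x**2)
        with pytest.raises(ValidationError, match="g\\(0\\)"):
            B.GFunction("offset", lambda x: x + 1.0)


class TestSpeedLimits:
    def test_frozen_dynamics_saturates_trivially(self):
        inst = fx.build_nested_periodic(3, 4, 1.0, seed=2)
        # the frozen unit {A}: no internal mechanisms, nothing moves
        rep = B.speed_limit_composite(inst.process, {"A"}, inst.p0, 1.0)
        assert rep.lhs == pytest.approx(0.0, abs=1e-12)
        assert rep.rhs == pytest.approx(0.0, abs=1e-12)
        assert rep.satisfied

    def test_stationary_start_has_zero_displacement(self, ring):
        pi = steady_state(ring.full_generator(), ring.state_space)
        rep = B.speed_limit_composite(ring, {"R"}, pi, 1.0)
        assert rep.lhs == pytest.approx(0.0, abs=1e-10)
        assert rep.rhs >= 0
        assert rep.satisfied

    def test_single_mechanism_bounds_coincide(self, ring):
        p0 = Distribution(ring.state_space, [0.8, 0.1, 0.1])
        rep = B.speed_limit_global(ring, {"R"}, p0, 0.7)
        assert rep.rhs == pytest.approx(rep.extras["rhs_composite"], rel=1e-12)

    def test_chain_on_random_instances(self):
        """𝕃 ≤ mechanism-resolved rhs ≤ single-activity rhs, always."""
        for s in range(10):
            proc = fx.random_composite_process(seed=s)
            p0 = random_distribution(proc, 900 + s)
            rep = B.speed_limit_global(proc, proc.subsystem_set, p0, 0.5)
            assert rep.lhs <= rep.extras["rhs_composite"] + 1e-10
            assert rep.extras["rhs_composite"] <= rep.rhs + 1e-10
            assert rep.extras["jensen_ok"]


class TestTauLowerBound:
    def test_stationary_start_gives_zero(self, ring):
        pi = steady_state(ring.full_generator(), ring.state_space)
        per, best = B.tau_lower_bound(ring, [{"R"}], pi, 1.0)
        assert best == pytest.approx(0.0, abs=1e-9)

    def test_self_consistency_on_random_instances(self):
        for s in range(10):
            proc = fx.random_composite_process(seed=s)
            p0 = random_distribution(proc, 1100 + s)
            _, best = B.tau_lower_bound(proc, [proc.subsystem_set], p0, 0.5)
            assert 0 <= best <= 0.5 + 1e-9

    def test_single_mechanism_matches_closed_form(self, ring):
        """One mechanism and Pinsker g: τ* = 2 L² / (⟨A⟩ ζ) algebraically
        (L = sqrt(⟨A⟩ τ* ζ / 2))."""
        p0 = Distribution(ring.state_space, [0.85, 0.1, 0.05])
        tau = 0.8
        per, best = B.tau_lower_bound(ring, [{"R"}], p0, tau)
        zeta, a_tot, pw0, pw1 = B._integrate_ep_activity(ring, {"R"}, p0, tau, None)
        L = B.total_variation(pw0, pw1)
        avg = a_tot["loop"] / tau
        closed = 2 * L**2 / (avg * zeta["loop"])
        assert best == pytest.approx(closed, rel=1e-6)
        assert best <= tau


class TestFiniteTimeTUR:
    def test_equilibrium_current_is_inconclusive(self, two_state):
        spec = CurrentSpec(two_state.state_space, {(("1",), ("0",)): 1.0})
        rep = B.finite_time_tur_check(two_state, {"S"}, spec, 1.0, 500, seed=4)
        assert rep.inconclusive

    def test_biased_ring_winding_current(self):
        ring = fx.biased_ring(forward=4.0, backward=1.0)
        spec = fx.winding_current_spec(ring.state_space)
        rep = B.finite_time_tur_check(ring, {"R"}, spec, 1.0, 2000, seed=5)
        assert not rep.inconclusive
        assert rep.satisfied
        assert rep.slack_in_se > 0.0  # the 3-SE check runs at n = 10^4

    def test_mechanism_restricted_current(self):
        proc = fx.two_mechanism_two_state()
        spec = CurrentSpec(proc.state_space, {(("1",), ("0",)): 1.0}, mechanism="m1")
        rep = B.finite_time_tur_check(proc, {"S"}, spec, 2.0, 2000, seed=6)
        assert not rep.inconclusive
        assert rep.satisfied

    def test_small_sample_rejected(self, ring):
        spec = fx.winding_current_spec(ring.state_space)
        with pytest.raises(ValueError, match="n_paths"):
            B.finite_time_tur_check(ring, {"R"}, spec, 1.0, 10, seed=0)


class TestVectorTUR:
    def test_single_current_reduces_to_scalar_form(self):
        ring = fx.biased_ring(4, 6.0, 1.0)
        spec = fx.winding_current_spec(ring.state_space)
        rep = B.vector_tur_check(ring, {"R"}, [spec], 1.0, 2000, seed=7)
        # ⟨C⟩²/Var ≤ σ/2 is the scalar TUR rearranged
        assert rep.satisfied

    def test_two_currents_on_four_state_ring(self):
        ring = fx.biased_ring(4, 6.0, 1.0)
        s1 = fx.winding_current_spec(ring.state_space)
        s2 = CurrentSpec(ring.state_space, {(("1",), ("0",)): 1.0})
        rep = B.vector_tur_check(ring, {"R"}, [s1, s2], 1.0, 3000, seed=8)
        assert rep.satisfied
        assert rep.se is not None and rep.se > 0

    def test_duplicated_current_is_singular(self):
        ring = fx.biased_ring(4, 6.0, 1.0)
        spec = fx.winding_current_spec(ring.state_space)
        with pytest.raises(ValidationError, match="linearly dependent"):
            B.vector_tur_check(ring, {"R"}, [spec, spec], 1.0, 500, seed=9)


class TestInfoFlowTUR:
    def test_independent_blocks_inconclusive(self):
        proc = fx.random_composite_process(seed=4, mpp=True, density=0.0)
        names = proc.state_space.subsystems
        from cothermo.process_model import closure_and_validate_structure

        st_ = closure_and_validate_structure(proc, [{s} for s in names])
        out = B.info_flow_tur_check(proc, st_, {names[0]}, {names[1]}, 1.0, 400, seed=3)
        assert all(r.inconclusive for r in out["reports"].values())

    def test_sensor_like_instance_smallest_unit(self):
        """Hub-leaf pair: the flow A→B is a real current at NESS and the TUR
        holds against the EP of the smallest containing unit."""
        proc = fx.random_overlapping_units_process(seed=23)
        from cothermo.process_model import closure_and_validate_structure

        st_ = closure_and_validate_structure(proc, [{"A", "B"}, {"A", "C"}])
        out = B.info_flow_tur_check(proc, st_, {"A"}, {"B"}, 4.0, 3000, seed=10)
        assert out["smallest_unit"] == frozenset({"A", "B"})
        small = out["reports"][frozenset({"A", "B"})]
        assert not small.inconclusive
        assert small.satisfied
        # larger containing units have at least the EP of the smaller one
        full = out["reports"][frozenset({"A", "B", "C"})]
        assert full.lhs >= small.lhs - 1e-12
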