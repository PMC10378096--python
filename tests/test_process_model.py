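"""Structural layer: leader sets, generators, units, structures, config I/O."""

import itertools
import json

import numpy as np
import pytest

from cothermo import fixtures as fx
from cothermo.process_model import (
    CompositeProcess,
    DependencyNetwork,
    Mechanism,
    StateSpace,
    ValidationError,
    closure_and_validate_structure,
    leader_set,
)


def _flip_mech(mid, sub, read=(), rates=(1.0, 1.0)):
    """Binary flip of `sub`, optionally reading extra subsystems (wildcarded)."""
    entries = []
    for extra in itertools.product("01", repeat=len(read)):
        base = dict(zip(read, extra))
        entries.append(({**base, sub: "0"}, {sub: "1"}, rates[0]))
        entries.append(({**base, sub: "1"}, {sub: "0"}, rates[1]))
    return Mechanism(id=mid, puppets=frozenset({sub}), entries=tuple(entries))


class TestLeaderSet:
    def test_puppets_with_declared_parents(self):
        # puppet {A,C,D} with B a parent of a puppet member: leaders ABCD
        proc = fx.build_fig2_network()
        assert proc.leader_set("v2") == frozenset("ABCD")
        assert proc.mechanism("v2").puppets < proc.leader_set("v2")

    def test_no_parents_leader_equals_puppet(self):
        dep = DependencyNetwork()
        m = Mechanism(id="m", puppets=frozenset({"A"}), entries=())
        assert leader_set(m, dep) == frozenset({"A"})

    def test_only_parents_not_grandparents(self):
        dep = DependencyNetwork(frozenset({("B", "A"), ("C", "B")}))
        m = Mechanism(id="m", puppets=frozenset({"A"}), entries=())
        assert leader_set(m, dep) == frozenset({"A", "B"})


class TestGenerators:
    def test_columns_sum_to_zero(self):
        for s in range(5):
            proc = fx.random_composite_process(seed=s)
            K = proc.full_generator(0.0)
            assert np.max(np.abs(K.sum(axis=0))) < 1e-10
            for m in proc.mechanisms:
                Km = proc.mechanism_generator(m.id)
                assert np.max(np.abs(Km.sum(axis=0))) < 1e-10

    def test_offdiagonal_support_respects_puppets(self):
        proc = fx.random_composite_process(seed=2)
        states = proc.state_space.states()
        for m in proc.mechanisms:
            K = proc.mechanism_generator(m.id)
            outside = [
                k
                for k, s in enumerate(proc.state_space.subsystems)
                if s not in m.puppets
            ]
            for i, j in zip(*np.nonzero(K)):
                if i == j:
                    continue
                assert all(states[i][k] == states[j][k] for k in outside)

    def test_full_generator_is_sum_of_mechanisms(self):
        proc = fx.random_composite_process(seed=7)
        total = sum(proc.mechanism_generator(m.id) for m in proc.mechanisms)
        assert np.allclose(proc.full_generator(0.0), total, atol=1e-12)

    def test_brute_force_assembly_matches(self):
        """Assemble the generator straight from the rate entries, bypassing
        the compiled-table path, and compare."""
        proc = fx.random_overlapping_units_process(seed=4)
        space = proc.state_space
        states = space.states()
        index = space.index()
        K = np.zeros((len(states), len(states)))
        for mech in proc.mechanisms:
            for src_map, tgt_map, rate in mech.entries:
                for j, x in enumerate(states):
                    if any(x[space.subsystems.index(s)] != v for s, v in src_map.items()):
                        continue
                    y = list(x)
                    for s, v in tgt_map.items():
                        y[space.subsystems.index(s)] = v
                    if tuple(y) == x:
                        continue
                    K[index[tuple(y)], j] += rate
        K[np.diag_indices_from(K)] -= K.sum(axis=0)
        assert np.allclose(K, proc.full_generator(0.0), atol=1e-12)

    def test_disjoint_puppets_disjoint_support(self):
        proc = fx.random_composite_process(seed=0, mpp=True)
        mechs = [m for m in proc.mechanisms]
        for a, b in itertools.combinations(mechs, 2):
            if a.puppets & b.puppets:
                continue
            Ka = proc.mechanism_generator(a.id).copy()
            Kb = proc.mechanism_generator(b.id).copy()
            np.fill_diagonal(Ka, 0)
            np.fill_diagonal(Kb, 0)
            assert not np.any((Ka != 0) & (Kb != 0))


class TestValidation:
    def test_irreversible_mechanism_rejected(self):
        space = StateSpace(("S",), {"S": ("0", "1")})
        m = Mechanism(
            id="bad", puppets=frozenset({"S"}), entries=(({"S": "0"}, {"S": "1"}, 1.0),)
        )
        with pytest.raises(ValidationError, match="irreversible"):
            CompositeProcess(space, DependencyNetwork(), (m,))

    def test_non_leader_reference_rejected(self):
        space = StateSpace(("A", "B"), {s: ("0", "1") for s in "AB"})
        m = Mechanism(
            id="m",
            puppets=frozenset({"A"}),
            entries=(
                ({"A": "0", "B": "0"}, {"A": "1"}, 1.0),
                ({"A": "1", "B": "0"}, {"A": "0"}, 1.0),
            ),
        )
        with pytest.raises(ValidationError, match="non-leader"):
            CompositeProcess(space, DependencyNetwork(), (m,))

    def test_undeclared_leader_reference_rejected(self):
        """Reading a coordinate outside the declared leader set is an Eq-5
        style violation even before dependence inference runs."""
        space = StateSpace(("A", "B"), {s: ("0", "1") for s in "AB"})
        entries = (
            ({"A": "0", "B": "0"}, {"B": "1"}, 1.0),
            ({"A": "0", "B": "1"}, {"B": "0"}, 1.0),
            ({"A": "1", "B": "0"}, {"B": "1"}, 3.0),
            ({"A": "1", "B": "1"}, {"B": "0"}, 3.0),
        )
        mB = Mechanism(id="mB", puppets=frozenset({"B"}), entries=entries)
        mA = _flip_mech("mA", "A")
        dep = DependencyNetwork(frozenset({("A", "B")}))
        CompositeProcess(space, dep, (mA, mB))  # declared edge present: fine
        with pytest.raises(ValidationError, match="non-leader"):
            CompositeProcess(space, DependencyNetwork(), (mA, mB))

    def test_missing_inferred_edge_rejected(self):
        """A joint-puppet mechanism whose rates vary with the source state
        realizes co-puppet dependence; it must be declared."""
        space = StateSpace(("A", "B"), {s: ("0", "1") for s in "AB"})
        entries = (
            ({"A": "0", "B": "0"}, {"A": "1", "B": "1"}, 1.0),
            ({"A": "1", "B": "1"}, {"A": "0", "B": "0"}, 2.0),
            ({"A": "0", "B": "1"}, {"A": "1", "B": "0"}, 3.0),
            ({"A": "1", "B": "0"}, {"A": "0", "B": "1"}, 4.0),
        )
        joint = Mechanism(id="joint", puppets=frozenset({"A", "B"}), entries=entries)
        both = DependencyNetwork(frozenset({("A", "B"), ("B", "A")}))
        CompositeProcess(space, both, (joint,))  # declared: fine
        with pytest.raises(ValidationError, match="missing inferred"):
            CompositeProcess(space, DependencyNetwork(), (joint,))

    def test_over_declared_edge_warns(self):
        space = StateSpace(("A", "B"), {s: ("0", "1") for s in "AB"})
        dep = DependencyNetwork(frozenset({("A", "B")}))
        mA = _flip_mech("mA", "A")
        mB = _flip_mech("mB", "B")  # rates ignore A
        with pytest.warns(UserWarning, match="over-declared"):
            CompositeProcess(space, dep, (mA, mB))

    def test_tiny_domain_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            StateSpace(("A",), {"A": ("0",)})

    def test_dependency_self_loop_rejected(self):
        with pytest.raises(ValidationError, match="self-loop"):
            DependencyNetwork(frozenset({("A", "A")}))


class TestUnits:
    def test_full_system_is_a_unit(self, overlap):
        ok, bad = overlap.is_unit(overlap.subsystem_set)
        assert ok and not bad

    def test_dependent_singleton_is_not_a_unit(self, overlap):
        # B has parent A, and vB's leader set {A,B} is not inside {B}
        ok, bad = overlap.is_unit({"B"})
        assert not ok and "vB" in bad

    def test_units_closed_under_union_and_intersection(self):
        for s in range(5):
            proc = fx.random_composite_process(n_subsystems=4, n_mechanisms=3, seed=s)
            names = proc.state_space.subsystems
            units = [
                frozenset(c)
                for r in range(1, len(names) + 1)
                for c in itertools.combinations(names, r)
                if proc.is_unit(c)[0]
            ]
            for a, b in itertools.combinations(units, 2):
                assert proc.is_unit(a | b)[0]
                if a & b:
                    assert proc.is_unit(a & b)[0]

    def test_unit_generator_of_full_system(self, overlap):
        assert np.allclose(
            overlap.unit_generator(overlap.subsystem_set),
            overlap.full_generator(0.0),
        )

    def test_unit_generator_rejects_non_unit(self, overlap):
        with pytest.raises(ValidationError, match="not a unit"):
            overlap.unit_generator({"B"})

    def test_independent_mpp_unit_generator_is_single_subsystem(self):
        proc = fx.random_composite_process(seed=1, mpp=True, density=0.0)
        for s in proc.state_space.subsystems:
            if not proc.is_unit({s})[0]:
                continue
            Ku = proc.unit_generator({s})
            assert Ku.shape == (len(proc.state_space.domains[s]),) * 2


class TestUnitStructure:
    def test_closure_adds_intersection(self, overlap):
        st = closure_and_validate_structure(overlap, [{"A", "B"}, {"A", "C"}])
        assert [sorted(u) for u in st] == [["A"], ["A", "B"], ["A", "C"]]

    def test_single_unit_structure(self, overlap):
        st = closure_and_validate_structure(overlap, [overlap.subsystem_set])
        assert len(st) == 1

    def test_disjoint_cover_needs_no_closure(self):
        proc = fx.random_composite_process(seed=1, mpp=True, density=0.0)
        singles = [{s} for s in proc.state_space.subsystems]
        st = closure_and_validate_structure(proc, singles)
        assert len(st) == len(singles)

    def test_cover_failure_names_missing(self, overlap):
        with pytest.raises(ValidationError, match="C"):
            closure_and_validate_structure(overlap, [{"A", "B"}])


class TestDependencyInference:
    def test_roundtrip_on_builders(self):
        for proc in (
            fx.build_fig2_network(),
            fx.build_fig1b_circuit(),
            fx.random_overlapping_units_process(seed=9),
        ):
            assert proc.infer_dependency_network().edges == proc.dependency.edges

    def test_rates_ignoring_parents_have_no_external_edges(self):
        proc = fx.random_composite_process(seed=1, mpp=True, density=0.0)
        inferred = proc.infer_dependency_network()
        for j, i in inferred.edges:
            # with singleton puppets and no cross-reads, no edges at all
            raise AssertionError(f"unexpected edge {(j, i)}")


class TestNonLeaderIrrelevance:
    def test_randomizing_ignored_coordinates_keeps_generators(self):
        """Rates read the leader set only: permuting any non-leader
        coordinate of the joint state relabels generator rows/columns."""
        proc = fx.random_overlapping_units_process(seed=3)
        space = proc.state_space
        states = space.states()
        index = space.index()
        KB = proc.mechanism_generator("vB")  # leaders {A,B}; C irrelevant
        cpos = space.subsystems.index("C")
        swap = {"0": "1", "1": "0"}
        perm = [
            index[tuple(swap[c] if k == cpos else c for k, c in enumerate(x))]
            for x in states
        ]
        assert np.allclose(KB, KB[np.ix_(perm, perm)])


class TestConfigRoundTrip:
    @pytest.mark.parametrize(
        "builder",
        [
            lambda: fx.build_fig2_network(),
            lambda: fx.build_fig1b_circuit(),
            lambda: fx.build_nested_periodic(3, 4, 1.0, seed=2).process,
            lambda: fx.random_composite_process(seed=5),
        ],
    )
    def test_lossless(self, builder):
        proc = builder()
        text = proc.to_json()
        again = CompositeProcess.from_json(text)
        assert again.to_json() == text
        assert np.allclose(again.full_generator(0.0), proc.full_generator(0.0))

    def test_dot_export_mentions_everything(self, overlap):
        dot = overlap.to_dot()
        for s in overlap.state_space.subsystems:
            assert f'"{s}"' in dot
        for m in overlap.mechanisms:
            assert m.id in dot


class TestStateSpace:
    def test_lexicographic_total_order(self):
        space = StateSpace(("A", "B"), {"A": ("0", "1"), "B": ("x", "y")})
        assert space.states() == [("0", "x"), ("0", "y"), ("1", "x"), ("1", "y")]

    def test_label_roundtrip(self):
        space = StateSpace(("A", "B"), {"A": ("0", "1"), "B": ("x", "y")})
        for x in space.states():
            assert space.parse_label(space.label(x)) == x
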