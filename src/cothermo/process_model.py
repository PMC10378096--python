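"""Structural model of composite processes.

A *composite process* is a continuous-time Markov chain over the joint state
of several finite-state subsystems, in which every jump is mediated by exactly
one *mechanism* (an external reservoir or coupling).  A mechanism ``v`` may
move several subsystems at once — its *puppet set* ``P(v)`` — and its rates
may read the state of a (possibly larger) *leader set* ``L(v)``: the puppets
together with their parents in a directed *dependency network* over the
subsystems.  Multipartite processes are the special case where every puppet
set is a singleton.

This module holds the declarative model (state spaces, mechanisms, dependency
networks), its validation, and the structural analysis built on it: leader
sets, mechanism-resolved generators, *units* (subsystem subsets whose marginal
evolves autonomously) and intersection-closed *unit structures*.

Conventions
-----------
* Generator entry ``K[x, x']`` is the rate from source ``x'`` to target ``x``;
  columns sum to zero and the diagonal carries negative exit rates.
* Joint states are tuples of per-subsystem labels in declared subsystem
  order; the total order over joint states is lexicographic in subsystem
  order and per-domain label order.  States serialize as comma-joined labels.
* Rates are primitive (no Hamiltonian is modelled), ``k_B = 1`` and entropy
  is measured in nats.  Local detailed balance is the caller's concern;
  per-mechanism reversibility (a transition has positive rate iff its reverse
  does) *is* enforced, because every entropy-production formula divides by
  reverse rates.
"""

from __future__ import annotations

import itertools
import json
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "StateSpace",
    "DependencyNetwork",
    "Protocol",
    "Mechanism",
    "CompositeProcess",
    "Unit",
    "UnitStructure",
    "leader_set",
    "closure_and_validate_structure",
]


class ValidationError(ValueError):
    """A composite-process declaration violates a structural invariant."""


JointState = tuple[str, ...]


@dataclass(frozen=True)
class StateSpace:
    """Ordered subsystems with finite, ordered label domains.

    The joint space is the Cartesian product of the domains in subsystem
    order; ``states()`` enumerates it lexicographically, which fixes the
    total order used by every "x > x'" summation in this package.
    """

    subsystems: tuple[str, ...]
    domains: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.subsystems)) != len(self.subsystems):
            raise ValidationError("duplicate subsystem identifiers")
        for s in self.subsystems:
            dom = self.domains.get(s)
            if dom is None:
                raise ValidationError(f"no domain declared for subsystem {s!r}")
            if len(dom) < 2:
                raise ValidationError(f"domain of {s!r} has fewer than 2 states")
            if len(set(dom)) != len(dom):
                raise ValidationError(f"domain of {s!r} has duplicate labels")
        extra = set(self.domains) - set(self.subsystems)
        if extra:
            raise ValidationError(f"domains declared for unknown subsystems {sorted(extra)}")

    # -- enumeration ------------------------------------------------------

    @property
    def n_states(self) -> int:
        n = 1
        for s in self.subsystems:
            n *= len(self.domains[s])
        return n

    def states(self) -> list[JointState]:
        """All joint states in lexicographic (subsystem-major) order."""
        return list(itertools.product(*(self.domains[s] for s in self.subsystems)))

    def index(self) -> dict[JointState, int]:
        return {x: i for i, x in enumerate(self.states())}

    # -- projection -------------------------------------------------------

    def order(self, members: Iterable[str]) -> tuple[str, ...]:
        """The given subsystems, reordered into declared subsystem order."""
        members = set(members)
        unknown = members - set(self.subsystems)
        if unknown:
            raise ValidationError(f"unknown subsystems {sorted(unknown)}")
        return tuple(s for s in self.subsystems if s in members)

    def subspace(self, members: Iterable[str]) -> "StateSpace":
        keep = self.order(members)
        return StateSpace(keep, {s: self.domains[s] for s in keep})

    def positions(self, members: Iterable[str]) -> tuple[int, ...]:
        idx = {s: i for i, s in enumerate(self.subsystems)}
        return tuple(idx[s] for s in self.order(members))

    def project(self, state: JointState, members: Iterable[str]) -> JointState:
        return tuple(state[i] for i in self.positions(members))

    def marginal_map(self, members: Iterable[str]) -> np.ndarray:
        """Array mapping each joint-state index to its subspace index.

        Marginalizing a probability vector ``p`` onto ``members`` is then
        ``np.bincount(marginal_map, weights=p, minlength=sub.n_states)``.
        """
        sub = self.subspace(members)
        pos = self.positions(members)
        sub_index = sub.index()
        return np.array(
            [sub_index[tuple(x[i] for i in pos)] for x in self.states()], dtype=np.intp
        )

    # -- serialization ----------------------------------------------------

    def label(self, state: JointState) -> str:
        return ",".join(state)

    def parse_label(self, text: str) -> JointState:
        parts = tuple(text.split(","))
        if len(parts) != len(self.subsystems):
            raise ValidationError(f"state label {text!r} has wrong arity")
        for s, lab in zip(self.subsystems, parts):
            if lab not in self.domains[s]:
                raise ValidationError(f"label {lab!r} not in domain of {s!r}")
        return parts


@dataclass(frozen=True)
class DependencyNetwork:
    """Directed graph over subsystems; edge ``(j, i)`` reads "j modulates i".

    Self-dependency is implicit and never carries its own edge.
    """

    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        for j, i in self.edges:
            if j == i:
                raise ValidationError(f"self-loop {j!r}->{i!r} in dependency network")

    def parents(self, i: str) -> set[str]:
        return {j for j, k in self.edges if k == i}

    def validate_against(self, space: StateSpace) -> None:
        known = set(space.subsystems)
        for j, i in self.edges:
            if j not in known or i not in known:
                raise ValidationError(f"dependency edge ({j!r}, {i!r}) names unknown subsystem")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant periodic driving protocol.

    ``switch_times`` are phase boundaries within one period, starting at 0;
    phase ``k`` is active on ``[switch_times[k], switch_times[k+1])``.  Rate
    entries of a mechanism carrying a protocol may supply one value per phase.
    """

    period: float
    switch_times: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValidationError("protocol period must be positive")
        st = self.switch_times
        if not st or st[0] != 0.0:
            raise ValidationError("switch_times must start at 0.0")
        if any(b <= a for a, b in zip(st, st[1:])) or st[-1] >= self.period:
            raise ValidationError("switch_times must be strictly increasing within the period")

    @property
    def n_phases(self) -> int:
        return len(self.switch_times)

    def phase_at(self, t: float) -> int:
        s = t % self.period
        # guard against roundoff placing s at ~period
        if s >= self.period - 1e-12 * max(1.0, self.period):
            s = 0.0
        return bisect_right(self.switch_times, s + 1e-15) - 1

    def breakpoints_between(self, t0: float, t1: float) -> list[float]:
        out: list[float] = []
        k = int(np.floor(t0 / self.period)) - 1
        while k * self.period <= t1:
            for s in self.switch_times:
                t = k * self.period + s
                if t0 < t < t1:
                    out.append(t)
            k += 1
        return out


@dataclass(frozen=True)
class Mechanism:
    """One reservoir/coupling: a puppet set plus a leader-conditioned rate table.

    ``entries`` is a sequence of ``(source, target, rate)`` triples.  ``source``
    is a partial assignment over the leader set (unassigned leader coordinates
    act as wildcards), ``target`` a partial assignment over the puppet set
    (unassigned puppets keep their source value).  ``rate`` is a nonnegative
    float, or a sequence of one float per protocol phase.  Entries matching
    the same (source state, resolved target) add.
    """

    id: str
    puppets: frozenset[str]
    entries: tuple[tuple[Mapping[str, str], Mapping[str, str], object], ...]
    protocol: Protocol | None = None

    def __post_init__(self) -> None:
        if not self.puppets:
            raise ValidationError(f"mechanism {self.id!r} has an empty puppet set")

    @property
    def n_phases(self) -> int:
        return 1 if self.protocol is None else self.protocol.n_phases

    def phase_at(self, t: float) -> int:
        return 0 if self.protocol is None else self.protocol.phase_at(t)


def leader_set(mechanism: Mechanism, dependency: DependencyNetwork) -> frozenset[str]:
    """Puppets of the mechanism together with all their dependency parents."""
    out = set(mechanism.puppets)
    for i in mechanism.puppets:
        out |= dependency.parents(i)
    return frozenset(out)


@dataclass(frozen=True)
class Unit:
    """A subsystem subset whose marginal evolves under its own CTMC."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("a unit cannot be empty")


@dataclass(frozen=True)
class UnitStructure:
    """An intersection-closed family of units covering all subsystems.

    Units are kept in a canonical order (sorted member tuples) so that
    inclusion–exclusion index sums are reproducible; the sums themselves are
    order-invariant.
    """

    units: tuple[frozenset[str], ...]

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def member_sets(self) -> list[frozenset[str]]:
        return list(self.units)


# ---------------------------------------------------------------------------
# the process itself
# ---------------------------------------------------------------------------


@dataclass
class CompositeProcess:
    """A validated composite process: state space + dependency network + mechanisms.

    The full generator is, by construction, the sum of the per-mechanism
    generators, each of which conserves probability on its own.
    """

    state_space: StateSpace
    dependency: DependencyNetwork
    mechanisms: tuple[Mechanism, ...]
    _compiled: dict = field(default_factory=dict, repr=False, compare=False)
    _gen_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if isinstance(self.mechanisms, list):
            self.mechanisms = tuple(self.mechanisms)
        self.validate()

    # -- lookups ----------------------------------------------------------

    def mechanism(self, mech_id: str) -> Mechanism:
        for m in self.mechanisms:
            if m.id == mech_id:
                return m
        raise KeyError(f"unknown mechanism {mech_id!r}")

    def leader_set(self, mech: Mechanism | str) -> frozenset[str]:
        if isinstance(mech, str):
            mech = self.mechanism(mech)
        return leader_set(mech, self.dependency)

    @property
    def subsystem_set(self) -> frozenset[str]:
        return frozenset(self.state_space.subsystems)

    @property
    def is_time_dependent(self) -> bool:
        return any(m.protocol is not None for m in self.mechanisms)

    # -- validation and rate-table compilation ----------------------------

    def validate(self) -> "CompositeProcess":
        space = self.state_space
        self.dependency.validate_against(space)
        ids = [m.id for m in self.mechanisms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate mechanism identifiers")
        if not self.mechanisms:
            raise ValidationError("a composite process needs at least one mechanism")
        for mech in self.mechanisms:
            self._compile_mechanism(mech)
        # reversibility must hold phase by phase
        for mech in self.mechanisms:
            for phase in range(mech.n_phases):
                K = self._mechanism_generator_phase(mech, phase, self.subsystem_set)
                self._check_reversible(mech, K)
        self._check_declared_superset()
        return self

    def _compile_mechanism(self, mech: Mechanism) -> None:
        """Expand wildcard entries into a dense map source-config -> targets."""
        space = self.state_space
        unknown = mech.puppets - self.subsystem_set
        if unknown:
            raise ValidationError(
                f"mechanism {mech.id!r} puppet set names unknown subsystems {sorted(unknown)}"
            )
        lead = self.leader_set(mech)
        lead_order = space.order(lead)
        pup_order = space.order(mech.puppets)
        pup_pos_in_lead = [lead_order.index(s) for s in pup_order]
        n_phases = mech.n_phases

        compiled: dict[tuple, dict[tuple, np.ndarray]] = {}
        lead_domains = [space.domains[s] for s in lead_order]
        all_sources = list(itertools.product(*lead_domains))
        for source, target, rate in mech.entries:
            bad = set(source) - lead
            if bad:
                raise ValidationError(
                    f"mechanism {mech.id!r}: rate table references non-leader "
                    f"coordinates {sorted(bad)} (leader set is {sorted(lead)})"
                )
            bad = set(target) - mech.puppets
            if bad:
                raise ValidationError(
                    f"mechanism {mech.id!r}: target reassigns non-puppet coordinates {sorted(bad)}"
                )
            for s, lab in list(source.items()) + list(target.items()):
                if lab not in space.domains[s]:
                    raise ValidationError(
                        f"mechanism {mech.id!r}: label {lab!r} not in domain of {s!r}"
                    )
            if np.ndim(rate) == 0:
                vec = np.full(n_phases, float(rate))
            else:
                vec = np.asarray(rate, dtype=float)
                if vec.shape != (n_phases,):
                    raise ValidationError(
                        f"mechanism {mech.id!r}: rate vector of length {vec.size} "
                        f"does not match {n_phases} protocol phase(s)"
                    )
            if np.any(vec < 0):
                raise ValidationError(f"mechanism {mech.id!r}: negative rate")
            for src_cfg in all_sources:
                if any(src_cfg[lead_order.index(s)] != lab for s, lab in source.items()):
                    continue
                tgt_cfg = tuple(
                    target.get(s, src_cfg[pup_pos_in_lead[k]])
                    for k, s in enumerate(pup_order)
                )
                if tgt_cfg == tuple(src_cfg[k] for k in pup_pos_in_lead):
                    continue  # self-transition: no jump; diagonal comes from conservation
                tgts = compiled.setdefault(src_cfg, {})
                if tgt_cfg in tgts:
                    tgts[tgt_cfg] = tgts[tgt_cfg] + vec
                else:
                    tgts[tgt_cfg] = vec.copy()
        self._compiled[mech.id] = {
            "lead_order": lead_order,
            "pup_order": pup_order,
            "table": compiled,
        }

    def _check_reversible(self, mech: Mechanism, K: np.ndarray) -> None:
        pos = K > 0
        np.fill_diagonal(pos, False)
        if not np.array_equal(pos, pos.T):
            states = self.state_space.states()
            bad = np.argwhere(pos & ~pos.T)
            x, xp = states[bad[0][0]], states[bad[0][1]]
            raise ValidationError(
                f"mechanism {mech.id!r} is irreversible: rate "
                f"{self.state_space.label(xp)} -> {self.state_space.label(x)} is positive "
                "but its reverse is zero"
            )

    def _check_declared_superset(self) -> None:
        inferred = self.infer_dependency_network()
        missing = inferred.edges - self.dependency.edges
        if missing:
            raise ValidationError(
                "declared dependency network is missing inferred edges "
                f"{sorted(missing)} (rates vary with the parent coordinate)"
            )
        extra = self.dependency.edges - inferred.edges
        if extra:
            warnings.warn(
                f"over-declared dependency edges {sorted(extra)}: no mechanism's "
                "rates actually vary with them",
                stacklevel=3,
            )

    # -- generators -------------------------------------------------------

    def _phase_signature(self, t: float) -> tuple[int, ...]:
        return tuple(m.phase_at(t) for m in self.mechanisms)

    def _mechanism_generator_phase(
        self, mech: Mechanism, phase: int, members: frozenset[str]
    ) -> np.ndarray:
        """Mechanism generator on the marginal space of ``members`` ⊇ L(v)."""
        key = ("mech", mech.id, phase, members)
        if key in self._gen_cache:
            return self._gen_cache[key]
        comp = self._compiled[mech.id]
        lead_order, pup_order = comp["lead_order"], comp["pup_order"]
        if not set(lead_order) <= members:
            raise ValidationError(
                f"cannot restrict mechanism {mech.id!r} to {sorted(members)}: "
                f"its leader set {sorted(lead_order)} is not contained"
            )
        sub = self.state_space.subspace(members)
        states = sub.states()
        index = sub.index()
        lead_pos = sub.positions(lead_order)
        pup_pos = sub.positions(pup_order)
        n = len(states)
        K = np.zeros((n, n))
        for j, x_src in enumerate(states):
            src_cfg = tuple(x_src[p] for p in lead_pos)
            tgts = comp["table"].get(src_cfg)
            if not tgts:
                continue
            for tgt_cfg, vec in tgts.items():
                rate = float(vec[phase])
                if rate == 0.0:
                    continue
                x_tgt = list(x_src)
                for p, lab in zip(pup_pos, tgt_cfg):
                    x_tgt[p] = lab
                i = index[tuple(x_tgt)]
                K[i, j] += rate
        K[np.diag_indices_from(K)] -= K.sum(axis=0)
        self._gen_cache[key] = K
        return K

    def mechanism_generator(
        self, mech_id: str, t: float = 0.0, members: Iterable[str] | None = None
    ) -> np.ndarray:
        """Rate matrix of one mechanism at time ``t`` (entry ``[x, x']`` = rate x'→x)."""
        mech = self.mechanism(mech_id)
        members = self.subsystem_set if members is None else frozenset(members)
        return self._mechanism_generator_phase(mech, mech.phase_at(t), members)

    def full_generator(self, t: float = 0.0) -> np.ndarray:
        sig = self._phase_signature(t)
        key = ("full", sig)
        if key not in self._gen_cache:
            n = self.state_space.n_states
            K = np.zeros((n, n))
            for mech, phase in zip(self.mechanisms, sig):
                K += self._mechanism_generator_phase(mech, phase, self.subsystem_set)
            self._gen_cache[key] = K
        return self._gen_cache[key]

    def breakpoints_between(self, t0: float, t1: float) -> list[float]:
        """Protocol switching times strictly inside (t0, t1), merged and sorted."""
        times: list[float] = []
        for m in self.mechanisms:
            if m.protocol is not None:
                times.extend(m.protocol.breakpoints_between(t0, t1))
        times.sort()
        out: list[float] = []
        for t in times:
            if not out or t - out[-1] > 1e-12:
                out.append(t)
        return out

    def pieces(self, t0: float, t1: float):
        """Yield ``(a, b)`` intervals on which all generators are constant."""
        knots = [t0] + self.breakpoints_between(t0, t1) + [t1]
        for a, b in zip(knots, knots[1:]):
            if b > a:
                yield a, b

    # -- units ------------------------------------------------------------

    def unit_mechanisms(self, members: Iterable[str]) -> list[Mechanism]:
        members = frozenset(members)
        return [m for m in self.mechanisms if self.leader_set(m) <= members]

    def is_unit(self, members: Iterable[str]) -> tuple[bool, list[str]]:
        """Structural autonomy test with a certificate of violating mechanisms.

        ``members`` is a unit iff every mechanism either has its whole leader
        set inside it or touches none of its subsystems with its puppets.
        """
        members = frozenset(members)
        if not members:
            raise ValidationError("is_unit: subset must be nonempty")
        unknown = members - self.subsystem_set
        if unknown:
            raise ValidationError(f"is_unit: unknown subsystems {sorted(unknown)}")
        bad = [
            m.id
            for m in self.mechanisms
            if not (self.leader_set(m) <= members) and (m.puppets & members)
        ]
        return (not bad, bad)

    def unit_generator(self, members: Iterable[str], t: float = 0.0) -> np.ndarray:
        """Marginal generator of a unit: sum of its internal mechanism generators."""
        members = frozenset(members)
        ok, bad = self.is_unit(members)
        if not ok:
            raise ValidationError(
                f"{sorted(members)} is not a unit: mechanisms {bad} straddle its boundary "
                "(puppets inside, leaders outside)"
            )
        sub = self.state_space.subspace(members)
        K = np.zeros((sub.n_states, sub.n_states))
        for m in self.unit_mechanisms(members):
            K += self._mechanism_generator_phase(m, m.phase_at(t), members)
        return K

    def restrict_to_unit(self, members: Iterable[str]) -> "CompositeProcess":
        """A standalone composite process for the unit's marginal dynamics."""
        members = frozenset(members)
        ok, bad = self.is_unit(members)
        if not ok:
            raise ValidationError(f"{sorted(members)} is not a unit (violations: {bad})")
        sub = self.state_space.subspace(members)
        edges = frozenset((j, i) for j, i in self.dependency.edges if j in members and i in members)
        mechs = tuple(self.unit_mechanisms(members))
        if not mechs:
            raise ValidationError(
                f"unit {sorted(members)} is frozen (no internal mechanisms); "
                "it cannot be restricted to a standalone process"
            )
        return CompositeProcess(sub, DependencyNetwork(edges), mechs)

    # -- dependency inference ---------------------------------------------

    def infer_dependency_network(self) -> DependencyNetwork:
        """Edges actually realized by the rate tables.

        ``(j, i)`` is inferred iff some mechanism with ``i`` in its puppet set
        has rates that change when only the ``j``-coordinate of the source
        configuration is varied.
        """
        space = self.state_space
        edges: set[tuple[str, str]] = set()
        for mech in self.mechanisms:
            comp = self._compiled[mech.id]
            lead_order, pup_order = comp["lead_order"], comp["pup_order"]
            table = comp["table"]
            pup_pos = [lead_order.index(s) for s in pup_order]
            for jpos, j in enumerate(lead_order):
                if self._depends_on(table, lead_order, jpos, pup_pos, space):
                    for i in mech.puppets:
                        if i != j:
                            edges.add((j, i))
        return DependencyNetwork(frozenset(edges))

    @staticmethod
    def _depends_on(table, lead_order, jpos, pup_pos, space) -> bool:
        """Do rates vary when only the ``jpos`` source coordinate is varied?

        Rate functions are compared on the targets reachable from *all*
        sources in a comparison group: a target equal to some group member's
        own puppet configuration is excluded, because "stay put" is not a
        jump and its absence from a table carries no rate information.
        """
        domains = [space.domains[s] for s in lead_order]
        groups: dict[tuple, list[tuple]] = {}
        for src_cfg in itertools.product(*domains):
            key = src_cfg[:jpos] + src_cfg[jpos + 1 :]
            groups.setdefault(key, []).append(src_cfg)
        for members in groups.values():
            selfs = {tuple(c[k] for k in pup_pos) for c in members}
            maps = []
            for src_cfg in members:
                tgts = table.get(src_cfg, {})
                maps.append(
                    {t: tuple(v) for t, v in tgts.items() if t not in selfs}
                )
            if any(m != maps[0] for m in maps[1:]):
                return True
        return False

    # -- config round-trip -------------------------------------------------

    def to_config(self) -> dict:
        cfg: dict = {
            "subsystems": [
                {"id": s, "states": list(self.state_space.domains[s])}
                for s in self.state_space.subsystems
            ],
            "dependencies": sorted([list(e) for e in self.dependency.edges]),
            "mechanisms": [],
        }
        for m in self.mechanisms:
            entry: dict = {
                "id": m.id,
                "puppets": sorted(m.puppets),
                "rates": [
                    {
                        "from": dict(sorted(src.items())),
                        "to": dict(sorted(tgt.items())),
                        "rate": (float(r) if np.ndim(r) == 0 else [float(v) for v in r]),
                    }
                    for src, tgt, r in m.entries
                ],
            }
            if m.protocol is not None:
                entry["protocol"] = {
                    "period": m.protocol.period,
                    "switch_times": list(m.protocol.switch_times),
                }
            cfg["mechanisms"].append(entry)
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping) -> "CompositeProcess":
        space = StateSpace(
            tuple(s["id"] for s in cfg["subsystems"]),
            {s["id"]: tuple(s["states"]) for s in cfg["subsystems"]},
        )
        dep = DependencyNetwork(frozenset(tuple(e) for e in cfg.get("dependencies", [])))
        mechs = []
        for mc in cfg["mechanisms"]:
            proto = None
            if "protocol" in mc:
                proto = Protocol(
                    period=float(mc["protocol"]["period"]),
                    switch_times=tuple(float(t) for t in mc["protocol"]["switch_times"]),
                )
            entries = tuple(
                (dict(r["from"]), dict(r["to"]), r["rate"]) for r in mc["rates"]
            )
            mechs.append(
                Mechanism(
                    id=mc["id"],
                    puppets=frozenset(mc["puppets"]),
                    entries=entries,
                    protocol=proto,
                )
            )
        return cls(space, dep, tuple(mechs))

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_config(), indent=kw.pop("indent", 2), **kw)

    @classmethod
    def from_json(cls, text: str) -> "CompositeProcess":
        return cls.from_config(json.loads(text))

    # -- DOT export --------------------------------------------------------

    def to_dot(self) -> str:
        """Graphviz DOT: dependency edges plus puppet sets as clusters."""
        lines = ["digraph dependency {"]
        for s in self.state_space.subsystems:
            lines.append(f'  "{s}";')
        for j, i in sorted(self.dependency.edges):
            lines.append(f'  "{j}" -> "{i}";')
        for k, m in enumerate(self.mechanisms):
            lines.append(f"  subgraph cluster_{k} {{")
            lines.append(f'    label="puppets of {m.id}"; style=dashed;')
            for s in sorted(m.puppets):
                lines.append(f'    "{s}";')
            lines.append("  }")
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# unit structures
# ---------------------------------------------------------------------------


def closure_and_validate_structure(
    process: CompositeProcess, units: Iterable[Iterable[str]]
) -> UnitStructure:
    """Close a family of verified units under intersection and check the cover.

    Every input subset must pass :meth:`CompositeProcess.is_unit`.  Nonempty
    pairwise intersections are added until closure (intersections of units
    are themselves units; a failure of that here indicates an internal bug
    and raises accordingly).  Units come back in canonical order: sorted by
    their member tuple in subsystem order.
    """
    fam: set[frozenset[str]] = set()
    for u in units:
        u = frozenset(u)
        ok, bad = process.is_unit(u)
        if not ok:
            raise ValidationError(f"{sorted(u)} is not a unit (violating mechanisms: {bad})")
        fam.add(u)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(fam), 2):
            c = a & b
            if c and c not in fam:
                ok, bad = process.is_unit(c)
                if not ok:  # pragma: no cover - impossible for valid units
                    raise RuntimeError(
                        f"internal consistency error: intersection {sorted(c)} of two "
                        f"units is not a unit (violations: {bad})"
                    )
                fam.add(c)
                changed = True
    covered = frozenset().union(*fam) if fam else frozenset()
    uncovered = process.subsystem_set - covered
    if uncovered:
        raise ValidationError(
            f"unit family does not cover the system: {sorted(uncovered)} uncovered"
        )
    order = {s: k for k, s in enumerate(process.state_space.subsystems)}
    canon = sorted(fam, key=lambda u: tuple(sorted(order[s] for s in u)))
    return UnitStructure(tuple(canon))
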