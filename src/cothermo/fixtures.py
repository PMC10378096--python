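"""Builders for worked examples, random ensembles, and benchmark instances.

Everything here is generated programmatically and reproducibly: the toy
reaction network and circuit, the dependency-network illustration, the
frozen-hub nested-periodic three-subsystem system used by the composite
periodicity bound, biased rings and two-mechanism systems for uncertainty
relations, and seeded random composite processes for property suites.

Where a figure in the source material fixes only topology, rate values are
documented placeholder constants (1.0 unless stated); where a builder must
assume structure a figure does not pin down, the assumption is stated in its
docstring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crn import parse_crn, crn_to_process
from .dynamics import Distribution, PropagatorKernel, period_propagator
from .process_model import (
    CompositeProcess,
    DependencyNetwork,
    Mechanism,
    Protocol,
    StateSpace,
    ValidationError,
)
from .thermo import CurrentSpec

__all__ = [
    "FIG1A_CRN_TEXT",
    "build_fig1a_crn",
    "build_fig1b_circuit",
    "build_fig2_network",
    "NestedPeriodicInstance",
    "build_nested_periodic",
    "random_composite_process",
    "random_overlapping_units_process",
    "biased_ring",
    "winding_current_spec",
    "two_mechanism_two_state",
]


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

#: Four species, three reversible reactions; reaction 1 changes X1, X2, X3
#: together by (−2, −1, +1).  Rate constants are placeholder 1.0: the toy
#: network fixes topology, not numerics.
FIG1A_CRN_TEXT = """\
2 X1 + 1 X2 <-> 1 X3 , 1.0 , 1.0
1 X3 <-> 1 X4 , 1.0 , 1.0
1 X2 + 1 X4 <-> 1 X1 , 1.0 , 1.0
"""


def build_fig1a_crn(cap: int = 5) -> CompositeProcess:
    """The toy stochastic CRN as a composite process on a truncated count box."""
    return crn_to_process(parse_crn(FIG1A_CRN_TEXT), caps=cap)


def build_fig1b_circuit(n_levels: int = 3) -> CompositeProcess:
    """A toy circuit: two free conductors, three devices.

    Conductors 2 and 3 carry a discretized voltage (``n_levels`` levels);
    conductors 1 and 4 are regulated (tied to fixed sources) and enter only
    as implicit constants in the rates.  Assumed incidence — the source
    figure fixes only the count of devices: device A steps conductor 2,
    device C steps conductor 3, device B shifts both together.  All rates
    are placeholder 1.0.
    """
    levels = tuple(str(i) for i in range(n_levels))
    space = StateSpace(("2", "3"), {"2": levels, "3": levels})
    up = [(str(i), str(i + 1)) for i in range(n_levels - 1)]

    def stepper(mid: str, sub: str) -> Mechanism:
        entries = []
        for lo, hi in up:
            entries.append(({sub: lo}, {sub: hi}, 1.0))
            entries.append(({sub: hi}, {sub: lo}, 1.0))
        return Mechanism(id=mid, puppets=frozenset({sub}), entries=tuple(entries))

    joint_entries = []
    for lo2, hi2 in up:
        for lo3, hi3 in up:
            joint_entries.append(({"2": lo2, "3": lo3}, {"2": hi2, "3": hi3}, 1.0))
            joint_entries.append(({"2": hi2, "3": hi3}, {"2": lo2, "3": lo3}, 1.0))
    dev_b = Mechanism(id="deviceB", puppets=frozenset({"2", "3"}), entries=tuple(joint_entries))
    dep = DependencyNetwork(frozenset({("2", "3"), ("3", "2")}))
    return CompositeProcess(space, dep, (stepper("deviceA", "2"), dev_b, stepper("deviceC", "3")))


def build_fig2_network() -> CompositeProcess:
    """The dependency-network illustration: a mechanism with a strictly larger leader set.

    Subsystems A, B, C, D (binary).  Mechanism ``v1`` flips B on its own;
    mechanism ``v2`` jointly flips its puppet set {A, C, D} at a rate
    modulated by the state of B, so its leader set is {A, B, C, D} — a
    proper superset of its puppets.  Rates are validated placeholders
    (1.0, doubled when B is up).
    """
    sub = ("A", "B", "C", "D")
    space = StateSpace(sub, {s: ("0", "1") for s in sub})
    v1 = Mechanism(
        id="v1",
        puppets=frozenset({"B"}),
        entries=(({"B": "0"}, {"B": "1"}, 1.0), ({"B": "1"}, {"B": "0"}, 1.0)),
    )
    flip = {"0": "1", "1": "0"}
    entries = []
    for b, rate in (("0", 1.0), ("1", 2.0)):
        for a in "01":
            for c in "01":
                for d in "01":
                    entries.append(
                        (
                            {"A": a, "B": b, "C": c, "D": d},
                            {"A": flip[a], "C": flip[c], "D": flip[d]},
                            rate,
                        )
                    )
    v2 = Mechanism(id="v2", puppets=frozenset({"A", "C", "D"}), entries=tuple(entries))
    edges = {("B", "A"), ("B", "C"), ("B", "D")}
    for i in ("A", "C", "D"):
        for j in ("A", "C", "D"):
            if i != j:
                edges.add((j, i))
    return CompositeProcess(space, DependencyNetwork(frozenset(edges)), (v1, v2))


# ---------------------------------------------------------------------------
# the nested-periodic instance
# ---------------------------------------------------------------------------


@dataclass
class NestedPeriodicInstance:
    """Frozen hub A; B and C periodically driven with commensurate periods.

    ``lam_B = m·lam_C/n`` with m, n coprime and n > m > 2; the overall
    system is periodic with ``tau = n·lam_B = m·lam_C``.  ``kernel_AB`` and
    ``kernel_AC`` are the per-period propagators of the units AB and AC.
    """

    process: CompositeProcess
    p0: Distribution
    lam_B: float
    lam_C: float
    m: int
    n: int
    tau: float
    kernel_AB: PropagatorKernel
    kernel_AC: PropagatorKernel
    seed: int


def build_nested_periodic(m: int, n: int, lam_C: float = 1.0, seed: int = 0) -> NestedPeriodicInstance:
    """Build the three-subsystem nested-periodic system.

    A is frozen (no mechanism moves it) but modulates the flip rates of both
    B and C, so {A}, {A,B} and {A,C} are the units of a unit structure.
    Each of B and C is driven by a two-phase piecewise-constant protocol
    with period ``lam_B`` resp. ``lam_C``; flip rates per hub state and
    phase are drawn from ``[0.5, 2.0]`` with the given seed, making both
    period kernels strictly positive (nondegenerate).
    """
    if m <= 2:
        raise ValueError("m must exceed 2 (the constraint m > 2 of the nested construction)")
    if n <= m:
        raise ValueError("need n > m")
    if math.gcd(m, n) != 1:
        raise ValueError(f"m={m} and n={n} must be coprime")
    if lam_C <= 0:
        raise ValueError("lam_C must be positive")
    lam_B = m * lam_C / n
    tau = m * lam_C
    if abs(n * lam_B - tau) > 1e-12 * tau:  # pragma: no cover - float sanity
        raise AssertionError("period arithmetic failed")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 331]))
    space = StateSpace(("A", "B", "C"), {s: ("0", "1") for s in "ABC"})

    def driven_flip(mid: str, sub: str, period: float) -> Mechanism:
        proto = Protocol(period=period, switch_times=(0.0, period / 2.0))
        entries = []
        for a in "01":
            for lo, hi in (("0", "1"), ("1", "0")):
                rates = tuple(rng.uniform(0.5, 2.0, size=2))
                entries.append(({"A": a, sub: lo}, {sub: hi}, rates))
        return Mechanism(id=mid, puppets=frozenset({sub}), entries=tuple(entries), protocol=proto)

    vB = driven_flip("vB", "B", lam_B)
    vC = driven_flip("vC", "C", lam_C)
    dep = DependencyNetwork(frozenset({("A", "B"), ("A", "C")}))
    proc = CompositeProcess(space, dep, (vB, vC))
    p0 = Distribution(space, rng.dirichlet(np.ones(space.n_states)))
    kernel_AB = period_propagator(proc, lam_B, unit={"A", "B"})
    kernel_AC = period_propagator(proc, lam_C, unit={"A", "C"})
    return NestedPeriodicInstance(
        proc, p0, lam_B, lam_C, m, n, tau, kernel_AB, kernel_AC, seed
    )


# ---------------------------------------------------------------------------
# random ensembles
# ---------------------------------------------------------------------------

_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def random_composite_process(
    n_subsystems: int = 3,
    n_mechanisms: int = 3,
    max_states: int = 2,
    density: float = 0.3,
    seed: int = 0,
    *,
    mpp: bool = False,
) -> CompositeProcess:
    """A seeded random composite process that always passes validation.

    Puppet sets are random (singletons when ``mpp=True``) and jointly cover
    all subsystems; dependency edges are drawn with probability ``density``
    on top of the intra-puppet edges realized by the dense rate tables;
    every (source, target) rate is drawn strictly positive, which makes
    each mechanism reversible by construction.
    """
    if n_subsystems > len(_NAMES):
        raise ValueError("too many subsystems for letter naming")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    names = tuple(_NAMES[:n_subsystems])
    domains = {
        s: tuple(str(i) for i in range(rng.integers(2, max_states + 1)))
        if max_states > 2
        else ("0", "1")
        for s in names
    }
    space = StateSpace(names, domains)

    # puppet sets: cover every subsystem, then sprinkle extras
    if mpp:
        # one singleton per subsystem (the cover requires it), padded with
        # extra singleton mechanisms if more were requested
        puppets: list[set[str]] = [{s} for s in names]
        while len(puppets) < n_mechanisms:
            puppets.append({names[int(rng.integers(0, n_subsystems))]})
    else:
        puppets = [set() for _ in range(n_mechanisms)]
        for k, s in enumerate(names):
            puppets[k % n_mechanisms].add(s)
        for k in range(n_mechanisms):
            if not puppets[k]:
                puppets[k].add(names[int(rng.integers(0, n_subsystems))])
            for s in names:
                if s not in puppets[k] and rng.random() < density:
                    puppets[k].add(s)

    edges: set[tuple[str, str]] = set()
    for p in puppets:
        for i in p:
            for j in p:
                if i != j:
                    edges.add((j, i))
    for j in names:
        for i in names:
            if i != j and rng.random() < density:
                # only meaningful if i sits in some puppet set (always true)
                edges.add((j, i))
    # dense rate tables read every leader coordinate, and a mechanism's
    # dependence on j is an edge to each of its puppets; close to a fixpoint
    # (adding edges can enlarge leader sets, which adds dependence)
    while True:
        new = set(edges)
        for p in puppets:
            lead = set(p)
            for i in p:
                lead |= {j for j, t in new if t == i}
            for j in lead:
                for i in p:
                    if j != i:
                        new.add((j, i))
        if new == edges:
            break
        edges = new
    dep = DependencyNetwork(frozenset(edges))

    import itertools

    mechs = []
    for k, pup in enumerate(puppets):
        pup_f = frozenset(pup)
        lead = set(pup)
        for i in pup:
            lead |= {j for j, t in edges if t == i}
        lead_order = space.order(lead)
        pup_order = space.order(pup)
        entries = []
        for src in itertools.product(*(domains[s] for s in lead_order)):
            src_pup = tuple(src[lead_order.index(s)] for s in pup_order)
            for tgt in itertools.product(*(domains[s] for s in pup_order)):
                if tgt == src_pup:
                    continue
                entries.append(
                    (
                        dict(zip(lead_order, src)),
                        dict(zip(pup_order, tgt)),
                        float(rng.uniform(0.2, 1.2)),
                    )
                )
        mechs.append(Mechanism(id=f"v{k + 1}", puppets=pup_f, entries=tuple(entries)))
    return CompositeProcess(space, dep, tuple(mechs))


def random_overlapping_units_process(seed: int = 0, leaves: tuple[str, ...] = ("B", "C")) -> CompositeProcess:
    """A random hub-and-leaves process admitting the unit structure {A, AB, AC, ...}.

    Binary subsystems: an autonomous hub A (its flip rates read only A) and
    one leaf mechanism per leaf whose flip rates read the hub and the leaf.
    Structurally this is exactly the ensemble on which {A} ∪ {{A, leaf}}
    forms an intersection-closed covering family of units.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 613]))
    names = ("A",) + tuple(leaves)
    space = StateSpace(names, {s: ("0", "1") for s in names})

    def flip_entries(read: tuple[str, ...], target_sub: str):
        import itertools

        entries = []
        for cfg in itertools.product("01", repeat=len(read)):
            src = dict(zip(read, cfg))
            cur = src[target_sub]
            entries.append((src, {target_sub: "1" if cur == "0" else "0"},
                            float(rng.uniform(0.3, 1.5))))
        return tuple(entries)

    mechs = [Mechanism(id="vA", puppets=frozenset({"A"}), entries=flip_entries(("A",), "A"))]
    edges = set()
    for leaf in leaves:
        mechs.append(
            Mechanism(
                id=f"v{leaf}",
                puppets=frozenset({leaf}),
                entries=flip_entries(("A", leaf), leaf),
            )
        )
        edges.add(("A", leaf))
    return CompositeProcess(space, DependencyNetwork(frozenset(edges)), tuple(mechs))


# ---------------------------------------------------------------------------
# uncertainty-relation workhorses
# ---------------------------------------------------------------------------


def biased_ring(n_states: int = 3, forward: float = 2.0, backward: float = 1.0) -> CompositeProcess:
    """A single-subsystem ring with uniform bias: the classic NESS current system."""
    labels = tuple(str(i) for i in range(n_states))
    space = StateSpace(("R",), {"R": labels})
    entries = []
    for i in range(n_states):
        nxt = labels[(i + 1) % n_states]
        entries.append(({"R": labels[i]}, {"R": nxt}, forward))
        entries.append(({"R": nxt}, {"R": labels[i]}, backward))
    mech = Mechanism(id="loop", puppets=frozenset({"R"}), entries=tuple(entries))
    return CompositeProcess(space, DependencyNetwork(), (mech,))


def winding_current_spec(space: StateSpace, mechanism: str | None = None) -> CurrentSpec:
    """Weight +1 on each forward ring edge: the integrated net number of forward hops."""
    labels = space.domains[space.subsystems[0]]
    n = len(labels)
    weights = {}
    for i in range(n):
        src = (labels[i],)
        tgt = (labels[(i + 1) % n],)
        weights[(tgt, src)] = 1.0
        weights[(src, tgt)] = -1.0
    return CurrentSpec(space, weights, mechanism=mechanism)


def two_mechanism_two_state(
    k1_up: float = 2.0, k1_dn: float = 1.0, k2_up: float = 0.5, k2_dn: float = 1.5
) -> CompositeProcess:
    """One binary subsystem driven by two competing mechanisms.

    With different up/down ratios the two mechanisms fight, producing a NESS
    with a nonzero mechanism-resolved cycle current even though the state
    space is only two states — the minimal testbed for mechanism-restricted
    uncertainty relations.
    """
    space = StateSpace(("S",), {"S": ("0", "1")})

    def mk(mid, up, dn):
        return Mechanism(
            id=mid,
            puppets=frozenset({"S"}),
            entries=(({"S": "0"}, {"S": "1"}, up), ({"S": "1"}, {"S": "0"}, dn)),
        )

    return CompositeProcess(
        space, DependencyNetwork(), (mk("m1", k1_up, k1_dn), mk("m2", k2_up, k2_dn))
    )
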