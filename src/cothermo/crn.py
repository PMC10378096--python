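"""Mass-action reaction networks compiled to composite processes.

A stochastic chemical reaction network with species counts as state is the
canonical composite process that is *not* multipartite: one reaction firing
changes several counts at once, so each reaction becomes one mechanism whose
puppet set is the set of net-changed species.  Propensities follow the
standard stochastic mass-action law ``k · ∏_s n_s!/(n_s − a_s)!`` (falling
factorials over reactant stoichiometries).

Counts are truncated to a finite box ``0..cap`` per species.  Truncation is
reflecting: a transition whose target leaves the box is deleted, and because
the falling-factorial zeros of a forward jump and of its reverse coincide
inside the box, the truncated process keeps per-mechanism reversibility.

Text format, one reversible reaction per line::

    2 X1 + 1 X2 <-> 1 X3 , 1.0 , 1.0

Coefficients default to 1; ``#`` starts a comment.  Irreversible reactions
(nonpositive backward constant) are rejected: every entropy-production
formula downstream divides by reverse rates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .process_model import (
    CompositeProcess,
    DependencyNetwork,
    Mechanism,
    StateSpace,
    ValidationError,
)

__all__ = ["Reaction", "ReactionNetwork", "parse_crn", "serialize_crn", "crn_to_process"]


class CRNParseError(ValidationError):
    pass


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[tuple[str, int], ...]  # (species, stoichiometric coefficient)
    products: tuple[tuple[str, int], ...]
    kf: float
    kr: float

    def net_change(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for s, c in self.reactants:
            net[s] = net.get(s, 0) - c
        for s, c in self.products:
            net[s] = net.get(s, 0) + c
        return {s: d for s, d in net.items() if d != 0}

    def participants(self) -> list[str]:
        seen: list[str] = []
        for s, _ in self.reactants + self.products:
            if s not in seen:
                seen.append(s)
        return seen


@dataclass
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Columns are reactions, rows species; entries are net changes."""
        S = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        idx = {s: i for i, s in enumerate(self.species)}
        for j, r in enumerate(self.reactions):
            for s, d in r.net_change().items():
                S[idx[s], j] = d
        return S

    def conservation_laws(self) -> np.ndarray:
        """A basis of left null vectors of the stoichiometric matrix."""
        from scipy.linalg import null_space

        ns = null_space(self.stoichiometric_matrix().T.astype(float))
        return ns.T


_SIDE_RE = re.compile(r"^\s*(?:(\d+)\s+)?(\S+)\s*$")


def _parse_side(text: str, line_no: int) -> tuple[tuple[str, int], ...]:
    terms = []
    for part in text.split("+"):
        m = _SIDE_RE.match(part)
        if not m:
            raise CRNParseError(f"line {line_no}: malformed species term {part.strip()!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff <= 0:
            raise CRNParseError(f"line {line_no}: nonpositive stoichiometry")
        terms.append((m.group(2), coeff))
    return tuple(terms)


def parse_crn(text: str) -> ReactionNetwork:
    """Parse the reaction-list text format; species order is first appearance."""
    species: list[str] = []
    reactions: list[Reaction] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            lhs_rhs, kf_s, kr_s = (p.strip() for p in line.rsplit(",", 2))
        except ValueError:
            raise CRNParseError(f"line {line_no}: expected 'reaction , kf , kr'") from None
        if "<->" not in lhs_rhs:
            raise CRNParseError(f"line {line_no}: missing '<->' (reactions must be reversible)")
        lhs, rhs = lhs_rhs.split("<->", 1)
        reactants = _parse_side(lhs, line_no)
        products = _parse_side(rhs, line_no)
        try:
            kf, kr = float(kf_s), float(kr_s)
        except ValueError:
            raise CRNParseError(f"line {line_no}: rate constants must be numbers") from None
        if kf <= 0 or kr <= 0:
            raise CRNParseError(
                f"line {line_no}: irreversible reaction (both rate constants must be positive)"
            )
        for s, _ in reactants + products:
            if s not in species:
                species.append(s)
        reactions.append(Reaction(reactants, products, kf, kr))
    if not reactions:
        raise CRNParseError("empty reaction network")
    return ReactionNetwork(tuple(species), tuple(reactions))


def serialize_crn(network: ReactionNetwork) -> str:
    lines = []
    for r in network.reactions:
        lhs = " + ".join(f"{c} {s}" for s, c in r.reactants)
        rhs = " + ".join(f"{c} {s}" for s, c in r.products)
        lines.append(f"{lhs} <-> {rhs} , {r.kf!r} , {r.kr!r}")
    return "\n".join(lines) + "\n"


def _falling_factorial(n: int, k: int) -> int:
    out = 1
    for i in range(k):
        out *= n - i
        if out <= 0:
            return 0
    return out


def crn_to_process(network: ReactionNetwork, caps: int | dict = 5) -> CompositeProcess:
    """Compile a reaction network to a composite process on a truncated count box.

    One mechanism per reaction; puppet set = net-changed species; rates are
    stochastic mass-action propensities.  ``caps`` is the maximum count,
    globally or per species; it must be at least each reaction's largest
    single-step change.
    """
    if isinstance(caps, int):
        caps = {s: caps for s in network.species}
    for s in network.species:
        if s not in caps:
            raise ValidationError(f"no cap declared for species {s!r}")
    for r in network.reactions:
        for s, d in r.net_change().items():
            if abs(d) > caps[s]:
                raise ValidationError(
                    f"cap {caps[s]} for species {s!r} is smaller than the change "
                    f"{abs(d)} of one reaction step"
                )
    domains = {s: tuple(str(i) for i in range(caps[s] + 1)) for s in network.species}
    space = StateSpace(tuple(network.species), domains)

    edges: set[tuple[str, str]] = set()
    mechanisms = []
    import itertools

    for ridx, r in enumerate(network.reactions):
        net = r.net_change()
        puppets = frozenset(net)
        if not puppets:
            raise ValidationError(f"reaction {ridx + 1} has no net change; cannot compile")
        part = r.participants()
        for i in puppets:
            for j in part:
                if j != i:
                    edges.add((j, i))
        a = {s: 0 for s in part}
        c = {s: 0 for s in part}
        for s, k in r.reactants:
            a[s] += k
        for s, k in r.products:
            c[s] += k
        entries = []
        for counts in itertools.product(*(range(caps[s] + 1) for s in part)):
            cfg = dict(zip(part, counts))
            # forward: consume reactants, make products
            fwd = r.kf * float(np.prod([_falling_factorial(cfg[s], a[s]) for s in part]))
            if fwd > 0:
                tgt = {s: cfg[s] + net[s] for s in puppets}
                if all(0 <= v <= caps[s] for s, v in tgt.items()):
                    entries.append(
                        (
                            {s: str(cfg[s]) for s in part},
                            {s: str(v) for s, v in tgt.items()},
                            fwd,
                        )
                    )
            rev = r.kr * float(np.prod([_falling_factorial(cfg[s], c[s]) for s in part]))
            if rev > 0:
                tgt = {s: cfg[s] - net[s] for s in puppets}
                if all(0 <= v <= caps[s] for s, v in tgt.items()):
                    entries.append(
                        (
                            {s: str(cfg[s]) for s in part},
                            {s: str(v) for s, v in tgt.items()},
                            rev,
                        )
                    )
        mechanisms.append(
            Mechanism(id=f"r{ridx + 1}", puppets=puppets, entries=tuple(entries))
        )
    return CompositeProcess(space, DependencyNetwork(frozenset(edges)), tuple(mechanisms))
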