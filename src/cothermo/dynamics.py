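"""Evolution of distributions and jump trajectories for composite processes.

Propagation is exact for the protocols this package supports: constant
generators use a single matrix exponential, piecewise-constant protocols one
exponential per constant piece.  Trajectory sampling is an exact Gillespie
scheme (exponential waiting times from the total exit rate, mechanism and
target chosen proportionally to rates); across a protocol breakpoint the
waiting time is simply re-drawn from the new rates, which is exact by
memorylessness of the exponential.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

from .process_model import CompositeProcess, StateSpace, ValidationError

__all__ = [
    "Distribution",
    "PropagatorKernel",
    "Jump",
    "Trajectory",
    "propagate",
    "propagate_grid",
    "steady_state",
    "period_propagator",
    "sample_trajectories",
    "empirical_current",
    "write_trajectories_tsv",
    "read_trajectories_tsv",
]


@dataclass
class Distribution:
    """A probability vector over a (marginal) joint state space."""

    space: StateSpace
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.space.n_states,):
            raise ValidationError(
                f"probability vector of length {self.p.size} does not match "
                f"{self.space.n_states} joint states"
            )
        if np.any(self.p < -1e-9):
            raise ValidationError("distribution has a significantly negative entry")
        self.p = np.clip(self.p, 0.0, None)
        s = self.p.sum()
        if s <= 0:
            raise ValidationError("distribution sums to zero")
        if abs(s - 1.0) > 1e-12:
            self.p = self.p / s

    @classmethod
    def uniform(cls, space: StateSpace) -> "Distribution":
        return cls(space, np.full(space.n_states, 1.0 / space.n_states))

    @classmethod
    def point(cls, space: StateSpace, state) -> "Distribution":
        p = np.zeros(space.n_states)
        p[space.index()[tuple(state)]] = 1.0
        return cls(space, p)

    @classmethod
    def random(cls, space: StateSpace, rng: np.random.Generator) -> "Distribution":
        return cls(space, rng.dirichlet(np.ones(space.n_states)))

    def marginal(self, members: Iterable[str]) -> "Distribution":
        sub = self.space.subspace(members)
        m = self.space.marginal_map(members)
        return Distribution(sub, np.bincount(m, weights=self.p, minlength=sub.n_states))

    def entropy(self) -> float:
        """Shannon entropy in nats."""
        p = self.p[self.p > 0]
        return float(-(p * np.log(p)).sum())


@dataclass
class PropagatorKernel:
    """Discrete-time conditional distribution; column ``x'`` is P(· | x')."""

    space: StateSpace
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n = self.space.n_states
        if self.P.shape != (n, n):
            raise ValidationError("kernel shape does not match the state space")
        if np.any(self.P < -1e-10):
            raise ValidationError("kernel has a negative conditional probability")
        cols = self.P.sum(axis=0)
        if np.any(np.abs(cols - 1.0) > 1e-10):
            raise ValidationError("kernel columns do not sum to 1 within 1e-10")

    def __matmul__(self, other):
        if isinstance(other, Distribution):
            return Distribution(self.space, self.P @ other.p)
        if isinstance(other, PropagatorKernel):
            return PropagatorKernel(self.space, self.P @ other.P)
        return NotImplemented

    def apply(self, p: np.ndarray) -> np.ndarray:
        return self.P @ p


@dataclass(frozen=True)
class Jump:
    t: float
    mechanism: str
    source: tuple
    target: tuple


@dataclass
class Trajectory:
    """A jump-resolved sample path over ``[0, horizon]``."""

    initial: tuple
    jumps: list[Jump]
    horizon: float
    seed: int | None = None

    @property
    def final(self) -> tuple:
        return self.jumps[-1].target if self.jumps else self.initial

    def __len__(self) -> int:
        return len(self.jumps)


# ---------------------------------------------------------------------------
# deterministic propagation
# ---------------------------------------------------------------------------


def _resolve(process_or_matrix, unit):
    """Return (space, pieces(t0,t1) iterator factory) for either input kind."""
    if isinstance(process_or_matrix, np.ndarray):
        K = process_or_matrix

        def pieces(t0, t1):
            yield t0, t1, K

        n = K.shape[0]
        return n, pieces
    proc: CompositeProcess = process_or_matrix
    members = proc.subsystem_set if unit is None else frozenset(unit)

    def pieces(t0, t1):
        for a, b in proc.pieces(t0, t1):
            tm = 0.5 * (a + b)
            if members == proc.subsystem_set:
                yield a, b, proc.full_generator(tm)
            else:
                yield a, b, proc.unit_generator(members, tm)

    if members == proc.subsystem_set:
        n = proc.state_space.n_states
    else:
        n = proc.state_space.subspace(members).n_states
    return n, pieces


def propagate(
    process_or_matrix,
    p0: Distribution | np.ndarray,
    t0: float = 0.0,
    t1: float | None = None,
    *,
    unit: Iterable[str] | None = None,
) -> Distribution | np.ndarray:
    """Solve the master equation from ``t0`` to ``t1`` exactly.

    Accepts either a :class:`CompositeProcess` (optionally restricted to a
    unit's marginal generator) or a bare constant generator matrix.  Matrix
    exponentials are exact per constant protocol piece; the result is
    renormalized within 1e-12.
    """
    if t1 is None:
        raise TypeError("propagate requires a final time t1")
    vec = p0.p if isinstance(p0, Distribution) else np.asarray(p0, dtype=float)
    n, pieces = _resolve(process_or_matrix, unit)
    if vec.shape != (n,):
        raise ValidationError("initial distribution does not match the generator dimension")
    out = vec.copy()
    if t1 > t0:
        for a, b, K in pieces(t0, t1):
            out = expm(K * (b - a)) @ out
    elif t1 < t0:
        raise ValueError("propagate: t1 must be >= t0")
    if np.any(out < -1e-8):
        raise FloatingPointError("integration produced negative probability beyond tolerance")
    out = np.clip(out, 0.0, None)
    out = out / out.sum()
    if isinstance(p0, Distribution):
        space = p0.space
        return Distribution(space, out)
    return out


def propagate_grid(
    process_or_matrix,
    p0: Distribution | np.ndarray,
    times: Sequence[float],
    *,
    unit: Iterable[str] | None = None,
) -> np.ndarray:
    """Distributions at each requested time (rows), times must be ascending."""
    vec = p0.p if isinstance(p0, Distribution) else np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    out = np.empty((len(times), vec.size))
    cur = vec.copy()
    t_cur = times[0]
    out[0] = cur
    for k in range(1, len(times)):
        cur = propagate(process_or_matrix, cur, t_cur, times[k], unit=unit)
        t_cur = times[k]
        out[k] = cur
    return out


def steady_state(generator: np.ndarray, space: StateSpace | None = None):
    """Stationary distribution of an irreducible constant generator.

    Raises on reducible generators, naming the communicating classes, rather
    than silently returning one class's stationary vector.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    K = np.asarray(generator, dtype=float)
    adj = (K > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=True, connection="strong")
    if n_comp > 1:
        classes = [list(np.where(labels == c)[0]) for c in range(n_comp)]
        raise ValidationError(
            f"generator is reducible: {n_comp} communicating classes {classes}"
        )
    from scipy.linalg import null_space

    ns = null_space(K, rcond=1e-12)
    if ns.shape[1] != 1:  # pragma: no cover - irreducible CTMCs have a 1-d kernel
        raise ValidationError(f"null space dimension {ns.shape[1]} != 1")
    pi = ns[:, 0]
    pi = np.abs(pi) / np.abs(pi).sum()
    # one step of refinement, then verify the residual
    resid = np.max(np.abs(K @ pi))
    if resid > 1e-10:
        # polish via least squares on the augmented system
        A = np.vstack([K, np.ones(K.shape[0])])
        b = np.zeros(K.shape[0] + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        pi /= pi.sum()
        resid = np.max(np.abs(K @ pi))
        if resid > 1e-10:
            raise ValidationError(f"steady state residual {resid:.2e} exceeds 1e-10")
    if space is not None:
        return Distribution(space, pi)
    return pi


def period_propagator(
    process: CompositeProcess,
    lam: float,
    *,
    unit: Iterable[str] | None = None,
    t0: float = 0.0,
) -> PropagatorKernel:
    """The conditional distribution of the state at ``t0 + λ`` given the state at ``t0``.

    For the kernel to define a genuinely periodic discrete-time chain, every
    driving protocol's period must divide λ; incommensurate protocols raise.
    """
    if lam < 0:
        raise ValueError("period must be nonnegative")
    members = process.subsystem_set if unit is None else frozenset(unit)
    for m in process.mechanisms:
        if m.protocol is not None and not (process.leader_set(m) <= members):
            continue
        if m.protocol is not None and lam > 0:
            ratio = lam / m.protocol.period
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValidationError(
                    f"protocol of mechanism {m.id!r} (period {m.protocol.period}) "
                    f"is incommensurate with λ = {lam}"
                )
    if unit is None:
        space = process.state_space
    else:
        space = process.state_space.subspace(members)
    n = space.n_states
    P = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        P[:, j] = propagate(process, e, t0, t0 + lam, unit=unit) if lam > 0 else e
    return PropagatorKernel(space, P)


# ---------------------------------------------------------------------------
# stochastic sampling
# ---------------------------------------------------------------------------


def _mechanism_columns(process: CompositeProcess, t: float):
    """Per-mechanism off-diagonal rate matrices at time t (cached upstream)."""
    mats = []
    for m in process.mechanisms:
        K = process.mechanism_generator(m.id, t)
        off = K.copy()
        np.fill_diagonal(off, 0.0)
        mats.append((m.id, off))
    return mats


def sample_trajectories(
    process: CompositeProcess,
    p0: Distribution,
    tau: float,
    n: int,
    seed: int,
    *,
    unit: Iterable[str] | None = None,
) -> list[Trajectory]:
    """Exact Gillespie sampling of ``n`` independent mechanism-resolved paths.

    One root seed spawns per-trajectory child streams, so results do not
    depend on how many paths are requested or in which order they are drawn.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    proc = process if unit is None else process.restrict_to_unit(unit)
    space = proc.state_space
    states = space.states()
    if isinstance(p0, Distribution):
        if p0.space.subsystems != space.subsystems:
            raise ValidationError("p0 is not on the sampled process's state space")
        weights = p0.p
    else:
        weights = np.asarray(p0, dtype=float)

    # piecewise-constant caches: one rate bundle per phase signature
    knots = [0.0] + proc.breakpoints_between(0.0, tau) + [tau]
    bundles = []
    for a, b in zip(knots, knots[1:]):
        tm = 0.5 * (a + b)
        mats = _mechanism_columns(proc, tm)
        stacked = np.stack([m for _, m in mats])  # (n_mech, n, n)
        exit_rates = stacked.sum(axis=(0, 1))  # total exit rate per source column
        bundles.append((a, b, mats, stacked, exit_rates))

    streams = np.random.SeedSequence(seed).spawn(n)
    out: list[Trajectory] = []
    for k in range(n):
        rng = np.random.default_rng(streams[k])
        i0 = int(rng.choice(len(states), p=weights))
        i = i0
        t = 0.0
        jumps: list[Jump] = []
        for a, b, mats, stacked, exit_rates in bundles:
            t = max(t, a)
            while t < b:
                r = exit_rates[i]
                if r <= 0:
                    t = b
                    break
                dt = rng.exponential(1.0 / r)
                if t + dt >= b:
                    t = b  # re-draw from the next piece's rates (memoryless)
                    break
                t += dt
                col = stacked[:, :, i].ravel()  # (n_mech * n,)
                pick = int(rng.choice(col.size, p=col / r))
                mech_idx, tgt = divmod(pick, len(states))
                jumps.append(Jump(t, mats[mech_idx][0], states[i], states[tgt]))
                i = tgt
        out.append(Trajectory(states[i0], jumps, tau, seed=k))
    return out


def empirical_current(trajectories: Sequence[Trajectory], current_spec):
    """Per-path time-integrated current values, their mean and unbiased variance.

    ``current_spec`` must expose ``weight(target, source) -> float`` (an
    antisymmetric weight, validated by the spec object) and an optional
    ``mechanism`` attribute restricting which jumps count.
    """
    mech = getattr(current_spec, "mechanism", None)
    vals = np.empty(len(trajectories))
    for k, tr in enumerate(trajectories):
        s = 0.0
        for j in tr.jumps:
            if mech is not None and j.mechanism != mech:
                continue
            s += current_spec.weight(j.target, j.source)
        vals[k] = s
    mean = float(vals.mean())
    var = float(vals.var(ddof=1)) if len(vals) > 1 else 0.0
    return vals, mean, var


# ---------------------------------------------------------------------------
# trajectory TSV
# ---------------------------------------------------------------------------

_TSV_HEADER = ["path_id", "t", "mechanism", "from_state", "to_state"]


def write_trajectories_tsv(trajectories: Sequence[Trajectory], space: StateSpace, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TSV_HEADER)
        for k, tr in enumerate(trajectories):
            for j in tr.jumps:
                w.writerow([k, repr(j.t), j.mechanism, space.label(j.source), space.label(j.target)])


def read_trajectories_tsv(path, space: StateSpace, horizon: float) -> list[Trajectory]:
    by_path: dict[int, list[Jump]] = {}
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != _TSV_HEADER:
            raise ValidationError(f"unexpected trajectory TSV header {header}")
        for row in r:
            k = int(row[0])
            by_path.setdefault(k, []).append(
                Jump(float(row[1]), row[2], space.parse_label(row[3]), space.parse_label(row[4]))
            )
    out = []
    for k in sorted(by_path):
        jumps = sorted(by_path[k], key=lambda j: j.t)
        out.append(Trajectory(jumps[0].source, jumps, horizon))
    return out
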