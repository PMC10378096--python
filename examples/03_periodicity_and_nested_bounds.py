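"""Strictly positive EP lower bounds from periodicity and unit overlap.

Over a single period, the periodicity mismatch-cost bound on a process is
vacuous (take the prior q = p0).  But in a three-subsystem system with a
frozen hub A and periodically driven leaves B (period λB) and C (λC), with
λB = mλC/n, the in–ex decomposition knits the two per-unit bounds — each
over several of its own periods — into a strictly positive bound on the
global EP over the common period τ = nλB = mλC, where the global bound
alone says nothing.
"""

from cothermo.bounds import nested_periodic_bound, periodicity_ep_bound
from cothermo.dynamics import period_propagator
from cothermo.fixtures import build_nested_periodic

inst = build_nested_periodic(m=3, n=4, lam_C=1.0, seed=0)
print(f"periods: lam_B = {inst.lam_B}, lam_C = {inst.lam_C}, common tau = {inst.tau}")

# the full system over one common period: the direct bound is zero
P_full = period_propagator(inst.process, inst.tau)
direct = periodicity_ep_bound(P_full, inst.p0, 1)
print(f"direct full-system bound over one period: {direct.bound:.3e}  (vacuous)")

rep = nested_periodic_bound(inst)
c = rep.components
print(f"-dI (overlap term)      = {c['minus_delta_inex_information']:.6f} >= 0")
print(f"JS drop, unit AB (n={inst.n}) = {c['djs_AB']:.6f}")
print(f"JS drop, unit AC (m={inst.m}) = {c['djs_AC']:.6f}")
print(f"composite lower bound   = {rep.bound:.6f} nats")
print(f"integrated global EP    = {rep.sigma:.6f} nats")
print(f"bound holds with slack  = {rep.slack:.6f}")
print("-> the unit structure turns two per-unit periodicity bounds into a")
print("   strictly positive bound on total dissipation.")
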