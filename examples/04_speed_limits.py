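"""Mechanism-resolved thermodynamic speed limits.

How far can a distribution travel (in total variation) in a time τ?  The
classic bound uses total activity and total EP; resolving both by mechanism
and applying the concave Pinsker function per mechanism always tightens it
(Jensen's inequality).  Inverting the bound in the duration variable gives
a lower bound τ* on how long the observed displacement must have taken.
"""

import numpy as np

from cothermo.bounds import speed_limit_global, tau_lower_bound
from cothermo.dynamics import Distribution
from cothermo.fixtures import random_composite_process

process = random_composite_process(n_subsystems=3, n_mechanisms=3, seed=3)
p0 = Distribution.random(process.state_space, np.random.default_rng(3))
tau = 0.5

rep = speed_limit_global(process, process.subsystem_set, p0, tau)
print(f"displacement L(p0, p_tau)        = {rep.lhs:.6f}")
print(f"mechanism-resolved bound (tight) = {rep.extras['rhs_composite']:.6f}")
print(f"single-activity bound (coarse)   = {rep.rhs:.6f}")
print(f"Jensen ordering holds: {rep.extras['jensen_ok']}")
for mid, row in rep.per_mechanism.items():
    print(f"  {mid}: activity {row['activity']:.4f}, EP share {row['zeta']:.4f}, term {row['term']:.4f}")

per_unit, tau_star = tau_lower_bound(process, [process.subsystem_set], p0, tau)
print(f"duration lower bound tau* = {tau_star:.4f}  (true duration {tau})")
print("-> no protocol with these per-mechanism budgets could have produced")
print("   this displacement faster than tau*.")
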