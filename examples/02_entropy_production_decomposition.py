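"""Decompose global entropy production over an overlapping unit structure.

A hub subsystem A drives two leaves B and C.  The families {A}, {A,B},
{A,C} are units: each marginal evolves autonomously.  Global EP then
decomposes exactly into an inclusion–exclusion sum of per-unit EPs minus
the change in the in–ex information (the overlap correction):

    σ_N = σ_AB + σ_AC − σ_A − ΔI

The residual of that identity is a stringent end-to-end test of the whole
propagation + EP machinery; it should sit at quadrature precision.
"""

import numpy as np

from cothermo import closure_and_validate_structure, ep_inex_decomposition
from cothermo.dynamics import Distribution
from cothermo.fixtures import random_overlapping_units_process

process = random_overlapping_units_process(seed=11)
structure = closure_and_validate_structure(process, [{"A", "B"}, {"A", "C"}])
p0 = Distribution.random(process.state_space, np.random.default_rng(0))

dec = ep_inex_decomposition(process, structure, p0, tau=1.0)

print("units in the structure:", [",".join(sorted(u)) for u in structure])
for u, sigma in dec.unit_sigma.items():
    print(f"  sigma[{','.join(sorted(u))}] = {sigma:.6f} nats")
print(f"in-ex sum of unit EPs  = {dec.inex_ep:.6f} nats")
print(f"change in in-ex info   = {dec.delta_I:+.6f} nats")
print(f"global EP sigma_N      = {dec.sigma_N:.6f} nats")
print(f"identity residual      = {dec.residual:.2e}  (tolerance {dec.tolerance:.1e})")
print("-> the correction term -dI accounts exactly for the units' overlap on A.")
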