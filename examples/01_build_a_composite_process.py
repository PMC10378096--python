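"""Build a composite process from a mass-action reaction network.

A stochastic reaction network is the canonical system in which several
degrees of freedom (species counts) must change together: one reaction
firing is one jump of one mechanism.  This script compiles a three-reaction
network into a composite process on a truncated count box and inspects its
structure: puppet sets, leader sets, and units.
"""

from cothermo.crn import crn_to_process, parse_crn

TEXT = """\
2 X1 + 1 X2 <-> 1 X3 , 1.0 , 1.0
1 X3 <-> 1 X4 , 1.0 , 1.0
1 X2 + 1 X4 <-> 1 X1 , 1.0 , 1.0
"""

network = parse_crn(TEXT)
process = crn_to_process(network, caps=2)

print(f"species: {network.species}")
print(f"joint states on the truncated box: {process.state_space.n_states}")
for mech in process.mechanisms:
    pup = sorted(mech.puppets)
    lead = sorted(process.leader_set(mech))
    print(f"mechanism {mech.id}: puppet set {pup}, leader set {lead}")
print("-> a mechanism with more than one puppet makes this a composite")
print("   process that is NOT multipartite: several counts jump together.")

ok, violations = process.is_unit(process.subsystem_set)
print(f"full system is a unit: {ok}")
ok, violations = process.is_unit({"X1"})
print(f"{{X1}} alone is a unit: {ok} (mechanisms straddling it: {violations})")
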