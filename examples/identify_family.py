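"""Mine a synthetic proteome for RB-GRP family members.

Generates a proteome with 12 planted members (classes IVa-IVd) plus
domain-only and glycine-only decoys, runs the identification pipeline
(E-value filter, RRM/CSD requirement, >50%-glycine 20-residue window,
architecture classification) and prints the roster.
"""

from rbgrp.family import identify_family_members, roster_table
from rbgrp.simulate import ProteomeConfig, simulate_proteome

sim = simulate_proteome(ProteomeConfig(seed=42))
members = identify_family_members(sim.proteins, sim.hits)

print(roster_table(members).to_string(index=False))
print()
print(f"planted members: {len(sim.truth['members'])}, "
      f"recovered: {len(members)}, "
      f"decoys rejected: {len(sim.truth['decoys_domain_only']) + len(sim.truth['decoys_glycine_only'])}")
# Every roster row shows the domain string, subfamily call, size (aa),
# average molecular weight (kDa) and theoretical pI; a perfect run recovers
# exactly the planted proteins and none of the decoys.
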