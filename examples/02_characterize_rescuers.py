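"""Characterize a knockout design: which metabolites rescue it, and how much?

A design is an auxotroph if it cannot grow on the base medium alone. Each
carbon exchange is opened one at a time; those restoring growth are the
design's rescuers, and the rescuer count classifies the design (1 rescuer =
specific essential-biomass-component auxotroph, 2-4 = semi-specific, >= 5 =
major subsystem elimination).
"""

from auxodesign import (
    KnockoutDesign,
    apply_medium,
    average_required_uptake,
    classify_design,
    rescue_metabolites,
)
from auxodesign.synthdata import ToyNetworkSpec, make_toy_network

net, truth = make_toy_network(
    ToyNetworkSpec(seed=1, n_precursors=3, biomass_stoich=(1.78, 2.876, 0.86),
                   alt_substrate_for=0)
)
netm = apply_medium(net, truth.medium)

design = KnockoutDesign(truth.routes[0])  # cut p0's only synthesis route
profile = rescue_metabolites(netm, design, growth_rate=0.1)

print(f"knockouts       : {sorted(design.knocked_out)}")
print(f"is auxotroph    : {profile.is_auxotroph}")
for exchange, uptake in sorted(profile.rescuers.items()):
    print(f"  rescuer {exchange:10s} min uptake {uptake:.4f} mmol/gDW/hr")
print(f"class           : {classify_design(profile).label}")
print(f"average uptake  : {average_required_uptake(profile):.4f} mmol/gDW/hr")
# p0 itself rescues, and so does the alternative substrate that converts to
# p0 - so this design is EBC_semi_specific with two rescuers.
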