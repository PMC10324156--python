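"""Where does the information about the treatment effect live?

Computes the information content (IC) of every centrosymmetric pair of
cluster-period cells for the complete 4x5 design under both supported
correlation structures. IC is the factor by which the treatment-effect
variance grows when that pair is dropped: values near 1 mark expendable
cells, large values mark cells the design cannot afford to lose. Under the
exchangeable structure the off-diagonal corners are information-rich
"hot-spots"; under discrete-time decay the information concentrates around
each cluster's treatment switch instead.
"""

from swdreduce import DesignConfig, build_complete_sw, ic_map

for structure, rho, r in [("exchangeable", 0.14, 1.0), ("discrete_time_decay", 0.15, 0.95)]:
    config = DesignConfig(T=5, m=90, rho=rho, r=r, structure=structure)
    design = build_complete_sw(config)
    icm = ic_map(design, config)
    print(f"{structure} (rho={rho}, r={r}):")
    print(design.schematic())
    print(icm.to_frame().round(3).to_string())
    print()
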