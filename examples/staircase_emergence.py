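"""A large stepped wedge reduces toward a staircase design.

Runs the removal algorithm on a 9-cluster, 10-period trial (50 per cell,
discrete-time decay, ICC 0.05, CAC 0.95) and shows the design once about
half of the 90 cells are gone: measurements cluster in a band around each
treatment switch — a staircase — with a few extra cells in the first and
final periods. The half-sized trial retains almost all of the complete
design's power.
"""

from swdreduce import DesignConfig, run_removal

config = DesignConfig(
    T=10, m=50, rho=0.05, r=0.95, structure="discrete_time_decay", effect_size=0.2
)
trace = run_removal(config)

complete = trace.steps[0]
mid = trace.step_at_removed_pairs(23)  # 46 of 90 cells removed (51.11%)
print(f"complete design: power {complete.power_pct:.2f}%")
print()
print(f"after 23 pair removals ({mid.design.pct_removed:.2f}% of cells removed):")
print(mid.design.schematic())
print()
print(f"power {mid.power_pct:.2f}%, precision loss {mid.precision_loss_pct:.2f}%")
# Halving the measurement burden costs about 2 points of power here.
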