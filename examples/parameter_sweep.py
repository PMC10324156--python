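"""How much precision is lost at fixed removal checkpoints, across trials?

Sweeps 36 trial configurations (5 or 10 periods; 10 or 100 participants
per cell; ICC 0.01/0.05/0.15; cluster autocorrelation 1/0.95/0.8) through
the removal algorithm and summarises the precision loss once 20%, ~50% and
80% of cells are removed. Removing a fifth of the cells is nearly free
everywhere; removing half costs at most ~21% of precision.
"""

from swdreduce import SweepGrid, run_sweep, summarise_sweep

result = run_sweep(SweepGrid())
print(f"{len(result)} checkpoint rows over 36 configurations")
for key, stats in summarise_sweep(result).items():
    print(
        f"{key}: precision loss min {stats['min_precision_loss_pct']:.2f}% "
        f"max {stats['max_precision_loss_pct']:.2f}%"
    )
print()
worst = result.loc[result["precision_loss_pct"].idxmax()]
print(
    "largest loss overall: T={T}, m={m}, rho={rho}, r={r} at the "
    "{checkpoint_pct:g}% checkpoint ({precision_loss_pct:.2f}% precision lost)".format(
        **worst[["T", "m", "rho", "r", "checkpoint_pct", "precision_loss_pct"]].to_dict()
    )
)
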