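"""Monitoring stability while a Delphi panel is still recruiting.

Feeds nested accrual snapshots (every 30 new raters) to the monitor,
which recomputes the replicability curve each time and flags the first
snapshot whose largest feasible probe enters the high band (>=80%) — a
data-driven signal that further recruitment mainly adds variance
reduction, not new medians.
"""

from delphi_stabilize import (
    ResampleConfig,
    SyntheticConfig,
    generate,
    stability_monitor,
)

rm, _, _ = generate(SyntheticConfig(n_participants=240, n_items=30, seed=11))
ids = rm.participant_ids
snapshots = [rm.subset(ids[:n]) for n in range(30, 241, 30)]

cfg = ResampleConfig(sizes=tuple(range(20, 241, 20)), n_draws=500, seed=4)
table = stability_monitor(snapshots, cfg, threshold=80)
print(table.to_string(index=False))
flagged = table.loc[table["high_band_entered"], "n_raw"]
print(
    f"\nhigh band first entered with {int(flagged.iloc[0])} raters enrolled"
    if not flagged.empty
    else "\nhigh band not yet entered"
)
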