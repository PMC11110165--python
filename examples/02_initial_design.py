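"""Greedy maximum-coverage opening block.

Before any model exists, experiments are chosen to expose as many unseen
categorical option levels as possible: each pick maximizes the number of
new levels over {substrate, solvent, iodine source, catalyst}.  On the full
grid this covers all 23 levels of those four fields in eleven experiments —
the minimum possible, since there are eleven solvents.
"""

from rxnopt import DiversityConfig, build_default_grid, coverage_complete_after, greedy_diverse_init

grid = build_default_grid()
picks = greedy_diverse_init(grid, DiversityConfig(n_init=11, seed=0))

for i, p in enumerate(picks, 1):
    print(
        f"{i:2d}. {p.alkyne:<26} {p.solvent:<12} {p.iodine_source:<5} "
        f"{p.catalyst:<5} {p.temperature:>4.0f} degC"
    )

fields = ("alkyne", "solvent", "iodine_source", "catalyst")
print("coverage complete after:", coverage_complete_after(picks, grid, fields), "picks")
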