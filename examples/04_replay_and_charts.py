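"""Replay a recorded campaign history and draw the progress charts.

The replay scanner recovers, from an ordered list of observations, the
experiment at which each substrate first surpassed the 80% conversion line,
how many of its own experiments ran before that, and the global stop.
Charts are written to ./figures/.
"""

from pathlib import Path

from rxnopt import (
    CampaignConfig,
    LandscapeConfig,
    build_default_grid,
    make_oracle,
    parallel_coordinates,
    progress_chart,
    replay_campaign,
    run_campaign,
    save_history,
)

Path("figures").mkdir(exist_ok=True)
grid = build_default_grid()
state, _ = run_campaign(
    make_oracle(LandscapeConfig(seed=11)), grid, CampaignConfig(seed=5)
)
history = state.observations
save_history(history, "figures/history.jsonl")

report = replay_campaign(history)
for alkyne, idx in sorted(report.first_pass.items()):
    print(f"{alkyne:<26} crossed 80% at experiment {idx} "
          f"after {report.experiments_per_alkyne[alkyne]} of its own experiments")
print("global stop index:", report.global_stop_index)

progress_chart(history, path="figures/progress.png")
n_converged = sum(o.outcome.conversion > 0.8 for o in history)
parallel_coordinates(history, converged_only=True, path="figures/parallel.png")
print(f"wrote figures/progress.png and figures/parallel.png "
      f"({n_converged} converged traces)")
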