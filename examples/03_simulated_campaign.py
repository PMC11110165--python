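"""One closed-loop optimization campaign against the synthetic oracle.

The loop: 11 diversity-driven experiments, then batches of two chosen by
constant-liar expected improvement under a Gaussian-process merit model.
A substrate leaves the search space once its measured conversion surpasses
80%; the campaign ends when all four have converged.  The synthetic
landscape hides a broad chloramine-route optimum (polar solvent, low
temperature, reagent excess, no catalyst) plus a deceptive acid-catalyzed
NIS region that converts the substrate without making product.
"""

from rxnopt import CampaignConfig, LandscapeConfig, build_default_grid, ground_truth, make_oracle, run_campaign

grid = build_default_grid()
landscape = LandscapeConfig(seed=11)
config = CampaignConfig(seed=3, max_experiments=60)

state, report = run_campaign(make_oracle(landscape), grid, config)

print(f"stop reason: {report.stop_reason} after {state.n_experiments} experiments "
      f"({state.iteration} iterations)")
for alkyne, idx in sorted(report.first_pass.items()):
    own = report.experiments_per_alkyne[alkyne]
    print(f"  {alkyne:<26} first >80% conversion at experiment {idx:>2} "
          f"({own} own experiments before)")

best = max(state.observations, key=lambda o: o.merit)
truth = ground_truth(landscape, grid)
print(f"best observed merit: {best.merit:.3f} at "
      f"{best.point.solvent}, {best.point.iodine_source}, "
      f"{best.point.temperature:.0f} degC")
print(f"ground-truth optimum merit: {truth.argmax_merit:.3f} "
      f"(grid scan of {len(grid)} points)")
print(f"fraction of the space explored: {100 * state.n_experiments / len(grid):.1f}%")
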