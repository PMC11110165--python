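"""t-SNE contour maps: ground truth versus surrogate belief.

The campaign's evaluated points are embedded to two dimensions (substrate
excluded, so experiments cluster by conditions) and two elevation maps are
interpolated over the embedding: the true merit of each point, and the
merit predicted by a Gaussian process trained on only the first eleven
observations.  Comparing the two maps side by side shows where the model's
beliefs already match reality and where it is still guessing.
"""

from pathlib import Path

import numpy as np

from rxnopt import (
    CampaignConfig,
    FeatureEncoding,
    LandscapeConfig,
    MeritGP,
    StoppingRule,
    build_default_grid,
    compute_merit,
    contour_from_values,
    embed_points,
    make_oracle,
    plot_contour,
    run_campaign,
    surrogate_contour,
    true_response,
)

Path("figures").mkdir(exist_ok=True)
grid = build_default_grid()
landscape = LandscapeConfig(seed=11)
state, _ = run_campaign(
    make_oracle(landscape), grid,
    CampaignConfig(seed=7, max_experiments=49, stopping=StoppingRule(1.0)),
)
points = [o.point for o in state.observations]
true_merit = np.array(
    [compute_merit(*reversed(true_response(p, landscape))) for p in points]
)

emap = embed_points(points, grid.space, exclude=("alkyne",), perplexity=10,
                    seed=7, grid=grid)
truth_surface = contour_from_values(emap, true_merit, name="true merit")
plot_contour(truth_surface, emap, true_merit, path="figures/tsne_true.png")

model = MeritGP(FeatureEncoding(grid.space, grid), seed=7).fit(
    state.observations[:11]
)
pred_surface = surrogate_contour(emap, model)
plot_contour(pred_surface, emap, model.predict(points).mean,
             path="figures/tsne_predicted.png")

pred = model.predict(points).mean
print(f"embedded {len(points)} evaluated points "
      f"(true merit range {true_merit.min():.2f}-{true_merit.max():.2f})")
print(f"11-point model vs truth, mean abs error at the markers: "
      f"{np.abs(pred - true_merit).mean():.3f}")
print("wrote figures/tsne_true.png and figures/tsne_predicted.png")
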