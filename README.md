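# rxnopt

Closed-loop Bayesian optimization of reaction conditions over constrained
categorical grids, built around a concrete campaign: the simultaneous
optimization of two iodination routes for four terminal alkynes.

## Who this is for

Chemists and self-driving-lab engineers who need to pick the next few
experiments from a large discrete space of reaction conditions — solvents,
reagents, stoichiometries, temperatures — under hard chemistry constraints,
and who want the planner's reasoning to be inspectable rather than a black
box. The package supplies the whole loop except the lab: grid construction,
objective bookkeeping, experiment selection, campaign orchestration, a
synthetic reaction oracle for dry runs, and visualization.

## The method

**Search space.** Eight parameters (substrate, chloramine eq., solvent,
iodine source and eq., catalyst and eq., temperature) span 253,440 raw
combinations. Declarative constraint rules — temperature capped a safety
margin below each solvent's boiling point, reagents in at least
stoichiometric amounts, no pairing of the NIS iodination agent with the
chloramine oxidant, no acid catalyst on the chloramine route — reduce this
to a feasible grid of 12,036 candidates.

**Objectives.** HPLC areas against an internal standard give conversion
`c = 1 − C_SM/C_IS` and yield `y = C_prod/C_IS`. The optimizer maximizes the
scalarized merit

```
m = 0.9 · clip(y) + 0.1 · clip(c),      clip into [0, 1]
```

so yield dominates but inert conditions are still penalized. A substrate is
done when any of its experiments strictly surpasses 80% conversion, after
which all of its grid points leave the candidate set; the campaign ends when
all substrates are done.

**Planner.** The opening block of 11 experiments is chosen by a greedy
maximum-coverage heuristic (each pick maximizes the number of not-yet-seen
levels of substrate, solvent, iodine source and catalyst — eleven picks
cover all 23 levels, the minimum possible given eleven solvents). After
that, a Gaussian process with an automatic-relevance Matérn-5/2 kernel over
a one-hot/standardized encoding models merit for all substrates jointly,
and batches of two are selected by expected improvement with the
constant-liar heuristic. The shared model is what lets optimal conditions
found on one substrate transfer to the others.

**Interpretability.** Evaluated points are embedded with t-SNE (substrate
excluded) and merit — true or model-predicted — is interpolated over the
embedding as a contour map, so the model's beliefs can be compared with
reality region by region. Progress charts and parallel-coordinates plots
cover the campaign view.

## Worked example

`examples/03_simulated_campaign.py` runs the full loop against the bundled
synthetic landscape (a broad chloramine-route optimum in polar solvents at
low temperature, a deceptive acid-catalyzed NIS region that converts
substrate without making product, Gaussian measurement noise):

```
stop reason: converged after 35 experiments (13 iterations)
  1-chloro-2-ethynylbenzene  first >80% conversion at experiment 30 (9 own experiments before)
  1-chloro-4-ethynylbenzene  first >80% conversion at experiment 26 (5 own experiments before)
  2-ethynyltoluene           first >80% conversion at experiment  5 (1 own experiments before)
  4-ethynyltoluene           first >80% conversion at experiment 34 (11 own experiments before)
best observed merit: 0.988 at MeOH, TBAI, 55 degC
ground-truth optimum merit: 0.960 (grid scan of 12036 points)
fraction of the space explored: 0.3%
```

All four substrates cross the 80% conversion line in 35 of a possible
12,036 experiments (0.3% of the space), the best observed merit (noisy
measurement) brackets the true optimum of 0.960, and the optimum is found
on the chloramine route in methanol — the hardest substrate
(1-chloro-2-ethynylbenzene) needs the most of its own experiments. The
other examples cover grid construction, the opening design, history replay
with charts, and the t-SNE truth-versus-prediction maps.

A thin CLI mirrors the library: `rxnopt build-grid`, `init`, `suggest`,
`observe`, `run-sim`, `replay` (see `rxnopt --help`).

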