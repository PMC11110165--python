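# Methods

This note documents the models, defaults and design choices behind rxnopt:
what is computed, why the defaults are what they are, and what the
synthetic test-bed does and does not establish about real campaigns.

## Search space and constraint engine

The space is a list of parameter definitions — categorical (substrate,
solvent, iodine source, catalyst) or ordinal-numeric (equivalents,
temperature in °C; numeric levels are kept as numbers so the surrogate sees
their ordering and spacing). The feasible grid is the Cartesian product
filtered through declarative rules of four kinds:

* `max-temperature-by-solvent` — temperature ≤ boiling point − safety
  margin. The shipped table uses nominal boiling points (MeOH 65, CH₃CN 82,
  CH₃CN/H₂O 76 — the azeotrope, THF 66, DMF 153, DMSO 189, DCM 40, EtOAc 77,
  1,4-dioxane 101, MTBE 55, DCE 84 °C) and a 5 °C margin against evaporation
  at reflux. These are editable config data, not engine behaviour.
* `min-equivalents-when-active` — a reagent used at all is used in at least
  stoichiometric amount (≥ 1 eq). Unconditional for the iodine source;
  conditional on the iodide-salt route for the chloramine oxidant. A
  consequence adopted here: iodine source at 0 eq is never feasible.
* `forbidden-combination` — the chloramine oxidant is never paired with the
  acid catalysts used alongside NIS.
* `conditional-requirement` — NIS implies no chloramine; "no catalyst"
  pairs with 0 eq loading and an active catalyst with a positive loading.

Route encoding follows from the rules: a point is on the NIS route iff its
iodine source is NIS (chloramine 0 eq, catalyst free to be PTSA/AcOH/none),
otherwise on the chloramine route (iodide salt ≥ 1 eq, chloramine ≥ 1 eq,
no catalyst). Under the default eight-parameter configuration this gives
51 reagent combinations × 59 feasible solvent–temperature pairs × 4
substrates = 12,036 candidates, enumerated in lexicographic declared-option
order so two builds are identical. Grid files are plain CSV, one column per
parameter.

## Objectives

Conversion is the consumed fraction of starting material,
`1 − C_SM/C_IS`, using the internal standard (added in the same amount as
the substrate) as the t = 0 proxy; yield is `C_prod/C_IS`. Calibration
offsets can push raw values slightly outside [0, 1]; raw values are stored
untouched and clipped copies enter the merit

`m = w_y·clip(y) + w_c·clip(c)`, defaults `w_y = 0.9`, `w_c = 0.1`.

"Normalized" is read as "fraction of the internal-standard concentration",
not batch min–max scaling: the latter would make merit non-stationary as
observations accumulate, which a fixed-target optimizer should not see.

Stopping is per substrate: strictly surpassing 80% conversion retires the
substrate and removes all its points from the candidate set. Threshold 1.0
is accepted and means "never" (clipped conversion cannot strictly exceed
it), which is how merit-seeking behaviour is measured without contraction.

## Experiment selection

**Opening block.** Greedy maximum coverage: picks are chosen sequentially,
each maximizing the number of option levels of {substrate, solvent, iodine
source, catalyst} not seen in earlier picks; ties break uniformly under the
campaign seed. Numeric parameters are excluded from the novelty count to
keep the heuristic scale-free. Eleven picks always cover all 23 levels on
the default grid — the minimum, since each pick carries one of eleven
solvents. Default block size: 11.

**Surrogate.** One Gaussian process over the pooled observations of all
substrates; the substrate is an ordinary one-hot block, which is the
mechanism of cross-substrate transfer. Encoding: one-hot per categorical
level plus numeric columns standardized with grid-wide statistics (so the
encoding never drifts). Kernel: signal variance × Matérn-5/2 with one
length-scale per encoded feature (bounds 10⁻²–10³), plus fitted white noise
floored at 10⁻⁶. Targets are mean-centred; hyperparameters maximize the
marginal likelihood from 5 seeded restarts, so refits on the same data are
bit-reproducible. Only merit is modelled — conversion for the stopping rule
is taken from the observations, never from the model.

**Acquisition.** Expected improvement for maximization with exploration
offset ξ = 0.01 on the merit scale; the deterministic limit max(0, μ−f*−ξ)
is used at σ = 0. Batches (default 2, matching two parallel reactors) use
the constant-liar heuristic: after each pick a fantasy observation at the
best observed merit is appended and the GP is re-conditioned with frozen
hyperparameters before the next pick. Freezing keeps within-batch ranking
deterministic and cheap; liar = best-merit biases the batch toward
diversity. Ties in EI break by seeded draw.

## Campaign loop and reproducibility

Iteration 1 is the opening block; every later iteration fits the surrogate
on everything observed, drops visited points and retired substrates from
the candidates, selects a batch, and evaluates it. The loop ends when all
substrates are retired ("converged"), the experiment budget is spent
("budget"), or no candidates remain ("exhausted"). Experiment indices are
1-based. Each iteration derives its random generator and GP seed from
(campaign seed, iteration number), so a campaign saved to JSON and resumed
reproduces the uninterrupted run exactly. The replay scanner recovers, in
one pass, each substrate's first crossing index and the count of its own
experiments strictly before that crossing; the global stop index is the
last first-crossing when every substrate converges.

## Synthetic reaction landscape

The oracle emulates the qualitative chemistry so the loop can be exercised
and measured without a lab:

* **Chloramine route** (additive effects, clamped to [0, 1]):
  yield = 0.55 + solvent effect + substrate shift + 0.04·(chloramine eq − 1)
  + 0.05·(iodide eq − 1); conversion likewise with base 0.50 and steeper
  equivalents gains 0.06/0.08; both take a quadratic penalty
  −0.35·((T−65)/30)² above 65 °C. Solvent effects: MeOH +0.30, CH₃CN +0.22,
  CH₃CN/H₂O +0.20, THF +0.05, the rest ≤ 0. Substrate shifts
  {+0.02, 0.00, −0.03, −0.06} keep optima transferable while making the
  ortho-chloro substrate hardest.
* **NIS route, uncatalyzed**: conversion ≤ ~0.29 and yield ≤ ~0.11
  everywhere (selectivity needs the acid catalyst).
* **NIS + PTSA**: the acid hydrates the alkyne — conversion
  0.55 + solvent effect + shift + 0.2·(T−25)/70 exceeds 0.8 in polar/warm
  conditions while yield collapses to 0.02.
* **NIS + AcOH**: moderate boosts (+0.35 conversion, +0.30 yield), never
  competitive with the chloramine optimum.

Measurement scatter is independent Gaussian noise (sd 0.05 fraction units)
on conversion and yield, allowed slightly outside [0, 1] as real assays
are; merit uses the clipped values. Draws are deterministic per (point,
landscape seed, draw index). The conversion surface is deliberately steeper
in the equivalents than the yield surface: crossing the 80% stopping line
requires a polar solvent *and* adequate stoichiometry, which reproduces the
qualitative campaign shape — few crossings in the opening block,
convergence of all substrates after roughly 23–37 experiments, and transfer
of the discovered conditions to the later substrates.

What the landscape does **not** emulate: kinetics, side-product channels
beyond the two scripted ones, correlated assay errors, or any quantitative
resemblance to real yields. Tests passing on it show the planner's
behaviour (sample efficiency, contraction, transfer), not chemical
predictive power.

## Visualization

t-SNE runs on the same one-hot/standardized encoding the surrogate uses
(Euclidean distances), with the substrate block dropped by default so maps
cluster by conditions; perplexity defaults to 10 (sized for ~50 points) and
the seed is the campaign seed. Only seeded reproducibility is claimed —
t-SNE coordinates have no stable scale or orientation. Contours interpolate
a per-point scalar linearly inside the convex hull of the embedding on a
200×200 mesh, with nearest-neighbour fill outside so the map is complete;
elevations are therefore bounded by the input value range. The surrogate
map evaluates the model's posterior mean at every embedded point, trained
on any subset, enabling the truth-versus-belief comparison.

## Problem sizes in the test suite

The suite runs entirely on synthetic data at desk scale: the full
12,036-point grid for counting, coverage and replay checks; a reduced
~300-point grid for loop-mechanics and persistence tests; GP cross-checks
at 2–25 training points against hand-rolled Cholesky conditioning (1e-8);
and two 20-seed campaign studies on the default landscape (budget 40
without contraction for merit-seeking, budget 60 with contraction for
experiments-to-all-converged), each paired with seeded random search.
Campaign histories standing in for the three real optimizer campaigns are
synthetic, generated in the test fixtures with the documented convergence
structure.

## Known limitations

* The boiling-point table, safety margin and solvent roster are
  configuration defaults chosen to reproduce the published grid size; a
  different lab should edit the YAML, not the engine.
* One GP over all substrates assumes their landscapes differ by roughly
  additive shifts; strongly interacting substrate effects would need a
  richer kernel.
* Constant-liar batches with frozen hyperparameters can under-explore when
  the batch size approaches the information content of the data; batch
  size 2 is well inside the safe regime.
* The interactive oracle trusts operator-entered conversions and yields
  verbatim; there is no outlier screening.
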