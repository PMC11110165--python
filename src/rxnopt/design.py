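"""Experiment selection: diversity-driven initialization and batch EI.

The opening block of a campaign is chosen without a model: points are picked
greedily, each maximizing the number of categorical option levels (over a
configurable set of coverage fields) not yet seen in the picks so far, with
seeded uniform tie-breaking.  On the full iodination grid this covers every
solvent, substrate, iodine source and catalyst in eleven experiments.

Subsequent experiments maximize expected improvement (EI) of the surrogate's
merit prediction.  Batches are assembled with the constant-liar heuristic:
after each pick a fantasy observation at the current best merit is appended
and EI is recomputed, so one batch does not pile onto a single mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .outcomes import Observation, Outcome
from .space import CandidatePoint, ParameterGrid
from .surrogate import MeritGP


@dataclass(frozen=True)
class DiversityConfig:
    """Greedy max-coverage initializer settings."""

    n_init: int = 11
    coverage_fields: tuple[str, ...] = (
        "alkyne",
        "solvent",
        "iodine_source",
        "catalyst",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass(frozen=True)
class AcquisitionConfig:
    """EI acquisition with constant-liar batching."""

    kind: str = "expected-improvement"
    xi: float = 0.01
    batch_size: int = 2
    liar_value: str = "best-merit"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


def greedy_diverse_init(
    grid: ParameterGrid, config: DiversityConfig = DiversityConfig()
) -> list[CandidatePoint]:
    """Pick ``n_init`` distinct points by greedy unseen-level coverage.

    At each step every remaining point is scored by how many of its levels on
    the coverage fields have not appeared in any earlier pick; a point of
    maximal score is chosen, ties broken uniformly with the seeded generator.
    Deterministic given the seed.
    """
    if len(grid) == 0:
        raise ValueError("grid is empty")
    if config.n_init > len(grid):
        raise ValueError(
            f"n_init={config.n_init} exceeds grid size {len(grid)}"
        )
    fields = [f for f in config.coverage_fields if f in grid.space]
    if set(fields) != set(config.coverage_fields):
        missing = set(config.coverage_fields) - set(fields)
        raise ValueError(f"coverage fields not in space: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    frame = grid.frame
    seen: dict[str, set] = {f: set() for f in fields}
    remaining = frame.index.to_numpy().copy()
    picks: list[int] = []
    for _ in range(config.n_init):
        novelty = np.zeros(len(remaining), dtype=int)
        sub = frame.loc[remaining]
        for f in fields:
            novelty += (~sub[f].isin(seen[f])).to_numpy(dtype=int)
        best = np.flatnonzero(novelty == novelty.max())
        chosen_pos = int(rng.choice(best))
        chosen = int(remaining[chosen_pos])
        picks.append(chosen)
        for f in fields:
            seen[f].add(frame.at[chosen, f])
        remaining = np.delete(remaining, chosen_pos)
    return [grid.point(i) for i in picks]


def coverage_complete_after(
    picks: Sequence[CandidatePoint], grid: ParameterGrid, fields: Sequence[str]
) -> int | None:
    """1-based pick count at which every level of every field is covered.

    Only levels that occur somewhere in the grid count as coverable.  Returns
    None if the picks never complete coverage.
    """
    needed = {
        f: set(grid.frame[f].unique()) for f in fields
    }
    seen: dict[str, set] = {f: set() for f in fields}
    for k, pt in enumerate(picks, start=1):
        for f in fields:
            seen[f].add(pt[f])
        if all(needed[f] <= seen[f] for f in fields):
            return k
    return None


def expected_improvement(
    mean: np.ndarray | float,
    sd: np.ndarray | float,
    best_seen: float,
    xi: float = 0.01,
) -> np.ndarray | float:
    """Expected improvement over ``best_seen`` for maximization.

    EI(x) = (mu - f* - xi) Phi(z) + sigma phi(z) with
    z = (mu - f* - xi) / sigma, and the deterministic limit
    max(0, mu - f* - xi) where sigma = 0.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be >= 0")
    improve = mean - best_seen - xi
    ei = np.maximum(improve, 0.0)
    pos = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(pos, improve / np.where(pos, sd, 1.0), 0.0)
    ei = np.where(pos, improve * norm.cdf(z) + sd * norm.pdf(z), ei)
    return float(ei) if ei.ndim == 0 else ei


@dataclass
class BatchSelection:
    """Result of one batch suggestion."""

    indices: list[int]
    points: list[CandidatePoint]
    exhausted: bool = False


def select_batch(
    model: MeritGP,
    grid: ParameterGrid,
    candidate_indices: np.ndarray | Sequence[int],
    history: Sequence[Observation],
    config: AcquisitionConfig = AcquisitionConfig(),
    rng: np.random.Generator | None = None,
) -> BatchSelection:
    """Choose a batch of unvisited candidates by constant-liar EI.

    ``candidate_indices`` must already exclude visited points and the points
    of converged substrates.  After each pick a fantasy observation at the
    best observed merit (the "liar") is appended, the GP is re-conditioned
    with fixed hyperparameters and EI is recomputed.  If fewer candidates
    remain than the batch size, all remaining are returned and the selection
    is flagged exhausted.
    """
    rng = rng or np.random.default_rng(0)
    idx = np.asarray(list(candidate_indices), dtype=int)
    if len(idx) == 0:
        return BatchSelection([], [], exhausted=True)
    exhausted = len(idx) < config.batch_size
    n_pick = min(config.batch_size, len(idx))
    best = max(obs.merit for obs in history)
    fantasies: list[Observation] = list(history)
    current = model
    chosen: list[int] = []
    names = grid.space.names
    for _ in range(n_pick):
        remaining = np.setdiff1d(idx, np.asarray(chosen, dtype=int))
        points = grid.points_at(remaining)
        pred = current.predict(points)
        ei = np.asarray(
            expected_improvement(pred.mean, pred.sd, best, config.xi)
        )
        ties = np.flatnonzero(np.isclose(ei, ei.max(), rtol=0, atol=1e-12))
        pick_pos = int(rng.choice(ties))
        pick = int(remaining[pick_pos])
        chosen.append(pick)
        if len(chosen) < n_pick:
            fantasy = Observation(
                point=points[pick_pos],
                outcome=Outcome(
                    conversion=0.0,
                    yield_=0.0,
                    merit=best,
                    raw_conversion=0.0,
                    raw_yield=0.0,
                ),
                experiment_index=0,
                point_index=pick,
                campaign_id="fantasy",
            )
            fantasies = fantasies + [fantasy]
            current = model.refit_fixed(fantasies)
    return BatchSelection(
        indices=chosen, points=[grid.point(i) for i in chosen], exhausted=exhausted
    )
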