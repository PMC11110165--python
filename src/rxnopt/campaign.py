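"""Closed-loop campaign orchestration and history replay.

One campaign is: an eleven-point greedy-diversity opening block, then
repeated rounds of {fit the merit surrogate on everything observed so far;
drop visited points and every point of an already-converged substrate from
the candidate set; pick a batch by constant-liar expected improvement;
evaluate it}.  A substrate leaves the search space the first time its
measured conversion strictly surpasses the stopping threshold; the campaign
ends when every substrate has converged, the experiment budget is exhausted,
or no candidates remain.  Experiment indices are 1-based; the opening block
is iteration 1 and every later batch adds one iteration.

All randomness flows from the campaign seed: the greedy tie-breaks use it
directly, and each iteration derives its own generator from (seed,
iteration), which is what makes a resumed campaign bit-identical to an
uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design import (
    AcquisitionConfig,
    DiversityConfig,
    greedy_diverse_init,
    select_batch,
)
from .outcomes import (
    MeritConfig,
    Observation,
    Outcome,
    StoppingRule,
)
from .space import CandidatePoint, ParameterGrid
from .surrogate import FeatureEncoding, MeritGP

STATE_FORMAT = "rxnopt-campaign/1"

Oracle = Callable[[CandidatePoint, int], Outcome]


class StateFormatError(ValueError):
    """A campaign state file has the wrong version or is corrupt."""


@dataclass(frozen=True)
class CampaignConfig:
    merit: MeritConfig = field(default_factory=MeritConfig)
    stopping: StoppingRule = field(default_factory=StoppingRule)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    max_experiments: int = 60
    seed: int = 0
    gp_restarts: int = 5
    campaign_id: str = "campaign"

    def __post_init__(self) -> None:
        if self.max_experiments < self.diversity.n_init:
            raise ValueError("budget smaller than the initial block")


@dataclass
class CampaignState:
    """Everything needed to continue or audit a campaign."""

    config: CampaignConfig
    visited: list[int] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    converged: set[str] = field(default_factory=set)
    iteration: int = 0
    stop_reason: str | None = None

    @property
    def n_experiments(self) -> int:
        return len(self.observations)

    def best_merit(self) -> float:
        return max((o.merit for o in self.observations), default=float("-inf"))


@dataclass
class ConvergenceReport:
    """Per-substrate first-crossing indices and the global stop."""

    first_pass: dict[str, int | None]
    global_stop_index: int | None
    experiments_per_alkyne: dict[str, int]
    stop_reason: str | None = None

    @property
    def all_converged(self) -> bool:
        return bool(self.first_pass) and all(
            v is not None for v in self.first_pass.values()
        )


def replay_campaign(
    observations: Sequence[Observation],
    rule: StoppingRule = StoppingRule(),
    alkynes: Sequence[str] | None = None,
) -> ConvergenceReport:
    """Scan an ordered history once for the stopping structure.

    For each substrate: the 1-based index of the first observation whose
    conversion strictly surpasses the threshold (None if it never does), and
    how many of its own experiments ran before that one (the crossing
    experiment itself is not counted).  The global stop is the index at
    which the last substrate first crosses, defined only when every
    substrate converges.
    """
    labels = list(alkynes) if alkynes is not None else sorted(
        {obs.alkyne for obs in observations}
    )
    first: dict[str, int | None] = {a: None for a in labels}
    counts: dict[str, int] = {a: 0 for a in labels}
    for i, obs in enumerate(observations, start=1):
        a = obs.alkyne
        if a not in first:
            first[a] = None
            counts[a] = 0
        if first[a] is None:
            if rule.passes(obs.outcome.conversion):
                first[a] = i
            else:
                counts[a] += 1
    done = [v for v in first.values() if v is not None]
    global_stop = max(done) if first and len(done) == len(first) else None
    return ConvergenceReport(
        first_pass=first,
        global_stop_index=global_stop,
        experiments_per_alkyne=counts,
    )


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), iteration])


def _iteration_int_seed(seed: int, iteration: int) -> int:
    return int(np.random.SeedSequence([seed % (2**31), iteration]).generate_state(1)[0] % (2**31))


def _candidate_indices(
    grid: ParameterGrid, visited: Sequence[int], converged: set[str]
) -> np.ndarray:
    frame = grid.frame
    mask = ~frame.index.isin(visited)
    if converged:
        mask &= ~frame["alkyne"].isin(converged).to_numpy()
    return frame.index.to_numpy()[mask]


def _evaluate(
    oracle: Oracle,
    point: CandidatePoint,
    index: int,
    state: CampaignState,
) -> None:
    exp_index = state.n_experiments + 1
    outcome = oracle(point, exp_index)
    state.observations.append(
        Observation(
            point=point,
            outcome=outcome,
            experiment_index=exp_index,
            point_index=index,
            campaign_id=state.config.campaign_id,
        )
    )
    state.visited.append(int(index))


def _update_converged(state: CampaignState) -> None:
    rule = state.config.stopping
    for obs in state.observations:
        if rule.passes(obs.outcome.conversion):
            state.converged.add(obs.alkyne)


def run_campaign(
    oracle: Oracle,
    grid: ParameterGrid,
    config: CampaignConfig = CampaignConfig(),
    state: CampaignState | None = None,
) -> tuple[CampaignState, ConvergenceReport]:
    """Run (or resume) the closed loop until convergence or budget.

    ``oracle`` is called as ``oracle(point, experiment_index)`` and must
    return an :class:`Outcome` for every feasible point.  Reproducible:
    identical (config, grid, oracle) give an identical history.
    """
    alkynes = list(dict.fromkeys(grid.frame["alkyne"]))
    state = state or CampaignState(config=config)
    config = state.config
    index_lookup = _build_index_lookup(grid)
    encoding = FeatureEncoding(grid.space, grid)

    if state.iteration == 0:
        div = dataclasses.replace(config.diversity, seed=config.seed)
        for pt in greedy_diverse_init(grid, div):
            _evaluate(oracle, pt, index_lookup[_point_key(pt, grid)], state)
        state.iteration = 1
        _update_converged(state)

    while True:
        if all(a in state.converged for a in alkynes):
            state.stop_reason = "converged"
            break
        if state.n_experiments >= config.max_experiments:
            state.stop_reason = "budget"
            break
        candidates = _candidate_indices(grid, state.visited, state.converged)
        if len(candidates) == 0:
            state.stop_reason = "exhausted"
            break
        iteration = state.iteration + 1
        batch_size = min(
            config.acquisition.batch_size,
            config.max_experiments - state.n_experiments,
        )
        acq = dataclasses.replace(config.acquisition, batch_size=batch_size)
        model = MeritGP(
            encoding,
            n_restarts=config.gp_restarts,
            seed=_iteration_int_seed(config.seed, iteration),
        ).fit(state.observations)
        batch = select_batch(
            model,
            grid,
            candidates,
            state.observations,
            acq,
            rng=_iteration_rng(config.seed, iteration),
        )
        for idx, pt in zip(batch.indices, batch.points):
            _evaluate(oracle, pt, idx, state)
        state.iteration = iteration
        _update_converged(state)

    report = replay_campaign(
        state.observations, config.stopping, alkynes=alkynes
    )
    report.stop_reason = state.stop_reason
    return state, report


def random_search_campaign(
    oracle: Oracle,
    grid: ParameterGrid,
    config: CampaignConfig = CampaignConfig(),
) -> tuple[CampaignState, ConvergenceReport]:
    """Baseline: same loop shape and stopping, uniformly random suggestions.

    Shares the stopping rule, contraction and budget with
    :func:`run_campaign` so the two are compared like for like.
    """
    alkynes = list(dict.fromkeys(grid.frame["alkyne"]))
    state = CampaignState(config=config)
    rng = np.random.default_rng(config.seed)
    while True:
        _update_converged(state)
        if all(a in state.converged for a in alkynes):
            state.stop_reason = "converged"
            break
        if state.n_experiments >= config.max_experiments:
            state.stop_reason = "budget"
            break
        candidates = _candidate_indices(grid, state.visited, state.converged)
        if len(candidates) == 0:
            state.stop_reason = "exhausted"
            break
        idx = int(rng.choice(candidates))
        _evaluate(oracle, grid.point(idx), idx, state)
    report = replay_campaign(state.observations, config.stopping, alkynes=alkynes)
    report.stop_reason = state.stop_reason
    return state, report


# --------------------------------------------------------------------------
# Point-index lookup

def _point_key(point: CandidatePoint, grid: ParameterGrid) -> tuple:
    return tuple(point[n] for n in grid.space.names)


def _build_index_lookup(grid: ParameterGrid) -> dict[tuple, int]:
    names = grid.space.names
    return {
        tuple(row): int(i)
        for i, row in zip(
            grid.frame.index, grid.frame[names].itertuples(index=False, name=None)
        )
    }


# --------------------------------------------------------------------------
# Persistence: state as JSON, histories as JSON-lines.

def _config_to_dict(config: CampaignConfig) -> dict:
    return dataclasses.asdict(config)


def _config_from_dict(data: dict) -> CampaignConfig:
    return CampaignConfig(
        merit=MeritConfig(**data["merit"]),
        stopping=StoppingRule(**data["stopping"]),
        diversity=DiversityConfig(
            n_init=data["diversity"]["n_init"],
            coverage_fields=tuple(data["diversity"]["coverage_fields"]),
            seed=data["diversity"]["seed"],
        ),
        acquisition=AcquisitionConfig(**data["acquisition"]),
        max_experiments=data["max_experiments"],
        seed=data["seed"],
        gp_restarts=data["gp_restarts"],
        campaign_id=data["campaign_id"],
    )


def save_state(state: CampaignState, path: str | Path) -> None:
    payload = {
        "format": STATE_FORMAT,
        "config": _config_to_dict(state.config),
        "visited": [int(i) for i in state.visited],
        "observations": [obs.to_record() for obs in state.observations],
        "param_names": list(state.observations[0].point) if state.observations else [],
        "converged": sorted(state.converged),
        "iteration": state.iteration,
        "stop_reason": state.stop_reason,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_state(path: str | Path) -> CampaignState:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StateFormatError(f"cannot read campaign state: {exc}") from exc
    if payload.get("format") != STATE_FORMAT:
        raise StateFormatError(
            f"unsupported state format {payload.get('format')!r}"
        )
    config = _config_from_dict(payload["config"])
    names = payload["param_names"]
    observations = [
        Observation.from_record(rec, names, config.merit)
        for rec in payload["observations"]
    ]
    return CampaignState(
        config=config,
        visited=[int(i) for i in payload["visited"]],
        observations=observations,
        converged=set(payload["converged"]),
        iteration=int(payload["iteration"]),
        stop_reason=payload["stop_reason"],
    )


def save_history(observations: Sequence[Observation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for obs in observations:
            fh.write(json.dumps(obs.to_record()) + "\n")


def load_history(
    path: str | Path,
    param_names: Sequence[str],
    merit_config: MeritConfig = MeritConfig(),
) -> list[Observation]:
    observations = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                observations.append(
                    Observation.from_record(
                        json.loads(line), param_names, merit_config
                    )
                )
    return observations
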