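"""Synthetic reaction landscape standing in for the robotic platform.

The generator emulates the qualitative chemistry of the two iodination
routes so the whole closed loop can be exercised and measured without a lab:

* a broad chloramine-route optimum — polar solvents (MeOH, CH3CN,
  CH3CN/H2O), temperatures up to 65 deg C, at least stoichiometric reagents,
  no catalyst — where the noiseless merit exceeds 0.8;
* uncatalyzed NIS reactions with low conversion and yield (selectivity is
  driven by the acid catalyst, which these points lack);
* a deceptive NIS + PTSA region with conversion above 0.8 but near-zero
  yield (the acid hydrates the alkyne to the ketone instead).

Effects are additive with route gates, then clamped to [0, 1]; measurement
scatter is independent Gaussian noise on conversion and yield, allowed to
fall slightly outside [0, 1] as real assays do, with merit computed from the
clipped values.  This is a behavioural test-bed, not a kinetic model, and it
makes no claim to predict real yields.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .outcomes import MeritConfig, Outcome, compute_merit
from .space import CandidatePoint, ParameterGrid


class InfeasiblePointError(ValueError):
    """The oracle was asked to run a chemically inconsistent point."""


def _default_solvent_effects() -> dict[str, float]:
    return {
        "MeOH": 0.30,
        "CH3CN": 0.22,
        "CH3CN/H2O": 0.20,
        "THF": 0.05,
        "DMF": 0.00,
        "DMSO": -0.05,
        "DCM": -0.05,
        "EtOAc": 0.00,
        "1,4-dioxane": -0.02,
        "MTBE": -0.08,
        "DCE": -0.05,
    }


def _default_alkyne_shifts() -> dict[str, float]:
    # small shifts (<= 0.1) so optima transfer across substrates; the
    # ortho-chloro substrate is deliberately the hardest
    return {
        "2-ethynyltoluene": 0.02,
        "4-ethynyltoluene": 0.00,
        "1-chloro-4-ethynylbenzene": -0.03,
        "1-chloro-2-ethynylbenzene": -0.06,
    }


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic conversion/yield surfaces.

    All effect magnitudes are in fraction units (the scale of conversion and
    yield).  Defaults are fixed so the documented qualitative structure
    holds; see the package methods note for the calibration arithmetic.
    """

    # chloramine route: conversion rises more steeply with stoichiometry than
    # yield, so crossing the 80% stopping line requires both a polar solvent
    # and an adequate reagent excess, not the solvent alone
    base_conversion: float = 0.50
    base_yield: float = 0.55
    solvent_effects: dict[str, float] = field(default_factory=_default_solvent_effects)
    conv_chloramine_eq_gain: float = 0.06   # per eq above 1, conversion
    conv_iodide_eq_gain: float = 0.08
    yield_chloramine_eq_gain: float = 0.04  # per eq above 1, yield
    yield_iodide_eq_gain: float = 0.05
    temp_optimum: float = 65.0          # deg C; no penalty at or below
    temp_penalty: float = 0.35          # quadratic coefficient over 30 deg C
    # NIS route
    nis_base_conversion: float = 0.12
    nis_base_yield: float = 0.05
    nis_modifier_scale: float = 0.3     # damping of solvent/substrate effects
    nis_eq_gain: float = 0.02
    nis_temp_gain: float = 0.05         # linear rise from 25 to 95 deg C
    ptsa_base_conversion: float = 0.55  # acid-driven consumption of alkyne
    ptsa_temp_gain: float = 0.20
    ptsa_yield: float = 0.02            # yield collapse under the acid
    acoh_conversion_boost: float = 0.35
    acoh_yield_boost: float = 0.30
    # shared
    alkyne_shifts: dict[str, float] = field(default_factory=_default_alkyne_shifts)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _check_route_consistency(point: Mapping) -> str:
    """Return the route name, or raise for chemically inconsistent points."""
    if float(point["iodine_source_eq"]) < 1:
        raise InfeasiblePointError("iodine source below stoichiometric amount")
    catalyst, cat_eq = point["catalyst"], float(point["catalyst_eq"])
    if (catalyst == "none") != (cat_eq == 0):
        raise InfeasiblePointError("catalyst / catalyst_eq mismatch")
    if point["iodine_source"] == "NIS":
        if float(point["chloramine_eq"]) != 0:
            raise InfeasiblePointError("NIS combined with chloramine oxidant")
        return "NIS"
    if float(point["chloramine_eq"]) < 1:
        raise InfeasiblePointError("chloramine route below stoichiometric amount")
    if catalyst != "none":
        raise InfeasiblePointError("acid catalyst on the chloramine route")
    return "chloramine"


def true_response(
    point: Mapping, config: LandscapeConfig = LandscapeConfig()
) -> tuple[float, float]:
    """Noiseless (conversion, yield) at a feasible point, clamped to [0, 1]."""
    route = _check_route_consistency(point)
    b = config.solvent_effects.get(point["solvent"], 0.0)
    s = config.alkyne_shifts.get(point["alkyne"], 0.0)
    temp = float(point["temperature"])
    if route == "chloramine":
        u = float(point["chloramine_eq"]) - 1.0
        v = float(point["iodine_source_eq"]) - 1.0
        tp = 0.0
        if temp > config.temp_optimum:
            tp = -config.temp_penalty * ((temp - config.temp_optimum) / 30.0) ** 2
        conv = (
            config.base_conversion + b + s + tp
            + config.conv_chloramine_eq_gain * u
            + config.conv_iodide_eq_gain * v
        )
        yld = (
            config.base_yield + b + s + tp
            + config.yield_chloramine_eq_gain * u
            + config.yield_iodide_eq_gain * v
        )
    else:
        scale = config.nis_modifier_scale
        e = config.nis_eq_gain * (float(point["iodine_source_eq"]) - 1.0)
        tau = (temp - 25.0) / 70.0
        conv = config.nis_base_conversion + scale * (b + s) + e + config.nis_temp_gain * tau
        yld = config.nis_base_yield + 0.5 * scale * (b + s) + 0.5 * e
        if point["catalyst"] == "PTSA":
            # electrophilic hydration of the alkyne: the material is consumed
            # but the iodoalkyne is not formed
            conv = config.ptsa_base_conversion + b + s + config.ptsa_temp_gain * tau
            yld = config.ptsa_yield
        elif point["catalyst"] == "AcOH":
            conv += config.acoh_conversion_boost
            yld += config.acoh_yield_boost
    return float(np.clip(conv, 0.0, 1.0)), float(np.clip(yld, 0.0, 1.0))


def _point_digest(point: Mapping) -> int:
    canon = repr(sorted((str(k), str(v)) for k, v in point.items()))
    return zlib.crc32(canon.encode())


def sample_outcome(
    point: Mapping,
    config: LandscapeConfig = LandscapeConfig(),
    draw_seed: int = 0,
    merit_config: MeritConfig = MeritConfig(),
) -> Outcome:
    """One noisy measurement; deterministic per (point, config seed, draw)."""
    conv, yld = true_response(point, config)
    rng = np.random.default_rng(
        [config.seed % (2**31), draw_seed % (2**31), _point_digest(point)]
    )
    noise = rng.normal(0.0, config.noise_sd, size=2) if config.noise_sd > 0 else (0.0, 0.0)
    return Outcome.from_raw(
        raw_yield=yld + noise[1], raw_conversion=conv + noise[0], config=merit_config
    )


@dataclass
class GroundTruth:
    """Noiseless surfaces over a grid plus the merit argmax."""

    indices: np.ndarray
    conversion: np.ndarray
    yield_: np.ndarray
    merit: np.ndarray
    argmax_index: int
    argmax_merit: float

    def to_frame(self, grid: ParameterGrid) -> pd.DataFrame:
        df = grid.frame.copy()
        df["true_conversion"] = self.conversion
        df["true_yield"] = self.yield_
        df["true_merit"] = self.merit
        return df


def ground_truth(
    config: LandscapeConfig,
    grid: ParameterGrid,
    merit_config: MeritConfig = MeritConfig(),
) -> GroundTruth:
    """Full noiseless scan; ties on merit resolve to the lowest grid index."""
    names = grid.space.names
    conv = np.empty(len(grid))
    yld = np.empty(len(grid))
    for i, row in enumerate(grid.frame[names].itertuples(index=False, name=None)):
        conv[i], yld[i] = true_response(dict(zip(names, row)), config)
    merit = np.array(
        [compute_merit(y, c, merit_config) for y, c in zip(yld, conv)]
    )
    pos = int(np.argmax(merit))
    return GroundTruth(
        indices=grid.indices,
        conversion=conv,
        yield_=yld,
        merit=merit,
        argmax_index=int(grid.indices[pos]),
        argmax_merit=float(merit[pos]),
    )


def make_oracle(config: LandscapeConfig = LandscapeConfig()):
    """Wrap the landscape as the campaign-facing callable.

    The returned function has signature ``(point, draw_seed) -> Outcome``,
    the contract :func:`rxnopt.campaign.run_campaign` expects.
    """

    def oracle(point: CandidatePoint, draw_seed: int = 0) -> Outcome:
        return sample_outcome(point, config, draw_seed)

    return oracle


def interactive_oracle(prompt=input):
    """Operator-driven oracle: ask for measured conversion and yield.

    Stands in for a real platform when the loop is run against actual
    experiments from a terminal.
    """

    def oracle(point: CandidatePoint, draw_seed: int = 0) -> Outcome:
        print(f"run experiment: {dict(point)}")
        conv = float(prompt("measured conversion (fraction): "))
        yld = float(prompt("measured yield (fraction): "))
        return Outcome.from_raw(raw_yield=yld, raw_conversion=conv)

    return oracle
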