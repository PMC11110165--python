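"""Reaction outcomes: conversion, yield, the weighted-sum merit, convergence.

The assay quantifies the reaction mixture by HPLC against an internal
standard added in the same amount as the starting alkyne, so the internal
standard concentration doubles as the t = 0 alkyne concentration.
Conversion is the consumed fraction of starting material, 1 - C_SM/C_IS;
yield is the product concentration over the internal standard, C_prod/C_IS.
Both are fractions; calibration offsets and injection scatter can push raw
values slightly outside [0, 1], so raw values are preserved and clipped
copies feed the scalarized merit

    merit = w_yield * clip(yield) + w_conversion * clip(conversion)

with default weights 0.9 / 0.1 — the optimizer's single maximization target.
A substrate counts as converged once any of its observations strictly
surpasses the conversion threshold (default 80%).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .space import CandidatePoint


class MeasurementError(ValueError):
    """A measured input is physically inadmissible (e.g. C_IS <= 0)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response: area = slope * concentration + intercept."""

    analyte: str
    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise MeasurementError(f"{self.analyte}: slope must be > 0")


def concentration_from_area(area: float, curve: CalibrationCurve) -> float:
    """Invert a calibration curve; negative results are returned, not hidden.

    A slightly negative concentration arises when the detector area falls
    below the calibration intercept — a known offset artefact.  A warning is
    emitted and the caller decides whether to clip.
    """
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"{curve.analyte}: area {area} below calibration intercept "
            f"{curve.intercept}; negative concentration {conc:.4g}",
            stacklevel=2,
        )
    return conc


def compute_conversion(c_sm: float, c_is: float) -> float:
    """Fraction of consumed starting material, 1 - C_SM / C_IS."""
    if c_is <= 0:
        raise MeasurementError("internal standard concentration must be > 0")
    return 1.0 - c_sm / c_is


def compute_yield(c_product: float, c_is: float) -> float:
    """Product concentration normalized by the internal standard."""
    if c_is <= 0:
        raise MeasurementError("internal standard concentration must be > 0")
    return c_product / c_is


@dataclass(frozen=True)
class MeritConfig:
    """Weights of the yield/conversion scalarization; must sum to one."""

    w_yield: float = 0.9
    w_conversion: float = 0.1
    clip_low: float = 0.0
    clip_high: float = 1.0

    def __post_init__(self) -> None:
        if self.w_yield < 0 or self.w_conversion < 0:
            raise ValueError("merit weights must be >= 0")
        if abs(self.w_yield + self.w_conversion - 1.0) > 1e-12:
            raise ValueError("merit weights must sum to 1")


def compute_merit(
    outcome_yield: float,
    outcome_conversion: float,
    config: MeritConfig = MeritConfig(),
) -> float:
    """Weighted sum of the clipped yield and conversion; lies in [0, 1]."""
    y = float(np.clip(outcome_yield, config.clip_low, config.clip_high))
    c = float(np.clip(outcome_conversion, config.clip_low, config.clip_high))
    return config.w_yield * y + config.w_conversion * c


@dataclass(frozen=True)
class Outcome:
    """Measured result of one experiment, raw and clipped.

    ``conversion`` and ``yield_`` are the clipped fractions that the merit is
    computed from; the unclipped assay values are kept in ``raw_*`` so a
    replayed record is never destroyed by clipping.
    """

    conversion: float
    yield_: float
    merit: float
    raw_conversion: float
    raw_yield: float

    @classmethod
    def from_raw(
        cls,
        raw_yield: float,
        raw_conversion: float,
        config: MeritConfig = MeritConfig(),
    ) -> "Outcome":
        y = float(np.clip(raw_yield, config.clip_low, config.clip_high))
        c = float(np.clip(raw_conversion, config.clip_low, config.clip_high))
        return cls(
            conversion=c,
            yield_=y,
            merit=compute_merit(raw_yield, raw_conversion, config),
            raw_conversion=float(raw_conversion),
            raw_yield=float(raw_yield),
        )


@dataclass(frozen=True)
class Observation:
    """A candidate point plus its measured outcome and campaign metadata."""

    point: CandidatePoint
    outcome: Outcome
    experiment_index: int = 0          # 1-based position in the campaign
    point_index: int | None = None     # stable grid id, if drawn from a grid
    campaign_id: str = ""

    @property
    def alkyne(self) -> str:
        return self.point["alkyne"]

    @property
    def merit(self) -> float:
        return self.outcome.merit

    def to_record(self) -> dict[str, Any]:
        rec = dict(self.point)
        rec.update(
            campaign_id=self.campaign_id,
            experiment_index=self.experiment_index,
            point_index=self.point_index,
            conversion=self.outcome.raw_conversion,
            **{"yield": self.outcome.raw_yield},
            merit=self.outcome.merit,
        )
        return rec

    @classmethod
    def from_record(
        cls,
        rec: Mapping[str, Any],
        param_names: Iterable[str],
        config: MeritConfig = MeritConfig(),
    ) -> "Observation":
        point = CandidatePoint({k: rec[k] for k in param_names})
        outcome = Outcome.from_raw(rec["yield"], rec["conversion"], config)
        raw_idx = rec.get("point_index")
        return cls(
            point=point,
            outcome=outcome,
            experiment_index=int(rec.get("experiment_index", 0)),
            point_index=None if raw_idx is None or (
                isinstance(raw_idx, float) and np.isnan(raw_idx)
            ) else int(raw_idx),
            campaign_id=str(rec.get("campaign_id", "")),
        )


@dataclass(frozen=True)
class StoppingRule:
    """Per-substrate stopping: conversion must strictly surpass the threshold."""

    conversion_threshold: float = 0.80

    def __post_init__(self) -> None:
        # threshold 1.0 disables convergence: clipped conversion never
        # strictly exceeds it, so the loop runs to its budget
        if not 0.0 < self.conversion_threshold <= 1.0:
            raise ValueError("conversion threshold must lie in (0, 1]")

    def passes(self, conversion: float) -> bool:
        return conversion > self.conversion_threshold


def check_converged(
    history: Iterable[Observation], rule: StoppingRule = StoppingRule()
) -> set[str]:
    """Substrates with at least one observation strictly above the threshold."""
    return {
        obs.alkyne for obs in history if rule.passes(obs.outcome.conversion)
    }
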