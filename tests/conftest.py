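"""Shared fixtures: grids, landscapes and synthetic reference histories."""

from __future__ import annotations

import numpy as np
import pytest

from rxnopt import (
    CandidatePoint,
    ConstraintRule,
    LandscapeConfig,
    Observation,
    Outcome,
    ParameterDef,
    ParameterSpace,
    build_default_grid,
    build_grid,
    default_space,
)

ALKYNE_A = "2-ethynyltoluene"
ALKYNE_B = "1-chloro-2-ethynylbenzene"
ALKYNE_C = "4-ethynyltoluene"
ALKYNE_D = "1-chloro-4-ethynylbenzene"
COVERAGE_FIELDS = ("alkyne", "solvent", "iodine_source", "catalyst")


@pytest.fixture(scope="session")
def space_rules():
    return default_space()


@pytest.fixture(scope="session")
def default_grid():
    return build_default_grid()


@pytest.fixture(scope="session")
def landscape():
    return LandscapeConfig(seed=11)


def make_toy_space(**overrides):
    """A reduced iodination-style space; keyword args replace option lists."""
    opts = {
        "alkyne": (ALKYNE_A, ALKYNE_B),
        "chloramine_eq": (0, 1, 2),
        "solvent": ("MeOH", "DMF", "DCM"),
        "iodine_source": ("KI", "NIS"),
        "iodine_source_eq": (1, 2),
        "catalyst": ("PTSA", "none"),
        "catalyst_eq": (0, 0.1),
        "temperature": (25, 65, 95),
    }
    opts.update(overrides)
    kinds = {
        "alkyne": "categorical",
        "chloramine_eq": "ordinal-numeric",
        "solvent": "categorical",
        "iodine_source": "categorical",
        "iodine_source_eq": "ordinal-numeric",
        "catalyst": "categorical",
        "catalyst_eq": "ordinal-numeric",
        "temperature": "ordinal-numeric",
    }
    return ParameterSpace(
        [ParameterDef(n, kinds[n], tuple(v)) for n, v in opts.items()]
    )


def toy_rules(boiling_points=None, margin=5.0):
    bps = boiling_points or {"MeOH": 65, "DMF": 153, "DCM": 40}
    return [
        ConstraintRule(
            "bp-cap",
            "max-temperature-by-solvent",
            {
                "boiling_points": bps,
                "safety_margin": margin,
            },
        ),
        ConstraintRule(
            "nis-no-chloramine",
            "conditional-requirement",
            {"when": {"iodine_source": ["NIS"]}, "require": {"chloramine_eq": [0]}},
        ),
        ConstraintRule(
            "chloramine-stoich",
            "min-equivalents-when-active",
            {"when": {"iodine_source": ["KI"]}, "field": "chloramine_eq", "min": 1},
        ),
        ConstraintRule(
            "no-acid-with-chloramine",
            "forbidden-combination",
            {"a": {"chloramine_eq": [1, 2]}, "b": {"catalyst": ["PTSA"]}},
        ),
        ConstraintRule(
            "catalyst-eq-none",
            "conditional-requirement",
            {"when": {"catalyst": ["none"]}, "require": {"catalyst_eq": [0]}},
        ),
        ConstraintRule(
            "catalyst-eq-active",
            "conditional-requirement",
            {"when": {"catalyst": ["PTSA"]}, "require": {"catalyst_eq": [0.1]}},
        ),
    ]


@pytest.fixture(scope="session")
def toy_grid():
    space = make_toy_space()
    return build_grid(space, toy_rules())


# ---------------------------------------------------------------------------
# Synthetic stand-in campaign histories.
#
# The real deposited campaign data is not bundled; these histories are
# SYNTHETIC stand-ins constructed to carry the published convergence
# structure of the three optimizer campaigns: a shared 11-experiment opening
# block with below-threshold conversions, per-substrate first crossings of
# the 80% line at experiments 17/19/20/22 for the first campaign (ending at
# 23 experiments), the slowest campaign ending at 25, 16 of the 49 pooled
# observations above 80% conversion, and own-experiment counts before
# convergence of 3/10/2/3.

_BELOW = [
    0.12, 0.33, 0.18, 0.41, 0.27, 0.55, 0.09, 0.62, 0.21, 0.48,
    0.36, 0.15, 0.58, 0.30, 0.44, 0.24, 0.51, 0.39, 0.66, 0.19,
    0.46, 0.28, 0.60, 0.35, 0.13, 0.53, 0.42, 0.23, 0.70, 0.31,
]
_ABOVE = [0.88, 0.92, 0.85, 0.95, 0.83, 0.90, 0.87, 0.93, 0.84, 0.89,
          0.91, 0.86, 0.94, 0.82, 0.96, 0.81]


class _PointPicker:
    """Deterministically hand out distinct feasible points per substrate."""

    def __init__(self, grid):
        self.grid = grid
        self.cursor: dict[str, int] = {}

    def chloramine(self, alkyne):
        f = self.grid.frame
        sel = f.index[(f["alkyne"] == alkyne) & (f["iodine_source"] != "NIS")]
        k = self.cursor.get(alkyne, 0)
        self.cursor[alkyne] = k + 7  # stride for variety in the encoding
        return self.grid.point(int(sel[k % len(sel)]))

    def nis_ptsa(self, alkyne):
        f = self.grid.frame
        sel = f.index[
            (f["alkyne"] == alkyne)
            & (f["iodine_source"] == "NIS")
            & (f["catalyst"] == "PTSA")
            & (f["solvent"] == "CH3CN/H2O")
            & (f["temperature"] == 55)
        ]
        return self.grid.point(int(sel[0]))


def _obs(point, conv, yld, index, campaign):
    return Observation(
        point=point,
        outcome=Outcome.from_raw(raw_yield=yld, raw_conversion=conv),
        experiment_index=index,
        campaign_id=campaign,
    )


def make_reference_histories(grid):
    """Build the three synthetic stand-in campaign histories (see above)."""
    picker = _PointPicker(grid)
    below = iter(_BELOW * 3)
    above = iter(_ABOVE)

    def lo(alkyne, index, campaign):
        conv = next(below)
        return _obs(picker.chloramine(alkyne), conv, max(conv - 0.1, 0.02), index, campaign)

    def hi(alkyne, index, campaign, nis=False):
        conv = next(above)
        if nis:
            return _obs(picker.nis_ptsa(alkyne), conv, 0.02, index, campaign)
        return _obs(picker.chloramine(alkyne), conv, conv - 0.05, index, campaign)

    A, B, C, D = ALKYNE_A, ALKYNE_B, ALKYNE_C, ALKYNE_D

    init_order = [A, B, D, B, B, B, A, B, B, C, B]
    init = [lo(a, i + 1, "shared-init") for i, a in enumerate(init_order)]

    def tail(campaign, layout):
        out = []
        for offset, (alkyne, kind) in enumerate(layout):
            idx = 12 + offset
            if kind == "lo":
                out.append(lo(alkyne, idx, campaign))
            elif kind == "hi":
                out.append(hi(alkyne, idx, campaign))
            else:
                out.append(hi(alkyne, idx, campaign, nis=True))
        return out

    camp_a = init + tail(
        "campaign-a",
        [(D, "lo"), (A, "lo"), (B, "lo"), (B, "lo"), (C, "lo"), (A, "hi"),
         (B, "lo"), (B, "hi"), (C, "hi"), (D, "lo"), (D, "hi"), (D, "hi")],
    )
    camp_b = init + tail(
        "campaign-b",
        [(B, "lo"), (B, "lo"), (A, "hi"), (A, "hi"), (C, "lo"), (C, "hi"),
         (B, "lo"), (B, "lo"), (D, "lo"), (B, "hi"), (D, "lo"), (D, "hi")],
    )
    camp_c = init + tail(
        "campaign-c",
        [(B, "lo"), (D, "lo"), (B, "lo"), (B, "lo"), (A, "hi"), (A, "nis"),
         (B, "lo"), (C, "hi"), (D, "lo"), (B, "lo"), (B, "hi"), (B, "hi"),
         (D, "lo"), (D, "hi")],
    )
    pooled = init + camp_a[11:] + camp_b[11:] + camp_c[11:]
    return {"a": camp_a, "b": camp_b, "c": camp_c, "pooled": pooled}


@pytest.fixture(scope="session")
def reference_histories(default_grid):
    return make_reference_histories(default_grid)
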