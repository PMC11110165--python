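"""Reaction parameter spaces, chemistry constraints and feasible grids.

A reaction condition is a point on a finite grid: every parameter is either
categorical (solvent, iodine source, catalyst, substrate) or a small ordered
set of numeric levels (equivalents, temperature in deg C).  The raw Cartesian
product is filtered through declarative constraint rules — a boiling-point cap
on the temperature, stoichiometry minimums, and exclusions of reagent
combinations that play no role in either iodination route — to produce the
feasible candidate set from which every experiment is drawn.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml


class ConfigError(ValueError):
    """A parameter-space or constraint configuration is invalid."""


class InfeasibleSpaceError(ValueError):
    """No grid point satisfies the constraint set."""


class GridFormatError(ValueError):
    """A grid file does not match the declared parameter space."""


CATEGORICAL = "categorical"
ORDINAL = "ordinal-numeric"


def _pyvalue(v):
    """Numpy scalar -> plain Python scalar (keeps points JSON-serializable)."""
    return v.item() if isinstance(v, np.generic) else v


@dataclass(frozen=True)
class ParameterDef:
    """One reaction parameter: a name, a kind and its ordered allowed values."""

    name: str
    kind: str
    options: tuple

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, ORDINAL):
            raise ConfigError(f"{self.name}: unknown parameter kind {self.kind!r}")
        opts = tuple(self.options)
        if self.kind == ORDINAL:
            try:
                opts = tuple(float(v) for v in opts)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{self.name}: non-numeric ordinal option") from exc
        object.__setattr__(self, "options", opts)
        if not opts:
            raise ConfigError(f"{self.name}: empty option list")
        if len(set(opts)) != len(opts):
            raise ConfigError(f"{self.name}: duplicate options")
        if self.kind == ORDINAL and any(
            b <= a for a, b in zip(opts, opts[1:])
        ):
            raise ConfigError(f"{self.name}: ordinal options must strictly increase")

    @property
    def is_numeric(self) -> bool:
        return self.kind == ORDINAL


class CandidatePoint(Mapping):
    """An immutable parameter-name -> value mapping for one grid cell.

    Values are attribute-accessible (``point.solvent``) for the conventional
    field names of the iodination space, but the container is generic and
    works for any parameter set.
    """

    __slots__ = ("_data", "_hash")

    def __init__(self, data: Mapping[str, Any] | None = None, **fields: Any):
        merged = dict(data or {})
        merged.update(fields)
        object.__setattr__(self, "_data", merged)
        object.__setattr__(self, "_hash", hash(tuple(sorted(merged.items()))))

    def __getitem__(self, key: str) -> Any:
        return self._data[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __getattr__(self, name: str) -> Any:
        try:
            return self._data[name]
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name: str, value: Any) -> None:
        raise AttributeError("CandidatePoint is immutable")

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v!r}" for k, v in self._data.items())
        return f"CandidatePoint({inner})"


@dataclass(frozen=True)
class ConstraintRule:
    """A declarative feasibility rule with an explicit payload (no code)."""

    rule_id: str
    rule_kind: str
    payload: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule_kind not in _RULE_KINDS:
            raise ConfigError(
                f"{self.rule_id}: unknown rule kind {self.rule_kind!r}"
            )


class ParameterSpace:
    """An ordered collection of :class:`ParameterDef`."""

    def __init__(self, params: list[ParameterDef] | tuple[ParameterDef, ...]):
        self.params = tuple(params)
        if len({p.name for p in self.params}) != len(self.params):
            raise ConfigError("duplicate parameter names")
        self._by_name = {p.name: p for p in self.params}

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def __getitem__(self, name: str) -> ParameterDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[ParameterDef]:
        return iter(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def categorical(self) -> list[ParameterDef]:
        return [p for p in self.params if not p.is_numeric]

    def numeric(self) -> list[ParameterDef]:
        return [p for p in self.params if p.is_numeric]

    def validate_point(self, point: Mapping[str, Any]) -> None:
        for p in self.params:
            if p.name not in point:
                raise ConfigError(f"point is missing field {p.name!r}")
            value = point[p.name]
            if p.is_numeric:
                value = float(value)
            if value not in p.options:
                raise ConfigError(
                    f"value {point[p.name]!r} not an option of {p.name!r}"
                )


# --------------------------------------------------------------------------
# Constraint engine: one scalar check and one vectorized mask per rule kind.

def _match_scalar(point: Mapping, cond: Mapping[str, list]) -> bool:
    return all(point[f] in vals for f, vals in cond.items())


def _match_mask(df: pd.DataFrame, cond: Mapping[str, list]) -> pd.Series:
    m = pd.Series(True, index=df.index)
    for f, vals in cond.items():
        m &= df[f].isin(vals)
    return m


def _check_max_temp(point: Mapping, payload: Mapping) -> bool:
    bps = payload["boiling_points"]
    margin = float(payload.get("safety_margin", 0.0))
    solvent = point[payload.get("solvent_field", "solvent")]
    temp = float(point[payload.get("temperature_field", "temperature")])
    return temp <= float(bps[solvent]) - margin


def _mask_max_temp(df: pd.DataFrame, payload: Mapping) -> pd.Series:
    bps = payload["boiling_points"]
    margin = float(payload.get("safety_margin", 0.0))
    caps = df[payload.get("solvent_field", "solvent")].map(
        lambda s: float(bps[s]) - margin
    )
    return df[payload.get("temperature_field", "temperature")].astype(float) <= caps


def _check_min_eq(point: Mapping, payload: Mapping) -> bool:
    when = payload.get("when")
    if when and not _match_scalar(point, when):
        return True
    return float(point[payload["field"]]) >= float(payload["min"])


def _mask_min_eq(df: pd.DataFrame, payload: Mapping) -> pd.Series:
    ok = df[payload["field"]].astype(float) >= float(payload["min"])
    when = payload.get("when")
    if when:
        return ok | ~_match_mask(df, when)
    return ok


def _check_forbidden(point: Mapping, payload: Mapping) -> bool:
    return not (
        _match_scalar(point, payload["a"]) and _match_scalar(point, payload["b"])
    )


def _mask_forbidden(df: pd.DataFrame, payload: Mapping) -> pd.Series:
    return ~(_match_mask(df, payload["a"]) & _match_mask(df, payload["b"]))


def _check_conditional(point: Mapping, payload: Mapping) -> bool:
    if not _match_scalar(point, payload["when"]):
        return True
    return _match_scalar(point, payload["require"])


def _mask_conditional(df: pd.DataFrame, payload: Mapping) -> pd.Series:
    return _match_mask(df, payload["require"]) | ~_match_mask(df, payload["when"])


_RULE_KINDS = {
    "max-temperature-by-solvent": (_check_max_temp, _mask_max_temp),
    "min-equivalents-when-active": (_check_min_eq, _mask_min_eq),
    "forbidden-combination": (_check_forbidden, _mask_forbidden),
    "conditional-requirement": (_check_conditional, _mask_conditional),
}


def _rule_fields(rule: ConstraintRule) -> set[str]:
    p = rule.payload
    if rule.rule_kind == "max-temperature-by-solvent":
        return {p.get("solvent_field", "solvent"), p.get("temperature_field", "temperature")}
    if rule.rule_kind == "min-equivalents-when-active":
        return {p["field"], *(p.get("when") or {})}
    if rule.rule_kind == "forbidden-combination":
        return {*p["a"], *p["b"]}
    return {*p["when"], *p["require"]}


def validate_constraints(space: ParameterSpace, constraints: list[ConstraintRule]) -> None:
    """Reject rules referencing unknown fields or nonsensical payloads."""
    for rule in constraints:
        for f in _rule_fields(rule):
            if f not in space:
                raise ConfigError(
                    f"constraint {rule.rule_id!r} references unknown field {f!r}"
                )
        if rule.rule_kind == "max-temperature-by-solvent":
            bps = rule.payload["boiling_points"]
            solvent_field = rule.payload.get("solvent_field", "solvent")
            for opt in space[solvent_field].options:
                if opt not in bps:
                    raise ConfigError(
                        f"constraint {rule.rule_id!r}: no boiling point for {opt!r}"
                    )
            if any(float(v) <= 0 for v in bps.values()):
                raise ConfigError(f"constraint {rule.rule_id!r}: boiling point <= 0")


def is_feasible(point: Mapping[str, Any], constraints: list[ConstraintRule]) -> bool:
    """True iff every constraint rule passes; order of rules is irrelevant."""
    return all(
        _RULE_KINDS[r.rule_kind][0](point, r.payload) for r in constraints
    )


class ParameterGrid:
    """The enumerated feasible candidate set with a stable integer index.

    Points live in a DataFrame whose index is the stable point id; removing a
    substrate keeps the ids of the surviving points unchanged.
    """

    def __init__(
        self,
        space: ParameterSpace,
        constraints: list[ConstraintRule],
        frame: pd.DataFrame,
    ):
        self.space = space
        self.constraints = list(constraints)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def indices(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def point(self, index: int) -> CandidatePoint:
        row = self.frame.loc[index]
        return CandidatePoint({k: _pyvalue(row[k]) for k in self.space.names})

    def points_at(self, indices) -> list[CandidatePoint]:
        names = self.space.names
        return [
            CandidatePoint({k: _pyvalue(v) for k, v in zip(names, row)})
            for row in self.frame.loc[indices, names].itertuples(
                index=False, name=None
            )
        ]

    def points(self) -> list[CandidatePoint]:
        names = self.space.names
        return [
            CandidatePoint({k: _pyvalue(v) for k, v in zip(names, row)})
            for row in self.frame[names].itertuples(index=False, name=None)
        ]

    def recheck(self) -> bool:
        """Re-apply every rule to every point (the grid invariant)."""
        names = self.space.names
        return all(
            is_feasible(dict(zip(names, row)), self.constraints)
            for row in self.frame[names].itertuples(index=False, name=None)
        )


def build_grid(
    space: ParameterSpace, constraints: list[ConstraintRule]
) -> ParameterGrid:
    """Enumerate the feasible grid in lexicographic declared-option order."""
    validate_constraints(space, constraints)
    index = pd.MultiIndex.from_product(
        [p.options for p in space], names=space.names
    )
    df = index.to_frame(index=False)
    mask = pd.Series(True, index=df.index)
    for rule in constraints:
        mask &= _RULE_KINDS[rule.rule_kind][1](df, rule.payload)
    df = df[mask].reset_index(drop=True)
    if df.empty:
        raise InfeasibleSpaceError("no grid point satisfies the constraints")
    return ParameterGrid(space, constraints, df)


def exclude_substrate(
    grid: ParameterGrid, alkyne: str, field_name: str = "alkyne"
) -> ParameterGrid:
    """Drop every point carrying ``alkyne``; surviving point ids are kept.

    Excluding a label absent from the remaining points is a no-op; an
    undefined label is an error.  The returned grid may be empty — campaign
    code treats an empty candidate set as an exhausted (infeasible) space.
    """
    if alkyne not in grid.space[field_name].options:
        raise ConfigError(f"{alkyne!r} is not an option of {field_name!r}")
    frame = grid.frame[grid.frame[field_name] != alkyne]
    return ParameterGrid(grid.space, grid.constraints, frame)


# --------------------------------------------------------------------------
# Grid files: CSV with one column per parameter, header row, "." decimals.

def write_grid(grid: ParameterGrid, path: str | Path) -> None:
    grid.frame.to_csv(path, index=False)


def read_grid(
    path: str | Path,
    space: ParameterSpace,
    constraints: list[ConstraintRule] | None = None,
) -> ParameterGrid:
    """Load a grid file, validating every cell against the space."""
    df = pd.read_csv(path)
    missing = [n for n in space.names if n not in df.columns]
    if missing:
        raise GridFormatError(f"missing column(s): {missing}")
    df = df[space.names]
    for p in space:
        col = df[p.name]
        if p.is_numeric:
            col = col.astype(float)
            df[p.name] = col
        bad = ~col.isin(p.options)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GridFormatError(
                f"row {row}: value {col.iloc[row]!r} not an option of {p.name!r}"
            )
    return ParameterGrid(space, list(constraints or []), df)


# --------------------------------------------------------------------------
# Config files and the default iodination space.

def _space_from_config(cfg: Mapping) -> tuple[ParameterSpace, list[ConstraintRule]]:
    params = [
        ParameterDef(d["name"], d["kind"], tuple(d["options"]))
        for d in cfg["parameters"]
    ]
    rules = [
        ConstraintRule(d["rule_id"], d["rule_kind"], d.get("payload", {}))
        for d in cfg.get("constraints", [])
    ]
    return ParameterSpace(params), rules


def load_space_config(path: str | Path) -> tuple[ParameterSpace, list[ConstraintRule]]:
    with open(path) as fh:
        return _space_from_config(yaml.safe_load(fh))


def default_space() -> tuple[ParameterSpace, list[ConstraintRule]]:
    """The eight-parameter alkyne-iodination space with its constraint set."""
    text = (
        resources.files("rxnopt").joinpath("data/default_space.yaml").read_text()
    )
    return _space_from_config(yaml.safe_load(text))


def build_default_grid() -> ParameterGrid:
    return build_grid(*default_space())


def brute_force_count(
    space: ParameterSpace, constraints: list[ConstraintRule]
) -> int:
    """Independent feasible-point count by plain nested iteration.

    Kept deliberately separate from :func:`build_grid` (no pandas, no masks)
    so the two can cross-check each other.
    """
    names = space.names
    n = 0
    for combo in itertools.product(*(p.options for p in space)):
        if is_feasible(dict(zip(names, combo)), constraints):
            n += 1
    return n
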