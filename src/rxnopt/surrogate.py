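"""Probabilistic merit model over the mixed categorical/numeric grid.

Candidate points are encoded as one-hot blocks (one per categorical
parameter) plus numeric columns standardized with grid-wide statistics, so
distances are comparable across parameters.  One Gaussian process with an
automatic-relevance Matern-5/2 kernel and a fitted observation-noise term is
trained on the pooled observations of all substrates — the substrate label is
itself a one-hot block, which is what lets optimality information found on
one alkyne transfer to the others.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .outcomes import Observation
from .space import CandidatePoint, ParameterGrid, ParameterSpace

NOISE_FLOOR = 1e-6


class NotFittedError(RuntimeError):
    """Prediction was requested before the model was fitted."""


class FeatureEncoding:
    """Deterministic, invertible point -> feature-vector map.

    One column per categorical level plus one standardized column per numeric
    parameter; the column order is fixed by the declared parameter and option
    order.  Numeric location/scale default to grid-wide statistics so the
    encoding does not drift as observations accumulate.
    """

    def __init__(self, space: ParameterSpace, grid: ParameterGrid | None = None):
        self.space = space
        self.columns: list[str] = []
        self._blocks: list[tuple[str, tuple]] = []  # categorical (name, options)
        self._numeric: list[str] = []
        for p in space:
            if p.is_numeric:
                self._numeric.append(p.name)
                self.columns.append(p.name)
            else:
                self._blocks.append((p.name, p.options))
                self.columns.extend(f"{p.name}={o}" for o in p.options)
        self.loc: dict[str, float] = {}
        self.scale: dict[str, float] = {}
        for name in self._numeric:
            if grid is not None:
                vals = grid.frame[name].to_numpy(dtype=float)
            else:
                vals = np.asarray(space[name].options, dtype=float)
            sd = float(vals.std())
            self.loc[name] = float(vals.mean())
            self.scale[name] = sd if sd > 0 else 1.0

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def encode(self, points: Iterable[Mapping]) -> np.ndarray:
        points = list(points)
        X = np.zeros((len(points), self.n_features))
        col = {c: j for j, c in enumerate(self.columns)}
        for i, pt in enumerate(points):
            for name, options in self._blocks:
                value = pt[name]
                if value not in options:
                    raise ValueError(f"unknown level {value!r} for {name!r}")
                X[i, col[f"{name}={value}"]] = 1.0
            for name in self._numeric:
                X[i, col[name]] = (float(pt[name]) - self.loc[name]) / self.scale[name]
        return X

    def decode(self, X: np.ndarray) -> list[CandidatePoint]:
        X = np.atleast_2d(X)
        out = []
        col = {c: j for j, c in enumerate(self.columns)}
        for row in X:
            data = {}
            for name, options in self._blocks:
                block = [row[col[f"{name}={o}"]] for o in options]
                data[name] = options[int(np.argmax(block))]
            for name in self._numeric:
                raw = row[col[name]] * self.scale[name] + self.loc[name]
                levels = np.asarray(self.space[name].options, dtype=float)
                data[name] = float(levels[np.argmin(np.abs(levels - raw))])
            out.append(CandidatePoint(data))
        return out


@dataclass
class SurrogatePrediction:
    """Posterior mean and standard deviation of merit per candidate."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean/sd length mismatch")

    def __len__(self) -> int:
        return len(self.mean)


class MeritGP:
    """Gaussian-process merit surrogate with seeded multi-start fitting.

    The kernel is signal_variance * Matern-5/2 with one length-scale per
    encoded feature, plus fitted observation noise floored at ``NOISE_FLOOR``.
    Targets are centred on their mean before fitting, so far from the data
    the posterior reverts to the average observed merit.
    """

    def __init__(
        self,
        encoding: FeatureEncoding,
        n_restarts: int = 5,
        seed: int = 0,
    ):
        self.encoding = encoding
        self.n_restarts = int(n_restarts)
        self.seed = int(seed)
        self._gpr: GaussianProcessRegressor | None = None
        self._y_mean = 0.0
        self._train_points: list[CandidatePoint] = []
        self._train_y: np.ndarray | None = None

    # -- fitting ----------------------------------------------------------
    def fit(self, observations: Sequence[Observation]) -> "MeritGP":
        if len(observations) < 2:
            raise ValueError("need at least 2 observations to fit")
        points = [obs.point for obs in observations]
        y = np.array([obs.merit for obs in observations], dtype=float)
        if np.allclose(y, y[0]):
            warnings.warn(
                "all merits identical; fitting with noise at the floor",
                stacklevel=2,
            )
        X = self.encoding.encode(points)
        self._y_mean = float(y.mean())
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.ones(self.encoding.n_features),
            length_scale_bounds=(1e-2, 1e3),
            nu=2.5,
        ) + WhiteKernel(1e-2, (NOISE_FLOOR, 1.0))
        self._gpr = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=self.n_restarts,
            normalize_y=False,
            random_state=self.seed % (2**31),
        )
        with warnings.catch_warnings():
            # one-hot blocks routinely push irrelevant length-scales to the
            # bound; that is the intended ARD behaviour, not a failure
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gpr.fit(X, y - self._y_mean)
        self._train_points = list(points)
        self._train_y = y
        return self

    def refit_fixed(
        self, observations: Sequence[Observation]
    ) -> "MeritGP":
        """Condition on new data reusing the already-fitted hyperparameters.

        Used for constant-liar batch fantasies, where re-optimizing the
        marginal likelihood per fantasy would be wasteful and would break
        determinism of the within-batch ranking.
        """
        if self._gpr is None:
            raise NotFittedError("fit before refit_fixed")
        clone = MeritGP(self.encoding, n_restarts=0, seed=self.seed)
        points = [obs.point for obs in observations]
        y = np.array([obs.merit for obs in observations], dtype=float)
        X = self.encoding.encode(points)
        clone._y_mean = float(y.mean())
        clone._gpr = GaussianProcessRegressor(
            kernel=self._gpr.kernel_, optimizer=None, normalize_y=False
        )
        clone._gpr.fit(X, y - clone._y_mean)
        clone._train_points = list(points)
        clone._train_y = y
        return clone

    # -- prediction -------------------------------------------------------
    @property
    def fitted(self) -> bool:
        return self._gpr is not None

    def predict(self, points: Sequence[Mapping]) -> SurrogatePrediction:
        if self._gpr is None:
            raise NotFittedError("model is not fitted")
        if len(points) == 0:
            return SurrogatePrediction(np.empty(0), np.empty(0))
        X = self.encoding.encode(points)
        mean, sd = self._gpr.predict(X, return_std=True)
        return SurrogatePrediction(mean + self._y_mean, sd)

    @property
    def hyperparameters(self) -> dict[str, float | list[float]]:
        if self._gpr is None:
            raise NotFittedError("model is not fitted")
        k = self._gpr.kernel_
        return {
            "signal_variance": float(k.k1.k1.constant_value),
            "length_scales": [float(v) for v in np.atleast_1d(k.k1.k2.length_scale)],
            "noise_variance": float(k.k2.noise_level),
        }

    @property
    def prior_sd(self) -> float:
        """Standard deviation of the prior signal (sqrt of signal variance)."""
        return float(np.sqrt(self.hyperparameters["signal_variance"]))

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        if self._gpr is None or self._train_y is None:
            raise NotFittedError("model is not fitted")
        payload = {
            "format": "rxnopt-gp/1",
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "theta": [float(t) for t in self._gpr.kernel_.theta],
            "train_points": [dict(p) for p in self._train_points],
            "train_merit": [float(v) for v in self._train_y],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(
        cls, source: str | Path, encoding: FeatureEncoding
    ) -> "MeritGP":
        text = Path(source).read_text() if isinstance(source, Path) else str(source)
        if isinstance(source, str) and not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        if payload.get("format") != "rxnopt-gp/1":
            raise ValueError("unrecognized surrogate state format")
        model = cls(encoding, n_restarts=payload["n_restarts"], seed=payload["seed"])
        points = [CandidatePoint(p) for p in payload["train_points"]]
        y = np.asarray(payload["train_merit"], dtype=float)
        X = encoding.encode(points)
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.ones(encoding.n_features),
            length_scale_bounds=(1e-2, 1e3),
            nu=2.5,
        ) + WhiteKernel(1e-2, (NOISE_FLOOR, 1.0))
        kernel = kernel.clone_with_theta(np.asarray(payload["theta"]))
        model._y_mean = float(y.mean())
        model._gpr = GaussianProcessRegressor(
            kernel=kernel, optimizer=None, normalize_y=False
        )
        model._gpr.fit(X, y - model._y_mean)
        model._train_points = points
        model._train_y = y
        return model


def fit_gp(
    observations: Sequence[Observation],
    space: ParameterSpace,
    grid: ParameterGrid | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> MeritGP:
    """Convenience: build the grid-wide encoding and fit the merit GP."""
    enc = FeatureEncoding(space, grid)
    return MeritGP(enc, n_restarts=n_restarts, seed=seed).fit(observations)
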