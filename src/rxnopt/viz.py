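"""Interpretability layer: t-SNE contour maps and campaign charts.

The mixed categorical/numeric grid is embedded to two dimensions with t-SNE
on the same one-hot/standardized encoding the surrogate sees (the substrate
block is dropped by default, so experiments cluster by conditions rather
than by which alkyne they used).  A scalar field — true merit, predicted
merit, conversion or yield — is then interpolated over the embedding to a
regular mesh, which is what lets the surrogate's beliefs be compared
side-by-side with the ground truth on one map.

t-SNE coordinates are reproducible only for a fixed seed; no claim is made
about their scale or orientation across runs.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.figure import Figure
from scipy.interpolate import griddata
from sklearn.manifold import TSNE

from .outcomes import Observation, StoppingRule
from .space import ParameterGrid, ParameterSpace
from .surrogate import FeatureEncoding, MeritGP


@dataclass
class EmbeddingMap:
    """2-D t-SNE coordinates of candidate points plus provenance."""

    coords: np.ndarray
    points: list
    excluded: tuple[str, ...]
    perplexity: float
    seed: int
    encoding: FeatureEncoding

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.points), 2):
            raise ValueError("one coordinate pair per embedded point required")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")


@dataclass
class ContourSurface:
    """A scalar field interpolated onto a regular mesh over the embedding."""

    xs: np.ndarray
    ys: np.ndarray
    z: np.ndarray
    name: str


def embed_points(
    points: Sequence,
    space: ParameterSpace,
    exclude: Sequence[str] = ("alkyne",),
    perplexity: float = 10.0,
    seed: int = 0,
    grid: ParameterGrid | None = None,
) -> EmbeddingMap:
    """t-SNE embedding of the encoded points with selected parameters dropped."""
    points = list(points)
    if len(points) < 5:
        raise ValueError("need at least 5 points to embed")
    if perplexity >= len(points):
        raise ValueError("perplexity must be below the number of points")
    enc = FeatureEncoding(space, grid)
    X = enc.encode(points)
    keep = [
        j
        for j, col in enumerate(enc.columns)
        if col.split("=")[0] not in exclude
    ]
    X = X[:, keep]
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed % (2**31),
        init="pca",
    ).fit_transform(X)
    return EmbeddingMap(
        coords=coords,
        points=points,
        excluded=tuple(exclude),
        perplexity=perplexity,
        seed=seed,
        encoding=enc,
    )


def contour_from_values(
    emap: EmbeddingMap,
    values: Sequence[float],
    mesh_resolution: int = 200,
    name: str = "merit",
) -> ContourSurface:
    """Interpolate per-point values onto a mesh covering the embedding.

    Linear interpolation inside the convex hull of the embedded points,
    nearest-neighbour fill outside, so the map is visually complete.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(emap.points):
        raise ValueError("one value per embedded point required")
    coords = emap.coords
    if np.allclose(coords, coords[0]):
        raise ValueError("all embedding coordinates identical")
    xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), mesh_resolution)
    ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), mesh_resolution)
    mx, my = np.meshgrid(xs, ys)
    z = griddata(coords, values, (mx, my), method="linear")
    fill = griddata(coords, values, (mx, my), method="nearest")
    z = np.where(np.isnan(z), fill, z)
    return ContourSurface(xs=xs, ys=ys, z=z, name=name)


def surrogate_contour(
    emap: EmbeddingMap,
    model: MeritGP,
    mesh_resolution: int = 200,
) -> ContourSurface:
    """Contour of the surrogate's predicted mean merit at every embedded point.

    The model may have been trained on any subset of the embedded points;
    predictions cover all of them, which is what enables the
    truth-versus-prediction comparison.
    """
    pred = model.predict(emap.points)
    return contour_from_values(
        emap, pred.mean, mesh_resolution, name="predicted merit"
    )


def plot_contour(
    surface: ContourSurface,
    emap: EmbeddingMap,
    values: Sequence[float] | None = None,
    path: str | None = None,
) -> Figure:
    """Render a contour surface with the embedded points overlaid."""
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.contourf(surface.xs, surface.ys, surface.z, levels=20, cmap="viridis")
    fig.colorbar(im, ax=ax, label=surface.name)
    c = None
    if values is not None:
        c = np.asarray(values, dtype=float)
    ax.scatter(
        emap.coords[:, 0],
        emap.coords[:, 1],
        c=c,
        cmap="viridis",
        edgecolors="k",
        s=30,
    )
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(surface.name)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


_ROUTE_COLORS = {"NIS": "tab:green", "chloramine": "tab:blue"}
_MARKERS = "osD^v<>Pp*"


def _route(point) -> str:
    return "NIS" if point["iodine_source"] == "NIS" else "chloramine"


def progress_chart(
    history: Sequence[Observation],
    rule: StoppingRule = StoppingRule(),
    n_init: int = 11,
    path: str | None = None,
) -> Figure:
    """Conversion versus experiment index with the stopping threshold marked.

    The opening diversity block is shaded; marker shape encodes the
    substrate and color the reaction route.
    """
    if not history:
        raise ValueError("history is empty")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    alkynes = list(dict.fromkeys(obs.alkyne for obs in history))
    marker_of = {a: _MARKERS[i % len(_MARKERS)] for i, a in enumerate(alkynes)}
    for obs in history:
        i = obs.experiment_index
        ax.scatter(
            i,
            obs.outcome.conversion,
            marker=marker_of[obs.alkyne],
            color=_ROUTE_COLORS[_route(obs.point)],
            zorder=3,
        )
    ax.axhline(
        rule.conversion_threshold, ls=":", color="k", label="stopping threshold"
    )
    ax.axvspan(0.5, n_init + 0.5, color="0.9", zorder=0, label="initial block")
    ax.set_xlabel("experiment")
    ax.set_ylabel("conversion")
    ax.set_ylim(-0.02, 1.05)
    handles = [
        plt.Line2D(
            [], [], marker=marker_of[a], ls="", color="k", label=a
        )
        for a in alkynes
    ] + [
        plt.Line2D([], [], marker="s", ls="", color=c, label=r)
        for r, c in _ROUTE_COLORS.items()
    ]
    ax.legend(handles=handles, fontsize=7, loc="lower right")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def parallel_coordinates(
    history: Sequence[Observation],
    converged_only: bool = False,
    rule: StoppingRule = StoppingRule(),
    path: str | None = None,
) -> Figure:
    """Parameter-then-objective parallel-coordinates chart, merit color-coded.

    With ``converged_only`` every trace whose conversion does not surpass the
    threshold is dropped; an all-below-threshold history yields an empty
    chart with a warning rather than an error.
    """
    if not history:
        raise ValueError("history is empty")
    traces = [
        obs
        for obs in history
        if not converged_only or rule.passes(obs.outcome.conversion)
    ]
    param_names = list(history[0].point)
    columns = param_names + ["conversion", "yield", "merit"]
    fig, ax = plt.subplots(figsize=(10, 4.5))
    if not traces:
        warnings.warn("no traces pass the conversion threshold", stacklevel=2)
    # per-column min/max over the full history for a stable normalization
    levels: dict[str, list] = {}
    for name in param_names:
        levels[name] = sorted({obs.point[name] for obs in history}, key=str)

    def _coord(obs: Observation, name: str) -> float:
        if name == "conversion":
            return obs.outcome.conversion
        if name == "yield":
            return obs.outcome.yield_
        if name == "merit":
            return obs.merit
        opts = levels[name]
        if len(opts) == 1:
            return 0.5
        return opts.index(obs.point[name]) / (len(opts) - 1)

    cmap = plt.get_cmap("viridis")
    xs = np.arange(len(columns))
    for obs in traces:
        ys = [_coord(obs, c) for c in columns]
        ax.plot(xs, ys, color=cmap(obs.merit), alpha=0.8, lw=1.2)
    ax.set_xticks(xs)
    ax.set_xticklabels(columns, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("normalized level / value")
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 1))
    fig.colorbar(sm, ax=ax, label="merit")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
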