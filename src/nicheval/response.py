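"""Assessment artefacts: single-axis response curves and bivariate niche
surfaces under two background-covariate strategies.

A response curve shows the modelled (favorability-rescaled) response along
one niche axis with the remaining six "background" covariates either fixed
at their training medians (the conventional partial-response display) or
set to their observed values in every training plot and averaged (the
alternative that respects realised covariate combinations). The 1D curve
shown to an assessor is the unweighted mean of the GLM, GAM, MARS and NN
predictions; RF is excluded from that average.

Bivariate surfaces evaluate the ensemble average over an axis pair — on a
grid with median backgrounds, or plot-wise at the observed covariates — and
carry two reference polygons: the convex hull of the species' observed
occurrences in the plane (occurrence envelope) and the hull of all training
plots (the sampled environmental space). For multimodal species the median
background represents none of the occurrence loci, so the two strategies
can disagree strongly; this module exposes both so the divergence can be
measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint, Point, Polygon

from .ensemble import (CURVE_METHODS, EnsembleFit, favorability_rescale,
                       predict)
from .synthetic import species_column

__all__ = [
    "BACKGROUND_STRATEGIES",
    "ResponseCurve",
    "NicheSurface",
    "Envelope",
    "response_curve",
    "niche_surface",
    "occurrence_envelope",
    "top_decile_points",
    "optimum_in_top_decile",
]

BACKGROUND_STRATEGIES = ("median", "observed")


@dataclass
class Envelope:
    """Convex hull of a 2D point cloud; degenerate inputs are flagged."""

    points: np.ndarray
    vertices: np.ndarray | None
    degenerate: bool

    def contains(self, xy) -> np.ndarray:
        """Boundary-inclusive point-in-polygon test (vectorised)."""
        q = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.degenerate:
            geom = MultiPoint([tuple(p) for p in self.points]).convex_hull
        else:
            geom = Polygon(self.vertices)
        hit = np.array([geom.distance(Point(*p)) <= 1e-9 for p in q])
        return hit if hit.size > 1 else bool(hit[0])

    def as_polygon(self) -> Polygon | None:
        return None if self.degenerate else Polygon(self.vertices)


def occurrence_envelope(points) -> Envelope:
    """Convex hull enclosing all points; < 3 points or collinear input is
    returned as a flagged degenerate envelope (displayable as points or a
    segment)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be 2D coordinates")
    if len(pts) < 3:
        return Envelope(points=pts, vertices=None, degenerate=True)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return Envelope(points=pts, vertices=None, degenerate=True)
    return Envelope(points=pts, vertices=pts[hull.vertices], degenerate=False)


@dataclass
class ResponseCurve:
    axis: str
    grid: np.ndarray
    per_method: dict[str, np.ndarray]
    average: np.ndarray
    background: str
    ribbons: dict[str, tuple[np.ndarray, np.ndarray]] | None = None


@dataclass
class NicheSurface:
    axis_pair: tuple[str, str]
    points: np.ndarray  # (n, 2) evaluation coordinates in the plane
    prediction: np.ndarray  # averaged rescaled value at each point
    background: str
    occurrence_envelope: Envelope
    training_polygon: Envelope
    grid_shape: tuple[int, int] | None = None
    per_method: dict[str, np.ndarray] = field(default_factory=dict)


def _axis_grid(fit: EnsembleFit, axis: str, n_points: int) -> np.ndarray:
    """Grid spanning exactly the training extremes; ordinal axes are
    evaluated on their integer levels only."""
    i = fit.space.axis_index(axis)
    lo = float(fit.covariate_mins[axis])
    hi = float(fit.covariate_maxs[axis])
    if fit.space.kinds[i] == "ordinal":
        return np.arange(round(lo), round(hi) + 1, dtype=float)
    return np.linspace(lo, hi, n_points)


def _check_background(background: str) -> None:
    if background not in BACKGROUND_STRATEGIES:
        raise ValueError(
            f"unknown background strategy {background!r}; "
            f"choose from {BACKGROUND_STRATEGIES}"
        )


def _method_curve(fit: EnsembleFit, method: str, axis: str,
                  grid: np.ndarray, background: str) -> np.ndarray:
    names = list(fit.space.names)
    if background == "median":
        base = fit.covariate_medians[names].to_numpy(dtype=float)
        X = np.tile(base, (len(grid), 1))
        X[:, names.index(axis)] = grid
        p = predict(fit, X, method)
    else:
        plots = fit.training_plots[names].to_numpy(dtype=float)
        n = len(plots)
        X = np.repeat(plots[None, :, :], len(grid), axis=0).reshape(-1, len(names))
        X[:, names.index(axis)] = np.repeat(grid, n)
        p = predict(fit, X, method).reshape(len(grid), n).mean(axis=1)
    return favorability_rescale(p, fit.n_presence, fit.n_absence)


def response_curve(fit: EnsembleFit, axis: str, background: str = "median",
                   n_points: int = 100, with_ribbons: bool = False,
                   n_boot: int = 50, seed: int = 0) -> ResponseCurve:
    """Single-axis rescaled response curves per method plus their 4-method
    average (RF excluded from the average by construction).

    ``median``: background covariates at training medians. ``observed``:
    for each grid value, predictions are averaged over all training plots
    with their observed backgrounds. Optional 95% ribbons per method come
    from a seeded bootstrap over training plots.
    """
    if axis not in fit.space.names:
        raise KeyError(f"unknown axis {axis!r}; axes are {list(fit.space.names)}")
    _check_background(background)
    grid = _axis_grid(fit, axis, n_points)
    per_method = {m: _method_curve(fit, m, axis, grid, background)
                  for m in fit.fitted_methods}
    avg_tags = [m for m in CURVE_METHODS if m in per_method]
    if not avg_tags:
        raise ValueError("no non-RF methods fitted; cannot form the curve average")
    average = np.mean([per_method[m] for m in avg_tags], axis=0)
    ribbons = None
    if with_ribbons:
        ribbons = _bootstrap_ribbons(fit, axis, grid, background, n_boot, seed)
    return ResponseCurve(axis=axis, grid=grid, per_method=per_method,
                         average=average, background=background, ribbons=ribbons)


def _bootstrap_ribbons(fit: EnsembleFit, axis: str, grid: np.ndarray,
                       background: str, n_boot: int, seed: int):
    """Seeded bootstrap 95% intervals per method (refit on resampled plots)."""
    from .ensemble import fit_ensemble  # local import to avoid cycle at import time

    rng = np.random.default_rng(seed)
    samples: dict[str, list[np.ndarray]] = {m: [] for m in fit.fitted_methods}
    plots = fit.training_plots
    col = species_column(fit.species)
    for _ in range(n_boot):
        idx = rng.integers(0, len(plots), size=len(plots))
        boot = plots.iloc[idx].reset_index(drop=True)
        if boot[col].nunique() < 2:
            continue
        try:
            bfit = fit_ensemble(boot, fit.species, fit.space,
                                methods=fit.fitted_methods,
                                seed=int(rng.integers(2**31 - 1)),
                                min_class_count=1)
        except Exception:
            continue
        for m in fit.fitted_methods:
            if m in bfit.models:
                samples[m].append(_method_curve(bfit, m, axis, grid, background))
    out = {}
    for m, curves in samples.items():
        if len(curves) >= 10:
            arr = np.vstack(curves)
            out[m] = (np.quantile(arr, 0.025, axis=0), np.quantile(arr, 0.975, axis=0))
    return out


def niche_surface(fit: EnsembleFit, axis_pair, background: str = "median",
                  n_grid: int = 50, include_rf: bool = True) -> NicheSurface:
    """Averaged rescaled prediction over a 2-axis plane plus reference hulls.

    ``observed``: the ensemble is solved at every training plot with all
    covariates at their observed values; the surface is the plot-wise point
    cloud in the chosen plane. ``median``: an ``n_grid`` x ``n_grid`` grid
    over the two axes (integer levels for an ordinal axis) with the other
    five covariates fixed at training medians. Surfaces average all fitted
    methods including RF by default (``include_rf=False`` drops it).
    """
    a, b = axis_pair
    if a == b:
        raise ValueError("axis pair must name two distinct axes")
    for ax in (a, b):
        if ax not in fit.space.names:
            raise KeyError(f"unknown axis {ax!r}; axes are {list(fit.space.names)}")
    _check_background(background)
    tags = fit.fitted_methods if include_rf else tuple(
        m for m in fit.fitted_methods if m != "RF")
    names = list(fit.space.names)
    col = species_column(fit.species)

    if background == "observed":
        X = fit.training_plots[names].to_numpy(dtype=float)
        pts = fit.training_plots[[a, b]].to_numpy(dtype=float)
        grid_shape = None
    else:
        ga = _axis_grid(fit, a, n_grid)
        gb = _axis_grid(fit, b, n_grid)
        A, B = np.meshgrid(ga, gb, indexing="ij")
        pts = np.column_stack([A.ravel(), B.ravel()])
        base = fit.covariate_medians[names].to_numpy(dtype=float)
        X = np.tile(base, (len(pts), 1))
        X[:, names.index(a)] = pts[:, 0]
        X[:, names.index(b)] = pts[:, 1]
        grid_shape = (len(ga), len(gb))

    per_method = {
        m: favorability_rescale(predict(fit, X, m), fit.n_presence, fit.n_absence)
        for m in tags
    }
    pred = np.mean([per_method[m] for m in tags], axis=0)

    presences = fit.training_plots.loc[fit.training_plots[col] == 1, [a, b]]
    occ_env = occurrence_envelope(presences.to_numpy(dtype=float))
    train_poly = occurrence_envelope(fit.training_plots[[a, b]].to_numpy(dtype=float))
    if occ_env.degenerate:
        warnings.warn("occurrence envelope is degenerate (fewer than 3 "
                      "non-collinear presences)", stacklevel=2)
    return NicheSurface(axis_pair=(a, b), points=pts, prediction=pred,
                        background=background, occurrence_envelope=occ_env,
                        training_polygon=train_poly, grid_shape=grid_shape,
                        per_method=per_method)


def top_decile_points(surface: NicheSurface) -> np.ndarray:
    """Evaluation points whose averaged prediction is in the top decile."""
    thr = np.quantile(surface.prediction, 0.9)
    return surface.points[surface.prediction >= thr]


def optimum_in_top_decile(surface: NicheSurface, optimum_xy,
                          breadths_xy, frac: float = 0.5) -> bool:
    """Whether a true niche optimum falls inside the top-decile prediction
    region: true iff some top-decile evaluation point lies within
    ``frac`` niche breadths of the optimum on both displayed axes."""
    top = top_decile_points(surface)
    o = np.asarray(optimum_xy, dtype=float)
    b = np.asarray(breadths_xy, dtype=float)
    if top.size == 0:
        return False
    close = np.all(np.abs(top - o) <= frac * b, axis=1)
    return bool(close.any())
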