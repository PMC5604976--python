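"""Spatial projection of fitted models and proximity-substitution scenarios.

Because the proximity predictors carry an explicit time lag, projecting a
fitted model onto a modified predictor stack answers different questions:

* current map — project the training stack as-is;
* forecast — substitute distance/count/presence computed from the *current*
  sites for the historical ones; the projection is read as the map at
  (present + minimal recentness);
* potential range — substitute constant zero/low distances (and saturating
  presence/count), giving the probability of final space infilling;
* emergence map — forecast minus current;
* unsaturation map — potential minus current, highlighting suitable but
  not-yet-reached areas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .grid import (GridSpec, RasterLayer, distance_to_nearest,
                   rasterize_count, to_presence)

logger = logging.getLogger("hpvsdm")

_HPV_NAME = re.compile(r"^(\d+)\.([PCD])$")


@dataclass
class ScenarioStack:
    """Predictor layers plus a record of any substitutions applied."""

    layers: dict[str, RasterLayer]
    substitutions: dict[str, str] = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    def hpv_names(self) -> list[str]:
        return [n for n in self.layers if _HPV_NAME.match(n)]

    def copy(self) -> "ScenarioStack":
        return ScenarioStack(dict(self.layers), dict(self.substitutions))


def project(scorer, stack: ScenarioStack | dict, predictor_names: list[str],
            name: str = "projection") -> RasterLayer:
    """Project a scorer over a predictor stack, cell by cell.

    ``predictor_names`` fixes the column order the scorer was trained
    with; a missing layer is an error naming it. Nodata in any input layer
    propagates to the output.
    """
    layers = stack.layers if isinstance(stack, ScenarioStack) else stack
    missing = [n for n in predictor_names if n not in layers]
    if missing:
        raise KeyError(f"stack is missing predictor layer(s): {missing}")
    grid = layers[predictor_names[0]].grid
    cols, valid = [], None
    for n in predictor_names:
        layer = layers[n]
        if layer.grid != grid:
            raise ValueError(f"layer {n!r} grid mismatch")
        v = np.asarray(layer.values, dtype=float).ravel()
        ok = v != layer.nodata
        valid = ok if valid is None else (valid & ok)
        cols.append(v)
    X = np.column_stack(cols)
    out = np.full(X.shape[0], -9999.0)
    if valid.any():
        out[valid] = np.clip(np.asarray(scorer(X[valid]), dtype=float), 0, 1)
    return RasterLayer(grid, name, out.reshape(grid.shape), nodata=-9999.0)


def _recompute_hpv(grid: GridSpec, sites: np.ndarray, period: int,
                   capacity: str) -> RasterLayer:
    count = rasterize_count(sites, grid, name=f"{period}.C")
    if capacity == "C":
        return count
    if capacity == "P":
        return to_presence(count, name=f"{period}.P")
    return distance_to_nearest(sites, grid, name=f"{period}.D")


def forecast_stack(stack: ScenarioStack, current_sites: np.ndarray
                   ) -> ScenarioStack:
    """Substitute proximity layers recomputed from the current sites.

    Every historical "<period>.<capacity>" layer is replaced by the same
    transform applied to ``current_sites``; the projection of the result
    is the forecast at (present + the layer's recentness).
    """
    hpv = stack.hpv_names()
    if not hpv:
        raise ValueError("stack contains no proximity layers to substitute")
    out = stack.copy()
    for n in hpv:
        period, cap = _HPV_NAME.match(n).groups()
        out.layers[n] = _recompute_hpv(stack.grid, current_sites,
                                       int(period), cap)
        out.substitutions[n] = "from-current"
    return out


def potential_stack(stack: ScenarioStack, fill: float = 0.0,
                    presence_fill: float = 1.0, count_fill: float = 1.0
                    ) -> ScenarioStack:
    """Substitute constant, saturating proximity values.

    Distance layers become the constant ``fill`` meters (default 0: a site
    next to every cell); presence and count layers become saturating
    constants. The projection reads as the probability of final space
    infilling.
    """
    if fill < 0:
        raise ValueError("fill distance must be non-negative")
    hpv = stack.hpv_names()
    if not hpv:
        raise ValueError("stack contains no proximity layers to substitute")
    out = stack.copy()
    for n in hpv:
        _, cap = _HPV_NAME.match(n).groups()
        value = {"D": fill, "P": presence_fill, "C": count_fill}[cap]
        const = np.full(stack.grid.shape, float(value))
        out.layers[n] = RasterLayer(stack.grid, n, const)
        out.substitutions[n] = f"constant:{value}"
    return out


def _difference(a: RasterLayer, b: RasterLayer, name: str) -> RasterLayer:
    if a.grid != b.grid:
        raise ValueError("difference maps need a shared grid")
    valid = a.mask() & b.mask()
    vals = np.where(valid, np.asarray(a.values, float) - np.asarray(b.values, float),
                    -9999.0)
    return RasterLayer(a.grid, name, vals, nodata=-9999.0)


def emergence_map(forecast_map: RasterLayer, current_map: RasterLayer
                  ) -> RasterLayer:
    """Forecast minus current probability: where new sites should emerge."""
    return _difference(forecast_map, current_map, "emergence")


def unsaturation_map(potential_map: RasterLayer, current_map: RasterLayer
                     ) -> RasterLayer:
    """Potential minus current probability: suitable but unreached areas."""
    return _difference(potential_map, current_map, "unsaturation")


def threshold_to_sites(prob_map: RasterLayer, threshold: float) -> np.ndarray:
    """Cell centers of super-threshold cells, as pseudo-sites.

    Used to iterate the forecast: each step's thresholded map becomes the
    site set from which the next step's proximity layers are derived. Note
    the environmental layers stay fixed, so iterated forecasts degrade as
    the predictor set ages.
    """
    valid = prob_map.mask()
    rows, cols = np.nonzero(valid & (np.asarray(prob_map.values, float)
                                     >= threshold))
    return np.array([prob_map.grid.cell_center(r, c)
                     for r, c in zip(rows, cols)]).reshape(-1, 2)
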