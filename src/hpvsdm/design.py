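"""Pseudoabsence sampling and model-matrix assembly.

Presence-only occurrence data are amended with randomly placed
pseudoabsences (background points) so that presence/absence classifiers
can be fitted. Pseudoabsences are drawn uniformly from cell centers of the
study mask, one per cell and never in a cell holding a presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterLayer, cells_of

logger = logging.getLogger("hpvsdm")


@dataclass
class ModelMatrix:
    """Predictors plus binary response for a set of cases.

    ``data`` holds one row per case with the predictor columns in
    ``predictor_names`` order, a ``response`` column in {0, 1} and a
    ``provenance`` column ('presence' or 'pseudoabsence').
    """

    data: pd.DataFrame
    predictor_names: list[str]
    n_dropped_nodata: int = 0
    n_dropped_outside: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.data[self.predictor_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def sample_pseudoabsences(mask: RasterLayer, n: int = 1000,
                          presences: np.ndarray | None = None,
                          seed: int = 0) -> np.ndarray:
    """Draw ``n`` pseudoabsence points uniformly from eligible mask cells.

    Eligible cells have a positive, valid mask value and do not contain a
    presence point. Returns an (n, 2) lon/lat array of cell centers,
    deterministic for a given seed. Raises when fewer than ``n`` cells are
    eligible.
    """
    eligible = mask.mask() & (mask.values > 0)
    if presences is not None and len(presences):
        presences = np.asarray(presences, dtype=float).reshape(-1, 2)
        rows, cols = cells_of(presences[:, 0], presences[:, 1], mask.grid,
                              drop_outside=True)
        eligible[rows, cols] = False
    idx = np.argwhere(eligible)
    if len(idx) < n:
        raise ValueError(
            f"only {len(idx)} eligible cells for {n} pseudoabsences"
        )
    rng = np.random.default_rng(seed)
    chosen = idx[rng.choice(len(idx), size=n, replace=False)]
    return np.array([mask.grid.cell_center(r, c) for r, c in chosen]
                    ).reshape(-1, 2)


def sample_pseudoabsence_sets(mask: RasterLayer, n: int, n_sets: int,
                              presences: np.ndarray | None = None,
                              seed: int = 0) -> list[np.ndarray]:
    """Multiple independent pseudoabsence sets (for replicated designs)."""
    rng = np.random.default_rng(seed)
    return [
        sample_pseudoabsences(mask, n, presences,
                              seed=int(rng.integers(2 ** 31)))
        for _ in range(n_sets)
    ]


def assemble_model_matrix(presences: np.ndarray, pseudoabsences: np.ndarray,
                          stack: dict[str, RasterLayer]) -> ModelMatrix:
    """Extract predictor values at each point and attach the 0/1 response.

    All layers must share one grid. Points outside the extent and rows with
    any nodata predictor are dropped, with counts recorded on the result.
    """
    if not stack:
        raise ValueError("empty predictor stack")
    layers = list(stack.values())
    grid = layers[0].grid
    for layer in layers[1:]:
        if layer.grid != grid:
            raise ValueError(
                f"layer {layer.name!r} grid differs from {layers[0].name!r}"
            )
    names = list(stack)

    frames = []
    n_outside = 0
    for pts, label, resp in ((presences, "presence", 1),
                             (pseudoabsences, "pseudoabsence", 0)):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            continue
        inside = (
            (pts[:, 0] >= grid.xmin) & (pts[:, 0] < grid.xmax)
            & (pts[:, 1] > grid.ymin) & (pts[:, 1] <= grid.ymax)
        )
        n_outside += int((~inside).sum())
        pts = pts[inside]
        rows, cols = cells_of(pts[:, 0], pts[:, 1], grid)
        cols_data = {"lon": pts[:, 0], "lat": pts[:, 1]}
        valid = np.ones(len(pts), dtype=bool)
        for name in names:
            layer = stack[name]
            vals = np.asarray(layer.values, dtype=float)[rows, cols]
            valid &= vals != layer.nodata
            cols_data[name] = vals
        df = pd.DataFrame(cols_data)
        df["response"] = resp
        df["provenance"] = label
        frames.append(df[valid])
        n_nodata = int((~valid).sum())
        if n_nodata:
            logger.info("dropped %d %s case(s) with nodata predictors",
                        n_nodata, label)

    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["lon", "lat", *names, "response", "provenance"])
    n_nodata_total = (len(presences) + len(pseudoabsences)
                      - n_outside - len(data))
    if n_outside:
        logger.info("dropped %d point(s) outside the grid extent", n_outside)
    return ModelMatrix(data, names, n_dropped_nodata=n_nodata_total,
                       n_dropped_outside=n_outside)


def write_model_matrix(matrix: ModelMatrix, path) -> None:
    """CSV export with a header sidecar recording column roles."""
    matrix.data.to_csv(path, index=False)
    with open(str(path) + ".roles", "w") as fh:
        fh.write("predictors: " + ",".join(matrix.predictor_names) + "\n")
        fh.write("response: response\n")


def read_model_matrix(path) -> ModelMatrix:
    data = pd.read_csv(path)
    with open(str(path) + ".roles") as fh:
        line = fh.readline().strip()
    names = line.split(": ", 1)[1].split(",")
    return ModelMatrix(data, names)
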