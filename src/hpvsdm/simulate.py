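"""Synthetic landscapes and dispersal-limited invasions with dated sites.

This module stands in for field data: it generates (a) a stack of spatially
autocorrelated environmental layers with a known habitat-suitability
surface, and (b) an invasion spreading from a few foci under a short-range
exponential dispersal kernel with rare long-distance jumps. The simulated
census (dated occurrence records, with decennial dating noise for old
sites) and a later response snapshot mirror the structure of a real
invasion survey: roughly a hundred dated sites at the census and several
hundred presences a few years later.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .grid import (GridSpec, RasterLayer, read_ascii_grid, read_points_csv,
                   write_ascii_grid, write_points_csv, EARTH_RADIUS_M)
from .history import OccurrenceRecord, coarsen_onset

logger = logging.getLogger("hpvsdm")

_DEFAULT_GRID = GridSpec.from_origin(19.0, 52.0 - 100.0 / 120.0, 200, 200)

#: Default linear weights of the suitability surface over the env layers.
#: Only the first six layers are informative; the last two are nuisance.
#: Magnitudes are small and the intercept strongly negative so that the
#: landscape is mostly unsuitable with sparse patches — the regime in which
#: a dispersal-limited invader stays far from environmental equilibrium.
_DEFAULT_WEIGHTS = (0.6, -0.5, 0.4, 0.35, -0.3, 0.25, 0.0, 0.0)


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the synthetic environmental landscape.

    The grid defaults to 200 x 200 cells of 1/120 degree centred near
    latitude 52 N (cells of roughly 1 km). Each environmental layer is
    white noise smoothed with a Gaussian kernel of ``autocorrelation_scale``
    cells and z-scored; true suitability is a logistic function of a linear
    combination of the layers. The intercept is negative so that suitable
    habitat is sparse and patchy, as for a ruderal invader.
    """

    grid: GridSpec = _DEFAULT_GRID
    n_env_layers: int = 8
    autocorrelation_scale: float = 15.0
    suitability_weights: tuple[float, ...] = _DEFAULT_WEIGHTS
    suitability_intercept: float = -4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_env_layers < 1:
            raise ValueError("n_env_layers must be >= 1")
        if self.autocorrelation_scale < 1:
            raise ValueError("autocorrelation_scale must be >= 1 cell")
        if len(self.suitability_weights) != self.n_env_layers:
            raise ValueError("need one suitability weight per env layer")
        if not np.all(np.isfinite(self.suitability_weights)):
            raise ValueError("suitability weights must be finite")


@dataclass(frozen=True)
class InvasionConfig:
    """Configuration of the dispersal-limited invasion.

    Each extant site emits ``events_per_site_per_year`` propagule events per
    year. An event travels an Exponential(``kernel_mean_km``) distance or,
    with probability ``p_long_distance``, a Uniform(0, ``long_distance_max_km``)
    jump, in a uniformly random direction; the target cell establishes with
    probability equal to its suitability. Onsets before
    ``decennial_noise_before`` are coarsened to mid-decade years, emulating
    imprecise historical dating.
    """

    n_initial_foci: int = 5
    start_year: int = 1980
    census_year: int = 2007
    response_year: int = 2012
    end_year: int | None = None  # extend the run past the response snapshot
    events_per_site_per_year: int = 3
    kernel_mean_km: float = 2.0
    p_long_distance: float = 0.01
    long_distance_max_km: float = 100.0
    persistence_prob: float = 1.0
    decennial_noise_before: int | None = 1997
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.start_year < self.census_year < self.response_year):
            raise ValueError("need start_year < census_year < response_year")
        for p in (self.p_long_distance, self.persistence_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class StudyBundle:
    """Everything downstream stages need, from one simulated study."""

    env_stack: dict[str, RasterLayer]
    true_suitability: RasterLayer
    mask: RasterLayer
    census_records: list[OccurrenceRecord]
    response_points: np.ndarray  # (n, 2) lon/lat of response-year presences
    yearly_occupancy: dict[int, np.ndarray]  # year -> (n, 2) lon/lat
    landscape_config: LandscapeConfig
    invasion_config: InvasionConfig


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def generate_landscape(config: LandscapeConfig
                       ) -> tuple[dict[str, RasterLayer], RasterLayer]:
    """Simulate the environmental stack and the true suitability surface."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    layers: dict[str, RasterLayer] = {}
    fields = []
    for i in range(config.n_env_layers):
        noise = rng.standard_normal(grid.shape)
        smooth = gaussian_filter(noise, sigma=config.autocorrelation_scale,
                                 mode="reflect")
        z = (smooth - smooth.mean()) / smooth.std()
        name = f"env_{i:02d}"
        layers[name] = RasterLayer(grid, name, z)
        fields.append(z)
    lin = config.suitability_intercept + sum(
        w * f for w, f in zip(config.suitability_weights, fields)
    )
    suitability = 1.0 / (1.0 + np.exp(-lin))
    return layers, RasterLayer(grid, "true_suitability", suitability)


# ---------------------------------------------------------------------------
# Invasion
# ---------------------------------------------------------------------------

def _displace(lon: float, lat: float, distance_m: np.ndarray,
              bearing_rad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Offset a point by (distance, bearing) on a spherical Earth.

    A local flat-Earth approximation is accurate to well under a cell at the
    dispersal distances simulated here (tens of km at most).
    """
    dlat = distance_m * np.cos(bearing_rad) / EARTH_RADIUS_M
    dlon = distance_m * np.sin(bearing_rad) / (
        EARTH_RADIUS_M * math.cos(math.radians(lat))
    )
    return lon + np.degrees(dlon), lat + np.degrees(dlat)


def simulate_invasion(landscape: tuple[dict[str, RasterLayer], RasterLayer] | RasterLayer,
                      config: InvasionConfig,
                      ) -> tuple[list[OccurrenceRecord], dict[int, np.ndarray]]:
    """Run the invasion and return dated census records plus yearly occupancy.

    Occupancy is tracked at cell resolution: a cell is a site. Returns the
    records extant at the census year (onset years optionally coarsened to
    mid-decade) and, for every simulated year, the lon/lat of the cells
    occupied at the end of that year.
    """
    suitability = landscape[1] if isinstance(landscape, tuple) else landscape
    grid = suitability.grid
    suit = suitability.values
    rng = np.random.default_rng(config.seed)

    pool_threshold = np.quantile(suit, 0.8)
    pool = np.argwhere(suit >= pool_threshold)
    if len(pool) == 0:
        raise ValueError("no cells above the 0.8 suitability quantile for foci")
    foci_idx = rng.choice(len(pool), size=min(config.n_initial_foci, len(pool)),
                          replace=False)

    onset: dict[tuple[int, int], int] = {}
    alive: set[tuple[int, int]] = set()
    for i in foci_idx:
        cell = (int(pool[i][0]), int(pool[i][1]))
        onset[cell] = config.start_year
        alive.add(cell)

    end_year = config.end_year or config.response_year
    yearly_cells: dict[int, frozenset[tuple[int, int]]] = {
        config.start_year: frozenset(alive)
    }

    for year in range(config.start_year + 1, end_year + 1):
        # mortality
        if config.persistence_prob < 1.0 and alive:
            keep = rng.random(len(alive)) < config.persistence_prob
            alive = {cell for cell, k in zip(sorted(alive), keep) if k}
        # dispersal from every extant site
        new_cells: set[tuple[int, int]] = set()
        for (r, c) in sorted(alive):
            lon, lat = grid.cell_center(r, c)
            k = config.events_per_site_per_year
            long_jump = rng.random(k) < config.p_long_distance
            dist_km = rng.exponential(config.kernel_mean_km, size=k)
            dist_km[long_jump] = rng.uniform(0.0, config.long_distance_max_km,
                                             size=int(long_jump.sum()))
            bearing = rng.uniform(0.0, 2.0 * math.pi, size=k)
            tlon, tlat = _displace(lon, lat, dist_km * 1000.0, bearing)
            for j in range(k):
                if not (grid.xmin <= tlon[j] < grid.xmax
                        and grid.ymin < tlat[j] <= grid.ymax):
                    continue  # absorbing boundary
                tr = int((grid.ymax - tlat[j]) / grid.resolution)
                tc = int((tlon[j] - grid.xmin) / grid.resolution)
                cell = (min(tr, grid.nrows - 1), min(tc, grid.ncols - 1))
                if cell in alive or cell in new_cells:
                    continue
                if rng.random() < suit[cell]:
                    new_cells.add(cell)
        for cell in new_cells:
            if cell not in onset:
                onset[cell] = year
            alive.add(cell)
        yearly_cells[year] = frozenset(alive)

    # census snapshot with decennial dating noise on old onsets
    records: list[OccurrenceRecord] = []
    for i, cell in enumerate(sorted(yearly_cells[config.census_year])):
        lon, lat = grid.cell_center(*cell)
        year0 = onset[cell]
        if (config.decennial_noise_before is not None
                and year0 < config.decennial_noise_before):
            year0 = coarsen_onset(year0)
        records.append(OccurrenceRecord(
            id=f"s{i:04d}", lon=lon, lat=lat,
            onset_year=min(year0, config.census_year),
            census_year=config.census_year,
        ))

    def _coords(cells) -> np.ndarray:
        if not cells:
            return np.empty((0, 2))
        return np.array([grid.cell_center(r, c) for r, c in sorted(cells)])

    yearly = {year: _coords(cells) for year, cells in yearly_cells.items()}
    return records, yearly


def make_study(landscape_config: LandscapeConfig | None = None,
               invasion_config: InvasionConfig | None = None) -> StudyBundle:
    """Generate a complete synthetic study in one call."""
    lc = landscape_config or LandscapeConfig()
    ic = invasion_config or InvasionConfig()
    env, suitability = generate_landscape(lc)
    records, yearly = simulate_invasion((env, suitability), ic)
    mask = RasterLayer(lc.grid, "mask", np.ones(lc.grid.shape, dtype=np.int32),
                       nodata=-1)
    response = yearly[ic.response_year]
    logger.info("synthetic study: %d census records, %d response presences",
                len(records), len(response))
    return StudyBundle(env, suitability, mask, records, response, yearly, lc, ic)


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------

def save_study(bundle: StudyBundle, directory) -> None:
    """Write a bundle as ASCII grids + CSVs + a YAML config."""
    os.makedirs(directory, exist_ok=True)
    for name, layer in bundle.env_stack.items():
        write_ascii_grid(layer, os.path.join(directory, f"{name}.asc"))
    write_ascii_grid(bundle.true_suitability,
                     os.path.join(directory, "true_suitability.asc"))
    write_ascii_grid(bundle.mask, os.path.join(directory, "mask.asc"))
    recs = bundle.census_records
    write_points_csv(os.path.join(directory, "census.csv"),
                     [r.lon for r in recs], [r.lat for r in recs],
                     onset_year=[r.onset_year for r in recs],
                     census_year=[r.census_year for r in recs],
                     ids=[r.id for r in recs])
    write_points_csv(os.path.join(directory, "response.csv"),
                     bundle.response_points[:, 0], bundle.response_points[:, 1])
    cfg = {
        "landscape": _config_dict(bundle.landscape_config),
        "invasion": dataclasses.asdict(bundle.invasion_config),
    }
    with open(os.path.join(directory, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)


def _config_dict(lc: LandscapeConfig) -> dict:
    d = dataclasses.asdict(lc)
    d["grid"] = {"xmin": lc.grid.xmin, "ymin": lc.grid.ymin,
                 "xmax": lc.grid.xmax, "ymax": lc.grid.ymax,
                 "resolution": lc.grid.resolution}
    d["suitability_weights"] = list(lc.suitability_weights)
    return d


def load_study(directory) -> StudyBundle:
    """Read back a bundle written by :func:`save_study`.

    Yearly occupancy is not serialized; only the census and response
    snapshots (all that the modelling stages use) are restored.
    """
    with open(os.path.join(directory, "config.yaml")) as fh:
        cfg = yaml.safe_load(fh)
    g = cfg["landscape"]["grid"]
    grid = GridSpec(g["xmin"], g["ymin"], g["xmax"], g["ymax"], g["resolution"])
    lc_kwargs = dict(cfg["landscape"])
    lc_kwargs["grid"] = grid
    lc_kwargs["suitability_weights"] = tuple(lc_kwargs["suitability_weights"])
    lc = LandscapeConfig(**lc_kwargs)
    ic = InvasionConfig(**cfg["invasion"])
    env = {}
    for i in range(lc.n_env_layers):
        name = f"env_{i:02d}"
        env[name] = read_ascii_grid(os.path.join(directory, f"{name}.asc"), name)
    suit = read_ascii_grid(os.path.join(directory, "true_suitability.asc"),
                           "true_suitability")
    mask = read_ascii_grid(os.path.join(directory, "mask.asc"), "mask")
    census = read_points_csv(os.path.join(directory, "census.csv"))
    records = [OccurrenceRecord(id=str(census["id"][i]),
                                lon=float(census["lon"][i]),
                                lat=float(census["lat"][i]),
                                onset_year=int(census["onset_year"][i]),
                                census_year=int(census["census_year"][i]))
               for i in range(len(census["lon"]))]
    resp = read_points_csv(os.path.join(directory, "response.csv"))
    response = np.column_stack((resp["lon"], resp["lat"])) if len(resp["lon"]) \
        else np.empty((0, 2))
    yearly = {ic.response_year: response}
    return StudyBundle(env, suit, mask, records, response, yearly, lc, ic)
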