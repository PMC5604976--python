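"""Dated-occurrence bookkeeping and historical-proximity-variable construction.

A historical proximity variable (HPV) encodes the state of an invasion at a
fixed time lag before the response snapshot, as a raster of presence, count
or distance-to-nearest-site values. Each variant predictor set combines one
information-capacity choice (P, C, D or CD) with an ordered subset of the
recentness periods {25, 10, 5} years.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .grid import (GridSpec, RasterLayer, distance_to_nearest,
                   rasterize_count, to_presence, _unit_sphere, EARTH_RADIUS_M)

logger = logging.getLogger("hpvsdm")

#: The recentness periods (years before the response snapshot) in use.
PERIODS = (25, 10, 5)

#: The six admissible period combinations (contiguous suffixes plus singles).
PERIOD_COMBINATIONS = ((5,), (10,), (25,), (10, 5), (25, 10), (25, 10, 5))

#: Information-capacity codes: presence, count, distance, count+distance.
CAPACITY_CODES = ("P", "C", "D", "CD")

CONTROL_LABEL = "No HPV"


@dataclass(frozen=True)
class OccurrenceRecord:
    """A dated population site.

    ``onset_year`` is the earliest year the population is known to have
    existed; ``census_year`` the year its presence was verified in the field.
    """

    id: str
    lon: float
    lat: float
    onset_year: int
    census_year: int

    def __post_init__(self) -> None:
        if self.onset_year > self.census_year:
            raise ValueError(
                f"record {self.id}: onset_year {self.onset_year} after "
                f"census_year {self.census_year}"
            )


@dataclass(frozen=True)
class VariantSpec:
    """One HPV predictor-set combination, e.g. ``25.10.5.CD``.

    The control variant (environmental predictors only) has empty periods
    and capacity code ``control``.
    """

    label: str
    periods: tuple[int, ...]
    capacity_code: str

    @property
    def capacities(self) -> tuple[str, ...]:
        if self.capacity_code == "control":
            return ()
        return tuple(self.capacity_code)  # "CD" -> ("C", "D")

    @property
    def minimal_recentness(self):
        return min(self.periods) if self.periods else "control"

    @property
    def n_periods(self):
        return len(self.periods) if self.periods else "control"

    @property
    def is_control(self) -> bool:
        return self.capacity_code == "control"

    @staticmethod
    def control() -> "VariantSpec":
        return VariantSpec(CONTROL_LABEL, (), "control")

    @staticmethod
    def from_parts(periods, capacity_code: str) -> "VariantSpec":
        periods = tuple(sorted(periods, reverse=True))
        label = ".".join([str(p) for p in periods] + [capacity_code])
        return VariantSpec(label, periods, capacity_code)

    @staticmethod
    def parse(label: str) -> "VariantSpec":
        """Inverse of label formatting; accepts the control label too."""
        if label == CONTROL_LABEL:
            return VariantSpec.control()
        parts = label.split(".")
        code = parts[-1]
        if code not in CAPACITY_CODES:
            raise ValueError(f"unknown capacity code in variant label {label!r}")
        periods = tuple(int(p) for p in parts[:-1])
        if not periods or any(p not in PERIODS for p in periods):
            raise ValueError(f"invalid periods in variant label {label!r}")
        return VariantSpec.from_parts(periods, code)

    def hpv_layer_names(self) -> list[str]:
        """Names of the HPV layers this variant requires, e.g. ['5.C', '5.D']."""
        return [f"{p}.{cap}" for p in self.periods for cap in self.capacities]


def enumerate_variants() -> list[VariantSpec]:
    """The control plus all 24 period-combination x capacity variants."""
    variants = [VariantSpec.control()]
    for periods, code in itertools.product(PERIOD_COMBINATIONS, CAPACITY_CODES):
        variants.append(VariantSpec.from_parts(periods, code))
    return variants


def variant_registry() -> "pd.DataFrame":
    """Tabular registry of all variants and their set attributes."""
    import pandas as pd

    rows = []
    for v in enumerate_variants():
        rows.append({
            "label": v.label,
            "periods": ".".join(str(p) for p in v.periods),
            "capacity_code": v.capacity_code,
            "minimal_recentness": v.minimal_recentness,
            "n_periods": v.n_periods,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Onset dating and population deduplication
# ---------------------------------------------------------------------------

def decennial_onset(decade_start: int) -> int:
    """Mid-decade onset estimate for an imprecisely dated population.

    When only the decade of first appearance is known, the onset is placed
    at the middle year: 1970 -> 1975.
    """
    if decade_start % 10 != 0:
        raise ValueError(f"decade_start must be divisible by 10, got {decade_start}")
    return decade_start + 5


def coarsen_onset(year: int) -> int:
    """Map an exact onset year to its decennial (mid-decade) estimate."""
    return decennial_onset((int(year) // 10) * 10)


def dedupe_populations(records: list[OccurrenceRecord],
                       radius_m: float = 500.0) -> list[OccurrenceRecord]:
    """Merge records closer than ``radius_m`` into single populations.

    Sites further apart than the radius are separate populations; closer
    ones are single-linkage clustered and each cluster is represented by one
    record with the earliest onset year and the centroid location.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if len(records) <= 1:
        return list(records)
    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    xyz = _unit_sphere(lons, lats)
    chord = 2.0 * np.sin(radius_m / EARTH_RADIUS_M / 2.0)
    tree = cKDTree(xyz)
    pairs = tree.sparse_distance_matrix(tree, chord, output_type="coo_matrix")
    n_clusters, labels = connected_components(pairs.tocsr(), directed=False)
    out: list[OccurrenceRecord] = []
    for cl in range(n_clusters):
        idx = np.flatnonzero(labels == cl)
        members = [records[i] for i in idx]
        if len(members) == 1:
            out.append(members[0])
            continue
        rep = min(members, key=lambda r: (r.onset_year, r.id))
        out.append(OccurrenceRecord(
            id=rep.id,
            lon=float(lons[idx].mean()),
            lat=float(lats[idx].mean()),
            onset_year=min(r.onset_year for r in members),
            census_year=max(r.census_year for r in members),
        ))
    return out


def subset_by_recentness(records: list[OccurrenceRecord], response_year: int,
                         recentness: int) -> list[OccurrenceRecord]:
    """Records already existing ``recentness`` years before the response.

    A record qualifies when ``onset_year <= response_year - recentness``;
    with the shortest lag (response year minus census year) this returns
    every censused record. Larger recentness always gives a subset, so the
    period subsets are nested.
    """
    cutoff = response_year - recentness
    return [r for r in records if r.onset_year <= cutoff]


# ---------------------------------------------------------------------------
# HPV layer construction
# ---------------------------------------------------------------------------

def build_hpv_layers(records: list[OccurrenceRecord], grid: GridSpec,
                     response_year: int,
                     periods=PERIODS,
                     capacities: tuple[str, ...] = ("P", "C", "D"),
                     ) -> dict[str, RasterLayer]:
    """Build every requested "<period>.<capacity>" HPV layer.

    For each period the censused records are filtered by recentness, then
    rasterized to count, converted to presence, and/or distance-transformed.
    An empty period subset is an error for capacity D (distance undefined)
    and yields an all-zero layer with a warning for P and C.
    """
    layers: dict[str, RasterLayer] = {}
    for p in periods:
        subset = subset_by_recentness(records, response_year, p)
        pts = np.array([[r.lon, r.lat] for r in subset]).reshape(-1, 2)
        if not subset:
            if "D" in capacities:
                raise ValueError(
                    f"no records existing {p} years before {response_year}: "
                    "distance layer undefined"
                )
            logger.warning("period %d: empty subset, zero P/C layers", p)
        count = rasterize_count(pts, grid, name=f"{p}.C")
        if "C" in capacities:
            layers[f"{p}.C"] = count
        if "P" in capacities:
            layers[f"{p}.P"] = to_presence(count, name=f"{p}.P")
        if "D" in capacities:
            layers[f"{p}.D"] = distance_to_nearest(pts, grid, name=f"{p}.D")
    return layers
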