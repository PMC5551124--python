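"""Synthetic city generator and in-package count fixtures.

Emulates the data a supplementary-monitoring design runs on: a planar city
with three location roles —

* ``current``   — existing regulatory monitors, spread evenly (one per
  administrative district, here a jittered grid);
* ``subject``   — residences whose exposure the network must represent,
  clumped into residential districts (Gaussian blobs);
* ``candidate`` — potential spots for new monitors, scattered uniformly —

plus point and line pollution sources (major roads, bus stops,
construction sites), proximity/density covariates derived from them, and an
annual-average concentration surface that is a sparse linear function of
the (recoded) covariates plus i.i.d. Gaussian noise.  The default role
counts, 37 / 31,097 / 412, match the Seoul application the design was
developed for.

Also ships the printed per-cluster count tables for the PM2.5 and NO2
applications as fixtures (see :func:`load_fixture`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geo_features import (
    DEFAULT_CAP,
    GeoFeatureMatrix,
    VariableMeta,
    density_variable,
    proximity_variable,
    recode_matrix,
)

__all__ = [
    "CityConfig",
    "SourceSet",
    "LineSource",
    "PointSource",
    "CityData",
    "ClusterCountsFixture",
    "generate_city",
    "generate_hourly_series",
    "load_fixture",
]


@dataclass(frozen=True)
class LineSource:
    x1: float
    y1: float
    x2: float
    y2: float
    kind: str


@dataclass(frozen=True)
class PointSource:
    x: float
    y: float
    kind: str


@dataclass
class SourceSet:
    """Pollution sources on the plane: line segments and points."""

    line_segments: list[LineSource] = field(default_factory=list)
    points: list[PointSource] = field(default_factory=list)

    def kinds(self) -> set[str]:
        return {s.kind for s in self.line_segments} | {p.kind for p in self.points}


#: (kind, metric, buffer radius m) of the covariates the generator builds.
_LINE_KINDS = ("major_road",)
_POINT_KINDS = ("bus_stop", "construction")
_DENSITY_RADII = {"major_road": 500.0, "bus_stop": 1000.0, "construction": 1000.0}


@dataclass
class CityConfig:
    """Parameters of a synthetic city.

    ``true_coefficients`` maps covariate names to effects in µg/m³ per
    covariate unit; proximity covariates enter the concentration model on
    their recoded scale (log of the capped distance).  ``noise_sd`` is the
    SD of i.i.d. Gaussian concentration noise in µg/m³.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 25_000.0, 25_000.0)
    n_current: int = 37
    n_subject: int = 31_097
    n_candidate: int = 412
    # densities sized so typical nearest-source distances fall inside the
    # 1 km truncation cap (dense-city regime: median distance to a major
    # road of a few hundred metres)
    n_sources_by_kind: dict[str, int] = field(
        default_factory=lambda: {"major_road": 250, "bus_stop": 2000,
                                 "construction": 300})
    n_noise_covariates: int = 10
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"prox_major_road": -0.9,
                                 "den_major_road_500m": 0.004,
                                 "prox_bus_stop": -0.5})
    noise_sd: float = 1.5
    intercept: float = 30.0
    n_subject_blobs: int = 6

    def __post_init__(self) -> None:
        if min(self.n_current, self.n_subject, self.n_candidate) < 1:
            raise ValueError("all role counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not any(v != 0 for v in self.true_coefficients.values()):
            raise ValueError("at least one true coefficient must be nonzero")
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate extent")


class CityData(NamedTuple):
    locations: pd.DataFrame
    sources: SourceSet
    covariates: GeoFeatureMatrix
    concentration: pd.Series


def _grid_positions(rng: np.random.Generator, n: int,
                    extent: tuple[float, float, float, float]) -> np.ndarray:
    """One jittered position per grid cell — even, district-like coverage."""
    x0, y0, x1, y1 = extent
    g = math.ceil(math.sqrt(n))
    cells = [(i, j) for i in range(g) for j in range(g)]
    rng.shuffle(cells)
    cw, ch = (x1 - x0) / g, (y1 - y0) / g
    pos = np.empty((n, 2))
    for k, (i, j) in enumerate(cells[:n]):
        pos[k, 0] = x0 + (i + rng.uniform(0.2, 0.8)) * cw
        pos[k, 1] = y0 + (j + rng.uniform(0.2, 0.8)) * ch
    return pos


def _blob_positions(rng: np.random.Generator, n: int, n_blobs: int,
                    extent: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = extent
    span = min(x1 - x0, y1 - y0)
    cx = rng.uniform(x0 + 0.1 * (x1 - x0), x1 - 0.1 * (x1 - x0), n_blobs)
    cy = rng.uniform(y0 + 0.1 * (y1 - y0), y1 - 0.1 * (y1 - y0), n_blobs)
    weights = rng.dirichlet(np.full(n_blobs, 5.0))
    which = rng.choice(n_blobs, size=n, p=weights)
    pos = np.column_stack([
        cx[which] + rng.normal(0, span / 15, n),
        cy[which] + rng.normal(0, span / 15, n),
    ])
    pos[:, 0] = np.clip(pos[:, 0], x0, x1)
    pos[:, 1] = np.clip(pos[:, 1], y0, y1)
    return pos


def _make_sources(rng: np.random.Generator, config: CityConfig) -> SourceSet:
    x0, y0, x1, y1 = config.extent
    sources = SourceSet()
    for kind in _LINE_KINDS:
        for _ in range(config.n_sources_by_kind.get(kind, 0)):
            cx, cy = rng.uniform(x0, x1), rng.uniform(y0, y1)
            ang = rng.uniform(0, math.pi)
            half = rng.uniform(1000, 4000)
            ax = np.clip(cx - half * math.cos(ang), x0, x1)
            ay = np.clip(cy - half * math.sin(ang), y0, y1)
            bx = np.clip(cx + half * math.cos(ang), x0, x1)
            by = np.clip(cy + half * math.sin(ang), y0, y1)
            sources.line_segments.append(LineSource(ax, ay, bx, by, kind))
    for kind in _POINT_KINDS:
        for _ in range(config.n_sources_by_kind.get(kind, 0)):
            sources.points.append(
                PointSource(rng.uniform(x0, x1), rng.uniform(y0, y1), kind))
    return sources


def generate_city(config: CityConfig) -> CityData:
    """Generate a reproducible synthetic city.

    Returns the location table (columns ``id``, ``role``, ``x``, ``y``),
    the source set, the raw covariate matrix (proximities untransformed,
    metadata carrying the truncation caps), and the concentration vector

    ``y = intercept + sum(true_coefficients * recoded covariates) + N(0, noise_sd)``.

    Identical configs (including seed) yield identical output.
    """
    rng = np.random.default_rng(config.seed)
    sources = _make_sources(rng, config)

    parts = []
    for role, n, sampler in [
        ("current", config.n_current,
         lambda n: _grid_positions(rng, n, config.extent)),
        ("subject", config.n_subject,
         lambda n: _blob_positions(rng, n, config.n_subject_blobs, config.extent)),
        ("candidate", config.n_candidate,
         lambda n: np.column_stack([
             rng.uniform(config.extent[0], config.extent[2], n),
             rng.uniform(config.extent[1], config.extent[3], n)])),
    ]:
        pos = sampler(n)
        width = len(str(n))
        parts.append(pd.DataFrame({
            "id": [f"{role[:4]}_{i + 1:0{width}d}" for i in range(n)],
            "role": role, "x": pos[:, 0], "y": pos[:, 1]}))
    locations = pd.concat(parts, ignore_index=True)

    cols: dict[str, pd.Series] = {}
    meta: dict[str, VariableMeta] = {}
    for kind in _LINE_KINDS + _POINT_KINDS:
        if config.n_sources_by_kind.get(kind, 0) == 0:
            continue
        prox = proximity_variable(locations, sources, kind)
        name = f"prox_{kind}"
        cols[name] = prox
        meta[name] = VariableMeta(name=name, category="traffic",
                                  metric="proximity", truncation_cap=DEFAULT_CAP)
        radius = _DENSITY_RADII[kind]
        den = density_variable(locations, sources, kind, radius)
        cols[den.name] = den
        meta[den.name] = VariableMeta(name=den.name, category="traffic",
                                      metric="density", buffer_radius=radius)
    n_loc = len(locations)
    loc_index = pd.Index(locations["id"], name="location_id")
    for i in range(config.n_noise_covariates):
        name = f"noise_{i + 1:02d}"
        cols[name] = pd.Series(rng.normal(0, 1, n_loc), index=loc_index,
                               name=name)
        meta[name] = VariableMeta(name=name, category="demographic",
                                  metric="density", buffer_radius=1000.0)
    values = pd.DataFrame(cols)
    values.index = pd.Index(locations["id"], name="location_id")
    covariates = GeoFeatureMatrix(values=values, meta=meta, state="raw")

    missing = set(config.true_coefficients) - set(values.columns)
    if missing:
        raise ValueError(f"true_coefficients reference unknown covariates: "
                         f"{sorted(missing)}")
    design = recode_matrix(covariates).values
    y = np.full(n_loc, config.intercept, dtype=float)
    for name, beta in config.true_coefficients.items():
        y += beta * design[name].to_numpy()
    if config.noise_sd > 0:
        y += rng.normal(0, config.noise_sd, n_loc)
    concentration = pd.Series(y, index=values.index, name="concentration")
    return CityData(locations, sources, covariates, concentration)


def generate_hourly_series(
    seed: int,
    year: int = 2010,
    gaps: list | None = None,
    site_id: str = "S001",
    mean: float = 26.8,
    sigma: float = 0.4,
) -> pd.DataFrame:
    """Hourly measurement table for one site-year, with injected gaps.

    ``gaps`` lists missing periods; each entry is a day (``"2010-03-15"``),
    an inclusive day range (``("2010-03-01", "2010-03-31")``), or an exact
    hour timestamp (``"2010-03-15 07:00"``).  Gap entries outside ``year``
    raise ``ValueError``.  Values are lognormal around ``mean`` µg/m³.
    Returns columns ``site_id``, ``datetime``, ``value`` with one record
    per non-missing hour.
    """
    hours = pd.date_range(f"{year}-01-01", f"{year + 1}-01-01",
                          freq="h", inclusive="left")
    drop = pd.Series(False, index=hours)
    for gap in gaps or []:
        if isinstance(gap, tuple):
            start = pd.Timestamp(gap[0])
            end = pd.Timestamp(gap[1]) + pd.Timedelta(days=1)
        else:
            ts = pd.Timestamp(gap)
            if ts.hour or ts.minute:
                start, end = ts, ts + pd.Timedelta(hours=1)
            else:
                start, end = ts, ts + pd.Timedelta(days=1)
        if start.year != year or (end - pd.Timedelta(hours=1)).year != year:
            raise ValueError(f"gap {gap!r} outside year {year}")
        drop[(hours >= start) & (hours < end)] = True
    kept = hours[~drop.to_numpy()]
    rng = np.random.default_rng(seed)
    values = rng.lognormal(math.log(mean) - sigma ** 2 / 2, sigma, len(kept))
    return pd.DataFrame({"site_id": site_id, "datetime": kept, "value": values})


@dataclass(frozen=True)
class ClusterCountsFixture:
    """Printed per-cluster role counts for one pollutant application."""

    pollutant: str
    counts: pd.DataFrame  # columns: cluster, n_current, n_subject, n_candidate

    @property
    def n_clusters(self) -> int:
        return len(self.counts)

    def totals(self) -> dict[str, int]:
        return {c: int(self.counts[c].sum())
                for c in ("n_current", "n_subject", "n_candidate")}


_FIXTURES = {"pm25_table2": "PM2.5", "no2_table3": "NO2"}


def load_fixture(name: str) -> ClusterCountsFixture:
    """Load a printed cluster-counts table (``pm25_table2``, ``no2_table3``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(_FIXTURES)}")
    with resources.files("monnet.data").joinpath(f"{name}.csv").open() as fh:
        counts = pd.read_csv(fh)
    return ClusterCountsFixture(pollutant=_FIXTURES[name], counts=counts)
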