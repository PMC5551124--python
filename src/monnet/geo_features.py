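"""Geographic covariates for land-use regression and clustering.

Covariates come in two metric families:

* **proximity** — Euclidean distance (m) from a location to the nearest
  pollution source of a given kind (road segment, bus stop, ...).  Before
  modelling, proximities are truncated at a cap (1 km by default, 2 km for
  large-scale physical features) and log transformed, so that the covariate
  saturates beyond the distance at which a source can plausibly influence
  local concentrations.
* **density** — amount of source within a circular buffer: a count for
  point sources, total clipped segment length (m) for line sources, or an
  area percentage for land-use variables.

The module also implements the two pre-modelling filters (low
unique-value fraction; negligible land-use area share) and joint z-scaling
of all locations, with the scaling statistics retained so new locations can
be placed on the same scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import shapely
from shapely import LineString, MultiLineString, Point
from shapely.strtree import STRtree

__all__ = [
    "VariableMeta",
    "GeoFeatureMatrix",
    "proximity_variable",
    "density_variable",
    "recode_proximity",
    "exclude_low_variability",
    "zscale",
]

#: Default truncation caps (m).  Large-scale physical features (coastline,
#: river, borderline) saturate more slowly and use the 2 km cap.
DEFAULT_CAP = 1000.0
LARGE_FEATURE_CAP = 2000.0


@dataclass(frozen=True)
class VariableMeta:
    """Per-variable metadata.

    Parameters
    ----------
    name
        Column name in the covariate matrix.
    category
        Source category (traffic, demographic, land use, transportation
        facility, physical geography, emission, vegetation, altitude).
    metric
        ``"proximity"`` or ``"density"``.
    buffer_radius
        Buffer radius in metres (density variables only).
    truncation_cap
        Distance cap in metres applied before the log transform
        (proximity variables only).
    land_use_flag
        True when the variable is a land-use area percentage (0-100),
        which makes it subject to the area-share exclusion rule.
    """

    name: str
    category: str = "traffic"
    metric: Literal["proximity", "density"] = "density"
    buffer_radius: float | None = None
    truncation_cap: float | None = None
    land_use_flag: bool = False

    def __post_init__(self) -> None:
        if self.metric == "density" and self.buffer_radius is not None:
            if self.buffer_radius <= 0:
                raise ValueError("buffer_radius must be positive")
        if self.metric == "proximity" and self.truncation_cap is not None:
            if self.truncation_cap <= 0:
                raise ValueError("truncation_cap must be positive")


@dataclass
class GeoFeatureMatrix:
    """Locations x covariates, with per-variable metadata and a state tag.

    ``values`` is indexed by location id.  ``state`` tracks whether the
    matrix holds raw covariates, recoded covariates (proximities truncated
    and logged), or z-scaled covariates.
    """

    values: pd.DataFrame
    meta: dict[str, VariableMeta] = field(default_factory=dict)
    state: Literal["raw", "recoded", "scaled"] = "raw"

    def __post_init__(self) -> None:
        for name in self.values.columns:
            self.meta.setdefault(name, VariableMeta(name=name))

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def location_ids(self) -> pd.Index:
        return self.values.index

    def subset(self, variables: list[str]) -> "GeoFeatureMatrix":
        return GeoFeatureMatrix(
            values=self.values[variables].copy(),
            meta={v: self.meta[v] for v in variables},
            state=self.state,
        )

    def to_csv(self, path) -> None:
        self.values.rename_axis("location_id").to_csv(path)

    @classmethod
    def from_csv(cls, path, meta: dict[str, VariableMeta] | None = None,
                 state: str = "raw") -> "GeoFeatureMatrix":
        values = pd.read_csv(path, index_col="location_id")
        return cls(values=values, meta=dict(meta or {}), state=state)  # type: ignore[arg-type]


def _source_geometries(sources, kind: str):
    """Shapely geometries of every source of ``kind`` (points and lines)."""
    geoms = []
    for seg in sources.line_segments:
        if seg.kind == kind:
            geoms.append(LineString([(seg.x1, seg.y1), (seg.x2, seg.y2)]))
    for pt in sources.points:
        if pt.kind == kind:
            geoms.append(Point(pt.x, pt.y))
    return geoms


def proximity_variable(locations: pd.DataFrame, sources, kind: str) -> pd.Series:
    """Distance (m) from each location to the nearest source of ``kind``.

    ``locations`` must carry ``x``/``y`` columns in planar metres and be
    indexed (or indexable) by a unique ``id`` column.  Point sources use
    point distance; line sources use the distance to the nearest point on
    the segment.
    """
    geoms = _source_geometries(sources, kind)
    if not geoms:
        raise ValueError(f"no sources of kind {kind!r}")
    idx = locations["id"] if "id" in locations.columns else locations.index
    pts = shapely.points(locations["x"].to_numpy(), locations["y"].to_numpy())
    tree = STRtree(geoms)
    nearest = tree.nearest(pts)
    dist = shapely.distance(pts, np.asarray(geoms, dtype=object)[nearest])
    return pd.Series(dist, index=pd.Index(idx, name="location_id"),
                     name=f"prox_{kind}")


def density_variable(locations: pd.DataFrame, sources, kind: str,
                     radius: float) -> pd.Series:
    """Source density within a circular buffer of ``radius`` metres.

    Point sources: count of points with distance <= radius.  Line sources:
    total length (m) of segments clipped to the buffer disc.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    idx = locations["id"] if "id" in locations.columns else locations.index
    x = locations["x"].to_numpy()
    y = locations["y"].to_numpy()

    pts = [(p.x, p.y) for p in sources.points if p.kind == kind]
    segs = [s for s in sources.line_segments if s.kind == kind]

    out = np.zeros(len(locations))
    if pts:
        parr = np.asarray(pts)
        # count within radius; chunked to bound the distance-matrix size
        for lo in range(0, len(x), 4096):
            hi = lo + 4096
            d2 = (x[lo:hi, None] - parr[None, :, 0]) ** 2 + (
                y[lo:hi, None] - parr[None, :, 1]) ** 2
            out[lo:hi] += (d2 <= radius * radius).sum(axis=1)
    if segs:
        lines = MultiLineString(
            [[(s.x1, s.y1), (s.x2, s.y2)] for s in segs])
        centers = shapely.points(x, y)
        buffers = shapely.buffer(centers, radius, quad_segs=64)
        out += shapely.length(shapely.intersection(buffers, lines))
    return pd.Series(out, index=pd.Index(idx, name="location_id"),
                     name=f"den_{kind}_{int(radius)}m")


def recode_proximity(column: pd.Series | np.ndarray, cap: float = DEFAULT_CAP,
                     eps: float = 1.0) -> pd.Series | np.ndarray:
    """Truncate a distance column at ``cap`` metres and log transform.

    Returns ``log(min(d, cap) + eps)`` (natural log).  The 1 m offset makes
    a zero distance map to 0 and keeps the transform defined everywhere.
    """
    arr = np.asarray(column, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    rec = np.log(np.minimum(arr, cap) + eps)
    if isinstance(column, pd.Series):
        return pd.Series(rec, index=column.index, name=column.name)
    return rec


def recode_matrix(matrix: GeoFeatureMatrix, eps: float = 1.0) -> GeoFeatureMatrix:
    """Apply the proximity recoding to every proximity variable.

    Density variables pass through unchanged; the resulting matrix is in
    ``recoded`` state.
    """
    values = matrix.values.copy()
    for name, m in matrix.meta.items():
        if m.metric == "proximity":
            cap = m.truncation_cap if m.truncation_cap is not None else DEFAULT_CAP
            values[name] = recode_proximity(values[name], cap=cap, eps=eps)
    return GeoFeatureMatrix(values=values, meta=dict(matrix.meta), state="recoded")


def exclude_low_variability(
    matrix: GeoFeatureMatrix,
    unique_frac: float = 0.10,
    land_use_frac: float = 0.10,
) -> tuple[GeoFeatureMatrix, pd.DataFrame]:
    """Drop covariates with too little spatial variability.

    Two independent rules:

    1. any variable whose fraction of distinct values across locations is
       below ``unique_frac`` is dropped (reason ``low_unique``);
    2. any land-use area-percentage variable whose maximum share across
       locations is below ``100 * land_use_frac`` percent is dropped
       (reason ``low_land_use_share``).

    Returns the filtered matrix and a report with one row per dropped
    variable (columns ``variable``, ``reason``, ``detail``).
    """
    n = len(matrix.values)
    dropped: list[dict] = []
    keep: list[str] = []
    for name in matrix.variables:
        col = matrix.values[name]
        ufrac = col.nunique() / n
        meta = matrix.meta[name]
        if ufrac < unique_frac:
            dropped.append({"variable": name, "reason": "low_unique",
                            "detail": f"unique fraction {ufrac:.4f}"})
        elif meta.land_use_flag and col.max() < 100.0 * land_use_frac:
            dropped.append({"variable": name, "reason": "low_land_use_share",
                            "detail": f"max share {col.max():.2f}%"})
        else:
            keep.append(name)
    report = pd.DataFrame(dropped, columns=["variable", "reason", "detail"])
    return matrix.subset(keep), report


def zscale(matrix: GeoFeatureMatrix, ddof: int = 1
           ) -> tuple[GeoFeatureMatrix, pd.DataFrame]:
    """Center and scale every column to mean 0, SD 1.

    Scaling statistics are computed jointly over all locations in the
    matrix (current + subject + candidate), because clustering runs on the
    pooled set.  Returns the scaled matrix and a per-variable frame of
    (mean, sd) so the identical transform can be applied to new locations.

    Raises ``ValueError`` on a zero-SD column: constant columns must be
    removed by :func:`exclude_low_variability` first.
    """
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=ddof)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(
            f"zero-SD column(s) {zero}: run exclude_low_variability first")
    scaled = (matrix.values - means) / sds
    stats = pd.DataFrame({"mean": means, "sd": sds}).rename_axis("variable")
    return (
        GeoFeatureMatrix(values=scaled, meta=dict(matrix.meta), state="scaled"),
        stats,
    )


def apply_scaling(matrix: GeoFeatureMatrix, stats: pd.DataFrame) -> GeoFeatureMatrix:
    """Scale ``matrix`` with previously computed (mean, sd) statistics."""
    values = (matrix.values - stats["mean"]) / stats["sd"]
    return GeoFeatureMatrix(values=values, meta=dict(matrix.meta), state="scaled")
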