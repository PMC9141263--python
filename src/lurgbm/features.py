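"""Buffer covariates around monitoring stations and bivariate screening.

Covariates follow the usual land-use-regression recipe: per-class land-use
fractions and per-class road lengths inside a circular buffer centred on the
station, plus point covariates sampled at the station cell.  Screening is a
plain Pearson correlation of each candidate against observed PM2.5 with a
two-sided t-test, reported at a primary and a secondary significance level.

Buffers are evaluated on a local planar (equirectangular) projection about
the buffer centre — buffer radii of a few km are negligible against Earth
curvature.  Cell membership is decided by cell centre inside the disc, which
keeps every operator checkable by exhaustive enumeration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point, shape

from .synthetic import KM_PER_DEG_LAT, KM_PER_DEG_LON_EQ, LANDUSE_CLASSES

ROAD_CLASSES = ("hig", "maj", "min")

#: integer raster codes for the six land-use classes
LANDUSE_CODES = {code: name for code, name in enumerate(LANDUSE_CLASSES, start=1)}

DEFAULT_BUFFER_RADIUS_M = 3000.0


@dataclass
class CategoricalGrid:
    """Georeferenced categorical raster: integer class codes on cell centres.

    ``crs`` is "lonlat" (coords in decimal degrees) or "planar" (coords already
    in metres, used directly).
    """

    data: np.ndarray            # (ny, nx) integer codes
    x: np.ndarray               # (nx,) cell-centre x coords
    y: np.ndarray               # (ny,) cell-centre y coords
    crs: str = "lonlat"

    def __post_init__(self):
        if self.data.shape != (len(self.y), len(self.x)):
            raise ValueError("grid data shape does not match coordinate vectors")
        if self.crs not in ("lonlat", "planar"):
            raise ValueError(f"unknown crs {self.crs!r}")


def _local_plane_m(lon, lat, center_lon: float, center_lat: float):
    """Project lon/lat to metres on an equirectangular plane about the centre."""
    kx = KM_PER_DEG_LON_EQ * np.cos(np.radians(center_lat)) * 1000.0
    ky = KM_PER_DEG_LAT * 1000.0
    return (np.asarray(lon) - center_lon) * kx, (np.asarray(lat) - center_lat) * ky


def landuse_fractions(grid: CategoricalGrid, center, radius_m: float) -> dict[str, float]:
    """Per-class land-use fractions inside a circular buffer.

    Fraction of class c = (cells of class c whose centres fall inside the
    disc) / (all cell centres inside the disc); the six fractions sum to 1.
    """
    if radius_m <= 0:
        raise ValueError("buffer radius must be positive")
    cx, cy = float(center[0]), float(center[1])
    xm, ym = np.meshgrid(grid.x, grid.y)
    if grid.crs == "lonlat":
        xs, ys = _local_plane_m(xm, ym, cx, cy)
    else:
        xs, ys = xm - cx, ym - cy
    inside = xs**2 + ys**2 <= radius_m**2
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError(f"buffer of radius {radius_m:g} m contains no cell centres")
    codes = grid.data[inside]
    return {name: float(np.sum(codes == code)) / n_in for code, name in LANDUSE_CODES.items()}


def road_length_in_buffer(
    segments: list[tuple[LineString, str]],
    center,
    radius_m: float,
    crs: str = "lonlat",
) -> dict[str, float]:
    """Clipped road length (m) per class inside a circular buffer, plus hm.

    Each line feature is clipped to the disc on the local plane and its
    clipped Euclidean length accumulated under its class tag; ``hm`` is the
    sum of the highway and major-road lengths.  Zero-length segments are
    skipped with a warning carrying their count.
    """
    if radius_m <= 0:
        raise ValueError("buffer radius must be positive")
    cx, cy = float(center[0]), float(center[1])
    disc = Point(0.0, 0.0).buffer(radius_m, quad_segs=256)
    totals = {c: 0.0 for c in ROAD_CLASSES}
    n_degenerate = 0
    for geom, cls in segments:
        if cls not in totals:
            raise ValueError(f"unknown road class {cls!r}; expected one of {ROAD_CLASSES}")
        coords = np.asarray(geom.coords, dtype=float)
        if crs == "lonlat":
            xs, ys = _local_plane_m(coords[:, 0], coords[:, 1], cx, cy)
        else:
            xs, ys = coords[:, 0] - cx, coords[:, 1] - cy
        line = LineString(np.column_stack([xs, ys]))
        if line.length == 0:
            n_degenerate += 1
            continue
        totals[cls] += line.intersection(disc).length
    if n_degenerate:
        warnings.warn(f"ignored {n_degenerate} zero-length road segment(s)", stacklevel=2)
    totals["hm"] = totals["hig"] + totals["maj"]
    return totals


def read_roads_geojson(path) -> list[tuple[LineString, str]]:
    """LineString features with a "class" property in {hig, maj, min}."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise ValueError(f"expected LineString features, got {geom.geom_type}")
        out.append((geom, feat["properties"]["class"]))
    return out


def station_covariates(
    stations: pd.DataFrame,
    landuse_grid: CategoricalGrid,
    roads: list[tuple[LineString, str]],
    point_grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    radius_m: float = DEFAULT_BUFFER_RADIUS_M,
) -> pd.DataFrame:
    """Buffer + point covariate table, one row per unique station.

    ``stations`` needs station_id, lon, lat.  ``point_grids`` maps a covariate
    name to (grid, x_coords, y_coords); the value at the nearest cell centre is
    taken (altitude, meteorology, AOD are gridded point covariates, not buffer
    aggregates).
    """
    uniq = stations.drop_duplicates("station_id")[["station_id", "lon", "lat"]]
    rows = []
    for _, st in uniq.iterrows():
        center = (st["lon"], st["lat"])
        row = {"station_id": st["station_id"]}
        row.update(landuse_fractions(landuse_grid, center, radius_m))
        row.update(road_length_in_buffer(roads, center, radius_m, crs=landuse_grid.crs))
        if point_grids:
            for name, (grid, xs, ys) in point_grids.items():
                ix = int(np.argmin(np.abs(xs - st["lon"])))
                iy = int(np.argmin(np.abs(ys - st["lat"])))
                row[name] = float(grid[iy, ix])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningReport:
    """Pearson r, p-value and pass flags per candidate covariate."""

    table: pd.DataFrame          # index = variable; r, p_value, passes flags
    alpha: float = 0.01
    alpha_secondary: float = 0.05
    excluded: list = field(default_factory=list)   # constant columns

    def passing(self, level: str = "primary") -> list[str]:
        col = "passes_alpha" if level == "primary" else "passes_alpha_secondary"
        return list(self.table.index[self.table[col]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="variable")


def screen_correlations(
    table: pd.DataFrame,
    target: pd.Series | np.ndarray,
    alpha: float = 0.01,
    alpha_secondary: float = 0.05,
) -> ScreeningReport:
    """Bivariate Pearson screening of every column against observed PM2.5.

    Constant columns have an undefined correlation: they are flagged, listed in
    ``excluded`` and never pass.  Requires ≥ 3 rows.
    """
    y = np.asarray(target, dtype=float)
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    if len(table) != len(y):
        raise ValueError("covariate table and target lengths differ")
    rows = {}
    excluded = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            excluded.append(name)
            rows[name] = (np.nan, np.nan, False, False)
            continue
        r, p = stats.pearsonr(x, y)
        rows[name] = (r, p, p < alpha, p < alpha_secondary)
    rep = pd.DataFrame.from_dict(
        rows, orient="index", columns=["r", "p_value", "passes_alpha", "passes_alpha_secondary"]
    )
    return ScreeningReport(table=rep, alpha=alpha, alpha_secondary=alpha_secondary, excluded=excluded)
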