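"""Synthetic station network and covariate grids for end-to-end testing.

The generator realises the statistical structure the estimation method
assumes: daily PM2.5 on a regular grid is a linear function of covariates,
plus a spatially correlated Gaussian residual field (fresh realisation each
day, covariance ``sill − γ(h)`` of a chosen variogram), plus a sinusoidal
monthly seasonal cycle, plus iid Gaussian observation noise at the stations.
Land-use class fractions come from a per-cell Dirichlet; terrain and
meteorology are smooth gradients with smoothed noise, so the bivariate
screening step sees realistic mixed-sign correlations.

The GRF is drawn by Cholesky factorisation of the full cell-covariance
matrix — exact for the desk-scale grids used here (≤ ~60×60 cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .kriging import VariogramModel, pairwise_distances_km

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

LANDUSE_CLASSES = ("cro", "for", "gra", "wat", "ind", "sem")

#: Dirichlet concentration per land-use class (cropland/forest-heavy mix).
_DIRICHLET_ALPHA = (2.0, 2.0, 1.5, 0.5, 1.0, 0.5)

DEFAULT_BETA: Mapping[str, float] = {
    "ind": 25.0,       # µg/m³ per unit fraction of industrial/residential land
    "for": -10.0,      # vegetated land scavenges
    "altitude": -0.004,  # µg/m³ per metre
    "TEM": 0.6,        # µg/m³ per °C
    "AOD": 20.0,       # µg/m³ per unit optical depth
    "WIN": -1.5,       # µg/m³ per m/s (ventilation)
}


def _default_variogram() -> VariogramModel:
    return VariogramModel("spherical", nugget=0.0, partial_sill=25.0, range_km=150.0)


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated monitoring network.

    Defaults describe a 400×400 km region (16×16 cells of 25 km) observed by
    36 stations over Jan–Feb 2016, with residual spatial correlation
    (spherical, sill 25 (µg/m³)², range 150 km) well beyond the mean station
    spacing, a 10 µg/m³ seasonal sinusoid and 2 µg/m³ observation noise.
    """

    grid_nx: int = 16
    grid_ny: int = 16
    cell_size_km: float = 25.0
    n_stations: int = 36
    date_start: str = "2016-01-01"
    date_end: str = "2016-02-29"
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept: float = 35.0
    residual_variogram: VariogramModel = field(default_factory=_default_variogram)
    seasonal_amplitude: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0
    origin_lon: float = 104.0
    origin_lat: float = 30.0

    def __post_init__(self):
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid must be at least 2×2")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.n_stations < 1:
            raise ValueError("n_stations must be ≥ 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be ≥ 0")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_start, self.date_end, freq="D")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "grid_nx", "grid_ny", "cell_size_km", "n_stations", "date_start",
                "date_end", "intercept", "seasonal_amplitude", "noise_sd", "seed",
                "origin_lon", "origin_lat",
            )
        }
        d["beta"] = dict(self.beta)
        d["residual_variogram"] = self.residual_variogram.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "residual_variogram" in d:
            d["residual_variogram"] = VariogramModel.from_dict(d["residual_variogram"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: covariate grids and the latent surface."""

    covariate_grids: dict[str, np.ndarray]     # each (ny, nx)
    latent_surface: np.ndarray                 # (n_days, ny, nx), µg/m³
    lons: np.ndarray                           # (nx,) cell-centre longitudes
    lats: np.ndarray                           # (ny,) cell-centre latitudes
    dates: pd.DatetimeIndex
    generating_params: SyntheticConfig

    @property
    def n_cells(self) -> int:
        return self.latent_surface.shape[1] * self.latent_surface.shape[2]


def _grid_coords(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre lon/lat arrays for the configured grid."""
    dlat = config.cell_size_km / KM_PER_DEG_LAT
    dlon = config.cell_size_km / (KM_PER_DEG_LON_EQ * np.cos(np.radians(config.origin_lat)))
    lons = config.origin_lon + dlon * (np.arange(config.grid_nx) + 0.5)
    lats = config.origin_lat + dlat * (np.arange(config.grid_ny) + 0.5)
    return lons, lats


def _smooth_field(rng: np.random.Generator, ny: int, nx: int, sigma_cells: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-sd smoothed white noise on the grid."""
    z = gaussian_filter(rng.standard_normal((ny, nx)), sigma=sigma_cells, mode="nearest")
    sd = z.std()
    return z / sd if sd > 0 else z


def _covariate_grids(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    ny, nx = config.grid_ny, config.grid_nx
    grids: dict[str, np.ndarray] = {}

    fracs = rng.dirichlet(_DIRICHLET_ALPHA, size=ny * nx).reshape(ny, nx, 6)
    for k, name in enumerate(LANDUSE_CLASSES):
        grids[name] = fracs[:, :, k]

    gx, gy = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny))
    altitude = np.clip(1200.0 * (1.0 - gx) * gy + 300.0 * _smooth_field(rng, ny, nx), 0.0, None)
    grids["altitude"] = altitude
    grids["TEM"] = 18.0 - 0.006 * altitude + 4.0 * _smooth_field(rng, ny, nx)
    grids["PRS"] = 1013.0 - 0.11 * altitude + 2.0 * _smooth_field(rng, ny, nx)
    grids["RHU"] = np.clip(60.0 + 15.0 * _smooth_field(rng, ny, nx), 20.0, 95.0)
    grids["WIN"] = 3.0 + 1.5 * np.abs(_smooth_field(rng, ny, nx))
    grids["pop"] = np.exp(4.0 + 1.5 * _smooth_field(rng, ny, nx))
    grids["AOD"] = np.clip(0.45 + 0.3 * _smooth_field(rng, ny, nx), 0.05, None)
    return grids


def _residual_cholesky(config: SyntheticConfig, cell_coords: np.ndarray) -> np.ndarray:
    vg = config.residual_variogram
    if vg.sill == 0:
        return np.zeros((cell_coords.shape[0], cell_coords.shape[0]))
    dmat = pairwise_distances_km(cell_coords)
    cov = vg.covariance(dmat)
    # tiny diagonal jitter guards against roundoff; genuine non-PD still fails
    jitter = 1e-10 * max(vg.sill, 1.0)
    try:
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "residual variogram implies a non-positive-definite covariance: "
            f"family={vg.family} nugget={vg.nugget} partial_sill={vg.partial_sill} "
            f"range_km={vg.range_km}"
        ) from exc


def seasonal_term(months, amplitude: float) -> np.ndarray:
    """Sinusoidal monthly cycle: amplitude · sin(2π (m − 1) / 12)."""
    m = np.asarray(months, dtype=float)
    return amplitude * np.sin(2.0 * np.pi * (m - 1.0) / 12.0)


def simulate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Simulate covariate grids and the daily latent PM2.5 surface.

    Deterministic given ``config.seed``.  The residual field is redrawn
    independently each day; within a day its covariance is ``sill − γ(h)`` of
    ``config.residual_variogram``.
    """
    rng = np.random.default_rng(config.seed)
    lons, lats = _grid_coords(config)
    ny, nx = config.grid_ny, config.grid_nx
    grids = _covariate_grids(config, rng)

    unknown = set(config.beta) - set(grids)
    if unknown:
        raise KeyError(f"beta names without a covariate grid: {sorted(unknown)}")

    mean = np.full((ny, nx), float(config.intercept))
    for name, b in config.beta.items():
        mean = mean + b * grids[name]

    lon_mesh, lat_mesh = np.meshgrid(lons, lats)
    cell_coords = np.column_stack([lon_mesh.ravel(), lat_mesh.ravel()])
    chol = _residual_cholesky(config, cell_coords)

    dates = config.dates
    latent = np.empty((len(dates), ny, nx))
    season = seasonal_term(dates.month.to_numpy(), config.seasonal_amplitude)
    for t in range(len(dates)):
        resid = (chol @ rng.standard_normal(ny * nx)).reshape(ny, nx)
        latent[t] = mean + resid + season[t]

    return SyntheticTruth(
        covariate_grids=grids,
        latent_surface=latent,
        lons=lons,
        lats=lats,
        dates=dates,
        generating_params=replace(config, beta=dict(config.beta)),
    )


def sample_stations(truth: SyntheticTruth, n_stations: int, seed: int) -> pd.DataFrame:
    """Place stations at distinct cells and observe PM2.5 with iid noise.

    Returns one row per station per day with columns station_id, lon, lat,
    date, pm25, latent (noise-free value) and every covariate at the station
    cell.
    """
    n_days, ny, nx = truth.latent_surface.shape
    n_cells = ny * nx
    if n_stations > n_cells:
        raise ValueError(f"n_stations={n_stations} exceeds the {n_cells} grid cells")
    rng = np.random.default_rng(seed)
    cells = rng.choice(n_cells, size=n_stations, replace=False)
    iy, ix = np.unravel_index(cells, (ny, nx))

    noise_sd = truth.generating_params.noise_sd
    rows = []
    for s, (cy, cx) in enumerate(zip(iy, ix)):
        latent = truth.latent_surface[:, cy, cx]
        obs = latent + rng.normal(0.0, noise_sd, size=n_days) if noise_sd > 0 else latent.copy()
        df = pd.DataFrame(
            {
                "station_id": f"S{s:03d}",
                "lon": truth.lons[cx],
                "lat": truth.lats[cy],
                "date": truth.dates,
                "pm25": obs,
                "latent": latent,
            }
        )
        for name, grid in truth.covariate_grids.items():
            df[name] = grid[cy, cx]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def write_station_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_covariate_csv(truth: SyntheticTruth, name: str, path) -> None:
    """Headered CSV grid: one row per latitude, columns are longitudes."""
    grid = truth.covariate_grids[name]
    pd.DataFrame(grid, index=truth.lats, columns=truth.lons).to_csv(path, index_label="lat")


def read_covariate_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col="lat")
    return df.to_numpy(dtype=float), df.columns.to_numpy(dtype=float), df.index.to_numpy(dtype=float)


def write_params_yaml(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_params_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        return SyntheticConfig.from_dict(yaml.safe_load(fh))
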