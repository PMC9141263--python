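"""Ordinary kriging of station PM2.5 and the spatio-temporal feature pair (Rd, Rt).

The spatial feature Rd at a point S0 is the ordinary-kriging estimate
``Rd(S0) = sum_i w_i R(S_i)`` built from the surrounding stations' same-day
observations; the temporal feature Rt is simply the calendar month index of the
observation.  Kriging weights solve the best-linear-unbiased-predictor system
derived from a semivariogram fitted to the station network:

* empirical semivariance per lag bin: ``gamma_hat(h) = mean of 0.5 (R_i - R_j)^2``
  over station pairs at great-circle distance ~ h,
* a parametric model (spherical / exponential / gaussian) fitted by weighted
  least squares (weights = pair counts),
* the (n+1) x (n+1) augmented linear system enforcing ``sum w_i = 1`` via a
  Lagrange multiplier.

Distances are great-circle kilometres throughout: the method targets national
extents where planar degrees distort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

EARTH_RADIUS_KM = 6371.0088

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian")

__all__ = [
    "EARTH_RADIUS_KM",
    "VARIOGRAM_FAMILIES",
    "EmpiricalVariogram",
    "VariogramModel",
    "KrigingSolution",
    "STFeature",
    "haversine_km",
    "pairwise_distances_km",
    "empirical_semivariogram",
    "fit_variogram",
    "ok_weights",
    "krige_values",
    "loo_krige",
    "krige_rd",
]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances_km(coords: np.ndarray) -> np.ndarray:
    """Full symmetric great-circle distance matrix for (n, 2) lon/lat coords."""
    coords = np.asarray(coords, dtype=float)
    lon = coords[:, 0][:, None]
    lat = coords[:, 1][:, None]
    return haversine_km(lon, lat, lon.T, lat.T)


# ---------------------------------------------------------------------------
# Variogram models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram γ(h).

    ``gamma(0) = nugget`` (the nugget discontinuity is attached at the origin);
    γ rises to ``nugget + partial_sill`` (the sill) at / beyond ``range_km``.
    Exponential and gaussian families use the practical-range convention
    (γ reaches 95% of the sill at ``range_km``).
    """

    family: str
    nugget: float
    partial_sill: float
    range_km: float
    fit_objective: float | None = dataclasses.field(default=None, compare=False)

    def __post_init__(self):
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}; expected one of {VARIOGRAM_FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError(
                "invalid variogram parameters: nugget=%r partial_sill=%r range_km=%r"
                % (self.nugget, self.partial_sill, self.range_km)
            )

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def structural(self, h) -> np.ndarray:
        """Normalised structural component f(h) in [0, 1] with f(0) = 0."""
        u = np.asarray(h, dtype=float) / self.range_km
        if self.family == "spherical":
            f = np.where(u < 1.0, 1.5 * u - 0.5 * u**3, 1.0)
        elif self.family == "exponential":
            f = 1.0 - np.exp(-3.0 * u)
        else:  # gaussian
            f = 1.0 - np.exp(-3.0 * u**2)
        return np.where(u > 0.0, f, 0.0)

    def gamma(self, h) -> np.ndarray:
        """Semivariance γ(h) = nugget + partial_sill · f(h)."""
        return self.nugget + self.partial_sill * self.structural(h)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill − γ(h), with C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return np.where(h > 0.0, self.sill - self.gamma(h), self.sill)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": float(self.nugget),
            "partial_sill": float(self.partial_sill),
            "range_km": float(self.range_km),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(d["family"], float(d["nugget"]), float(d["partial_sill"]), float(d["range_km"]))


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned empirical semivariogram: lag bin centres (km), γ̂ and pair counts."""

    lag_centres: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self):
        lc = np.asarray(self.lag_centres, dtype=float)
        if np.any(np.diff(lc) <= 0):
            raise ValueError("lag_centres must be strictly increasing")
        if np.any(np.asarray(self.gamma_hat) < 0):
            raise ValueError("gamma_hat must be nonnegative")


@dataclass(frozen=True)
class KrigingSolution:
    """Weights, Lagrange multiplier, estimate and kriging variance of one solve."""

    weights: np.ndarray
    multiplier: float
    estimate: float
    kriging_variance: float


@dataclass(frozen=True)
class STFeature:
    """The spatio-temporal feature pair: kriged Rd (µg/m³) and month index Rt."""

    rd: float
    rt: int

    def __post_init__(self):
        if not (1 <= int(self.rt) <= 12):
            raise ValueError(f"Rt must be a month index in 1..12, got {self.rt}")


# ---------------------------------------------------------------------------
# Empirical semivariogram
# ---------------------------------------------------------------------------


def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Binned semivariance of station observations.

    Parameters
    ----------
    coords : (n, 2) lon/lat in decimal degrees.
    values : (n,) one day's observations, or (d, n) for a pooled estimate over
        d days (pairs are pooled across days; NaN entries are ignored).
    n_bins : number of equal-width lag bins spanning (0, max_lag].
    max_lag : km; defaults to half the maximum pairwise distance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 stations for a semivariogram")
    if values.shape[1] != n:
        raise ValueError("values and coords disagree on station count")

    dmat = pairwise_distances_km(coords)
    iu, ju = np.triu_indices(n, k=1)
    d = dmat[iu, ju]
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")

    in_range = (d > 0) & (d <= max_lag)
    if not np.any(in_range):
        raise ValueError(f"no station pairs within max_lag={max_lag:g} km")

    # Half squared differences per (day, pair); NaNs (absent station-days) drop out.
    sq = 0.5 * (values[:, iu] - values[:, ju]) ** 2
    valid = np.isfinite(sq)

    edges = np.linspace(0.0, max_lag, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)

    centres, gammas, counts = [], [], []
    for b in range(n_bins):
        sel = in_range & (bin_idx == b)
        if not np.any(sel):
            continue
        vals = sq[:, sel]
        ok = valid[:, sel]
        c = int(ok.sum())
        if c == 0:
            continue
        centres.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(float(np.nansum(np.where(ok, vals, 0.0)) / c))
        counts.append(c)

    return EmpiricalVariogram(np.array(centres), np.array(gammas), np.array(counts, dtype=int))


# ---------------------------------------------------------------------------
# Variogram fitting
# ---------------------------------------------------------------------------


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of a parametric variogram to γ̂.

    Residuals are weighted by sqrt(pair count); parameters are bounded
    nonnegative with range > 0.  Several starting points are tried and the
    lowest-objective solution kept; the WLS objective is attached to the
    returned model as ``fit_objective``.
    """
    if family not in VARIOGRAM_FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    h = np.asarray(emp.lag_centres, dtype=float)
    g = np.asarray(emp.gamma_hat, dtype=float)
    w = np.sqrt(np.asarray(emp.pair_counts, dtype=float))
    if h.size < 3:
        raise ValueError("need at least 3 occupied lag bins to fit a variogram")

    def resid(theta):
        m = VariogramModel(family, theta[0], theta[1], theta[2])
        return w * (m.gamma(h) - g)

    gmax = max(g.max(), 1e-12)
    hmax = h.max()
    starts = []
    for n0 in (0.0, 0.25 * g.min() if g.min() > 0 else 0.0):
        for r0 in (hmax / 3.0, 2.0 * hmax / 3.0, hmax):
            starts.append([n0, max(gmax - n0, 1e-12), r0])

    best = None
    trace = []
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]), method="trf"
            )
        except Exception:  # noqa: BLE001 - record and try next start
            continue
        trace.append((x0, getattr(sol, "cost", np.inf), getattr(sol, "status", -1)))
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"variogram fit did not converge; objective trace: {trace}")
    nugget, psill, rng = best.x
    return VariogramModel(family, float(nugget), float(psill), float(rng), fit_objective=float(best.cost))


# ---------------------------------------------------------------------------
# Ordinary-kriging system
# ---------------------------------------------------------------------------


def _dedup_stations(coords: np.ndarray, values: np.ndarray | None):
    """Average values at exactly coincident station coordinates."""
    coords = np.asarray(coords, dtype=float)
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if uniq.shape[0] == coords.shape[0]:
        order = None
        return coords, values, order
    vals = None
    if values is not None:
        values = np.asarray(values, dtype=float)
        vals = np.zeros(uniq.shape[0])
        cnt = np.zeros(uniq.shape[0])
        np.add.at(vals, inverse, values)
        np.add.at(cnt, inverse, 1.0)
        vals = vals / cnt
    return uniq, vals, inverse


def _ok_solve(gamma_mat: np.ndarray, gamma_target: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the augmented OK system; returns (weights, Lagrange multiplier)."""
    n = gamma_mat.shape[0]
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = gamma_target
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    return sol[:n], float(sol[n])


def ok_weights(
    model: VariogramModel,
    station_coords: np.ndarray,
    target_coord: Sequence[float],
    values: np.ndarray | None = None,
) -> KrigingSolution:
    """Ordinary-kriging weights, multiplier, estimate and variance at one target.

    Duplicate station locations are averaged before solving (they make the
    system singular).  The kriging variance is ``sum w_i γ(x0, x_i) + φ``,
    clipped at 0 against roundoff.
    """
    coords, vals, inverse = _dedup_stations(station_coords, values)
    if coords.shape[0] < 1:
        raise ValueError("need at least one station")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite station coordinates")
    dmat = pairwise_distances_km(coords)
    gmat = model.gamma(dmat)
    np.fill_diagonal(gmat, 0.0)
    target = np.asarray(target_coord, dtype=float)
    d0 = haversine_km(coords[:, 0], coords[:, 1], target[0], target[1])
    g0 = np.where(d0 > 0, model.gamma(d0), 0.0)
    try:
        w, phi = _ok_solve(gmat, g0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular kriging system after deduplication: {exc}") from exc
    est = float(w @ vals) if vals is not None else float("nan")
    var = max(float(w @ g0 + phi), 0.0)
    return KrigingSolution(weights=w, multiplier=phi, estimate=est, kriging_variance=var)


def krige_values(
    model: VariogramModel,
    station_coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
) -> np.ndarray:
    """Krige one or more days of station values at each target point.

    ``values`` is (n,) or (d, n); returns (m,) or (d, m).  Weights depend only
    on geometry and the variogram, so each target is solved once and its
    weights reused across days.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    vmat = values[None, :] if squeeze else values
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    out = np.empty((vmat.shape[0], targets.shape[0]))
    for j, t in enumerate(targets):
        sol = ok_weights(model, station_coords, t)
        coords, _, inverse = _dedup_stations(station_coords, None)
        if inverse is not None:
            # average duplicate columns to match deduplicated weights
            vm = np.zeros((vmat.shape[0], coords.shape[0]))
            cnt = np.zeros(coords.shape[0])
            np.add.at(cnt, inverse, 1.0)
            for k, idx in enumerate(inverse):
                vm[:, idx] += vmat[:, k]
            vm /= cnt
        else:
            vm = vmat
        out[:, j] = vm @ sol.weights
    return out[0] if squeeze else out


def loo_krige(model: VariogramModel, station_coords: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Leave-one-out kriged estimate at each station from the remaining n−1.

    ``values`` is (n,) or (d, n); returns the same leading shape.  Each
    station's weight vector is computed once and reused across days, so the
    LOO estimate at station i never touches station i's own observations.
    """
    coords = np.asarray(station_coords, dtype=float)
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    vmat = values[None, :] if squeeze else values
    n = coords.shape[0]
    if n < 2:
        raise ValueError("leave-one-out kriging needs at least 2 stations")
    dmat = pairwise_distances_km(coords)
    gfull = model.gamma(dmat)
    np.fill_diagonal(gfull, 0.0)
    out = np.empty((vmat.shape[0], n))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        w, _ = _ok_solve(gfull[np.ix_(keep, keep)], gfull[keep, i])
        out[:, i] = vmat[:, keep] @ w
    return out[0] if squeeze else out


def krige_rd(
    stations_one_day: pd.DataFrame,
    targets: np.ndarray,
    model: VariogramModel,
    leave_one_out: bool = False,
) -> tuple[np.ndarray, list[STFeature]]:
    """Spatio-temporal features for one day: Rd at each target, Rt = the day's month.

    ``stations_one_day`` needs columns lon, lat, pm25, date (a single calendar
    day).  With ``leave_one_out``, a target exactly coinciding with a station
    is kriged from the other n−1 stations — the anti-leakage mode used for
    model-training rows.
    """
    df = stations_one_day
    days = pd.to_datetime(df["date"]).dt.normalize().unique()
    if len(days) != 1:
        raise ValueError("krige_rd expects records from a single day")
    month = int(pd.Timestamp(days[0]).month)
    coords = df[["lon", "lat"]].to_numpy(dtype=float)
    values = df["pm25"].to_numpy(dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if leave_one_out and coords.shape[0] < 2:
        raise ValueError("leave-one-out kriging needs at least 2 stations on the day")

    rd = np.empty(targets.shape[0])
    for j, t in enumerate(targets):
        if leave_one_out:
            at_target = np.all(np.isclose(coords, t[None, :], atol=1e-9), axis=1)
            keep = ~at_target
            if keep.sum() < 1:
                raise ValueError("no stations left after leave-one-out exclusion")
            sol = ok_weights(model, coords[keep], t, values[keep])
        else:
            sol = ok_weights(model, coords, t, values)
        rd[j] = sol.estimate
    feats = [STFeature(rd=float(r), rt=month) for r in rd]
    return rd, feats
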