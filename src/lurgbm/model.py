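"""Gradient-boosted-tree estimation stage and the assembled feature vector.

The estimator is an additive ensemble of ``Ntree`` regression trees,
``phi(x) = sum_k f_k(x)``, trained by LightGBM with the configuration used
throughout: GBDT base learner, 100 trees, 31 leaves, learning rate 0.05,
feature fraction 0.9, bagging fraction 0.8 every 5 iterations.  Tree
induction itself is delegated to LightGBM; the feature assembly, the
Eq-style per-tree accounting (staged contributions), and the split/gain
importance aggregation are defined here.

Feature vector ordering is fixed: [Rd, Rt, selected covariates..., LAT, LON]
— the kriged spatial attribute, the month index, the stepwise-selected
land-use/meteorology covariates and the raw coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd


@dataclass
class GBMConfig:
    """Boosting configuration; defaults mirror the reference setup."""

    base_learner: str = "gbdt"
    n_trees: int = 100
    num_leaves: int = 31
    learning_rate: float = 0.05
    feature_fraction: float = 0.9
    bagging_fraction: float = 0.8
    bagging_freq: int = 5
    early_stop_gain: float | None = None   # min per-tree train-RMSE gain to keep adding trees
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0 < self.feature_fraction <= 1 and 0 < self.bagging_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.num_leaves < 2:
            raise ValueError("num_leaves must be ≥ 2")

    def lgb_params(self) -> dict:
        return {
            "objective": "regression",
            "boosting": self.base_learner,
            "num_leaves": self.num_leaves,
            "learning_rate": self.learning_rate,
            "feature_fraction": self.feature_fraction,
            "bagging_fraction": self.bagging_fraction,
            "bagging_freq": self.bagging_freq,
            "seed": self.seed,
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": 1,
            "verbosity": -1,
        }

    def to_dict(self) -> dict:
        return {
            "base_learner": self.base_learner,
            "n_trees": self.n_trees,
            "num_leaves": self.num_leaves,
            "learning_rate": self.learning_rate,
            "feature_fraction": self.feature_fraction,
            "bagging_fraction": self.bagging_fraction,
            "bagging_freq": self.bagging_freq,
            "early_stop_gain": self.early_stop_gain,
            "seed": self.seed,
        }


@dataclass
class EnsembleModel:
    """Trained additive tree ensemble with its feature names and config."""

    booster: lgb.Booster
    feature_names: list[str]
    config: GBMConfig

    @property
    def n_trees(self) -> int:
        return self.booster.num_trees()

    def save(self, path) -> None:
        self.booster.save_model(str(path))


@dataclass
class ImportanceReport:
    """Per-feature split counts (PM_Split) and total gains (PM_Gain)."""

    table: pd.DataFrame   # index = feature; columns PM_Split, PM_Gain

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def assemble_features(
    records: pd.DataFrame,
    rd_values: pd.Series | np.ndarray | None,
    selected_covariates: list[str],
    use_rd: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the model feature matrix and target from station records.

    Columns: [Rd, Rt, selected..., LAT, LON]; Rt is the integer calendar
    month.  ``rd_values`` must align with ``records`` (same index) and be
    finite; records lacking an Rd are reported by id.  With ``use_rd`` False
    the Rd column is omitted (the ablation used to measure its contribution).
    """
    missing_cols = [c for c in selected_covariates if c not in records.columns]
    if missing_cols:
        raise KeyError(f"records lack selected covariates: {missing_cols}")
    months = pd.to_datetime(records["date"]).dt.month.to_numpy()
    X = pd.DataFrame(index=records.index)
    if use_rd:
        if rd_values is None:
            raise ValueError("rd_values required when use_rd is True")
        rd = pd.Series(np.asarray(rd_values, dtype=float), index=records.index)
        bad = records.index[~np.isfinite(rd.to_numpy())]
        if len(bad):
            ids = records.loc[bad, "station_id"].astype(str) + "@" + records.loc[bad, "date"].astype(str)
            raise ValueError(f"missing Rd for records: {list(ids)[:10]}{'...' if len(bad) > 10 else ''}")
        X["Rd"] = rd
    X["Rt"] = months.astype(int)
    for c in selected_covariates:
        X[c] = records[c].to_numpy(dtype=float)
    X["LAT"] = records["lat"].to_numpy(dtype=float)
    X["LON"] = records["lon"].to_numpy(dtype=float)
    y = records["pm25"].to_numpy(dtype=float)
    return X, y


class _GainStopping:
    """Stop adding trees once the per-tree training-RMSE gain falls below a threshold."""

    def __init__(self, min_gain: float):
        self.min_gain = min_gain
        self._last: float | None = None
        self.order = 10
        self.before_iteration = False

    def __call__(self, env):
        rmse = env.evaluation_result_list[0][2]
        if self._last is not None and (self._last - rmse) < self.min_gain:
            raise lgb.callback.EarlyStopException(env.iteration, env.evaluation_result_list)
        self._last = rmse


def train(features: pd.DataFrame, targets, config: GBMConfig | None = None) -> EnsembleModel:
    """Train the boosted ensemble; deterministic given ``config.seed``.

    Requires ≥ 20 rows and finite targets.  With ``early_stop_gain`` set, tree
    addition stops when the training-RMSE improvement of a new tree drops
    below the threshold; otherwise exactly ``n_trees`` trees are grown.
    """
    config = config or GBMConfig()
    y = np.asarray(targets, dtype=float)
    if len(features) < 20:
        raise ValueError("need at least 20 training rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values")
    dset = lgb.Dataset(features, label=y, params={"verbosity": -1})
    callbacks = []
    kwargs = {}
    if config.early_stop_gain is not None:
        kwargs["valid_sets"] = [dset]
        kwargs["valid_names"] = ["train"]
        callbacks.append(_GainStopping(config.early_stop_gain))
    booster = lgb.train(
        config.lgb_params(),
        dset,
        num_boost_round=config.n_trees,
        callbacks=callbacks or None,
        **kwargs,
    )
    return EnsembleModel(booster=booster, feature_names=list(features.columns), config=config)


def predict(model: EnsembleModel, features: pd.DataFrame) -> np.ndarray:
    return np.asarray(model.booster.predict(features[model.feature_names]))


def tree_contributions(model: EnsembleModel, features: pd.DataFrame) -> np.ndarray:
    """(n_trees, n_rows) additive per-tree contributions f_k(x).

    The ensemble prediction equals the column sum of this matrix (LightGBM
    folds the mean-target initial score into the first tree's leaves).
    """
    X = features[model.feature_names]
    out = np.empty((model.n_trees, len(X)))
    for k in range(model.n_trees):
        out[k] = model.booster.predict(X, start_iteration=k, num_iteration=1)
    return out


def importance(model: EnsembleModel) -> ImportanceReport:
    """Aggregate split counts and gains over all trees of the ensemble."""
    if model.n_trees == 0:
        raise ValueError("untrained model: ensemble holds no trees")
    tab = pd.DataFrame(
        {
            "PM_Split": model.booster.feature_importance(importance_type="split"),
            "PM_Gain": model.booster.feature_importance(importance_type="gain"),
        },
        index=model.feature_names,
    )
    return ImportanceReport(table=tab)


def predict_grid(
    model: EnsembleModel,
    covariate_grids: dict[str, np.ndarray],
    rd_grid: np.ndarray | None,
    month: int,
    lons: np.ndarray | None = None,
    lats: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-cell prediction surface for one month.

    All grids must share shape; cells True in ``mask`` (or NaN in any input
    grid) are set to NaN in the output and excluded from the logged summary.
    No nonnegativity clamp is applied.
    """
    names = model.feature_names
    shapes = {g.shape for g in covariate_grids.values()}
    if rd_grid is not None:
        shapes.add(rd_grid.shape)
    if len(shapes) != 1:
        raise ValueError(f"feature grids disagree on shape: {shapes}")
    ny, nx = shapes.pop()

    cols = {}
    for name in names:
        if name == "Rd":
            if rd_grid is None:
                raise ValueError("model uses Rd but no rd_grid supplied")
            cols[name] = rd_grid.ravel()
        elif name == "Rt":
            cols[name] = np.full(ny * nx, int(month))
        elif name == "LON":
            if lons is None:
                raise ValueError("model uses LON but no lons supplied")
            cols[name] = np.tile(np.asarray(lons, dtype=float), ny)
        elif name == "LAT":
            if lats is None:
                raise ValueError("model uses LAT but no lats supplied")
            cols[name] = np.repeat(np.asarray(lats, dtype=float), nx)
        else:
            cols[name] = covariate_grids[name].ravel()
    X = pd.DataFrame(cols)

    bad = ~np.all(np.isfinite(X.to_numpy()), axis=1)
    if mask is not None:
        bad |= np.asarray(mask, dtype=bool).ravel()
    surface = np.full(ny * nx, np.nan)
    if (~bad).any():
        surface[~bad] = model.booster.predict(X.loc[~bad])
    surface = surface.reshape(ny, nx)
    good = surface[np.isfinite(surface)]
    summary = {
        "n_cells": int(good.size),
        "mean": float(good.mean()) if good.size else float("nan"),
        "min": float(good.min()) if good.size else float("nan"),
        "max": float(good.max()) if good.size else float("nan"),
    }
    return surface, summary
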