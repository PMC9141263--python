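"""Configuration, dataset I/O and the end-to-end pipeline runner.

``run_pipeline`` chains the stages in method order — screen → stepwise →
monthly variogram + leave-one-out Rd → feature assembly → boosted-tree
training → cross-validation → optional grid prediction — and writes every
artifact (tables as CSV, metrics as JSON, model descriptions as YAML, the
trained booster in LightGBM's text format) together with a config snapshot
and the seed, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, kriging, lur, model as gbm, synthetic
from .evaluation import ChainSettings, cross_validate
from .features import screen_correlations
from .model import GBMConfig
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs: data source, chain settings, CV plan, seed."""

    synthetic: SyntheticConfig | None = None     # generate data in-process
    station_csv: str | None = None               # ... or load from files
    covariate_csvs: dict[str, str] = field(default_factory=dict)
    screening_alpha: float = 0.01
    stepwise: lur.StepwiseCriteria = field(default_factory=lur.StepwiseCriteria)
    variogram_family: str = "spherical"
    variogram_n_bins: int = 12
    gbm: GBMConfig = field(default_factory=GBMConfig)
    cv_schemes: list[str] = field(default_factory=lambda: ["sample", "site", "time"])
    cv_k: int = 10
    # daily blocks by default: the bundled synthetic span (two months) must
    # still provide >= k whole blocks for time-based folds
    time_block: str = "D"
    seed: int = 0
    predict_month: int | None = None             # month index for a grid prediction

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "station_csv": self.station_csv,
            "covariate_csvs": dict(self.covariate_csvs),
            "screening_alpha": self.screening_alpha,
            "stepwise": {
                "p_enter": self.stepwise.p_enter,
                "p_remove": self.stepwise.p_remove,
                "criterion": self.stepwise.criterion,
            },
            "variogram_family": self.variogram_family,
            "variogram_n_bins": self.variogram_n_bins,
            "gbm": self.gbm.to_dict(),
            "cv_schemes": list(self.cv_schemes),
            "cv_k": self.cv_k,
            "time_block": self.time_block,
            "seed": self.seed,
            "predict_month": self.predict_month,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if d.get("stepwise"):
            d["stepwise"] = lur.StepwiseCriteria(**d["stepwise"])
        if d.get("gbm"):
            d["gbm"] = GBMConfig(**{k: v for k, v in d["gbm"].items()})
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = cls.from_dict(yaml.safe_load(fh))
        for p in [cfg.station_csv, *cfg.covariate_csvs.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


REQUIRED_STATION_COLUMNS = ("station_id", "lon", "lat", "date", "pm25")


def load_station_csv(path) -> pd.DataFrame:
    """Read, validate and clean a station observation table.

    Cleaning drops records with negative or missing PM2.5 and averages
    duplicate (station, date) rows; every dropped or merged record is counted
    in the log (input count = used + dropped + merged-away).
    """
    df = pd.read_csv(path)
    for col in REQUIRED_STATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"station CSV is missing required column {col!r}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        bad = pd.to_datetime(df["date"], format="ISO8601", errors="coerce").isna()
        line = int(np.argmax(bad.to_numpy())) + 2  # 1-based plus header
        raise ValueError(f"unparseable date near line {line} of {path}: {exc}") from exc

    n_in = len(df)
    bad_pm = df["pm25"].isna() | (df["pm25"] < 0)
    if bad_pm.any():
        logger.info("dropped %d record(s) with negative or missing pm25", int(bad_pm.sum()))
    df = df[~bad_pm]

    dup = df.duplicated(["station_id", "date"], keep=False)
    if dup.any():
        n_before = len(df)
        agg = {c: "mean" if np.issubdtype(df[c].dtype, np.number) else "first" for c in df.columns
               if c not in ("station_id", "date")}
        df = df.groupby(["station_id", "date"], as_index=False).agg(agg)[list(df.columns)]
        logger.info("averaged %d duplicate (station, date) record(s)", n_before - len(df))
    logger.info("loaded %d/%d records from %s", len(df), n_in, path)
    return df.reset_index(drop=True)


def _prepare_data(config: PipelineConfig, outdir: Path):
    if config.synthetic is not None:
        truth = synthetic.simulate_truth(config.synthetic)
        records = synthetic.sample_stations(truth, config.synthetic.n_stations, seed=config.synthetic.seed + 1)
        synthetic.write_station_csv(records, outdir / "stations.csv")
        synthetic.write_params_yaml(config.synthetic, outdir / "generating_params.yaml")
        return records, truth
    if config.station_csv is None:
        raise ValueError("config must provide either synthetic settings or a station CSV")
    return load_station_csv(config.station_csv), None


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full chain; returns a manifest of metrics and artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_snapshot.yaml")
    stage = "load"
    try:
        records, truth = _prepare_data(config, outdir)

        stage = "screen"
        settings = ChainSettings(
            screening_alpha=config.screening_alpha,
            stepwise=config.stepwise,
            variogram_family=config.variogram_family,
            variogram_n_bins=config.variogram_n_bins,
            gbm=config.gbm,
        )
        cand = evaluation.candidate_columns(records, settings)
        screening = screen_correlations(records[cand], records["pm25"], alpha=config.screening_alpha)
        screening.to_csv(outdir / "screening.csv")
        passing = screening.passing() or screening.passing("secondary") or cand

        stage = "stepwise"
        selected, lur_model = lur.stepwise_select(records[passing], records["pm25"], config.stepwise)
        if not selected:
            selected = passing
        lur_model.to_yaml(outdir / "lur_model.yaml")

        stage = "kriging"
        all_train = pd.Series(True, index=records.index)
        rd, dropped = evaluation.compute_rd(records, all_train, settings)
        pd.DataFrame({"rd": rd}).to_csv(outdir / "rd_training.csv", index_label="record")
        keep = records.index[np.isfinite(rd)]
        if len(dropped):
            logger.info("pipeline: %d record(s) lacked kriging sources", len(dropped))

        stage = "train"
        X, y = gbm.assemble_features(records.loc[keep], rd.loc[keep], selected)
        final_model = gbm.train(X, y, config.gbm)
        final_model.save(outdir / "model.txt")
        gbm.importance(final_model).to_csv(outdir / "importance.csv")

        stage = "cross-validation"
        metrics = {}
        for scheme in config.cv_schemes:
            pooled, _ = cross_validate(
                records, scheme, settings, k=config.cv_k, seed=config.seed, time_block=config.time_block
            )
            metrics[scheme] = pooled.to_dict()
            with open(outdir / f"metrics_{scheme}.json", "w") as fh:
                json.dump(pooled.to_dict(), fh, indent=2, sort_keys=True)

        stage = "predict-grid"
        if config.predict_month is not None and truth is not None:
            month = config.predict_month
            dates = pd.to_datetime(records["date"])
            in_month = records[dates.dt.month == month]
            day = pd.to_datetime(sorted(in_month["date"].unique())[len(in_month["date"].unique()) // 2])
            day_rec = records[dates.dt.normalize() == day]
            lon_mesh, lat_mesh = np.meshgrid(truth.lons, truth.lats)
            targets = np.column_stack([lon_mesh.ravel(), lat_mesh.ravel()])
            piv = in_month.pivot_table(index="date", columns="station_id", values="pm25")
            scoords = in_month.drop_duplicates("station_id").set_index("station_id")[["lon", "lat"]].loc[piv.columns]
            emp = kriging.empirical_semivariogram(scoords.to_numpy(), piv.to_numpy(), n_bins=config.variogram_n_bins)
            vg = kriging.fit_variogram(emp, config.variogram_family)
            rd_flat, _ = kriging.krige_rd(day_rec, targets, vg)
            rd_grid = rd_flat.reshape(len(truth.lats), len(truth.lons))
            surface, summary = gbm.predict_grid(
                final_model, truth.covariate_grids, rd_grid, month, lons=truth.lons, lats=truth.lats
            )
            pd.DataFrame(surface, index=truth.lats, columns=truth.lons).to_csv(
                outdir / f"predicted_grid_month{month:02d}.csv", index_label="lat"
            )
            logger.info("grid prediction summary: %s", summary)

        manifest = {
            "n_records": int(len(records)),
            "selected_covariates": list(selected),
            "cv_metrics": metrics,
            "seed": config.seed,
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
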