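"""Accuracy metrics, the three ten-fold CV designs, and model comparison.

Metrics (predicted PMF vs observed PMT, N samples):

* RMSE  = sqrt( sum (PMF − PMT)² / N )
* R²    = squared Pearson correlation of predicted vs observed
* MAE   = mean |PMF − PMT|
* MAPE  = mean 100·|PMF − PMT| / PMT  (undefined when any PMT is 0)

Cross-validation partitions records three ways: *sample* (random record
partition), *site* (whole stations held out — spatial generalisation) and
*time* (whole contiguous calendar blocks held out — temporal
generalisation).  The full estimation chain is refitted inside each training
fold: screening, stepwise selection, the monthly pooled variogram, and the
kriged Rd — held-out records receive Rd kriged from training-fold stations
only, and training rows use leave-one-out Rd, so no held-out observation can
leak into its own prediction.

``relative_improvement`` implements the comparison arithmetic used to rank
models: R² change = (ref − base)/base·100; RMSE/MAE reduction =
(base − ref)/base·100; multi-scheme results are arithmetic means of the
per-scheme changes, reported to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import kriging, lur, model as gbm
from .features import screen_correlations
from .model import GBMConfig

logger = logging.getLogger(__name__)

CV_SCHEMES = ("sample", "site", "time")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """R², RMSE, MAE, MAPE and sample count for one evaluation run."""

    r2: float
    rmse: float
    mae: float
    mape: float
    n: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "R2": float(self.r2),
            "RMSE": float(self.rmse),
            "MAE": float(self.mae),
            "MAPE": float(self.mape),
            "n": int(self.n),
            "flags": list(self.flags),
        }


def compute_metrics(predicted, observed) -> MetricsReport:
    """The four accuracy metrics for a predicted-vs-observed pair of vectors.

    R² is the squared Pearson correlation; it is flagged undefined (NaN) when
    either vector is constant.  MAPE is flagged undefined when an observed
    value is zero; the remaining metrics are still computed.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    err = p - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    flags = []
    if np.any(o == 0):
        mape = float("nan")
        flags.append("mape_undefined_zero_observed")
    else:
        mape = float(np.mean(np.abs(err) / np.abs(o)) * 100.0)
    if np.std(p) == 0 or np.std(o) == 0:
        r2 = float("nan")
        flags.append("r2_undefined_constant_input")
    else:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    return MetricsReport(r2=r2, rmse=rmse, mae=mae, mape=mape, n=n, flags=flags)


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Fold id (1..k) per record under one partitioning scheme."""

    scheme: str
    k: int
    fold_id: pd.Series      # aligned with the records' index
    seed: int

    def to_csv(self, path) -> None:
        pd.DataFrame({"record": self.fold_id.index, "scheme": self.scheme, "fold": self.fold_id.values}).to_csv(
            path, index=False
        )


def make_folds(
    records: pd.DataFrame,
    scheme: str,
    k: int = 10,
    seed: int = 0,
    time_block: str = "M",
) -> FoldAssignment:
    """Partition records for cross-validation.

    sample — records shuffled and split into k folds whose sizes differ by at
    most 1.  site — station ids shuffled, dealt round-robin, every record of a
    station lands in that station's fold.  time — contiguous calendar blocks
    (months by default, ``time_block="D"`` for days) in chronological order
    dealt round-robin to folds.
    """
    if scheme not in CV_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {CV_SCHEMES}")
    rng = np.random.default_rng(seed)
    idx = records.index
    fold = pd.Series(0, index=idx, dtype=int)

    if scheme == "sample":
        perm = rng.permutation(len(idx))
        # dealing shuffled records round-robin keeps fold sizes within 1
        fold.iloc[perm] = np.arange(len(idx)) % k + 1
    elif scheme == "site":
        stations = np.sort(records["station_id"].unique())
        if len(stations) < k:
            raise ValueError(f"only {len(stations)} stations for k={k}; use a smaller k")
        perm = rng.permutation(len(stations))
        mapping = {stations[j]: i % k + 1 for i, j in enumerate(perm)}
        fold[:] = records["station_id"].map(mapping)
    else:  # time
        dates = pd.to_datetime(records["date"])
        blocks = dates.dt.to_period(time_block)
        uniq = blocks.sort_values().unique()
        if len(uniq) < k:
            raise ValueError(f"only {len(uniq)} time blocks for k={k}; use a smaller k or finer blocks")
        mapping = {b: i % k + 1 for i, b in enumerate(uniq)}
        fold[:] = blocks.map(mapping).astype(int)
    return FoldAssignment(scheme=scheme, k=k, fold_id=fold, seed=seed)


# ---------------------------------------------------------------------------
# In-fold Rd computation
# ---------------------------------------------------------------------------


@dataclass
class ChainSettings:
    """Configuration of the full estimation chain used inside each fold."""

    use_rd: bool = True
    selected: list[str] | None = None          # None → screen + stepwise per training fold
    screening_alpha: float = 0.01
    stepwise: lur.StepwiseCriteria = field(default_factory=lur.StepwiseCriteria)
    variogram_family: str = "spherical"
    variogram_n_bins: int = 12
    gbm: GBMConfig = field(default_factory=GBMConfig)
    min_stations_per_day: int = 2
    candidate_covariates: list[str] | None = None   # None → every non-core numeric column


_CORE_COLUMNS = {"station_id", "lon", "lat", "date", "pm25", "latent"}


def candidate_columns(records: pd.DataFrame, settings: ChainSettings) -> list[str]:
    if settings.candidate_covariates is not None:
        return list(settings.candidate_covariates)
    return [c for c in records.columns if c not in _CORE_COLUMNS and np.issubdtype(records[c].dtype, np.number)]


def compute_rd(
    records: pd.DataFrame,
    train_mask: pd.Series,
    settings: ChainSettings,
    sources: str = "train",
) -> tuple[pd.Series, list]:
    """Kriged Rd for every record, with strict fold hygiene.

    One pooled variogram is fitted per calendar month from training records.
    With ``sources="train"`` (sample- and site-style folds), held-out rows are
    kriged from the training stations observed that day and training rows get
    leave-one-out Rd (their own station excluded from the same-day system).
    With ``sources="all"`` (time-style folds, where entire days are held out
    and no same-day training observation exists), every row is kriged
    leave-one-out from the other stations observed that day — the monitoring
    network's concurrent readings are prediction-time inputs, and only the
    record's own observation is ever excluded from its own estimate.  Days
    with fewer eligible source stations than ``min_stations_per_day`` yield
    NaN Rd and are reported as dropped.
    """
    if sources not in ("train", "all"):
        raise ValueError("sources must be 'train' or 'all'")
    rd = pd.Series(np.nan, index=records.index)
    dropped = []
    dates = pd.to_datetime(records["date"])
    months = dates.dt.to_period("M")
    weight_cache: dict = {}

    def _pooled_variogram(rows: pd.DataFrame):
        piv = rows.pivot_table(index="date", columns="station_id", values="pm25")
        scoords = rows.drop_duplicates("station_id").set_index("station_id")[["lon", "lat"]].loc[piv.columns]
        emp = kriging.empirical_semivariogram(
            scoords.to_numpy(), piv.to_numpy(), n_bins=settings.variogram_n_bins
        )
        return kriging.fit_variogram(emp, settings.variogram_family)

    global_vg = None   # lazy fallback, pooled over every training record

    for month, midx in records.groupby(months).groups.items():
        mrec = records.loc[midx]
        mtrain = mrec[train_mask.loc[midx]]
        try:
            vg = _pooled_variogram(mtrain)
        except (ValueError, RuntimeError) as exc:
            # e.g. an entirely held-out month under time-based folds: fall back
            # to the variogram pooled over all training records
            if global_vg is None:
                try:
                    global_vg = _pooled_variogram(records[train_mask])
                except (ValueError, RuntimeError):
                    logger.warning("month %s: no fittable variogram (%s); records dropped", month, exc)
                    dropped.extend(list(midx))
                    continue
            vg = global_vg

        all_pos = records.drop_duplicates("station_id").set_index("station_id")[["lon", "lat"]]
        station_pos = {s: (all_pos.loc[s, "lon"], all_pos.loc[s, "lat"]) for s in all_pos.index}
        for day, didx in mrec.groupby(dates.loc[midx]).groups.items():
            drec = records.loc[didx]
            day_src = drec[train_mask.loc[didx]] if sources == "train" else drec
            src_ids = day_src["station_id"].to_numpy()
            if len(src_ids) < settings.min_stations_per_day:
                dropped.extend(list(didx))
                continue
            src_vals = day_src.set_index("station_id")["pm25"]
            for ridx, row in drec.iterrows():
                own_in_pool = sources == "all" or bool(train_mask.loc[ridx])
                use_ids = tuple(s for s in src_ids if not (own_in_pool and s == row["station_id"]))
                if len(use_ids) < 1:
                    dropped.append(ridx)
                    continue
                key = (month, use_ids, (row["lon"], row["lat"]))
                w = weight_cache.get(key)
                if w is None:
                    coords = np.array([station_pos[s] for s in use_ids])
                    sol = kriging.ok_weights(vg, coords, (row["lon"], row["lat"]))
                    w = sol.weights
                    weight_cache[key] = w
                rd.loc[ridx] = float(w @ src_vals.loc[list(use_ids)].to_numpy())
    return rd, dropped


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _default_predict_fn(
    train: pd.DataFrame, test: pd.DataFrame, settings: ChainSettings, rd_sources: str = "train"
) -> np.ndarray:
    """The full LUR-GBM chain fitted on the training fold, applied to the test fold."""
    if settings.selected is not None:
        selected = list(settings.selected)
    else:
        cand = candidate_columns(train, settings)
        rep = screen_correlations(train[cand], train["pm25"], alpha=settings.screening_alpha)
        passing = rep.passing() or rep.passing("secondary") or cand
        selected, _ = lur.stepwise_select(train[passing], train["pm25"], settings.stepwise)
        if not selected:
            selected = passing

    rd_all = None
    if settings.use_rd:
        both = pd.concat([train, test])
        mask = pd.Series(False, index=both.index)
        mask.loc[train.index] = True
        rd_all, dropped = compute_rd(both, mask, settings, sources=rd_sources)
        if dropped:
            logger.info("dropped %d record(s) with no kriging sources", len(dropped))
        keep_train = train.index[np.isfinite(rd_all.loc[train.index])]
        train = train.loc[keep_train]

    Xtr, ytr = gbm.assemble_features(
        train, rd_all.loc[train.index] if rd_all is not None else None, selected, use_rd=settings.use_rd
    )
    mdl = gbm.train(Xtr, ytr, settings.gbm)
    # held-out rows whose Rd could not be kriged (no eligible source stations
    # that day) are unpredictable by contract; they stay NaN for the caller
    preds = np.full(len(test), np.nan)
    if settings.use_rd:
        ok = np.isfinite(rd_all.loc[test.index].to_numpy())
        test = test.loc[test.index[ok]]
    else:
        ok = np.ones(len(test), dtype=bool)
    if len(test):
        Xte, _ = gbm.assemble_features(
            test, rd_all.loc[test.index] if rd_all is not None else None, selected, use_rd=settings.use_rd
        )
        preds[ok] = gbm.predict(mdl, Xte)
    return preds


def cross_validate(
    records: pd.DataFrame,
    scheme: str,
    settings: ChainSettings | None = None,
    k: int = 10,
    seed: int = 0,
    time_block: str = "M",
    predict_fn: Callable[[pd.DataFrame, pd.DataFrame, ChainSettings], np.ndarray] | None = None,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Pooled out-of-fold evaluation of the full chain under one CV scheme.

    Returns the pooled report and the per-fold reports.  ``predict_fn`` may
    replace the default chain (used for oracle/baseline checks); it receives
    (training records, held-out records, settings) and returns held-out
    predictions, NaN marking records it could not predict.
    """
    settings = settings or ChainSettings()
    if predict_fn is None:
        # whole days are held out under the time scheme: Rd comes from the
        # concurrent network (own station excluded) instead of same-day
        # training stations, which do not exist there
        from functools import partial

        predict_fn = partial(_default_predict_fn, rd_sources="all" if scheme == "time" else "train")
    folds = make_folds(records, scheme, k=k, seed=seed, time_block=time_block)

    pooled_pred, pooled_obs = [], []
    per_fold = []
    n_dropped = 0
    for f in range(1, k + 1):
        test = records[folds.fold_id == f]
        train = records[folds.fold_id != f]
        if settings.use_rd and scheme == "site" and train["station_id"].nunique() < 2:
            raise ValueError("training fold must retain at least 2 stations")
        preds = np.asarray(predict_fn(train, test, settings), dtype=float)
        ok = np.isfinite(preds)
        n_dropped += int((~ok).sum())
        obs = test["pm25"].to_numpy(dtype=float)
        if ok.sum() >= 2:
            per_fold.append(compute_metrics(preds[ok], obs[ok]))
        pooled_pred.append(preds[ok])
        pooled_obs.append(obs[ok])
    if n_dropped:
        logger.info("cross_validate(%s): %d held-out record(s) dropped", scheme, n_dropped)
    pooled = compute_metrics(np.concatenate(pooled_pred), np.concatenate(pooled_obs))
    return pooled, per_fold


def repeated_split_eval(
    records: pd.DataFrame,
    settings: ChainSettings | None = None,
    train_fraction: float = 0.7,
    n_repeats: int = 10,
    seed: int = 0,
    predict_fn: Callable | None = None,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Repeated random 70/30 split evaluation, metrics averaged over repeats."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be ≥ 1")
    settings = settings or ChainSettings()
    predict_fn = predict_fn or _default_predict_fn
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_repeats):
        perm = rng.permutation(len(records))
        n_train = int(round(train_fraction * len(records)))
        train = records.iloc[perm[:n_train]]
        test = records.iloc[perm[n_train:]]
        preds = np.asarray(predict_fn(train, test, settings), dtype=float)
        ok = np.isfinite(preds)
        reports.append(compute_metrics(preds[ok], test["pm25"].to_numpy(dtype=float)[ok]))
    mean = MetricsReport(
        r2=float(np.mean([r.r2 for r in reports])),
        rmse=float(np.mean([r.rmse for r in reports])),
        mae=float(np.mean([r.mae for r in reports])),
        mape=float(np.mean([r.mape for r in reports])),
        n=int(np.sum([r.n for r in reports])),
    )
    return mean, reports


# ---------------------------------------------------------------------------
# Model comparison arithmetic
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Relative metric changes of a reference model against a baseline, in %."""

    per_scheme: pd.DataFrame   # index = scheme label; columns R2, RMSE, MAE
    mean: dict                 # arithmetic mean across schemes, rounded to 2 dp
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_scheme": {
                str(i): {c: round(float(v), 2) for c, v in row.items()} for i, row in self.per_scheme.iterrows()
            },
            "mean": self.mean,
            "flags": list(self.flags),
        }


def relative_improvement(
    reference: MetricsReport | Sequence[MetricsReport],
    baseline: MetricsReport | Sequence[MetricsReport],
    scheme_labels: Sequence[str] | None = None,
) -> ComparisonReport:
    """Percentage improvement of a reference model over a baseline.

    R² improves when larger: (ref − base)/base·100.  RMSE and MAE improve when
    smaller: (base − ref)/base·100.  With several evaluation schemes the
    headline numbers are the arithmetic means of the per-scheme changes.  Zero
    baseline metrics make the ratio undefined and are flagged.
    """
    refs = [reference] if isinstance(reference, MetricsReport) else list(reference)
    bases = [baseline] if isinstance(baseline, MetricsReport) else list(baseline)
    if len(refs) != len(bases):
        raise ValueError("reference and baseline scheme lists must match in length")
    labels = list(scheme_labels) if scheme_labels is not None else [f"scheme{i+1}" for i in range(len(refs))]

    rows = {}
    flags = []
    for lab, ref, base in zip(labels, refs, bases):
        row = {}
        for name, rv, bv, larger_better in (
            ("R2", ref.r2, base.r2, True),
            ("RMSE", ref.rmse, base.rmse, False),
            ("MAE", ref.mae, base.mae, False),
        ):
            if bv == 0 or not np.isfinite(bv):
                row[name] = float("nan")
                flags.append(f"{lab}:{name}_undefined_zero_baseline")
            else:
                row[name] = ((rv - bv) if larger_better else (bv - rv)) / bv * 100.0
        rows[lab] = row
    per_scheme = pd.DataFrame.from_dict(rows, orient="index")
    mean = {c: round(float(per_scheme[c].mean()), 2) for c in per_scheme.columns}
    return ComparisonReport(per_scheme=per_scheme, mean=mean, flags=flags)


# ---------------------------------------------------------------------------
# Published benchmark metrics consumed by the comparison report
# ---------------------------------------------------------------------------

#: Ten-fold CV accuracy of six PM2.5 estimators on a national multi-year
#: station dataset (input data for `relative_improvement`; the comparison
#: models themselves are not re-trained here).  Keys: model → scheme →
#: MetricsReport (MAPE/n not published per cell; set NaN/0).
REFERENCE_MODEL_METRICS: dict[str, dict[str, MetricsReport]] = {
    name: {
        scheme: MetricsReport(r2=r2, rmse=rmse, mae=mae, mape=float("nan"), n=0)
        for scheme, (r2, rmse, mae) in by_scheme.items()
    }
    for name, by_scheme in {
        "BPNN":     {"sample": (0.76, 11.27, 8.35), "site": (0.65, 11.26, 9.34), "time": (0.56, 13.28, 9.69)},
        "DNN":      {"sample": (0.84, 10.33, 8.05), "site": (0.78, 11.09, 8.86), "time": (0.77, 10.43, 7.67)},
        "RF":       {"sample": (0.86, 9.19, 6.08),  "site": (0.81, 11.03, 7.46), "time": (0.79, 11.27, 8.03)},
        "XGBoost":  {"sample": (0.88, 7.34, 4.79),  "site": (0.83, 10.54, 6.78), "time": (0.81, 9.86, 6.93)},
        "LightGBM": {"sample": (0.91, 6.56, 4.56),  "site": (0.85, 8.32, 5.76),  "time": (0.83, 7.86, 5.49)},
        "LUR-GBM":  {"sample": (0.98, 6.43, 4.17),  "site": (0.91, 7.46, 5.01),  "time": (0.89, 7.07, 4.95)},
    }.items()
}


def benchmark_comparison(reference: str = "LUR-GBM", baseline: str = "BPNN") -> ComparisonReport:
    """Comparison report between two benchmarked models across all three schemes."""
    ref = [REFERENCE_MODEL_METRICS[reference][s] for s in CV_SCHEMES]
    base = [REFERENCE_MODEL_METRICS[baseline][s] for s in CV_SCHEMES]
    return relative_improvement(ref, base, scheme_labels=CV_SCHEMES)


def benchmark_scheme_comparison(reference_scheme: str = "sample", baseline_scheme: str = "site",
                                model_name: str = "LUR-GBM") -> ComparisonReport:
    """Comparison of one model's accuracy between two CV schemes."""
    ref = REFERENCE_MODEL_METRICS[model_name][reference_scheme]
    base = REFERENCE_MODEL_METRICS[model_name][baseline_scheme]
    return relative_improvement(ref, base, scheme_labels=[f"{reference_scheme}_vs_{baseline_scheme}"])
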