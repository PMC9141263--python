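"""Metrics, fold assignment, cross-validation contracts and comparison arithmetic."""

import numpy as np
import pandas as pd
import pytest

from lurgbm import evaluation as ev
from lurgbm.evaluation import (
    ChainSettings,
    MetricsReport,
    compute_metrics,
    cross_validate,
    make_folds,
    relative_improvement,
    repeated_split_eval,
)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0 and m.mae == 0.0 and m.mape == 0.0

    def test_hand_computed_example(self):
        m = compute_metrics([12.0, 18.0, 33.0], [10.0, 20.0, 30.0])
        assert m.rmse == pytest.approx(np.sqrt(17.0 / 3.0), abs=1e-3)
        assert m.mae == pytest.approx(7.0 / 3.0, abs=1e-3)
        assert m.mape == pytest.approx(13.333, abs=1e-2)
        assert m.r2 == pytest.approx(0.9423, abs=1e-3)

    def test_constant_shift_keeps_r2_at_one(self):
        obs = np.array([10.0, 20.0, 30.0])
        m = compute_metrics(obs + 5.0, obs)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(5.0)
        assert m.mae == pytest.approx(5.0)

    def test_zero_observed_flags_mape_only(self):
        m = compute_metrics([1.0, 2.0, 3.0], [0.0, 2.0, 3.0])
        assert np.isnan(m.mape)
        assert "mape_undefined_zero_observed" in m.flags
        assert np.isfinite(m.rmse) and np.isfinite(m.mae)

    def test_rmse_never_below_mae(self, rng):
        for _ in range(200):
            p = rng.normal(size=20)
            o = rng.normal(size=20) + 1000.0
            m = compute_metrics(p, o)
            assert m.rmse >= m.mae

    def test_r2_invariant_to_positive_affine_prediction_transform(self, rng):
        p = rng.normal(size=40)
        o = 2 * p + rng.normal(size=40)
        assert compute_metrics(p, o).r2 == pytest.approx(compute_metrics(3 * p + 7, o).r2)


def _records(n_stations=12, n_days=40, seed=0, start="2016-01-01"):
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days)
    rows = []
    for s in range(n_stations):
        rows.append(
            pd.DataFrame(
                {
                    "station_id": f"S{s:02d}",
                    "lon": 104.0 + rng.uniform(0.0, 2.0),
                    "lat": 30.0 + rng.uniform(0.0, 2.0),
                    "date": dates,
                    "pm25": rng.normal(50, 8, size=n_days).clip(1.0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestMakeFolds:
    def test_sample_folds_balanced(self):
        rec = _records(10, 10)  # 100 records
        f = make_folds(rec, "sample", k=10, seed=1)
        sizes = f.fold_id.value_counts()
        assert (sizes == 10).all()

    def test_site_folds_keep_stations_whole(self):
        rec = _records(12, 5)
        f = make_folds(rec, "site", k=10, seed=1)
        per_station = rec.groupby("station_id").apply(lambda g: f.fold_id.loc[g.index].nunique(),
                                                      include_groups=False)
        assert (per_station == 1).all()

    def test_time_folds_deal_whole_blocks_round_robin(self):
        rec = _records(2, 140, start="2016-01-04")  # Monday start: exactly 20 weekly blocks
        f = make_folds(rec, "time", k=10, seed=0, time_block="W")
        blocks = pd.to_datetime(rec["date"]).dt.to_period("W")
        per_block = blocks.groupby(blocks).apply(lambda g: f.fold_id.loc[g.index].nunique())
        assert (per_block == 1).all()
        blocks_per_fold = pd.DataFrame({"b": blocks, "f": f.fold_id}).groupby("f")["b"].nunique()
        assert (blocks_per_fold == 2).all()

    def test_every_record_in_exactly_one_fold(self):
        rec = _records(12, 30)
        for scheme, kw in (("sample", {}), ("site", {}), ("time", {"time_block": "D"})):
            f = make_folds(rec, scheme, k=10, seed=2, **kw)
            assert f.fold_id.between(1, 10).all()
            assert len(f.fold_id) == len(rec)

    def test_fewer_groups_than_k_rejected(self):
        rec = _records(5, 30)
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(rec, "site", k=10)
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(rec, "time", k=10, time_block="M")


class TestCrossValidate:
    def test_oracle_pipeline_scores_perfectly(self):
        rec = _records()
        oracle = lambda train, test, s: test["pm25"].to_numpy()
        pooled, per_fold = cross_validate(rec, "sample", predict_fn=oracle, seed=0)
        assert pooled.r2 == pytest.approx(1.0)
        assert pooled.rmse == 0.0
        assert len(per_fold) == 10

    def test_constant_mean_pipeline_rmse_is_heldout_sd(self):
        rec = _records(seed=3)
        const = lambda train, test, s: np.full(len(test), train["pm25"].mean())
        pooled, per_fold = cross_validate(rec, "sample", predict_fn=const, seed=0)
        # within a fold the prediction is constant, so R² is undefined there;
        # pooled folds differ only by their training means, leaving R² ≈ 0
        assert all(np.isnan(r.r2) and "r2_undefined_constant_input" in r.flags for r in per_fold)
        assert pooled.r2 < 0.05
        sd = rec["pm25"].std(ddof=0)
        assert pooled.rmse == pytest.approx(sd, rel=0.05)

    def test_site_predictions_ignore_heldout_observations(self):
        """Anti-leakage: chain predictions for held-out stations are invariant to their PM2.5."""
        rec = _records(n_stations=10, n_days=31, seed=4)
        settings = ChainSettings(selected=[], variogram_n_bins=6)
        stations = sorted(rec["station_id"].unique())
        test = rec[rec["station_id"].isin(stations[:2])]
        train = rec[~rec["station_id"].isin(stations[:2])]
        p1 = ev._default_predict_fn(train, test, settings)
        scrambled = test.copy()
        scrambled["pm25"] = scrambled["pm25"].sample(frac=1.0, random_state=9).to_numpy()
        p2 = ev._default_predict_fn(train, scrambled, settings)
        assert np.allclose(p1, p2, equal_nan=True)


class TestRelativeImprovement:
    def test_self_comparison_is_zero(self):
        m = MetricsReport(r2=0.9, rmse=5.0, mae=3.0, mape=10.0, n=100)
        rep = relative_improvement(m, m)
        assert rep.mean == {"R2": 0.0, "RMSE": 0.0, "MAE": 0.0}

    def test_single_scheme_r2_gain(self):
        ref = MetricsReport(r2=0.98, rmse=6.43, mae=4.17, mape=np.nan, n=0)
        base = MetricsReport(r2=0.91, rmse=7.46, mae=5.01, mape=np.nan, n=0)
        rep = relative_improvement(ref, base)
        assert rep.mean["R2"] == pytest.approx(7.69, abs=0.005)

    def test_three_scheme_mean_gain(self):
        refs = [MetricsReport(r2, 0.0, 0.0, np.nan, 0) for r2 in (0.98, 0.91, 0.89)]
        bases = [MetricsReport(r2, 0.0, 0.0, np.nan, 0) for r2 in (0.76, 0.65, 0.56)]
        rep = relative_improvement(refs, bases)
        assert rep.mean["R2"] == pytest.approx(42.63, abs=0.005)
        assert "scheme1:RMSE_undefined_zero_baseline" in rep.flags

    def test_zero_baseline_flagged(self):
        ref = MetricsReport(r2=0.9, rmse=1.0, mae=1.0, mape=np.nan, n=0)
        base = MetricsReport(r2=0.0, rmse=1.0, mae=1.0, mape=np.nan, n=0)
        rep = relative_improvement(ref, base, scheme_labels=["s"])
        assert np.isnan(rep.per_scheme.loc["s", "R2"])
        assert "s:R2_undefined_zero_baseline" in rep.flags

    def test_mismatched_scheme_lists_rejected(self):
        m = MetricsReport(0.9, 1.0, 1.0, np.nan, 0)
        with pytest.raises(ValueError, match="match"):
            relative_improvement([m, m], [m])


class TestRepeatedSplit:
    def test_single_repeat_equals_single_split(self):
        rec = _records(seed=5)
        oracle = lambda train, test, s: test["pm25"].to_numpy() + 1.0
        mean, reports = repeated_split_eval(rec, n_repeats=1, seed=3, predict_fn=oracle)
        assert len(reports) == 1
        assert mean.rmse == reports[0].rmse == pytest.approx(1.0)

    def test_oracle_predictor_averages_to_zero_rmse(self):
        rec = _records(seed=6)
        oracle = lambda train, test, s: test["pm25"].to_numpy()
        mean, _ = repeated_split_eval(rec, n_repeats=3, seed=3, predict_fn=oracle)
        assert mean.rmse == 0.0 and mean.mae == 0.0

    def test_zero_repeats_rejected(self):
        with pytest.raises(ValueError, match="n_repeats"):
            repeated_split_eval(_records(), n_repeats=0)
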