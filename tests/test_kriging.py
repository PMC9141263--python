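"""Semivariogram estimation, variogram fitting and the ordinary-kriging solver."""

import numpy as np
import pandas as pd
import pytest

from lurgbm import kriging as kg

TOY_COORDS = np.array(
    [[104.0, 30.0], [104.5, 30.2], [105.1, 30.9], [104.2, 31.4], [105.6, 30.1]]
)


class TestEmpiricalSemivariogram:
    def test_two_stations_single_bin(self):
        coords = np.array([[104.0, 30.0], [104.0, 30.5]])
        emp = kg.empirical_semivariogram(coords, np.array([0.0, 2.0]), n_bins=1, max_lag=100.0)
        assert emp.gamma_hat[0] == pytest.approx(2.0)  # 0.5 * (2-0)^2
        assert emp.pair_counts[0] == 1

    def test_constant_field_has_zero_semivariance(self):
        emp = kg.empirical_semivariogram(TOY_COORDS, np.full(5, 7.0), n_bins=3, max_lag=200.0)
        assert np.all(emp.gamma_hat == 0.0)

    def test_matches_exhaustive_pair_enumeration(self):
        values = np.array([10.0, 14.0, 9.0, 21.0, 12.0])
        n_bins, max_lag = 2, 200.0
        emp = kg.empirical_semivariogram(TOY_COORDS, values, n_bins=n_bins, max_lag=max_lag)
        # oracle: loop over all 10 pairs, assign to equal-width bins by haversine
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for i in range(5):
            for j in range(i + 1, 5):
                d = float(kg.haversine_km(*TOY_COORDS[i], *TOY_COORDS[j]))
                if d > max_lag:
                    continue
                b = min(int(d // (max_lag / n_bins)), n_bins - 1)
                sums[b] += 0.5 * (values[i] - values[j]) ** 2
                counts[b] += 1
        keep = counts > 0
        assert np.allclose(emp.gamma_hat, sums[keep] / counts[keep])
        assert np.array_equal(emp.pair_counts, counts[keep])

    def test_all_pairs_beyond_max_lag_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            kg.empirical_semivariogram(TOY_COORDS, np.arange(5.0), n_bins=2, max_lag=1e-3)


class TestFitVariogram:
    def test_noiseless_spherical_recovered_exactly(self):
        true = kg.VariogramModel("spherical", 0.0, 25.0, 10.0)
        h = np.linspace(0.5, 15.0, 10)
        emp = kg.EmpiricalVariogram(h, true.gamma(h), np.full(10, 100))
        fit = kg.fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(0.0, abs=1e-6)
        assert fit.partial_sill == pytest.approx(25.0, abs=1e-6)
        assert fit.range_km == pytest.approx(10.0, abs=1e-6)

    def test_constant_gamma_fits_pure_nugget(self):
        emp = kg.EmpiricalVariogram(np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 5.0), np.full(4, 10))
        fit = kg.fit_variogram(emp, "spherical")
        assert fit.nugget == pytest.approx(5.0, abs=1e-6)
        assert fit.partial_sill == pytest.approx(0.0, abs=1e-6)

    def test_objective_beats_dense_parameter_grid(self, rng):
        h = np.linspace(1.0, 30.0, 12)
        true = kg.VariogramModel("spherical", 2.0, 20.0, 12.0)
        g = true.gamma(h) + rng.normal(0, 1.0, size=12)
        g = np.clip(g, 0.0, None)
        counts = np.full(12, 50)
        emp = kg.EmpiricalVariogram(h, g, counts)
        fit = kg.fit_variogram(emp, "spherical")
        # 20^3 grid-search lower-bound oracle on the same WLS objective
        best = np.inf
        for n0 in np.linspace(0, 10, 20):
            for p0 in np.linspace(0.1, 40, 20):
                for r0 in np.linspace(1, 40, 20):
                    m = kg.VariogramModel("spherical", n0, p0, r0)
                    best = min(best, float(np.sum(counts * (m.gamma(h) - g) ** 2)))
        assert 2 * fit.fit_objective <= best + 1e-9  # least_squares cost is 1/2 * WLS sum

    def test_too_few_bins_rejected(self):
        emp = kg.EmpiricalVariogram(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([5, 5]))
        with pytest.raises(ValueError, match="3 occupied"):
            kg.fit_variogram(emp)


class TestOKWeights:
    def test_single_station_gets_unit_weight(self, toy_variogram):
        sol = kg.ok_weights(toy_variogram, np.array([[104.0, 30.0]]), (105.0, 31.0), np.array([12.0]))
        assert sol.weights == pytest.approx([1.0])
        assert sol.estimate == pytest.approx(12.0)

    def test_equidistant_pair_splits_weight_evenly(self, toy_variogram):
        coords = np.array([[104.0, 30.0], [104.0, 31.0]])
        sol = kg.ok_weights(toy_variogram, coords, (104.0, 30.5), np.array([1.0, 3.0]))
        assert sol.weights == pytest.approx([0.5, 0.5], abs=1e-12)
        assert sol.estimate == pytest.approx(2.0)

    def test_weights_sum_to_one(self, toy_variogram, rng):
        for _ in range(50):
            coords = np.column_stack([104 + 3 * rng.random(8), 30 + 3 * rng.random(8)])
            sol = kg.ok_weights(toy_variogram, coords, (104 + 3 * rng.random(), 30 + 3 * rng.random()))
            assert abs(sol.weights.sum() - 1.0) < 1e-10

    def test_matches_constrained_minimum_variance_oracle(self, toy_variogram):
        """Weights equal the reduced QP solution (w_n eliminated via the unit-sum constraint)."""
        target = np.array([104.8, 30.6])
        coords = TOY_COORDS
        sol = kg.ok_weights(toy_variogram, coords, target)
        gmat = toy_variogram.gamma(kg.pairwise_distances_km(coords))
        np.fill_diagonal(gmat, 0.0)
        g0 = toy_variogram.gamma(kg.haversine_km(coords[:, 0], coords[:, 1], *target))
        # variance(w) = 2 w.g0 - w^T G w on the constraint plane; substitute
        # w_n = 1 - sum(v) and minimise the unconstrained quadratic in v
        n = len(coords)
        e = np.eye(n - 1)
        B = np.vstack([e, -np.ones(n - 1)])       # w = B v + c
        c = np.zeros(n)
        c[-1] = 1.0
        H = -2.0 * B.T @ gmat @ B                 # Hessian of variance in v
        lin = 2.0 * B.T @ g0 - 2.0 * B.T @ gmat @ c
        v = np.linalg.solve(H, -lin)
        w_oracle = B @ v + c
        assert np.allclose(sol.weights, w_oracle, atol=1e-8)

    def test_duplicate_stations_averaged_not_singular(self, toy_variogram):
        coords = np.array([[104.0, 30.0], [104.0, 30.0], [105.0, 31.0]])
        sol = kg.ok_weights(toy_variogram, coords, (104.5, 30.5), np.array([2.0, 4.0, 10.0]))
        assert len(sol.weights) == 2
        assert abs(sol.weights.sum() - 1.0) < 1e-10

    def test_ok_variance_not_above_random_admissible_weights(self, toy_variogram, rng):
        target = np.array([104.9, 30.7])
        gmat = toy_variogram.gamma(kg.pairwise_distances_km(TOY_COORDS))
        np.fill_diagonal(gmat, 0.0)
        g0 = toy_variogram.gamma(kg.haversine_km(TOY_COORDS[:, 0], TOY_COORDS[:, 1], *target))
        sol = kg.ok_weights(toy_variogram, TOY_COORDS, target)

        def variance(w):
            return 2 * w @ g0 - w @ gmat @ w

        v_ok = variance(sol.weights)
        w = rng.normal(size=(2000, 5))
        w /= w.sum(axis=1, keepdims=True)
        v_rand = 2 * w @ g0 - np.einsum("ij,jk,ik->i", w, gmat, w)
        assert np.all(v_rand >= v_ok - 1e-9)


class TestKrigeRd:
    def _day_records(self, values):
        return pd.DataFrame(
            {
                "station_id": [f"S{i}" for i in range(len(values))],
                "lon": TOY_COORDS[: len(values), 0],
                "lat": TOY_COORDS[: len(values), 1],
                "date": pd.Timestamp("2016-07-15"),
                "pm25": values,
            }
        )

    def test_nugget_zero_exact_at_station(self, toy_variogram):
        rec = self._day_records([10.0, 20.0, 30.0, 25.0, 15.0])
        rd, feats = kg.krige_rd(rec, TOY_COORDS[2:3], toy_variogram, leave_one_out=False)
        assert rd[0] == pytest.approx(30.0, abs=1e-8)
        assert feats[0].rt == 7

    def test_constant_field_preserved_everywhere(self, toy_variogram):
        rec = self._day_records([9.0] * 5)
        targets = np.array([[104.7, 30.4], [105.0, 31.0]])
        rd, _ = kg.krige_rd(rec, targets, toy_variogram)
        assert np.allclose(rd, 9.0)

    def test_loo_matches_explicit_refit(self, toy_variogram, rng):
        coords = np.column_stack([104 + 2 * rng.random(6), 30 + 2 * rng.random(6)])
        values = rng.normal(50, 8, size=6)
        loo = kg.loo_krige(toy_variogram, coords, values)
        for i in range(6):
            keep = np.arange(6) != i
            refit = kg.ok_weights(toy_variogram, coords[keep], coords[i], values[keep])
            assert loo[i] == pytest.approx(refit.estimate, abs=1e-10)

    def test_loo_invariant_to_own_observation(self, toy_variogram, rng):
        coords = np.column_stack([104 + 2 * rng.random(6), 30 + 2 * rng.random(6)])
        values = rng.normal(50, 8, size=6)
        loo1 = kg.loo_krige(toy_variogram, coords, values)
        bumped = values.copy()
        bumped[3] += 100.0
        loo2 = kg.loo_krige(toy_variogram, coords, bumped)
        assert loo2[3] == pytest.approx(loo1[3])

    def test_krige_rd_loo_excludes_coincident_station(self, toy_variogram):
        rec = self._day_records([10.0, 20.0, 30.0, 25.0, 15.0])
        rd_loo, _ = kg.krige_rd(rec, TOY_COORDS[2:3], toy_variogram, leave_one_out=True)
        refit = kg.ok_weights(
            toy_variogram,
            np.delete(TOY_COORDS, 2, axis=0),
            TOY_COORDS[2],
            np.array([10.0, 20.0, 25.0, 15.0]),
        )
        assert rd_loo[0] == pytest.approx(refit.estimate)

    def test_multiday_records_rejected(self, toy_variogram):
        rec = self._day_records([1.0, 2.0, 3.0, 4.0, 5.0])
        rec.loc[0, "date"] = pd.Timestamp("2016-07-16")
        with pytest.raises(ValueError, match="single day"):
            kg.krige_rd(rec, TOY_COORDS[:1], toy_variogram)


def test_gamma_limits_and_monotonicity():
    for family in kg.VARIOGRAM_FAMILIES:
        m = kg.VariogramModel(family, 1.5, 10.0, 20.0)
        h = np.linspace(0, 200, 500)
        g = m.gamma(h)
        assert g[0] == pytest.approx(1.5)          # gamma(0) = nugget
        assert np.all(np.diff(g) >= -1e-12)        # nondecreasing
        assert g[-1] == pytest.approx(11.5, rel=1e-3)  # nugget + partial sill
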