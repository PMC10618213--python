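import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from canapy.drivers import (
    assemble_driver_table,
    compute_anomaly,
    elevation_range,
    fit_ols,
    fit_sar_error,
    fit_sar_error_scan,
    knn_weights,
    model_selection,
    moran_correlogram,
    moran_test,
    simulate_sar_error,
    standardize,
    vif,
)


def _series(vals, name=None):
    return pd.Series(vals, index=[f"c{i}" for i in range(len(vals))], name=name)


class TestLayerOps:
    def test_anomaly_is_past_minus_present(self):
        past, present = _series([10.0, 5.0]), _series([4.0, 5.0])
        out = compute_anomaly(past, present)
        assert list(out) == [6.0, 0.0]

    def test_anomaly_cell_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_anomaly(_series([1.0]), _series([1.0, 2.0]))

    def test_anomaly_random_matches_elementwise(self):
        rng = np.random.default_rng(0)
        a, b = _series(rng.normal(size=20)), _series(rng.normal(size=20))
        assert np.allclose(compute_anomaly(a, b), a.to_numpy() - b.to_numpy())

    def test_elevation_range(self):
        samples = pd.DataFrame(
            {
                "cell_id": ["a", "a", "a", "b", "b"],
                "elevation": [100.0, 350.0, 80.0, 7.0, 7.0],
            }
        )
        out = elevation_range(samples)
        assert out["a"] == 270.0
        assert out["b"] == 0.0  # constant samples

    def test_elevation_range_random_matches_brute_force(self):
        rng = np.random.default_rng(1)
        samples = pd.DataFrame(
            {
                "cell_id": rng.choice(["a", "b", "c"], size=50),
                "elevation": rng.normal(500, 200, size=50),
            }
        )
        out = elevation_range(samples)
        for cid in "abc":
            vals = samples.loc[samples.cell_id == cid, "elevation"]
            assert out[cid] == pytest.approx(vals.max() - vals.min())

    def test_standardize_hand_example(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        out, params = standardize(table)
        assert np.allclose(out["v"], [-1, 0, 1])  # sd uses the n-1 denominator
        assert params.loc["v", "sd"] == 1.0

    def test_standardize_idempotent_and_constant_error(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"v": rng.normal(size=30)})
        once, _ = standardize(table)
        twice, _ = standardize(once)
        assert np.allclose(once["v"], twice["v"], atol=1e-12)
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": np.ones(5)}))


class TestVif:
    def test_orthogonal_columns_give_one(self):
        x = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        assert np.allclose(vif(x), 1.0)

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        x = pd.DataFrame({"a": a, "b": a})
        assert np.isinf(vif(x)).all()

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=500)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.normal(size=500)
        x = pd.DataFrame({"a": a, "b": b})
        r = np.corrcoef(a, b)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        assert np.allclose(vif(x), expected, rtol=1e-9)


class TestOls:
    def test_exact_linear_fit(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = 2.0 + 3.0 * x["x"]
        fit = fit_ols(y, x)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.params["x"] == pytest.approx(3.0)

    def test_noise_response_has_near_zero_adjusted_r2(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"x": rng.normal(size=400)})
        fit = fit_ols(pd.Series(rng.normal(size=400)), x)
        assert abs(fit.adj_r2) < 0.02

    def test_matches_normal_equations(self):
        x = pd.DataFrame({"x1": [1.0, 2, 3, 4], "x2": [0.0, 1, 0, 1]})
        y = pd.Series([1.0, 3.0, 2.0, 5.0])
        X = np.column_stack([np.ones(4), x.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        fit = fit_ols(y, x)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_rank_deficiency_raises(self):
        x = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6]})
        with pytest.raises(ValueError, match="rank"):
            fit_ols(pd.Series([1.0, 2, 3]), x)


class TestKnnWeights:
    def test_collinear_points_nearest(self):
        coords = np.array([[0.0, 0], [1.0, 0], [3.0, 0]])
        w = knn_weights(coords, 1)
        assert w.neighbors[1, 0] == 0  # middle point's neighbour is the nearer end

    def test_row_sums_one(self):
        rng = np.random.default_rng(6)
        w = knn_weights(rng.normal(size=(30, 2)), 4)
        assert np.allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)
        assert w.W.diagonal().sum() == 0.0

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(25, 2))
        w = knn_weights(coords, 3)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        for i in range(25):
            assert set(w.neighbors[i]) == set(np.argsort(d[i])[:3])

    def test_k_validation(self):
        with pytest.raises(ValueError):
            knn_weights(np.zeros((3, 2)), 3)


def _lattice(n_side=15, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    g = np.arange(n_side, dtype=float)
    xx, yy = np.meshgrid(g, g)
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    if jitter:
        coords = coords + rng.normal(0, jitter, coords.shape)
    return coords


class TestSarError:
    def test_lambda_zero_reproduces_ols(self):
        coords = _lattice(10)
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = pd.Series(1.0 + 0.5 * X["x"] + rng.normal(0, 0.3, 100))
        w = knn_weights(coords, 4)
        sar = fit_sar_error(y, X, w, lam=0.0)
        ols = fit_ols(y, X)
        assert np.allclose(sar.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)
        assert sar.loglik == pytest.approx(ols.loglik, abs=1e-6)

    def test_null_process_estimates_small_lambda(self):
        coords = _lattice(12)
        rng = np.random.default_rng(9)
        w = knn_weights(coords, 4)
        X = pd.DataFrame({"x": rng.normal(size=144)})
        y = pd.Series(simulate_sar_error(X.to_numpy(), [1.0, 0.5], 0.0, w, 0.5, rng))
        sar = fit_sar_error(y, X, w)
        ols = fit_ols(y, X)
        assert abs(sar.lam) < 0.25
        for name in ("const", "x"):
            lo, hi = ols.conf_int.loc[name]
            assert lo - 0.05 <= sar.params[name] <= hi + 0.05

    def test_recovers_strong_spatial_error(self):
        coords = _lattice(15)
        rng = np.random.default_rng(10)
        w = knn_weights(coords, 6)
        X = pd.DataFrame({"x": rng.normal(size=225)})
        y = pd.Series(simulate_sar_error(X.to_numpy(), [0.0, 1.0], 0.7, w, 0.5, rng))
        sar = fit_sar_error(y, X, w)
        assert 0.45 < sar.lam < 0.9
        assert sar.nagelkerke_r2 > 0.4

    def test_scan_selects_by_aic(self):
        coords = _lattice(10)
        rng = np.random.default_rng(11)
        w = knn_weights(coords, 4)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = pd.Series(simulate_sar_error(X.to_numpy(), [0.0, 1.0], 0.5, w, 0.5, rng))
        best, table = fit_sar_error_scan(y, X, coords, k_scan=[2, 4, 6])
        assert best.aic == table["AIC"].min()
        assert set(table["k"]) == {2, 4, 6}


class TestMoran:
    def test_checkerboard_is_minus_one(self):
        # rook weights on an even lattice, alternating +-1 values
        n_side = 6
        coords = _lattice(n_side)
        vals = np.array(
            [1.0 if (int(x) + int(y)) % 2 == 0 else -1.0 for x, y in coords]
        )
        d = np.abs(coords[:, None] - coords[None, :]).sum(axis=2)
        W = sp.csr_matrix((d == 1).astype(float))
        res = moran_test(vals, W)
        assert res["I"] == pytest.approx(-1.0)

    def test_iid_expectation(self):
        rng = np.random.default_rng(12)
        coords = _lattice(8)
        w = knn_weights(coords, 4)
        res = moran_test(rng.normal(size=64), w)
        assert res["expected"] == pytest.approx(-1.0 / 63)

    def test_permutation_p_close_to_analytic(self):
        rng = np.random.default_rng(13)
        coords = _lattice(8)
        w = knn_weights(coords, 4)
        vals = rng.normal(size=64)
        res = moran_test(vals, w, n_perm=999, seed=3)
        se = 3 * np.sqrt(res["p"] * (1 - res["p"]) / 999)
        assert abs(res["p_perm"] - res["p"]) < max(se, 0.05)

    def test_constant_values_raise(self):
        w = knn_weights(_lattice(3), 2)
        with pytest.raises(ValueError, match="constant"):
            moran_test(np.ones(9), w)

    def test_correlogram_decays_for_smooth_field(self):
        from canapy.synthetic import gaussian_random_field

        rng = np.random.default_rng(14)
        field = gaussian_random_field(rng, 12, 12, 2.0)
        coords = _lattice(12)
        cg = moran_correlogram(field.ravel(), coords, bins=6)
        assert cg["I"].iloc[0] > 0.3  # strong short-range autocorrelation
        assert cg["I"].iloc[0] > cg["I"].iloc[-1]


class TestModelSelection:
    def test_sar_beats_ols_on_spatial_data(self):
        coords = _lattice(12)
        rng = np.random.default_rng(15)
        w = knn_weights(coords, 5)
        X = pd.DataFrame({"x": rng.normal(size=144)})
        y = pd.Series(simulate_sar_error(X.to_numpy(), [0.0, 1.0], 0.7, w, 0.5, rng))
        sar, ols = fit_sar_error(y, X, w), fit_ols(y, X)
        table = model_selection([ols, sar])
        assert table.iloc[0]["model"].startswith("SAR")
        assert table["dAIC"].iloc[0] == 0.0

    def test_identical_fits_have_zero_delta(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = pd.Series(rng.normal(size=50))
        t = model_selection([fit_ols(y, X), fit_ols(y, X)])
        assert np.allclose(t["dAIC"], 0.0)

    def test_mismatched_responses_raise(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        f1 = fit_ols(pd.Series(rng.normal(size=50)), X)
        f2 = fit_ols(pd.Series(rng.normal(size=50)), X)
        with pytest.raises(ValueError):
            model_selection([f1, f2])


def test_assemble_driver_table_drops_zero_pe_and_standardizes():
    idx = pd.Index([f"c{i}" for i in range(6)], name="cell_id")
    pe = pd.Series([0.1, 0.2, 0.0, 0.4, 0.3, 0.5], index=idx)
    rng = np.random.default_rng(18)
    layers = pd.DataFrame(
        {"MAT": rng.normal(20, 5, 6), "AP": rng.normal(1000, 100, 6)}, index=idx
    )
    coords = pd.DataFrame({"x": range(6), "y": 0}, index=idx)
    table, params = assemble_driver_table(pe, layers, coords, ["MAT", "AP"])
    assert len(table) == 5  # the PE = 0 cell is gone
    assert table.attrs["n_dropped_zero_pe"] == 1
    assert np.allclose(table[["MAT", "AP"]].mean(), 0.0, atol=1e-9)
    assert np.allclose(table[["MAT", "AP"]].std(ddof=1), 1.0, atol=1e-9)
    assert np.allclose(table["response"], np.log10(pe[pe > 0]))
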