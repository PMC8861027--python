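"""Network stage: perturbation statistic, sign conventions, grids, t-tests."""

import numpy as np
import pandas as pd
import pytest

from fluxdry.ann import (AnnSpec, SensitivityGrid, bin_aggregate, cross_site_grid,
                         perturbation_sensitivity, sensitivity_vs_truth,
                         site_sensitivities, train_ann)
from fluxdry.errors import ContractError, UsageError

from conftest import make_linear_days


class FakeLinearModel:
    """Exact linear predictor over (ta, vpd, swc, rg) z-scores."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def predict(self, X):
        return X @ self.w


def _X(n=50, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2015-06-01", periods=n, freq="D")
    return pd.DataFrame(rng.standard_normal((n, 4)),
                        columns=["ta", "vpd", "swc", "rg"], index=idx)


class TestPerturbation:
    def test_linear_model_vpd_sensitivity_is_the_coefficient(self):
        model = FakeLinearModel([0.1, -0.45, 0.22, 0.5])
        sens = perturbation_sensitivity(model, _X(), "vpd")
        np.testing.assert_allclose(sens, -0.45, atol=1e-12)

    def test_swc_reported_with_drying_orientation(self):
        # raw SWC coefficient +0.22: drying (-1 sd) must report -0.22
        model = FakeLinearModel([0.1, -0.45, 0.22, 0.5])
        sens = perturbation_sensitivity(model, _X(), "swc")
        np.testing.assert_allclose(sens, -0.22, atol=1e-12)

    def test_constant_predictor_has_zero_sensitivity(self):
        model = FakeLinearModel([0.0, 0.0, 0.0, 0.0])
        sens = perturbation_sensitivity(model, _X(), "swc")
        np.testing.assert_allclose(sens, 0.0)

    def test_explicit_direction_overrides_default(self):
        model = FakeLinearModel([0.0, 0.0, 0.22, 0.0])
        sens = perturbation_sensitivity(model, _X(), "swc", direction=+1.0)
        np.testing.assert_allclose(sens, 0.22, atol=1e-12)

    def test_unknown_variable_is_usage_error(self):
        with pytest.raises(UsageError):
            perturbation_sensitivity(FakeLinearModel([0] * 4), _X(), "pressure")


class TestTraining:
    def test_linear_noise_free_response_is_learned(self):
        rng = np.random.default_rng(1)
        days = make_linear_days(400, {"swc": 0.22, "vpd": -0.45, "rg": 0.5}, 0.0, rng)
        X = days[["ta", "vpd", "swc", "rg"]]
        fit = train_ann(X, days["gpp_nt"], AnnSpec(), seed=5)
        assert fit.r_test > 0.999

    def test_same_seed_reproduces_predictions(self):
        rng = np.random.default_rng(2)
        days = make_linear_days(200, {"swc": 0.3}, 0.2, rng)
        X = days[["ta", "vpd", "swc", "rg"]]
        f1 = train_ann(X, days["gpp_nt"], AnnSpec(), seed=7)
        f2 = train_ann(X, days["gpp_nt"], AnnSpec(), seed=7)
        np.testing.assert_array_equal(f1.predict(X.to_numpy()), f2.predict(X.to_numpy()))
        assert f1.r_test == f2.r_test

    def test_too_few_days_rejected(self):
        rng = np.random.default_rng(3)
        days = make_linear_days(50, {"swc": 0.3}, 0.2, rng)
        with pytest.raises(ContractError):
            train_ann(days[["ta", "vpd", "swc", "rg"]], days["gpp_nt"], AnnSpec(), 0)

    def test_pure_noise_response_fails_the_performance_rule(self):
        rng = np.random.default_rng(4)
        excluded = 0
        n_seeds = 40
        for s in range(n_seeds):
            days = make_linear_days(150, {}, 1.0, rng)
            fit = train_ann(days[["ta", "vpd", "swc", "rg"]], days["gpp_nt"],
                            AnnSpec(), seed=s)
            excluded += not fit.passes(0.5)
        assert excluded >= 0.9 * n_seeds

    def test_linear_equivalence_of_binned_sensitivities(self):
        """For a linear response, per-bin network sensitivities equal the
        (orientation-adjusted) regression coefficients in every populated cell."""
        rng = np.random.default_rng(5)
        days = make_linear_days(600, {"swc": 0.22, "vpd": -0.45, "rg": 0.5},
                                0.02, rng)
        X = days[["ta", "vpd", "swc", "rg"]]
        from fluxdry.ingest import assign_bins
        _, labels = assign_bins(days.rename(columns={}), "swc", "vpd")
        res = site_sensitivities(X, days["gpp_nt"], labels, AnnSpec(repeats=3),
                                 base_seed=0, site_index=0)
        swc = res.grids["swc"].sens
        vpd = res.grids["vpd"].sens
        assert np.nanmax(np.abs(swc - (-0.22))) < 0.05
        assert np.nanmax(np.abs(vpd - (-0.45))) < 0.05
        assert not res.excluded


class TestGrids:
    def test_cell_median_of_single_repeat(self):
        idx = pd.date_range("2015-06-01", periods=3, freq="D")
        labels = pd.DataFrame({"i_swc": [1, 1, 1], "j_vpd": [1, 1, 1]}, index=idx)
        sens = pd.Series([0.1, 0.2, 0.9], index=idx)
        grid = bin_aggregate([sens], labels)
        assert grid.sens[0, 0] == pytest.approx(0.2)
        assert grid.n_days[0, 0] == 3

    def test_median_across_five_repeats(self):
        idx = pd.date_range("2015-06-01", periods=1, freq="D")
        labels = pd.DataFrame({"i_swc": [1], "j_vpd": [1]}, index=idx)
        reps = [pd.Series([v], index=idx) for v in (-0.5, -0.4, -0.45, -0.41, -0.44)]
        grid = bin_aggregate(reps, labels)
        assert grid.sens[0, 0] == pytest.approx(-0.44)

    def test_repeat_order_is_irrelevant(self):
        rng = np.random.default_rng(6)
        idx = pd.date_range("2015-06-01", periods=80, freq="D")
        labels = pd.DataFrame({"i_swc": rng.integers(1, 11, 80),
                               "j_vpd": rng.integers(1, 11, 80)}, index=idx)
        reps = [pd.Series(rng.standard_normal(80), index=idx) for _ in range(5)]
        a = bin_aggregate(reps, labels).sens
        b = bin_aggregate(reps[::-1], labels).sens
        np.testing.assert_array_equal(a, b)

    def test_empty_cells_stay_missing(self):
        idx = pd.date_range("2015-06-01", periods=2, freq="D")
        labels = pd.DataFrame({"i_swc": [1, 2], "j_vpd": [1, 2]}, index=idx)
        grid = bin_aggregate([pd.Series([0.1, 0.2], index=idx)], labels)
        assert np.isnan(grid.sens[4, 4])


def _grid_with(value, n_days=40):
    sens = np.full((10, 10), np.nan)
    nd = np.zeros((10, 10), dtype=int)
    sens[0, 0] = value
    nd[0, 0] = n_days
    return SensitivityGrid(sens=sens, n_days=nd, variable="swc")


class TestCrossSite:
    def test_degenerate_certainty_is_significant(self):
        grids = [_grid_with(-0.3) for _ in range(20)]
        g = cross_site_grid(grids)
        assert g.sens[0, 0] == pytest.approx(-0.3)
        assert g.se[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert g.pval[0, 0] < 1e-10

    def test_single_site_reports_median_without_p(self):
        g = cross_site_grid([_grid_with(-0.3)])
        assert g.sens[0, 0] == pytest.approx(-0.3)
        assert np.isnan(g.pval[0, 0]) and np.isnan(g.se[0, 0])

    def test_two_site_standard_error_hand_value(self):
        g = cross_site_grid([_grid_with(-0.2), _grid_with(-0.4)])
        assert g.se[0, 0] == pytest.approx(0.0707, abs=1e-4)
        assert np.isnan(g.pval[0, 0])  # t-test needs >= 3 sites

    def test_null_sites_reject_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 800
        for _ in range(n_rep):
            grids = [_grid_with(rng.normal(0.0, 0.1)) for _ in range(20)]
            g = cross_site_grid(grids)
            rejections += g.pval[0, 0] < 0.05
        assert 0.030 <= rejections / n_rep <= 0.070


class TestErrorMap:
    def test_grid_against_itself_is_zero(self):
        g = _grid_with(-0.3)
        out = sensitivity_vs_truth(g, g)
        assert out["mae"] == 0.0
        assert out["n_cells"] == 1

    def test_absent_truth_is_contract_error(self):
        with pytest.raises(ContractError):
            sensitivity_vs_truth(_grid_with(-0.3), None)

    def test_sparse_cells_excluded_from_mae(self):
        a = _grid_with(-0.3, n_days=10)
        b = _grid_with(-0.1, n_days=10)
        out = sensitivity_vs_truth(a, b, min_days=30)
        assert np.isnan(out["mae"]) and out["n_cells"] == 0
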