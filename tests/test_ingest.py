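"""CSV dialect round trip, QC masking, daily aggregation, filters, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxdry import synthetic as syn
from fluxdry.core import SiteSeries
from fluxdry.errors import (BinningError, ContractError, DegenerateVariableError,
                            FormatError, SchemaError, UsageError)
from fluxdry.ingest import (aggregate_daytime_daily, assign_bins,
                            filter_growing_season, qc_mask, read_flux_csv,
                            relative_change, summer_relative_changes, zscore)


@pytest.fixture(scope="module")
def written_site(tmp_path_factory, one_year_site):
    path = tmp_path_factory.mktemp("csv") / f"{one_year_site.site_id}.csv"
    syn.write_fluxnet_csv(one_year_site, path)
    return one_year_site, path


class TestReader:
    def test_round_trips_all_finite_values_exactly(self, written_site):
        site, path = written_site
        back = read_flux_csv(path, site_id=site.site_id)
        for col in ("gpp_nt", "le", "vpd", "swc_1", "ta", "rg"):
            a = site.data[col].to_numpy()
            b = back.data[col].to_numpy()
            finite = np.isfinite(a)
            np.testing.assert_array_equal(a[finite], b[finite])
            assert np.isnan(b[~finite]).all()

    def test_sentinel_becomes_missing(self, tmp_path, written_site):
        site, path = written_site
        back = read_flux_csv(path)
        n_na_written = site.data["gpp_nt"].isna().sum()
        assert back.data["gpp_nt"].isna().sum() == n_na_written
        assert not (back.data["gpp_nt"] <= -9990).any()

    def test_missing_swc_layer_is_schema_error(self, tmp_path, written_site):
        site, path = written_site
        raw = pd.read_csv(path).drop(columns=["SWC_F_MDS_1"])
        bad = tmp_path / "bad.csv"
        raw.to_csv(bad, index=False)
        with pytest.raises(SchemaError, match="SWC_F_MDS_1"):
            read_flux_csv(bad, swc_layers=(1,))

    def test_unparseable_timestamp_reports_row(self, tmp_path, written_site):
        _, path = written_site
        raw = pd.read_csv(path)
        raw.loc[5, "TIMESTAMP_START"] = "not-a-time"
        bad = tmp_path / "bad_ts.csv"
        raw.to_csv(bad, index=False)
        with pytest.raises(FormatError, match="row 7"):
            read_flux_csv(bad)

    def test_hourly_file_flagged_not_interpolated(self, tmp_path, written_site):
        site, path = written_site
        raw = pd.read_csv(path).iloc[::2].reset_index(drop=True)
        hourly = tmp_path / "hourly.csv"
        raw.to_csv(hourly, index=False)
        back = read_flux_csv(hourly)
        assert back.is_hourly
        assert len(back.data) == len(raw)


class TestQcMask:
    def _series(self, values, qc):
        idx = pd.date_range("2015-01-01", periods=len(values), freq="30min")
        data = pd.DataFrame({"gpp_nt": values, "qc_nee": qc}, index=idx)
        return SiteSeries(site_id="t", pft="ENF", zm=20.0, data=data)

    def test_flags_above_one_are_rejected(self):
        s = self._series([1.0] * 5, [0, 1, 2, 3, 0])
        assert qc_mask(s, "gpp_nt").tolist() == [True, True, False, False, True]

    def test_all_measured_all_true(self):
        s = self._series([1.0] * 4, [0] * 4)
        assert qc_mask(s, "gpp_nt").all()

    def test_missing_value_dominates_good_flag(self):
        s = self._series([1.0, np.nan], [0, 0])
        assert qc_mask(s, "gpp_nt").tolist() == [True, False]


class TestDailyAggregation:
    def _site(self, gpp, qc=None, n_days=1):
        n = 48 * n_days
        idx = pd.date_range("2015-06-01", periods=n, freq="30min")
        data = pd.DataFrame({
            "gpp_nt": gpp, "ta": 20.0, "vpd": 1.0, "rg": 300.0,
            "swc_1": 25.0, "precip": 0.0,
            "qc_nee": qc if qc is not None else 0,
            "qc_ta": 0, "qc_vpd": 0, "qc_rg": 0, "qc_swc_1": 0,
        }, index=idx)
        return SiteSeries(site_id="t", pft="ENF", zm=20.0, data=data)

    def test_constant_flux_aggregates_to_itself(self):
        daily = aggregate_daytime_daily(self._site(10.0)).data
        assert daily["gpp_nt"].iloc[0] == pytest.approx(10.0)
        assert daily["fraction_valid"].iloc[0] == 1.0

    def test_night_values_excluded_from_daytime_mean(self):
        idx = pd.date_range("2015-06-01", periods=48, freq="30min")
        hours = idx.hour + idx.minute / 60
        gpp = np.where((hours >= 7) & (hours < 19), 10.0, 0.0)
        daily = aggregate_daytime_daily(self._site(gpp)).data
        assert daily["gpp_nt"].iloc[0] == pytest.approx(10.0)

    def test_bad_slots_lower_fraction_valid_but_day_kept(self):
        qc = np.zeros(48, dtype=int)
        qc[14:26] = 2  # 12 of 24 daytime slots bad
        table = aggregate_daytime_daily(self._site(10.0, qc=qc))
        assert table.data["fraction_valid"].iloc[0] == pytest.approx(0.5)
        assert not table.low_coverage.iloc[0]  # threshold is strict <
        assert len(table.data) == 1

    def test_empty_day_yields_missing_record(self):
        qc = np.full(48, 2)
        daily = aggregate_daytime_daily(self._site(10.0, qc=qc)).data
        assert np.isnan(daily["gpp_nt"].iloc[0])


class TestGrowingSeason:
    def _daily(self, rows, start="2015-06-01"):
        idx = pd.date_range(start, periods=len(rows), freq="D")
        return pd.DataFrame(rows, index=idx, columns=["ta", "vpd", "rg"]).assign(gpp_nt=5.0)

    def test_printed_thresholds_keep_exactly_two_of_five(self):
        days = self._daily([(16, 0.6, 300), (14, 0.6, 300), (16, 0.4, 300),
                            (16, 0.6, 200), (20, 1.0, 400)])
        sel = filter_growing_season(days)
        assert sel.n_selected == 2

    def test_all_failing_days_means_ineligible_empty_selection(self):
        days = self._daily([(10, 0.1, 100)] * 5)
        sel = filter_growing_season(days)
        assert sel.n_selected == 0 and not sel.eligible

    def test_unknown_mode_is_usage_error(self):
        with pytest.raises(UsageError):
            filter_growing_season(self._daily([(20, 1, 300)]), mode="bogus")

    def test_constant_gpp_peak_window_breaks_tie_to_january(self):
        idx = pd.date_range("2015-01-01", "2016-12-31", freq="D")
        days = pd.DataFrame({"ta": 20.0, "vpd": 1.0, "rg": 300.0, "gpp_nt": 5.0},
                            index=idx)
        sel = filter_growing_season(days, mode="peak3mo")
        assert set(sel.days.index.month.unique()) == {1, 2, 3}

    def test_deseason_removes_the_seasonal_cycle(self):
        idx = pd.date_range("2014-01-01", "2016-12-31", freq="D")
        doy = idx.dayofyear.to_numpy().astype(float)
        seasonal = 10 + 5 * np.cos(2 * np.pi * (doy - 200) / 365)
        days = pd.DataFrame({"ta": 20.0, "vpd": 1.0, "rg": 300.0,
                             "gpp_nt": seasonal}, index=idx)
        sel = filter_growing_season(days, mode="deseason")
        assert np.abs(sel.days["gpp_nt"]).max() < 0.5


class TestZscore:
    def test_symmetric_triple(self):
        days = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, params = zscore(days, ["x"])
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0])
        assert params.sds["x"] == pytest.approx(1.0)

    def test_inverse_transform_recovers_originals(self):
        rng = np.random.default_rng(0)
        days = pd.DataFrame({"x": rng.normal(5, 3, 50), "y": rng.uniform(0, 9, 50)})
        z, params = zscore(days, ["x", "y"])
        back = params.inverse(z)
        np.testing.assert_allclose(back["x"], days["x"], atol=1e-12)
        np.testing.assert_allclose(back["y"], days["y"], atol=1e-12)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateVariableError, match="x"):
            zscore(pd.DataFrame({"x": [2.0] * 5}), ["x"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40, unique=True))
    def test_standardized_output_has_zero_mean_unit_sd(self, values):
        z, _ = zscore(pd.DataFrame({"x": values}), ["x"])
        assert abs(z["x"].mean()) < 1e-9
        assert abs(z["x"].std(ddof=1) - 1.0) < 1e-9


class TestRelativeChange:
    @pytest.mark.parametrize("x_year,x_ref,expect", [
        (75.0, 100.0, -25.0), (100.0, 100.0, 0.0), (122.0, 100.0, 22.0),
    ])
    def test_arithmetic(self, x_year, x_ref, expect):
        assert relative_change(x_year, x_ref) == pytest.approx(expect)

    def test_zero_reference_rejected(self):
        with pytest.raises(ContractError):
            relative_change(1.0, 0.0)

    def test_summer_table_is_zero_mean_by_construction(self):
        idx = pd.date_range("2014-01-01", "2018-12-31", freq="D")
        rng = np.random.default_rng(2)
        daily = pd.DataFrame({"gpp_nt": rng.uniform(2, 12, len(idx)),
                              "swc": rng.uniform(10, 40, len(idx)),
                              "vpd": rng.uniform(0.2, 3, len(idx))}, index=idx)
        table = summer_relative_changes(daily)
        assert table.shape == (5, 3)
        assert abs(table.mean().mean()) < 5.0  # each year's change is vs pooled mean


class TestBinning:
    def test_uniform_values_fill_deciles_evenly(self):
        days = pd.DataFrame({"swc": np.arange(100, dtype=float),
                             "vpd": np.arange(100, dtype=float)})
        _, labels = assign_bins(days)
        counts = labels.groupby("i_swc").size()
        assert (counts == 10).all()

    def test_value_on_first_edge_falls_in_second_bin(self):
        days = pd.DataFrame({"swc": np.arange(101, dtype=float),
                             "vpd": np.arange(101, dtype=float)})
        grid, labels = assign_bins(days)
        assert grid.swc_edges[0] == pytest.approx(10.0)
        assert labels.loc[days.index[days["swc"] == 10.0], "i_swc"].iloc[0] == 2

    def test_labels_partition_the_day_set(self):
        rng = np.random.default_rng(3)
        days = pd.DataFrame({"swc": rng.uniform(0, 1, 500),
                             "vpd": rng.uniform(0, 1, 500)})
        _, labels = assign_bins(days)
        assert labels["i_swc"].between(1, 10).all()
        assert labels["j_vpd"].between(1, 10).all()
        assert len(labels) == 500

    def test_independent_uniform_cells_hold_binomial_counts(self):
        rng = np.random.default_rng(4)
        days = pd.DataFrame({"swc": rng.uniform(0, 1, 10000),
                             "vpd": rng.uniform(0, 1, 10000)})
        _, labels = assign_bins(days)
        counts = labels.groupby(["i_swc", "j_vpd"]).size()
        assert len(counts) == 100
        assert counts.between(60, 140).all()

    def test_too_few_days_is_binning_error(self):
        days = pd.DataFrame({"swc": [1.0] * 5, "vpd": [1.0] * 5})
        with pytest.raises(BinningError):
            assign_bins(days)
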