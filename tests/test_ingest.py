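import numpy as np
import pandas as pd
import pytest

from heatresp import (
    FluxSeries,
    align,
    read_flux_csv,
    read_hourly_temperature_csv,
    resample_to_hourly,
)


def write_csv(path, rows, header="timestamp,flux_umol_m2_s"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadFlux:
    def test_reads_valid_rows(self, tmp_path):
        p = write_csv(
            tmp_path / "f.csv",
            ["2016-02-01T00:00,1.0", "2016-02-01T00:12,1.1", "2016-02-01T00:24,0.9"],
        )
        series = read_flux_csv(p)
        assert len(series) == 3
        assert series.report.n_dropped == 0

    def test_drops_and_counts_bad_value(self, tmp_path):
        p = write_csv(
            tmp_path / "f.csv",
            ["2016-02-01T00:00,1.0", "2016-02-01T01:00,oops", "2016-02-01T02:00,0.9"],
        )
        series = read_flux_csv(p)
        assert len(series) == 2
        assert series.report.n_dropped == 1

    def test_empty_file_errors(self, tmp_path):
        p = (tmp_path / "empty.csv")
        p.write_text("timestamp,flux_umol_m2_s\n")
        with pytest.raises(ValueError, match="no parseable rows"):
            read_flux_csv(p)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_flux_csv(tmp_path / "absent.csv")

    def test_duplicate_timestamp_errors(self, tmp_path):
        p = write_csv(tmp_path / "f.csv", ["2016-02-01T00:00,1.0", "2016-02-01T00:00,1.1"])
        with pytest.raises(ValueError, match="duplicate"):
            read_flux_csv(p)

    def test_many_negative_fluxes_warn(self):
        idx = pd.date_range("2016-02-01", periods=10, freq="h")
        rs = np.r_[np.full(9, 1.0), -0.5]
        with pytest.warns(UserWarning, match="negative"):
            FluxSeries(data=pd.DataFrame({"rs": rs}, index=idx))


class TestReadTemperature:
    def test_one_day(self, tmp_path):
        rows = [f"2016-02-01T{h:02d}:00,{10 + h * 0.1}" for h in range(24)]
        p = write_csv(tmp_path / "t.csv", rows, header="timestamp,tair_c")
        assert len(read_hourly_temperature_csv(p)) == 24

    def test_duplicated_hour_keeps_first_with_warning(self, tmp_path):
        rows = [f"2016-02-01T{h:02d}:00,10" for h in range(24)]
        rows.insert(6, "2016-02-01T05:30,11")  # second record in hour 5
        p = write_csv(tmp_path / "t.csv", rows, header="timestamp,tair_c")
        with pytest.warns(UserWarning, match="duplicated hour"):
            series = read_hourly_temperature_csv(p)
        assert len(series) == 24
        assert series.data.loc["2016-02-01 05:00", "tair"] == 10

    def test_sentinel_treated_as_missing(self, tmp_path):
        rows = ["2016-02-01T00:00,10", "2016-02-01T01:00,999.9", "2016-02-01T02:00,12"]
        p = write_csv(tmp_path / "t.csv", rows, header="timestamp,tair_c")
        series = read_hourly_temperature_csv(p, missing_sentinel=999.9)
        assert len(series) == 2
        assert series.report.n_dropped == 1


class TestResample:
    def test_mean_of_constants(self):
        idx = pd.date_range("2016-02-01 00:00", periods=5, freq="12min")
        hourly = resample_to_hourly(FluxSeries(pd.DataFrame({"rs": np.ones(5)}, index=idx)))
        assert len(hourly) == 1
        assert hourly.data["rs"].iloc[0] == 1.0
        assert hourly.data["n_obs"].iloc[0] == 5

    def test_arithmetic_mean(self):
        idx = pd.date_range("2016-02-01 00:00", periods=3, freq="20min")
        hourly = resample_to_hourly(
            FluxSeries(pd.DataFrame({"rs": [0.8, 1.0, 1.2]}, index=idx))
        )
        assert hourly.data["rs"].iloc[0] == pytest.approx(1.0)

    def test_empty_hour_absent(self):
        stamps = pd.to_datetime(["2016-02-01 00:10", "2016-02-01 02:10"])
        hourly = resample_to_hourly(FluxSeries(pd.DataFrame({"rs": [1.0, 2.0]}, index=stamps)))
        assert list(hourly.data.index.hour) == [0, 2]

    def test_idempotent_on_hourly(self):
        idx = pd.date_range("2016-02-01", periods=48, freq="h")
        rs = np.random.default_rng(0).normal(1, 0.1, 48)
        once = resample_to_hourly(FluxSeries(pd.DataFrame({"rs": rs}, index=idx)))
        twice = resample_to_hourly(once)
        pd.testing.assert_series_equal(once.data["rs"], twice.data["rs"])

    def test_grand_mean_preserved_under_equal_counts(self):
        idx = pd.date_range("2016-02-01", periods=4 * 12, freq="5min")
        rs = np.random.default_rng(1).normal(1, 0.3, len(idx))
        hourly = resample_to_hourly(FluxSeries(pd.DataFrame({"rs": rs}, index=idx)))
        assert hourly.data["rs"].mean() == pytest.approx(rs.mean())


class TestAlign:
    def _flux(self, hours, values=None):
        idx = pd.DatetimeIndex([pd.Timestamp(f"2016-02-01 {h:02d}:00") for h in hours])
        values = np.ones(len(hours)) if values is None else values
        return FluxSeries(pd.DataFrame({"rs": values}, index=idx))

    def _temp(self, hours):
        from heatresp import TemperatureSeries

        idx = pd.DatetimeIndex([pd.Timestamp(f"2016-02-01 {h:02d}:00") for h in hours])
        return TemperatureSeries(pd.DataFrame({"tair": np.full(len(hours), 15.0)}, index=idx))

    def _sm(self, hours):
        from heatresp import MoistureSeries

        idx = pd.DatetimeIndex([pd.Timestamp(f"2016-02-01 {h:02d}:00") for h in hours])
        return MoistureSeries(pd.DataFrame({"sm": np.full(len(hours), 0.25)}, index=idx))

    def test_inner_join_on_clock_hour(self):
        ds = align(self._flux([1, 2, 3]), self._temp([2, 3, 4]))
        assert list(ds.data.index.hour) == [2, 3]

    def test_partial_moisture_is_unknown(self):
        ds = align(self._flux([2, 3]), self._temp([2, 3]), self._sm([2]))
        assert np.isfinite(ds.data["sm"].iloc[0])
        assert np.isnan(ds.data["sm"].iloc[1])

    def test_disjoint_hours_error(self):
        with pytest.raises(ValueError, match="no overlapping hours"):
            align(self._flux([1, 2]), self._temp([5, 6]))

    def test_row_order_in_source_file_is_irrelevant(self, tmp_path):
        rows = [f"2016-02-01T{h:02d}:00,{1 + 0.1 * h}" for h in range(6)]
        shuffled = [rows[i] for i in [3, 0, 5, 1, 4, 2]]
        a = read_flux_csv(write_csv(tmp_path / "a.csv", rows))
        b = read_flux_csv(write_csv(tmp_path / "b.csv", shuffled))
        temp = self._temp(range(6))
        pd.testing.assert_frame_equal(align(a, temp).data, align(b, temp).data)
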