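"""Reading, resampling and temporal alignment of flux / weather series.

All timestamps are interpreted as local standard time (fixed UTC offset per
site, no daylight-saving transitions), because the downstream climatology is
keyed by local clock hour. Gaps are dropped, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FluxSeries",
    "TemperatureSeries",
    "MoistureSeries",
    "AlignedDataset",
    "ReadReport",
    "read_flux_csv",
    "read_hourly_temperature_csv",
    "read_moisture_csv",
    "resample_to_hourly",
    "align",
]


@dataclass
class ReadReport:
    """Row accounting for a CSV read: rows seen, kept, and dropped (with why)."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)

    def add(self, reason: str, count: int) -> None:
        if count:
            self.reasons[reason] = self.reasons.get(reason, 0) + count
            self.n_dropped += count


@dataclass
class FluxSeries:
    """Soil CO2 efflux record (μmol CO2 m-2 s-1), sub-hourly or hourly.

    ``data`` is indexed by timestamp (strictly increasing) with column ``rs``
    and, after hourly resampling, ``n_obs`` (observations contributing to each
    hourly mean). Negative fluxes are retained (instrument noise around zero)
    but trigger a warning if they exceed 5% of records.
    """

    data: pd.DataFrame
    report: ReadReport | None = None

    def __post_init__(self) -> None:
        _check_increasing(self.data.index, "flux")
        rs = self.data["rs"].to_numpy()
        if not np.all(np.isfinite(rs)):
            raise ValueError("flux series contains non-finite rs values")
        n_neg = int((rs < 0).sum())
        if len(rs) and n_neg / len(rs) >= 0.05:
            warnings.warn(
                f"{n_neg}/{len(rs)} flux values are negative (>=5% of records)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TemperatureSeries:
    """Hourly air temperature (°C); at most one record per clock hour."""

    data: pd.DataFrame  # column 'tair'
    report: ReadReport | None = None

    def __post_init__(self) -> None:
        _check_increasing(self.data.index, "temperature")
        t = self.data["tair"].to_numpy()
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature series contains non-finite values")
        if len(t) and (t.min() < -60 or t.max() > 60):
            raise ValueError("temperature outside plausible range [-60, 60] °C")
        hours = self.data.index.floor("h")
        if hours.has_duplicates:
            dup = hours[hours.duplicated()][0]
            raise ValueError(f"more than one temperature record in hour {dup}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MoistureSeries:
    """Hourly volumetric soil water content (m3/m3), values in [0, 1]."""

    data: pd.DataFrame  # column 'sm'
    report: ReadReport | None = None

    def __post_init__(self) -> None:
        _check_increasing(self.data.index, "moisture")
        sm = self.data["sm"].to_numpy()
        if not np.all(np.isfinite(sm)):
            raise ValueError("moisture series contains non-finite values")
        if len(sm) and (sm.min() < 0 or sm.max() > 1):
            raise ValueError("volumetric water content outside [0, 1]")
        hours = self.data.index.floor("h")
        if hours.has_duplicates:
            dup = hours[hours.duplicated()][0]
            raise ValueError(f"more than one moisture record in hour {dup}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AlignedDataset:
    """Hourly joined record of rs, air temperature and (optionally) SM.

    Every row has non-missing ``rs`` and ``tair`` (strict inner join on clock
    hour); ``sm`` is NaN where no moisture observation exists. The unit of all
    downstream analysis.
    """

    data: pd.DataFrame  # columns rs, tair, sm
    site: str = ""

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)


def _check_increasing(index: pd.Index, what: str) -> None:
    if len(index) > 1 and not index.is_monotonic_increasing:
        raise ValueError(f"{what} timestamps are not increasing")
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} timestamp {dup}")


def _read_csv_column(
    path: str | Path,
    value_column: str,
    out_name: str,
    timestamp_column: str = "timestamp",
    missing_sentinel: float | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Shared CSV reader: parse timestamps and one numeric column, dropping
    and counting unparseable rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    report = ReadReport(n_read=len(raw))
    for col in (timestamp_column, value_column):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    ts = pd.to_datetime(raw[timestamp_column], errors="coerce")
    val = pd.to_numeric(raw[value_column], errors="coerce")
    if missing_sentinel is not None:
        val = val.mask(val == missing_sentinel)
    bad_ts = ts.isna()
    bad_val = val.isna() & ~bad_ts
    report.add("unparseable timestamp", int(bad_ts.sum()))
    report.add("missing or non-numeric value", int(bad_val.sum()))
    keep = ~(bad_ts | bad_val)
    out = pd.DataFrame({out_name: val[keep].to_numpy()}, index=pd.DatetimeIndex(ts[keep], name="timestamp"))
    if out.empty:
        raise ValueError(f"no parseable rows in {path.name}")
    out = out.sort_index(kind="stable")
    report.n_kept = len(out)
    return out, report


def read_flux_csv(
    path: str | Path,
    timestamp_column: str = "timestamp",
    flux_column: str = "flux_umol_m2_s",
) -> FluxSeries:
    """Read a COSORE-style flux table into a :class:`FluxSeries`.

    Unparseable rows are dropped and counted in ``series.report``; duplicate
    timestamps raise.
    """
    data, report = _read_csv_column(path, flux_column, "rs", timestamp_column)
    return FluxSeries(data=data, report=report)


def read_hourly_temperature_csv(
    path: str | Path,
    timestamp_column: str = "timestamp",
    temperature_column: str = "tair_c",
    missing_sentinel: float | None = None,
) -> TemperatureSeries:
    """Read an hourly station-temperature table (NOAA-hourly-style dialect).

    ``missing_sentinel`` (e.g. 999.9) marks values treated as missing. If a
    clock hour carries more than one record the first is kept with a warning.
    """
    data, report = _read_csv_column(
        path, temperature_column, "tair", timestamp_column, missing_sentinel
    )
    hours = data.index.floor("h")
    dup = hours.duplicated()
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicated hour(s) in {Path(path).name}; keeping first",
            stacklevel=2,
        )
        report.add("duplicated hour", int(dup.sum()))
        data = data[~dup]
        report.n_kept = len(data)
    return TemperatureSeries(data=data, report=report)


def read_moisture_csv(
    path: str | Path,
    timestamp_column: str = "timestamp",
    moisture_column: str = "sm_m3_m3",
) -> MoistureSeries:
    """Read hourly volumetric soil moisture; same dialect as the flux table
    (the SM column may live in the flux CSV itself)."""
    data, report = _read_csv_column(path, moisture_column, "sm", timestamp_column)
    hours = data.index.floor("h")
    dup = hours.duplicated()
    if dup.any():
        warnings.warn("duplicated moisture hour(s); keeping first", stacklevel=2)
        report.add("duplicated hour", int(dup.sum()))
        data = data[~dup]
        report.n_kept = len(data)
    return MoistureSeries(data=data, report=report)


def resample_to_hourly(flux: FluxSeries) -> FluxSeries:
    """Average sub-hourly flux into an hourly series.

    Each output record is the arithmetic mean of all observations whose
    timestamp falls in the half-open hour-beginning window [H:00, H+1:00);
    hours with no observations are absent from the output. The per-hour
    contributing count is kept in column ``n_obs``.
    """
    if flux.data.empty:
        return FluxSeries(data=flux.data.copy(), report=flux.report)
    grouped = flux.data["rs"].groupby(flux.data.index.floor("h"))
    out = pd.DataFrame({"rs": grouped.mean(), "n_obs": grouped.size()})
    out.index.name = "timestamp"
    return FluxSeries(data=out, report=flux.report)


def align(
    flux: FluxSeries,
    temp: TemperatureSeries,
    sm: MoistureSeries | None = None,
    site: str = "",
) -> AlignedDataset:
    """Strict inner join of hourly flux and temperature on clock hour.

    Soil moisture is attached where available; hours without an SM record get
    NaN (labelled ``unknown`` downstream). The join is exact — no
    nearest-neighbour tolerance — and order-independent.
    """
    f = flux.data.copy()
    f.index = f.index.floor("h")
    if f.index.has_duplicates:
        raise ValueError("flux series is not hourly; resample_to_hourly first")
    t = temp.data.copy()
    t.index = t.index.floor("h")
    joined = f[["rs"]].join(t[["tair"]], how="inner")
    if joined.empty:
        raise ValueError("no overlapping hours between flux and temperature")
    if sm is not None:
        m = sm.data.copy()
        m.index = m.index.floor("h")
        joined = joined.join(m[["sm"]], how="left")
    else:
        joined["sm"] = np.nan
    return AlignedDataset(data=joined.sort_index(kind="stable"), site=site)
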