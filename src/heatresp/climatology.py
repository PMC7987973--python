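"""Hour-of-month percentile climatology and per-hour heatwave classification.

A heatwave hour is an hour whose air temperature strictly exceeds the q-th
percentile (default 0.85) of the long-term record pooled over all years for
that (month, hour-of-day) cell — 24 thresholds per month, at most 288 cells.
Classification is per-hour exceedance; an optional minimum run length is
available for sensitivity analyses but defaults to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import AlignedDataset, TemperatureSeries

__all__ = [
    "ClimatologyThresholds",
    "HeatLabels",
    "fit_climatology",
    "classify_heat",
    "heatwave_fraction",
]

HOURS_PER_YEAR = 8766  # Julian year


@dataclass
class ClimatologyThresholds:
    """(month, hour-of-day) -> threshold °C table with per-cell sample sizes.

    ``table`` is indexed by a (month, hour) MultiIndex with columns
    ``threshold_c`` and ``n``; cells failing the minimum-sample rule are
    absent (never defaulted). Quantiles use the linear-interpolation
    order-statistic estimator at position (n-1)q.
    """

    table: pd.DataFrame
    q: float
    years: float
    min_samples: int
    unpopulated: list = field(default_factory=list)

    def lookup(self, month: np.ndarray, hour: np.ndarray) -> np.ndarray:
        """Vectorised threshold lookup; NaN where the cell is unpopulated."""
        full = self.table["threshold_c"].reindex(
            pd.MultiIndex.from_product([range(1, 13), range(24)], names=["month", "hour"])
        )
        flat = full.to_numpy().reshape(12, 24)
        return flat[np.asarray(month) - 1, np.asarray(hour)]

    def to_csv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, q: float, years: float = np.nan, min_samples: int = 0):
        table = pd.read_csv(path).set_index(["month", "hour"])
        return cls(table=table, q=q, years=years, min_samples=min_samples)


@dataclass
class HeatLabels:
    """Per-hour heat state, 'HW' or 'NHW', for hours with a populated
    threshold cell; hours without one are excluded (``n_excluded``)."""

    labels: pd.Series  # values in {'HW', 'NHW'}, index = analysis timestamps
    thresholds: ClimatologyThresholds
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.labels)


def fit_climatology(
    temp: TemperatureSeries,
    q: float = 0.85,
    min_years: float = 30.0,
    min_samples: int = 30,
    enforce_min_years: bool = True,
) -> ClimatologyThresholds:
    """Fit (month, hour) percentile thresholds from a long hourly record.

    Observations are pooled across years per cell; Feb 29 hours pool into
    February. Cells with fewer than ``min_samples`` observations are left
    unpopulated and reported. A record spanning fewer than ``min_years``
    years raises unless ``enforce_min_years=False`` (intended for small
    fixtures).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("percentile level q must be in (0, 1)")
    idx = temp.data.index
    span_years = len(idx) / HOURS_PER_YEAR
    if enforce_min_years and span_years < min_years:
        raise ValueError(
            f"temperature record spans {span_years:.1f} years; "
            f"{min_years:g} required (pass enforce_min_years=False to override)"
        )
    df = pd.DataFrame(
        {"tair": temp.data["tair"].to_numpy(), "month": idx.month, "hour": idx.hour}
    )
    grouped = df.groupby(["month", "hour"])["tair"]
    table = pd.DataFrame(
        {"threshold_c": grouped.quantile(q, interpolation="linear"), "n": grouped.size()}
    )
    small = table["n"] < min_samples
    unpopulated = [tuple(c) for c in table.index[small]]
    table = table[~small]
    return ClimatologyThresholds(
        table=table, q=q, years=span_years, min_samples=min_samples, unpopulated=unpopulated
    )


def classify_heat(
    ds: AlignedDataset,
    thr: ClimatologyThresholds,
    min_run_hours: int = 1,
) -> HeatLabels:
    """Label each analysis hour 'HW' (temperature strictly above the cell
    threshold) or 'NHW'. Hours whose (month, hour) cell is unpopulated are
    excluded and counted, not defaulted.

    ``min_run_hours`` > 1 additionally demotes exceedance runs shorter than
    that many consecutive hours to 'NHW' (sensitivity analyses only).
    """
    idx = ds.data.index
    cell_thr = thr.lookup(idx.month.to_numpy(), idx.hour.to_numpy())
    known = np.isfinite(cell_thr)
    hot = ds.data["tair"].to_numpy() > cell_thr  # strict: ties are NHW
    if min_run_hours > 1:
        hot = _enforce_min_run(hot, idx, min_run_hours)
    labels = pd.Series(np.where(hot[known], "HW", "NHW"), index=idx[known])
    n_excluded = int((~known).sum())
    if labels.empty:
        warnings.warn("no hours could be classified (all threshold cells missing)", stacklevel=2)
    return HeatLabels(labels=labels, thresholds=thr, n_excluded=n_excluded)


def _enforce_min_run(hot: np.ndarray, idx: pd.DatetimeIndex, min_run: int) -> np.ndarray:
    """Demote exceedance runs of consecutive clock hours shorter than min_run."""
    hot = hot.copy()
    contiguous = np.ones(len(idx), dtype=bool)
    contiguous[1:] = np.diff(idx.asi8) == 3_600_000_000_000
    # simple scan: runs broken by time gaps or cold hours
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1] and contiguous[j + 1]:
                j += 1
            if j - i + 1 < min_run:
                hot[i : j + 1] = False
            i = j + 1
        else:
            i += 1
    return hot


def heatwave_fraction(labels: HeatLabels) -> float:
    """Share of labelled hours that are heatwave hours, in [0, 1]."""
    if len(labels) == 0:
        raise ValueError("no labelled hours")
    return float((labels.labels == "HW").mean())
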