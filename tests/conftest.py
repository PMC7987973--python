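import numpy as np
import pandas as pd
import pytest

from heatresp import (
    AlignedDataset,
    ClimatologyThresholds,
    HeatLabels,
    SynthConfig,
    generate_temperature,
)


def make_dataset(rs, tair=None, sm=None, start="2016-02-01", site="fixture"):
    """Aligned hourly dataset from plain arrays (NaN sm = unknown)."""
    rs = np.asarray(rs, dtype=float)
    n = len(rs)
    index = pd.date_range(start, periods=n, freq="h", name="timestamp")
    tair = np.full(n, 20.0) if tair is None else np.asarray(tair, dtype=float)
    sm = np.full(n, np.nan) if sm is None else np.asarray(sm, dtype=float)
    return AlignedDataset(
        data=pd.DataFrame({"rs": rs, "tair": tair, "sm": sm}, index=index), site=site
    )


def make_heat_labels(ds, hot_mask):
    """HeatLabels straight from a boolean mask (bypasses climatology)."""
    dummy = ClimatologyThresholds(
        table=pd.DataFrame(
            columns=["threshold_c", "n"],
            index=pd.MultiIndex.from_tuples([], names=["month", "hour"]),
        ),
        q=0.85,
        years=0.0,
        min_samples=0,
    )
    labels = pd.Series(
        np.where(np.asarray(hot_mask, dtype=bool), "HW", "NHW"), index=ds.data.index
    )
    return HeatLabels(labels=labels, thresholds=dummy)


def interpolated_quantile(values, q):
    """Independent order-statistic oracle: sort, linear interpolation at
    zero-based position (n-1)q."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (len(v) - 1) * q
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


@pytest.fixture(scope="session")
def station_record():
    """30-year synthetic hourly station temperature record."""
    cfg = SynthConfig(seed=7, climatology_years=30, study_hours=0)
    return generate_temperature(cfg)


@pytest.fixture
def default_cfg():
    return SynthConfig(seed=3)
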