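"""Soil-moisture regime classification from site-specific quantiles.

Hours below the 30th quantile of the site's volumetric water content are
'dry', hours above the 70th quantile are 'wet'; the band in between is
'neutral' and is excluded from dry/wet conditional analyses rather than
merged into either tail. Missing SM gives 'unknown'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import AlignedDataset, MoistureSeries

__all__ = ["MoistureThresholds", "MoistureLabels", "fit_sm_thresholds", "classify_moisture"]

MIN_SM_SAMPLES = 50  # mirrors the minimum subsample size of the density analyses


@dataclass
class MoistureThresholds:
    dry: float  # m3/m3, q_dry quantile
    wet: float  # m3/m3, q_wet quantile
    n: int
    q_dry: float = 0.30
    q_wet: float = 0.70


@dataclass
class MoistureLabels:
    """Per-hour regime in {'dry', 'wet', 'neutral', 'unknown'}."""

    labels: pd.Series
    thresholds: MoistureThresholds

    def __len__(self) -> int:
        return len(self.labels)


def fit_sm_thresholds(
    sm: MoistureSeries | pd.Series | np.ndarray,
    q_dry: float = 0.30,
    q_wet: float = 0.70,
) -> MoistureThresholds:
    """Quantile thresholds of the soil-moisture record (linear-interpolation
    order-statistic estimator, matching the temperature climatology).

    Accepts a MoistureSeries or the aligned study-period SM column; requires
    at least 50 non-missing values.
    """
    if not 0.0 < q_dry < q_wet < 1.0:
        raise ValueError("need 0 < q_dry < q_wet < 1")
    if isinstance(sm, MoistureSeries):
        values = sm.data["sm"].to_numpy()
    else:
        values = np.asarray(sm, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < MIN_SM_SAMPLES:
        raise ValueError(
            f"only {len(values)} non-missing SM values; {MIN_SM_SAMPLES} required"
        )
    dry, wet = np.quantile(values, [q_dry, q_wet], method="linear")
    return MoistureThresholds(dry=float(dry), wet=float(wet), n=len(values), q_dry=q_dry, q_wet=q_wet)


def classify_moisture(ds: AlignedDataset, thr: MoistureThresholds) -> MoistureLabels:
    """Label each aligned hour dry / wet / neutral / unknown.

    Strict inequalities on both sides: an hour exactly at either threshold is
    neutral, matching the strict exceedance convention used for heat.
    """
    sm = ds.data["sm"].to_numpy()
    labels = np.full(len(sm), "neutral", dtype=object)
    labels[sm < thr.dry] = "dry"
    labels[sm > thr.wet] = "wet"
    labels[~np.isfinite(sm)] = "unknown"
    return MoistureLabels(labels=pd.Series(labels, index=ds.data.index), thresholds=thr)
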