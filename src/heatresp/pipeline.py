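"""End-to-end per-site analysis: labels, threshold, exceedance table.

Glue over the analysis modules: classify heat and moisture states on an
aligned dataset, take the site-mean Rs as the exceedance threshold, and
compute P_ex for the pooled record and all six heat x moisture conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climatology import ClimatologyThresholds, HeatLabels, classify_heat, heatwave_fraction
from .ingest import AlignedDataset
from .moisture import MIN_SM_SAMPLES, MoistureLabels, classify_moisture, fit_sm_thresholds
from .probability import (
    CONDITIONS,
    ExceedanceResult,
    exceedance_probability,
    select_condition,
    site_mean_threshold,
)
from .synthesis import SiteResult, summarize_site

__all__ = ["SiteAnalysis", "analyze_site"]


@dataclass
class SiteAnalysis:
    """Everything computed for one site, ready for multi-site aggregation."""

    result: SiteResult
    exceedance: dict[str, ExceedanceResult]
    heat: HeatLabels
    moisture: MoistureLabels | None
    r_star: float


def analyze_site(
    ds: AlignedDataset,
    thresholds: ClimatologyThresholds,
    q_dry: float = 0.30,
    q_wet: float = 0.70,
    r_star: float | None = None,
) -> SiteAnalysis:
    """Run the full conditional-exceedance analysis on one aligned dataset.

    Moisture thresholds are fitted on the study-period SM column when at
    least 50 hours carry moisture; otherwise only the heat-only conditions
    are evaluated. ``r_star`` defaults to the site-mean Rs.
    """
    heat = classify_heat(ds, thresholds)
    if r_star is None:
        r_star = site_mean_threshold(ds)

    moisture = None
    sm = ds.data["sm"].to_numpy()
    if np.isfinite(sm).sum() >= MIN_SM_SAMPLES:
        moisture = classify_moisture(ds, fit_sm_thresholds(sm, q_dry=q_dry, q_wet=q_wet))

    conditions = CONDITIONS if moisture is not None else ("HW", "NHW")
    exceedance = {
        cond: exceedance_probability(ds, heat, cond, r_star, moisture)
        for cond in conditions
    }

    hw_rs = select_condition(ds, heat, "HW")
    nhw_rs = select_condition(ds, heat, "NHW")
    result = summarize_site(
        site=ds.site,
        results=exceedance,
        heat_fraction=heatwave_fraction(heat),
        mean_rs=r_star,
        rs_mean_hw=float(np.mean(hw_rs)) if len(hw_rs) else None,
        rs_mean_nhw=float(np.mean(nhw_rs)) if len(nhw_rs) else None,
    )
    return SiteAnalysis(
        result=result, exceedance=exceedance, heat=heat, moisture=moisture, r_star=r_star
    )
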