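"""Multi-site synthesis: per-site exceedance tables, cross-site means,
relative changes, wet/dry contrast, and an annualised excess-flux estimate.

Cross-site means are unweighted over the sites where a condition passed the
minimum-sample rule; two studies at one location count as separate entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probability import CONDITIONS, ExceedanceResult

__all__ = [
    "SiteResult",
    "MultiSiteSummary",
    "summarize_site",
    "aggregate_sites",
    "annualized_excess_flux",
    "SECONDS_PER_YEAR",
    "CO2_G_PER_UMOL",
]

SECONDS_PER_YEAR = 31_557_600.0  # Julian year
CO2_G_PER_UMOL = 44.01e-6  # g CO2 per μmol


@dataclass
class SiteResult:
    """One site's exceedance probabilities and summary quantities.

    ``pex`` maps condition -> P_ex in [0, 1] for conditions that passed the
    minimum-sample rule; ``excluded`` lists conditions that did not.
    """

    site: str
    pex: dict[str, float]
    mean_rs: float
    heat_fraction: float
    excluded: list[str] = field(default_factory=list)
    rs_mean_hw: float | None = None
    rs_mean_nhw: float | None = None


@dataclass
class MultiSiteSummary:
    """Cross-site synthesis of exceedance probabilities.

    ``mean_pex`` holds the unweighted per-condition mean over populated
    sites; ``n_sites`` the contributing site count per condition.
    ``relative_change_pct`` is 100*(mean_HW - mean_NHW)/mean_NHW rounded to
    the nearest whole percent. The wet-vs-dry contrast is reported both as a
    ratio of cross-site means and as a mean of per-site ratios (how such a
    factor is formed is ambiguous; both are given).
    """

    mean_pex: dict[str, float]
    n_sites: dict[str, int]
    relative_change_pct: float | None
    wet_dry_ratio_of_means: float | None
    wet_dry_mean_of_ratios: float | None
    annualized_excess_g: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_pex": pd.Series(self.mean_pex), "n_sites": pd.Series(self.n_sites)}
        )


def summarize_site(
    site: str,
    results: dict[str, ExceedanceResult],
    heat_fraction: float,
    mean_rs: float,
    rs_mean_hw: float | None = None,
    rs_mean_nhw: float | None = None,
) -> SiteResult:
    """Assemble one site's record from its per-condition exceedance results.

    Conditions flagged insufficient are listed in ``excluded``; at least one
    of HW / NHW must be populated.
    """
    pex: dict[str, float] = {}
    excluded: list[str] = []
    for cond, res in results.items():
        if res.sufficient:
            pex[cond] = res.pex_empirical
        else:
            excluded.append(cond)
    if "HW" not in pex and "NHW" not in pex:
        raise ValueError(f"site {site!r}: neither HW nor NHW condition has enough data")
    return SiteResult(
        site=site,
        pex=pex,
        mean_rs=mean_rs,
        heat_fraction=heat_fraction,
        excluded=excluded,
        rs_mean_hw=rs_mean_hw,
        rs_mean_nhw=rs_mean_nhw,
    )


def aggregate_sites(sites: list[SiteResult]) -> MultiSiteSummary:
    """Unweighted cross-site mean P_ex per condition, the HW-vs-NHW relative
    change, and wet-vs-dry contrast factors.

    Each condition's mean is over the sites where it is populated; the
    contributing site count is reported alongside.
    """
    if not sites:
        raise ValueError("no site results")
    mean_pex: dict[str, float] = {}
    n_sites: dict[str, int] = {}
    for cond in CONDITIONS:
        values = [s.pex[cond] for s in sites if cond in s.pex]
        if values:
            mean_pex[cond] = float(np.mean(values))
            n_sites[cond] = len(values)
    rel = None
    if "HW" in mean_pex and "NHW" in mean_pex and mean_pex["NHW"] > 0:
        rel = relative_change_pct(mean_pex["NHW"], mean_pex["HW"])
    ratio_of_means = None
    wet = [mean_pex[c] for c in ("wHW", "wNHW") if c in mean_pex]
    dry = [mean_pex[c] for c in ("dHW", "dNHW") if c in mean_pex]
    if wet and dry and np.mean(dry) > 0:
        ratio_of_means = float(np.mean(wet) / np.mean(dry))
    per_site_ratios = []
    for s in sites:
        w = [s.pex[c] for c in ("wHW", "wNHW") if c in s.pex]
        d = [s.pex[c] for c in ("dHW", "dNHW") if c in s.pex]
        if w and d and np.mean(d) > 0:
            per_site_ratios.append(np.mean(w) / np.mean(d))
    mean_of_ratios = float(np.mean(per_site_ratios)) if per_site_ratios else None
    return MultiSiteSummary(
        mean_pex=mean_pex,
        n_sites=n_sites,
        relative_change_pct=rel,
        wet_dry_ratio_of_means=ratio_of_means,
        wet_dry_mean_of_ratios=mean_of_ratios,
    )


def relative_change_pct(baseline: float, elevated: float) -> float:
    """100*(elevated - baseline)/baseline, rounded to the nearest percent."""
    return float(round((elevated - baseline) / baseline * 100.0))


def annualized_excess_flux(
    rs_mean_hw: float, rs_mean_nhw: float, heat_fraction: float
) -> float:
    """Annual excess soil CO2 efflux attributable to heatwave hours.

        excess [g CO2 m-2 yr-1] = (Rs_HW - Rs_NHW) [μmol m-2 s-1]
                                  x heat_fraction
                                  x 31,557,600 s yr-1
                                  x 44.01e-6 g μmol-1

    i.e. the mean-rate difference sustained over the heatwave share of the
    year, converted to mass of CO2. Linear in both the rate difference and
    the duty fraction; negative if Rs_HW < Rs_NHW.
    """
    if not (np.isfinite(rs_mean_hw) and np.isfinite(rs_mean_nhw)):
        raise ValueError("mean Rs inputs must be finite")
    if not 0.0 <= heat_fraction <= 1.0:
        raise ValueError("heat fraction must be in [0, 1]")
    delta = rs_mean_hw - rs_mean_nhw
    return float(delta * heat_fraction * SECONDS_PER_YEAR * CO2_G_PER_UMOL)
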