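"""Diel (hour-of-day) statistics of soil respiration by heat condition.

Groups matched hourly Rs by local clock hour and heatwave state and reports
mean, median, quartiles and sample size per cell — the numbers behind a mean
diel-cycle line plus hourly boxplots. Dawn/dusk shading bounds used in such
figures are report metadata, not computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climatology import HeatLabels
from .ingest import AlignedDataset

__all__ = ["DielCycle", "compute_diel", "diel_peak_window"]


@dataclass
class DielCycle:
    """Per (hour-of-day, condition) cell: mean, median, q25, q75, n.

    ``table`` is indexed by (hour, condition); hours with no observations for
    a condition are simply absent.
    """

    table: pd.DataFrame

    def mean_cycle(self, condition: str) -> pd.Series:
        """24-value hour-of-day mean Rs for one condition (NaN where absent)."""
        sub = self.table.xs(condition, level="condition")["mean"]
        return sub.reindex(range(24))

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)


def compute_diel(ds: AlignedDataset, heat: HeatLabels) -> DielCycle:
    """Hour-of-day distributional summary of Rs under HW and NHW conditions."""
    labels = heat.labels
    rs = ds.data["rs"].reindex(labels.index)
    df = pd.DataFrame({"rs": rs.to_numpy(), "hour": labels.index.hour, "condition": labels.to_numpy()})
    grouped = df.groupby(["hour", "condition"])["rs"]
    table = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "median": grouped.median(),
            "q25": grouped.quantile(0.25),
            "q75": grouped.quantile(0.75),
            "n": grouped.size(),
        }
    )
    return DielCycle(table=table)


def diel_peak_window(
    cycle: DielCycle, condition: str, tolerance: float = 0.05
) -> tuple[int, int]:
    """Shortest contiguous clock-hour window containing every hour whose mean
    Rs is within ``tolerance`` (fraction) of the cycle maximum.

    A formalisation of the 'morning peak' read off a diel plot by eye. The
    window is inclusive on both ends; a flat cycle degenerates to the full
    day (0, 23). Requires all 24 hourly means.
    """
    means = cycle.mean_cycle(condition)
    if means.isna().any():
        missing = list(means.index[means.isna()])
        raise ValueError(f"incomplete diel cycle for {condition!r}: missing hours {missing}")
    values = means.to_numpy()
    near_max = np.flatnonzero(values >= values.max() * (1 - tolerance))
    # windows may wrap midnight; try every rotation and keep the shortest span
    best = (0, 23)
    best_width = 24
    for shift in range(24):
        rotated = (near_max - shift) % 24
        width = rotated.max() - rotated.min() + 1
        if width < best_width:
            best_width = width
            best = (int((rotated.min() + shift) % 24), int((rotated.max() + shift) % 24))
    return best
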