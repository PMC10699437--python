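"""Min-max normalization and weighted aggregation into composite scores.

Each indicator is mapped to [0, 1] by orientation-aware min-max scaling:
positive indicators as (x - min)/(max - min), negative ones as
(max - x)/(max - min).  The composite score Z of a unit-year is the
weight-tree-weighted sum of its normalized indicators, and decomposes
exactly into per-group sub-scores (one per secondary indicator family).

Extrema are taken either pooled over the whole panel (default — preserves
comparability of Z across years) or within each year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ahp import WeightTree
from .io_panel import IndicatorPanel, PanelValidationError, RegionPartition

__all__ = ["ScorePanel", "normalize", "composite_score", "summarize_by_region"]


class ScoringError(ValueError):
    pass


def normalize(panel: IndicatorPanel, scope: str = "pooled") -> pd.DataFrame:
    """Orientation-aware min-max normalization of a complete panel.

    Returns a tidy frame ``unit, year, indicator, d`` with d in [0, 1].
    ``scope='pooled'`` takes per-indicator extrema over all unit-years;
    ``scope='per_year'`` within each year separately.
    """
    if scope not in ("pooled", "per_year"):
        raise ScoringError(f"unknown normalization scope {scope!r}")
    panel.require_complete()

    df = panel.data.copy()
    by = ["indicator"] if scope == "pooled" else ["indicator", "year"]
    grp = df.groupby(by)["value"]
    lo = grp.transform("min")
    hi = grp.transform("max")
    span = hi - lo
    if (span == 0).any():
        bad = df.loc[span == 0]
        ind = bad["indicator"].iloc[0]
        where = f" in year {bad['year'].iloc[0]}" if scope == "per_year" else ""
        raise ScoringError(
            f"indicator {ind!r} is constant{where} (max = min); "
            "min-max normalization is undefined"
        )
    orient = panel.meta["orientation"].reindex(df["indicator"]).to_numpy()
    d = (df["value"] - lo) / span
    d = np.where(orient == "negative", 1.0 - d, d)
    out = df[["unit", "year", "indicator"]].copy()
    out["d"] = d
    return out


@dataclass
class ScorePanel:
    """Composite score Z and per-group sub-scores per unit-year.

    Z equals the sum of the sub-scores; each sub-score lies in
    [0, secondary weight of its group]; Z lies in [0, 1].
    """

    scores: pd.DataFrame          # columns: unit, year, Z, then one per group
    groups: list[str]
    scope: str = "pooled"

    def year(self, year: int) -> pd.Series:
        sub = self.scores[self.scores["year"] == year]
        if sub.empty:
            raise ScoringError(f"year {year} not present in score panel")
        return sub.set_index("unit")["Z"]

    @property
    def years(self) -> list[int]:
        return sorted(self.scores["year"].unique())

    @property
    def units(self) -> list[str]:
        return sorted(self.scores["unit"].unique())


def composite_score(
    normalized: pd.DataFrame,
    weights: WeightTree,
    scope: str = "pooled",
) -> ScorePanel:
    """Aggregate normalized indicators into sub-scores and composite Z.

    The weight tree's indicators must cover exactly the panel's indicators.
    """
    inds = set(normalized["indicator"].unique())
    w = weights.global_weights
    missing = inds - set(w)
    extra = set(w) - inds
    if missing:
        raise ScoringError(f"indicator(s) without a weight: {sorted(missing)}")
    if extra:
        raise ScoringError(f"weight(s) without a panel indicator: {sorted(extra)}")

    df = normalized.copy()
    df["wd"] = df["d"] * df["indicator"].map(w)
    df["group"] = df["indicator"].map(weights.group_of)
    by_group = (
        df.pivot_table(index=["unit", "year"], columns="group", values="wd",
                       aggfunc="sum")
        .reindex(columns=weights.groups)
    )
    by_group.columns.name = None
    out = by_group.reset_index()
    out.insert(2, "Z", by_group.sum(axis=1).to_numpy())
    return ScorePanel(scores=out, groups=list(weights.groups), scope=scope)


def score_panel(
    panel: IndicatorPanel, weights: WeightTree, scope: str = "pooled"
) -> ScorePanel:
    """Convenience: normalize then aggregate."""
    return composite_score(normalize(panel, scope=scope), weights, scope=scope)


def summarize_by_region(
    scores: ScorePanel, partition: RegionPartition
) -> pd.DataFrame:
    """Per-region per-year mean composite scores, plus two grand summaries.

    ``mean_of_region_means`` averages the region means (the headline
    "average score of the zones"); ``mean_over_units`` is the plain
    all-units mean.  Both are reported for transparency since they differ
    whenever region sizes differ.
    """
    df = scores.scores.copy()
    df["region"] = partition.labels_for(df["unit"].tolist())
    empty = [g for g in partition.groups if g not in set(df["region"])]
    if empty:
        raise ScoringError(f"region(s) with no scored units: {empty}")
    region_means = (
        df.groupby(["year", "region"], sort=True)["Z"].mean().unstack("region")
        .reindex(columns=partition.groups)
    )
    region_means["mean_of_region_means"] = region_means.mean(axis=1)
    region_means["mean_over_units"] = df.groupby("year")["Z"].mean()
    return region_means.reset_index()
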