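"""Two-timepoint quadrant classification of units against the cross-unit
mean composite score at each timepoint.

The origin is (mean score at t0, mean score at t1); quadrant I holds units
at or above average at both timepoints, II below-then-above, III below at
both, IV above-then-below.  Ties at the mean count as above-average (the
closed ">=" convention keeps counts deterministic) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_panel import RegionPartition

__all__ = ["QuadrantResult", "classify_quadrants"]


class QuadrantError(ValueError):
    pass


@dataclass
class QuadrantResult:
    frame: pd.DataFrame          # unit, score_t0, score_t1, quadrant, tie_flag
    origin: tuple[float, float]
    year0: int
    year1: int

    def counts(self) -> dict[str, int]:
        c = self.frame["quadrant"].value_counts()
        return {q: int(c.get(q, 0)) for q in ("I", "II", "III", "IV")}

    def counts_by_region(self, partition: RegionPartition) -> pd.DataFrame:
        df = self.frame.copy()
        df["region"] = partition.labels_for(df["unit"].tolist())
        out = (
            df.pivot_table(index="region", columns="quadrant", values="unit",
                           aggfunc="count", fill_value=0)
            .reindex(index=partition.groups,
                     columns=["I", "II", "III", "IV"], fill_value=0)
        )
        return out.reset_index()


def classify_quadrants(scores, year0: int, year1: int) -> QuadrantResult:
    """Classify every unit by its position relative to the two-year means.

    ``scores`` is a ScorePanel or a frame with columns unit, year, Z; both
    years must be present for every unit.
    """
    frame = scores.scores if hasattr(scores, "scores") else scores
    t0 = frame[frame["year"] == year0].set_index("unit")["Z"]
    t1 = frame[frame["year"] == year1].set_index("unit")["Z"]
    for yr, s in ((year0, t0), (year1, t1)):
        if s.empty:
            raise QuadrantError(f"year {yr} not present in scores")
    if set(t0.index) != set(t1.index):
        raise QuadrantError(
            f"unit sets differ between {year0} and {year1}"
        )
    t1 = t1.reindex(t0.index)
    m0, m1 = float(t0.mean()), float(t1.mean())

    # exact ties at the mean count as above-average; the tolerance absorbs
    # the rounding error of the mean itself (e.g. mean of three 0.4s)
    atol0 = 1e-9 * max(1.0, abs(m0))
    atol1 = 1e-9 * max(1.0, abs(m1))
    above0 = t0 >= m0 - atol0
    above1 = t1 >= m1 - atol1
    quad = pd.Series("III", index=t0.index)
    quad[above0 & above1] = "I"
    quad[~above0 & above1] = "II"
    quad[above0 & ~above1] = "IV"
    tie = ((t0 - m0).abs() <= atol0) | ((t1 - m1).abs() <= atol1)

    out = pd.DataFrame({
        "unit": t0.index,
        "score_t0": t0.to_numpy(),
        "score_t1": t1.to_numpy(),
        "quadrant": quad.to_numpy(),
        "tie_at_mean": tie.to_numpy(),
    }).reset_index(drop=True)
    return QuadrantResult(frame=out, origin=(m0, m1), year0=year0, year1=year1)
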