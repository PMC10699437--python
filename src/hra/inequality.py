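"""Generalized-entropy inequality and exact Theil within/between
decomposition over a region partition.

The generalized-entropy family GE(c) over positive values y_i with unit
weights p_i (default 1/n):

    GE(c) = (1 / (c (c - 1))) * sum_i p_i ((y_i / mu)^c - 1)   for c not in {0, 1}
    GE(1) = sum_i p_i (y_i / mu) ln(y_i / mu)                  (Theil T)
    GE(0) = sum_i p_i ln(mu / y_i)                             (mean log deviation)

For equal weights GE(1) equals the income-share form sum_i s_i ln(n s_i)
with s_i = y_i / sum(y).  Theil T decomposes exactly over any partition
into groups g:

    T = TWR + TBR,   TWR = sum_g S_g T_g,   TBR = sum_g S_g ln(S_g / (n_g/n))

where S_g is group g's share of the total and T_g its internal Theil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_panel import RegionPartition

__all__ = ["TheilResult", "ge_index", "theil_decompose", "theil_timeseries"]


class InequalityError(ValueError):
    pass


def _check_positive(values: np.ndarray, shift_epsilon: bool) -> np.ndarray:
    """Validate positivity; optionally apply the explicit epsilon shift.

    Min-max composite scores can be exactly 0 for the pooled-minimum unit,
    which makes the logarithm undefined.  The default is a hard error; the
    caller may opt into shifting all values by 1e-6 * mean, which is
    recorded by the caller, never silent.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise InequalityError("values must be a nonempty 1-d array")
    if (values <= 0).any():
        if not shift_epsilon:
            raise InequalityError(
                "nonpositive value(s) encountered; the Theil logarithm is "
                "undefined. Pass shift_epsilon=True to apply an explicit "
                "1e-6*mean shift."
            )
        values = values + 1e-6 * values.mean()
        if (values <= 0).any():
            raise InequalityError("values remain nonpositive after epsilon shift")
    return values


def ge_index(
    values,
    c: float = 1.0,
    weights=None,
    shift_epsilon: bool = False,
) -> float:
    """Generalized-entropy index GE(c) of positive values.

    ``weights`` are unit weights p_i summing to 1 (default equal).  GE is
    scale invariant and nonnegative, zero iff all values are equal.
    """
    y = _check_positive(values, shift_epsilon)
    n = len(y)
    if weights is None:
        p = np.full(n, 1.0 / n)
    else:
        p = np.asarray(weights, dtype=float)
        if p.shape != y.shape or (p < 0).any():
            raise InequalityError("weights must be nonnegative, one per value")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InequalityError(f"weights sum to {p.sum()}, expected 1")
    mu = float(p @ y)
    r = y / mu
    if c == 1.0:
        return float(p @ (r * np.log(r)))
    if c == 0.0:
        return float(p @ np.log(1.0 / r))
    return float(p @ (r**c - 1.0) / (c * (c - 1.0)))


def _theil_share_form(y: np.ndarray) -> float:
    """GE(1) via income shares: sum_i s_i ln(n s_i)."""
    s = y / y.sum()
    return float(np.sum(s * np.log(len(y) * s)))


@dataclass
class TheilResult:
    """Theil T of one cross-section with its within/between decomposition."""

    t: float
    twr: float
    tbr: float
    within: dict[str, float]          # per-group component S_g * T_g
    group_sizes: dict[str, int]
    year: int | None = None

    @property
    def contributions(self) -> dict[str, float]:
        """Percent contribution of each component to total T (sums to 100)."""
        if self.t == 0:
            return {**{g: 0.0 for g in self.within}, "TWR": 0.0, "TBR": 0.0}
        out = {g: 100.0 * v / self.t for g, v in self.within.items()}
        out["TWR"] = 100.0 * self.twr / self.t
        out["TBR"] = 100.0 * self.tbr / self.t
        return out

    def as_row(self) -> dict:
        row = {"year": self.year, **{f"T_{g}": v for g, v in self.within.items()}}
        row.update({"TWR": self.twr, "TBR": self.tbr, "T": self.t})
        return row


def theil_decompose(
    values,
    partition: RegionPartition,
    units: list[str] | None = None,
    shift_epsilon: bool = False,
    year: int | None = None,
) -> TheilResult:
    """Theil T with exact within/between decomposition over the partition.

    ``values`` may be a pandas Series indexed by unit id, or an array with
    an explicit ``units`` list.  Groups of size 1 contribute a within
    component of 0.  The identity T = TWR + TBR holds to machine precision.
    """
    if isinstance(values, pd.Series):
        units = [str(u) for u in values.index]
        y = values.to_numpy(dtype=float)
    else:
        if units is None:
            raise InequalityError("units must be given when values is an array")
        y = np.asarray(values, dtype=float)
    y = _check_positive(y, shift_epsilon)
    labels = partition.labels_for(units)

    n = len(y)
    total = y.sum()
    t = _theil_share_form(y)

    within: dict[str, float] = {}
    tbr = 0.0
    sizes: dict[str, int] = {}
    for g in partition.groups:
        mask = labels == g
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        sizes[g] = n_g
        y_g = y[mask]
        s_g = y_g.sum() / total
        t_g = _theil_share_form(y_g) if n_g > 1 else 0.0
        within[g] = s_g * t_g
        tbr += s_g * np.log(s_g / (n_g / n))
    twr = sum(within.values())
    return TheilResult(t=t, twr=twr, tbr=float(tbr), within=within,
                       group_sizes=sizes, year=year)


def theil_timeseries(
    scores,
    partition: RegionPartition,
    shift_epsilon: bool = False,
) -> tuple[list[TheilResult], pd.DataFrame]:
    """Per-year Theil decomposition of a score panel, plus a long table.

    Returns one :class:`TheilResult` per year and a tidy contribution table
    with full-precision values; percent changes between the first and last
    year are computed from unrounded values and attached as a final block.
    """
    from .scoring import ScorePanel  # local import to avoid cycle

    if isinstance(scores, ScorePanel):
        frame = scores.scores
    else:
        frame = scores
    results: list[TheilResult] = []
    for yr in sorted(frame["year"].unique()):
        sub = frame[frame["year"] == yr].set_index("unit")["Z"]
        results.append(
            theil_decompose(sub, partition, shift_epsilon=shift_epsilon, year=int(yr))
        )

    rows = [r.as_row() for r in results]
    table = pd.DataFrame(rows)
    contrib = pd.DataFrame(
        [{"year": r.year, **{f"pct_{k}": v for k, v in r.contributions.items()}}
         for r in results]
    )
    table = table.merge(contrib, on="year")

    first, last = results[0], results[-1]
    change: dict[str, float] = {}
    for key in ("t", "twr", "tbr"):
        a, b = getattr(first, key), getattr(last, key)
        change[f"pct_change_{key.upper()}"] = 100.0 * (b - a) / a if a != 0 else np.nan
    table.attrs["pct_change_first_to_last"] = change
    return results, table
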