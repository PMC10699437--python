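"""Readers, writers and validated containers for panel data, region
partitions and spatial weights.

The canonical interchange format is tidy long CSV (``unit,year,indicator,
value``) with a separate indicator metadata table (``indicator,orientation,
group``).  Spatial weights come either from a GeoDa GAL adjacency file or a
CSV edge list; region partitions from a two-column ``unit,group`` CSV.

All identifiers are matched case-sensitively after whitespace trimming.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorPanel",
    "RegionPartition",
    "SpatialWeights",
    "PanelValidationError",
    "read_panel",
    "read_partition",
    "read_spatial_weights",
    "write_results",
]

ORIENTATIONS = ("positive", "negative")


class PanelValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# Indicator panel
# ---------------------------------------------------------------------------

@dataclass
class IndicatorPanel:
    """Tidy unit x year x indicator observations plus indicator metadata.

    ``data`` has columns ``unit, year, indicator, value``; ``meta`` is
    indexed by indicator id with columns ``orientation`` ('positive' or
    'negative') and ``group`` (the secondary-indicator family the tertiary
    indicator belongs to).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        data = self.data.copy()
        data["unit"] = data["unit"].astype(str).str.strip()
        data["indicator"] = data["indicator"].astype(str).str.strip()
        data["year"] = data["year"].astype(int)
        data["value"] = data["value"].astype(float)

        dup = data.duplicated(["unit", "year", "indicator"])
        if dup.any():
            key = data.loc[dup, ["unit", "year", "indicator"]].iloc[0]
            raise PanelValidationError(
                f"duplicate observation for (unit={key['unit']!r}, "
                f"year={key['year']}, indicator={key['indicator']!r})"
            )
        if data["value"].isna().any():
            bad = data[data["value"].isna()].iloc[0]
            raise PanelValidationError(
                f"missing value for (unit={bad['unit']!r}, year={bad['year']}, "
                f"indicator={bad['indicator']!r})"
            )

        meta = self.meta.copy()
        if meta.index.name != "indicator":
            if "indicator" in meta.columns:
                meta = meta.set_index("indicator")
            else:
                meta.index.name = "indicator"
        meta.index = meta.index.astype(str).str.strip()
        meta["orientation"] = meta["orientation"].astype(str).str.strip()
        meta["group"] = meta["group"].astype(str).str.strip()

        bad_orient = set(meta["orientation"]) - set(ORIENTATIONS)
        if bad_orient:
            raise PanelValidationError(
                f"unknown orientation token(s) {sorted(bad_orient)}; "
                f"expected one of {ORIENTATIONS}"
            )
        missing_meta = set(data["indicator"]) - set(meta.index)
        if missing_meta:
            raise PanelValidationError(
                f"indicator(s) without metadata: {sorted(missing_meta)}"
            )

        object.__setattr__(self, "data", data.reset_index(drop=True))
        object.__setattr__(self, "meta", meta)

    # -- basic views ----------------------------------------------------

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def indicators(self) -> list[str]:
        return sorted(self.data["indicator"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def wide(self) -> pd.DataFrame:
        """(unit, year) x indicator value matrix."""
        return self.data.pivot_table(
            index=["unit", "year"], columns="indicator", values="value",
            aggfunc="first",
        )

    # -- completeness ---------------------------------------------------

    def completeness_report(self) -> dict:
        """Check rectangular completeness (every unit x year x indicator).

        Scoring requires a complete panel; inequality/spatial stages only
        need complete per-year cross-sections.
        """
        n_expected = len(self.units) * len(self.years) * len(self.indicators)
        missing = n_expected - len(self.data)
        return {
            "n_units": len(self.units),
            "n_years": len(self.years),
            "n_indicators": len(self.indicators),
            "n_observations": len(self.data),
            "n_expected": n_expected,
            "n_missing": missing,
            "complete": missing == 0,
        }

    def require_complete(self) -> None:
        rep = self.completeness_report()
        if not rep["complete"]:
            raise PanelValidationError(
                f"panel is not rectangular: {rep['n_missing']} of "
                f"{rep['n_expected']} unit x year x indicator cells missing"
            )


def read_panel(path: str | Path, meta_path: str | Path) -> IndicatorPanel:
    """Read a tidy long panel CSV and its indicator metadata CSV."""
    data = pd.read_csv(path, comment="#")
    need = {"unit", "year", "indicator", "value"}
    if not need.issubset(data.columns):
        raise PanelValidationError(
            f"panel file must have columns {sorted(need)}, got {list(data.columns)}"
        )
    meta = pd.read_csv(meta_path, comment="#")
    need_m = {"indicator", "orientation", "group"}
    if not need_m.issubset(meta.columns):
        raise PanelValidationError(
            f"metadata file must have columns {sorted(need_m)}, got {list(meta.columns)}"
        )
    return IndicatorPanel(data=data, meta=meta)


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Assignment of every unit to exactly one region group."""

    assignment: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assignment = {
            str(u).strip(): str(g).strip() for u, g in self.assignment.items()
        }
        if not assignment:
            raise PanelValidationError("empty partition")
        seen: list[str] = []
        for g in assignment.values():
            if g not in seen:
                seen.append(g)
        order = [str(g).strip() for g in self.group_order] or seen
        extra = set(assignment.values()) - set(order)
        if extra:
            raise PanelValidationError(f"groups missing from group_order: {sorted(extra)}")
        empty = [g for g in order if g not in set(assignment.values())]
        if empty:
            raise PanelValidationError(f"empty group(s): {empty}")
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "group_order", order)

    @property
    def units(self) -> list[str]:
        return list(self.assignment)

    @property
    def groups(self) -> list[str]:
        return list(self.group_order)

    def sizes(self) -> dict[str, int]:
        out = {g: 0 for g in self.group_order}
        for g in self.assignment.values():
            out[g] += 1
        return out

    def members(self, group: str) -> list[str]:
        return [u for u, g in self.assignment.items() if g == group]

    def labels_for(self, units: Sequence[str]) -> np.ndarray:
        """Group label per unit, erroring on unassigned units."""
        missing = [u for u in units if u not in self.assignment]
        if missing:
            raise PanelValidationError(f"unit(s) not assigned to any region: {missing}")
        return np.array([self.assignment[u] for u in units])


def read_partition(path: str | Path) -> RegionPartition:
    df = pd.read_csv(path, comment="#")
    if not {"unit", "group"}.issubset(df.columns):
        raise PanelValidationError(
            f"partition file must have columns ['unit', 'group'], got {list(df.columns)}"
        )
    units = df["unit"].astype(str).str.strip()
    if units.duplicated().any():
        raise PanelValidationError(
            f"unit assigned more than once: {units[units.duplicated()].iloc[0]!r}"
        )
    order: list[str] = []
    for g in df["group"].astype(str).str.strip():
        if g not in order:
            order.append(g)
    return RegionPartition(
        assignment=dict(zip(units, df["group"].astype(str).str.strip())),
        group_order=order,
    )


# ---------------------------------------------------------------------------
# Spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Square nonnegative spatial weights matrix over an ordered unit list.

    ``mode`` is ``binary`` (symmetric 0/1 contiguity) or ``row_standardized``
    (each row with at least one neighbour sums to 1).  Isolated units (zero
    rows) are permitted but flagged; their spatial lag is undefined.
    """

    units: list[str]
    w: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        units = [str(u).strip() for u in self.units]
        w = np.asarray(self.w, dtype=float)
        n = len(units)
        if w.shape != (n, n):
            raise PanelValidationError(f"weights shape {w.shape} != ({n}, {n})")
        if len(set(units)) != n:
            raise PanelValidationError("duplicate unit ids in weights matrix")
        if (w < 0).any():
            raise PanelValidationError("negative spatial weights")
        if np.diag(w).any():
            raise PanelValidationError("nonzero diagonal in spatial weights")
        if self.mode not in ("binary", "row_standardized"):
            raise PanelValidationError(f"unknown weights mode {self.mode!r}")
        if self.mode == "binary" and not np.allclose(w, w.T):
            raise PanelValidationError("binary weights must be symmetric")
        if self.mode == "row_standardized":
            rs = w.sum(axis=1)
            live = rs > 0
            if not np.allclose(rs[live], 1.0):
                raise PanelValidationError(
                    "row_standardized weights must have unit row sums"
                )
        if w.sum() <= 0:
            raise PanelValidationError("all-zero spatial weights matrix (S0 = 0)")
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "w", w)

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    @property
    def isolated(self) -> list[str]:
        deg = self.w.sum(axis=1) + self.w.sum(axis=0)
        return [u for u, d in zip(self.units, deg) if d == 0]

    def row_standardize(self) -> "SpatialWeights":
        rs = self.w.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(rs > 0, self.w / rs, 0.0)
        return SpatialWeights(units=self.units, w=w, mode="row_standardized")

    def subset(self, units: Sequence[str]) -> "SpatialWeights":
        """Reorder/restrict to the given unit order (all must be present)."""
        idx = {u: i for i, u in enumerate(self.units)}
        missing = [u for u in units if u not in idx]
        if missing:
            raise PanelValidationError(f"unit(s) absent from spatial weights: {missing}")
        sel = [idx[u] for u in units]
        return SpatialWeights(
            units=list(units), w=self.w[np.ix_(sel, sel)], mode=self.mode
        )


def _weights_from_edges(
    edges: Iterable[tuple[str, str, float]],
    units: Sequence[str] | None,
) -> tuple[list[str], np.ndarray]:
    edges = [(str(a).strip(), str(b).strip(), float(v)) for a, b, v in edges]
    if units is None:
        seen: list[str] = []
        for a, b, _ in edges:
            for u in (a, b):
                if u not in seen:
                    seen.append(u)
        units = sorted(seen)
    units = [str(u).strip() for u in units]
    idx = {u: i for i, u in enumerate(units)}
    w = np.zeros((len(units), len(units)))
    for a, b, v in edges:
        for u in (a, b):
            if u not in idx:
                raise PanelValidationError(
                    f"edge references unknown unit {u!r} (not in unit list)"
                )
        if a == b:
            raise PanelValidationError(f"self-loop on unit {a!r}")
        w[idx[a], idx[b]] = v
        w[idx[b], idx[a]] = v
    return list(units), w


def _parse_gal(text: str) -> list[tuple[str, str, float]]:
    """Parse a GeoDa GAL adjacency file into an undirected edge list.

    Header is one line whose last-but-? field is the record count; GeoDa
    writes either ``n`` or ``0 n shapefile key``.  Then pairs of lines:
    ``id k`` followed by ``k`` neighbour ids.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PanelValidationError("empty GAL file")
    header = lines[0].split()
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    edges: list[tuple[str, str, float]] = []
    i = 1
    records = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2:
            raise PanelValidationError(f"malformed GAL record header: {lines[i]!r}")
        uid, k = head[0], int(head[1])
        i += 1
        if k > 0:
            if i >= len(lines):
                raise PanelValidationError(f"GAL record for {uid!r} truncated")
            nbrs = lines[i].split()
            if len(nbrs) != k:
                raise PanelValidationError(
                    f"GAL record for {uid!r} lists {len(nbrs)} neighbours, expected {k}"
                )
            for v in nbrs:
                a, b = sorted((uid, v))
                if (a, b, 1.0) not in edges:
                    edges.append((a, b, 1.0))
            i += 1
        records += 1
    if records != n:
        raise PanelValidationError(f"GAL header says {n} records, found {records}")
    return edges


def read_spatial_weights(
    path: str | Path,
    format: str = "edge_list",
    mode: str = "binary",
    units: Sequence[str] | None = None,
) -> SpatialWeights:
    """Read spatial weights from a GAL file or a CSV edge list.

    The edge list has columns ``unit_a,unit_b[,weight]``; links are treated
    as undirected and a symmetric binary matrix is built, optionally
    row-standardized afterwards.  If ``units`` is given, every listed unit
    appears in the matrix (possibly isolated) and edge endpoints must be
    drawn from it.
    """
    text = Path(path).read_text()
    if format == "gal":
        edges = _parse_gal(text)
    elif format == "edge_list":
        df = pd.read_csv(io.StringIO(text), comment="#")
        cols = list(df.columns)
        if len(cols) < 2:
            raise PanelValidationError("edge list needs columns unit_a,unit_b[,weight]")
        wcol = df[cols[2]] if len(cols) > 2 else pd.Series(1.0, index=df.index)
        edges = list(zip(df[cols[0]], df[cols[1]], wcol.astype(float)))
    else:
        raise PanelValidationError(f"unknown weights format {format!r}")

    unit_list, w = _weights_from_edges(edges, units)
    sw = SpatialWeights(units=unit_list, w=w, mode="binary")
    if mode == "row_standardized":
        sw = sw.row_standardize()
    elif mode != "binary":
        raise PanelValidationError(f"unknown weights mode {mode!r}")
    return sw


def write_gal(sw: SpatialWeights, path: str | Path) -> None:
    """Write binary contiguity as a GAL file (row-standardized is written
    by neighbour pattern; weights are not preserved by the format)."""
    lines = [str(sw.n)]
    for i, u in enumerate(sw.units):
        nbrs = [sw.units[j] for j in np.flatnonzero(sw.w[i] > 0)]
        lines.append(f"{u} {len(nbrs)}")
        if nbrs:
            lines.append(" ".join(nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> list[Path]:
    """Write result tables as CSV with a run-metadata comment header.

    The header carries the seed and a config hash so any table can be traced
    back to the run that produced it; pandas re-reads these files with
    ``comment='#'``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# seed={seed} config_hash={config_hash(config) if config else 'none'}\n"
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(p)
    return written
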