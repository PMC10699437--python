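"""End-to-end orchestration: weights -> scores -> Theil table -> Moran/LISA
tables -> quadrant table, from one YAML config, reproducibly.

Outputs are plain CSV at full precision (plus 4 d.p. display copies of the
headline tables) and a ``manifest.json`` that echoes the config, seed,
package versions, per-stage record counts and collected warnings.  Nothing
time-dependent is written, so a fixed seed gives byte-identical outputs
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ahp import AhpError, WeightTree, build_weight_tree, read_judgment_matrix
from .fixtures import published_weight_tree
from .inequality import theil_timeseries
from .io_panel import (
    IndicatorPanel,
    PanelValidationError,
    RegionPartition,
    SpatialWeights,
    config_hash,
    read_panel,
    read_partition,
    read_spatial_weights,
)
from .quadrant import classify_quadrants
from .scoring import score_panel, summarize_by_region
from .spatial import lisa_summary, moran_global, moran_local
from .synth import SyntheticConfig, write_bundle

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    scope: str = "pooled"
    c: float = 1.0
    permutations: int = 999
    alpha: float = 0.05
    quadrant_years: tuple[int, int] | None = None
    moran_years: list[int] | None = None      # None = all years
    shift_epsilon: bool = False
    weights_mode: str = "fixture"             # fixture | csv | matrices
    weights_csv: str | None = None
    secondary_matrix: str | None = None
    tertiary_matrices: dict[str, str] = field(default_factory=dict)
    panel: str | None = None
    meta: str | None = None
    partition: str | None = None
    spatial_path: str | None = None
    spatial_format: str = "gal"
    spatial_mode: str = "row_standardized"
    simulate: dict | None = None              # SyntheticConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        weights = raw.pop("weights", {}) or {}
        spatial = raw.pop("spatial", {}) or {}
        kw = dict(raw)
        kw["weights_mode"] = weights.get("mode", "fixture")
        kw["weights_csv"] = weights.get("csv")
        kw["secondary_matrix"] = weights.get("secondary")
        kw["tertiary_matrices"] = weights.get("tertiary", {}) or {}
        if spatial:
            kw["spatial_path"] = spatial.get("path")
            kw["spatial_format"] = spatial.get("format", "gal")
            kw["spatial_mode"] = spatial.get("mode", "row_standardized")
        if kw.get("quadrant_years"):
            kw["quadrant_years"] = tuple(int(y) for y in kw["quadrant_years"])
        unknown = set(kw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kw)

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _load_weight_tree(cfg: RunConfig, warnings: list[str]) -> WeightTree:
    if cfg.weights_mode == "fixture":
        return published_weight_tree()
    if cfg.weights_mode == "csv":
        df = pd.read_csv(cfg.weights_csv, comment="#")
        gw = dict(zip(df["indicator"].astype(str), df["global_weight"].astype(float)))
        grp = dict(zip(df["indicator"].astype(str), df["group"].astype(str)))
        from .ahp import WeightTree
        return WeightTree.from_global_weights(gw, grp)
    if cfg.weights_mode == "matrices":
        secondary = read_judgment_matrix(cfg.secondary_matrix)
        tertiary = {
            g: read_judgment_matrix(p) for g, p in cfg.tertiary_matrices.items()
        }
        return build_weight_tree(secondary, tertiary)
    raise PipelineError(f"unknown weights mode {cfg.weights_mode!r}")


def _write_csv(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in order; returns a result bundle keyed by stage.

    Any stage failure raises :class:`PipelineError` naming the stage; no
    partial manifest is written in that case.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}
    header = f"# seed={cfg.seed} config_hash={config_hash(cfg.echo())}\n"
    bundle: dict = {}

    def run_stage(name, fn):
        try:
            return fn()
        except (PanelValidationError, AhpError, ValueError) as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- inputs ---------------------------------------------------------
    def _inputs():
        if cfg.simulate is not None:
            sim_cfg = SyntheticConfig(**cfg.simulate)
            paths = write_bundle(sim_cfg, out / "inputs", seed=cfg.seed)
            panel = read_panel(paths["panel"], paths["meta"])
            partition = read_partition(paths["regions"])
            weights = read_spatial_weights(
                paths["gal"], format="gal", mode=cfg.spatial_mode,
                units=panel.units,
            )
        else:
            if not (cfg.panel and cfg.meta and cfg.partition and cfg.spatial_path):
                raise PanelValidationError(
                    "config must give panel, meta, partition and spatial paths "
                    "(or a simulate block)"
                )
            panel = read_panel(cfg.panel, cfg.meta)
            partition = read_partition(cfg.partition)
            weights = read_spatial_weights(
                cfg.spatial_path, format=cfg.spatial_format,
                mode=cfg.spatial_mode, units=panel.units,
            )
        return panel, partition, weights

    panel, partition, weights = run_stage("inputs", _inputs)
    counts["panel_observations"] = len(panel)
    if weights.isolated:
        warnings.append(f"isolated spatial unit(s): {weights.isolated}")

    # -- weights --------------------------------------------------------
    def _weights():
        tree = _load_weight_tree(cfg, warnings)
        extra = set(tree.global_weights) - set(panel.indicators)
        missing = set(panel.indicators) - set(tree.global_weights)
        if extra or missing:
            raise AhpError(
                f"weight/indicator mismatch: extra={sorted(extra)}, "
                f"missing={sorted(missing)}"
            )
        return tree

    tree = run_stage("weights", _weights)
    weights_table = tree.as_frame()
    _write_csv(out / "weights.csv", weights_table, header)
    counts["weights"] = len(weights_table)
    bundle["weights"] = tree

    # -- scores ---------------------------------------------------------
    def _score():
        scores = score_panel(panel, tree, scope=cfg.scope)
        region_means = summarize_by_region(scores, partition)
        return scores, region_means

    scores, region_means = run_stage("score", _score)
    _write_csv(out / "scores.csv", scores.scores, header)
    _write_csv(out / "region_means.csv", region_means, header)
    counts["scores"] = len(scores.scores)
    bundle["scores"] = scores

    # -- theil ----------------------------------------------------------
    def _theil():
        n_zero = int((scores.scores["Z"] <= 0).sum())
        if n_zero and cfg.shift_epsilon:
            warnings.append(
                f"epsilon shift applied to {n_zero} nonpositive score(s)"
            )
        return theil_timeseries(scores, partition,
                                shift_epsilon=cfg.shift_epsilon)

    theil_results, theil_table = run_stage("theil", _theil)
    _write_csv(out / "theil.csv", theil_table, header)
    counts["theil_years"] = len(theil_results)
    bundle["theil"] = theil_results

    # -- moran / lisa ---------------------------------------------------
    def _moran():
        yrs = cfg.moran_years or scores.years
        rows = []
        lisa_frames = []
        summaries = []
        for yr in yrs:
            vals = scores.year(int(yr))
            g = moran_global(vals, weights, n_permutations=cfg.permutations,
                             seed=cfg.seed)
            rows.append({"year": int(yr), **g.as_row()})
            l = moran_local(vals, weights, n_permutations=cfg.permutations,
                            seed=cfg.seed, alpha=cfg.alpha)
            lf = l.frame.copy()
            lf.insert(0, "year", int(yr))
            lisa_frames.append(lf)
            s = lisa_summary(l, partition)
            s.insert(0, "year", int(yr))
            summaries.append(s)
            und = lf[lf["label"] == "undefined"]["unit"].tolist()
            if und:
                warnings.append(
                    f"year {yr}: undefined LISA label for isolated unit(s) {und}"
                )
        return (pd.DataFrame(rows), pd.concat(lisa_frames, ignore_index=True),
                pd.concat(summaries, ignore_index=True))

    moran_table, lisa_table, lisa_sum = run_stage("moran", _moran)
    _write_csv(out / "moran_global.csv", moran_table, header)
    _write_csv(out / "lisa.csv", lisa_table, header)
    _write_csv(out / "lisa_summary.csv", lisa_sum, header)
    counts["moran_years"] = len(moran_table)
    bundle["moran"] = moran_table
    bundle["lisa"] = lisa_table

    # -- quadrant -------------------------------------------------------
    def _quadrant():
        y0, y1 = cfg.quadrant_years or (scores.years[0], scores.years[-1])
        q = classify_quadrants(scores, int(y0), int(y1))
        return q

    q = run_stage("quadrant", _quadrant)
    _write_csv(out / "quadrant.csv", q.frame, header)
    _write_csv(out / "quadrant_counts.csv", q.counts_by_region(partition), header)
    counts["quadrant_units"] = len(q.frame)
    bundle["quadrant"] = q
    if q.frame["tie_at_mean"].any():
        warnings.append(
            f"{int(q.frame['tie_at_mean'].sum())} unit(s) tied exactly at a "
            "quadrant mean (counted as above-average)"
        )

    # -- display copies and manifest ------------------------------------
    display = out / "display"
    display.mkdir(exist_ok=True)
    for name, df in (("theil", theil_table), ("scores", scores.scores)):
        _write_csv(display / f"{name}_4dp.csv", df.round(4), header)

    manifest = {
        "config": cfg.echo(),
        "config_hash": config_hash(cfg.echo()),
        "seed": cfg.seed,
        "versions": {
            "hra": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "record_counts": counts,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
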