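"""Global and local Moran's I spatial autocorrelation with LISA cluster
typing.

Global Moran's I over mean-deviations z_i = x_i - xbar:

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),  E[I] = -1/(n-1)

with analytic variance under either the normality or the randomization
assumption, plus conditional-permutation inference.  Local Moran's I uses
values standardized by the n-divisor standard deviation,

    I_i = zs_i * sum_j w_ij zs_j,

and under row-standardized weights satisfies sum_i I_i = n * I.

Permutation scheme (deterministic given a seed): the global test permutes
the value vector as whole rows drawn from ``default_rng(seed)``; the local
test for unit i holds x_i fixed and permutes the remaining n-1 values with
``default_rng([seed, i])``, ordering by a stable argsort of uniform keys.
Directional pseudo-p is the GeoDa-style tail count
(1 + #{permuted >= observed}) / (R + 1) on the side of the observed
deviation from expectation; the reported two-sided pseudo-p doubles it
(capped at 1) and is what significance gating uses.

Isolated units (no neighbours) have an undefined spatial lag: they keep
their place in the global statistic (n and S0 unchanged) but are labelled
``undefined`` locally rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_panel import RegionPartition, SpatialWeights

__all__ = ["MoranGlobalResult", "LisaResult", "moran_global", "moran_local",
           "lisa_summary"]

LABELS = ("HH", "HL", "LH", "LL", "NS", "undefined")


class SpatialError(ValueError):
    pass


def _align(values, w: SpatialWeights) -> np.ndarray:
    if isinstance(values, pd.Series):
        idx = [str(u) for u in values.index]
        if sorted(idx) != sorted(w.units):
            raise SpatialError(
                "value units do not match spatial-weights units"
            )
        return values.reindex(w.units).to_numpy(dtype=float)
    x = np.asarray(values, dtype=float)
    if x.shape != (w.n,):
        raise SpatialError(f"expected {w.n} values, got shape {x.shape}")
    return x


def _moran_variances(w: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Analytic Var(I) under the normality and randomization assumptions."""
    n = len(z)
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    e_i = -1.0 / (n - 1)

    var_norm = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2

    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_rand = num / den - e_i**2
    return var_norm, var_rand


@dataclass
class MoranGlobalResult:
    i: float
    expected_i: float
    variance: float                 # under the chosen assumption
    var_normality: float
    var_randomization: float
    z_score: float
    p_analytic: float               # two-sided normal on z_score
    pseudo_p: float                 # two-sided permutation p
    pseudo_p_directional: float     # one-tail count on the observed side
    n_permutations: int
    seed: int | None
    assumption: str
    n: int

    def as_row(self) -> dict:
        return {
            "I": self.i, "expected_I": self.expected_i,
            "variance_randomization": self.var_randomization,
            "variance_normality": self.var_normality,
            "z": self.z_score, "p_analytic": self.p_analytic,
            "pseudo_p": self.pseudo_p, "n_permutations": self.n_permutations,
        }


def moran_global(
    values,
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    assumption: str = "randomization",
) -> MoranGlobalResult:
    """Global Moran's I with analytic and permutation inference.

    ``values`` is a Series indexed by unit id (aligned to ``w``) or an array
    already in ``w.units`` order.  Permutation inference requires a seed.
    """
    if assumption not in ("randomization", "normality"):
        raise SpatialError(f"unknown assumption {assumption!r}")
    x = _align(values, w)
    n = w.n
    if n < 3:
        raise SpatialError("global Moran's I needs at least 3 units")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise SpatialError("values are constant; Moran's I is undefined")

    W = w.w
    s0 = w.s0
    i_obs = (n / s0) * float(z @ W @ z) / ss
    e_i = -1.0 / (n - 1)
    var_norm, var_rand = _moran_variances(W, z)
    variance = var_rand if assumption == "randomization" else var_norm
    z_score = (i_obs - e_i) / math.sqrt(variance)
    p_analytic = math.erfc(abs(z_score) / math.sqrt(2.0))

    pseudo_p = pseudo_dir = float("nan")
    if n_permutations > 0:
        if seed is None:
            raise SpatialError("permutation inference requires a seed")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(
            np.tile(np.arange(n), (n_permutations, 1)), axis=1
        )
        zp = z[perms]                                # (R, n); mean/ss invariant
        i_star = (n / s0) * np.einsum("rj,rj->r", zp, zp @ W.T) / ss
        if i_obs >= e_i:
            count = int((i_star >= i_obs).sum())
        else:
            count = int((i_star <= i_obs).sum())
        pseudo_dir = (1 + count) / (n_permutations + 1)
        pseudo_p = min(1.0, 2.0 * pseudo_dir)

    return MoranGlobalResult(
        i=i_obs, expected_i=e_i, variance=variance,
        var_normality=var_norm, var_randomization=var_rand,
        z_score=z_score, p_analytic=p_analytic,
        pseudo_p=pseudo_p, pseudo_p_directional=pseudo_dir,
        n_permutations=n_permutations, seed=seed, assumption=assumption, n=n,
    )


@dataclass
class LisaResult:
    """Per-unit local Moran's I with significance-gated cluster labels."""

    frame: pd.DataFrame   # unit, local_I, pseudo_p, mean_comparison, lag_comparison, label
    alpha: float
    n_permutations: int
    seed: int | None

    @property
    def labels(self) -> pd.Series:
        return self.frame.set_index("unit")["label"]

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["label"].isin(("HH", "HL", "LH", "LL"))]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def moran_local(
    values,
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> LisaResult:
    """Local Moran's I per unit with conditional-permutation pseudo-p.

    Units are typed HH/HL/LH/LL from the sign of their standardized value
    and of their spatial lag, gated by two-sided pseudo_p <= alpha (NS
    otherwise); isolated units are ``undefined``.  ``fdr=True`` gates on
    Benjamini-Hochberg adjusted p-values instead (off by default: the 31
    per-unit tests are conventionally reported unadjusted).
    """
    x = _align(values, w)
    n = w.n
    if n < 3:
        raise SpatialError("local Moran's I needs at least 3 units")
    z = x - x.mean()
    var_n = float(z @ z) / n
    if var_n == 0:
        raise SpatialError("values are constant; local Moran's I is undefined")
    zs = z / math.sqrt(var_n)

    W = w.w
    deg = W.sum(axis=1)
    lag = W @ zs
    local_i = zs * lag

    if n_permutations > 0 and seed is None:
        raise SpatialError("permutation inference requires a seed")

    rows = []
    pvals = np.full(n, np.nan)
    for i, unit in enumerate(w.units):
        isolated = deg[i] == 0 and W[:, i].sum() == 0
        if isolated:
            rows.append({
                "unit": unit, "local_I": np.nan, "pseudo_p": np.nan,
                "mean_comparison": "high" if zs[i] >= 0 else "low",
                "lag_comparison": "undefined", "label": "undefined",
            })
            continue
        p2 = np.nan
        if n_permutations > 0:
            others = np.delete(zs, i)
            wrow = np.delete(W[i], i)
            rng = np.random.default_rng([seed, i])
            keys = rng.random((n_permutations, n - 1))
            order = np.argsort(keys, axis=1, kind="stable")
            lag_star = others[order] @ wrow
            i_star = zs[i] * lag_star
            # expected local I under conditional permutation of the others
            e_i = -zs[i] ** 2 * wrow.sum() / (n - 1)
            if local_i[i] >= e_i:
                count = int((i_star >= local_i[i]).sum())
            else:
                count = int((i_star <= local_i[i]).sum())
            p_dir = (1 + count) / (n_permutations + 1)
            p2 = min(1.0, 2.0 * p_dir)
        pvals[i] = p2
        rows.append({
            "unit": unit, "local_I": float(local_i[i]), "pseudo_p": p2,
            "mean_comparison": "high" if zs[i] >= 0 else "low",
            "lag_comparison": "high" if lag[i] >= 0 else "low",
            "label": None,
        })

    frame = pd.DataFrame(rows)
    gate = pvals.copy()
    if fdr:
        live = ~np.isnan(pvals)
        gate[live] = _bh_adjust(pvals[live])
    for i in range(n):
        if frame.loc[i, "label"] == "undefined":
            continue
        if not np.isnan(gate[i]) and gate[i] <= alpha:
            hi_lo = frame.loc[i, "mean_comparison"] == "high"
            lag_hi = frame.loc[i, "lag_comparison"] == "high"
            frame.loc[i, "label"] = ("H" if hi_lo else "L") + ("H" if lag_hi else "L")
        else:
            frame.loc[i, "label"] = "NS"
    return LisaResult(frame=frame, alpha=alpha,
                      n_permutations=n_permutations, seed=seed)


def lisa_summary(l: LisaResult, partition: RegionPartition) -> pd.DataFrame:
    """Counts of significant units per cluster label per region."""
    sig = l.significant().copy()
    out = pd.DataFrame(
        0, index=pd.Index(partition.groups, name="region"),
        columns=["HH", "HL", "LH", "LL"],
    )
    if not sig.empty:
        sig["region"] = partition.labels_for(sig["unit"].tolist())
        for _, row in sig.iterrows():
            out.loc[row["region"], row["label"]] += 1
    out["total"] = out.sum(axis=1)
    return out.reset_index()
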