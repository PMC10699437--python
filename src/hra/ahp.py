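"""Analytic Hierarchy Process weighting with consistency testing.

Weights are derived from pairwise-comparison (judgment) matrices on Saaty's
1-9 importance scale by the sum-product method: normalise each column to sum
one, average across rows, renormalise.  The principal eigenvalue is
estimated as the mean componentwise Rayleigh ratio (Xw)_i / w_i, from which
the consistency index CI = (lambda_max - n)/(n - 1) and consistency ratio
CR = CI / RI follow; a matrix is acceptably consistent when CR < 0.1.

A power-iteration eigenpair solver is provided as an independent
cross-check route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "JudgmentMatrix",
    "AhpResult",
    "WeightTree",
    "RANDOM_INDEX",
    "derive_weights",
    "consistency_check",
    "build_weight_tree",
    "read_judgment_matrix",
]

#: Saaty's average random consistency index for matrix orders 1..10.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Relative tolerance for the reciprocity check x_ij * x_ji = 1.  Published
#: matrices often print reciprocal pairs rounded to 4 d.p. (e.g. 0.9500 vs
#: 1.0526, product 0.99997), so exact reciprocity must not be enforced.
RECIPROCITY_RTOL = 1e-3

SCALE_EPS = 1e-6


class AhpError(ValueError):
    """Judgment-matrix validation or consistency failure."""


@dataclass
class JudgmentMatrix:
    """Square positive reciprocal matrix of pairwise importance ratios."""

    labels: list[str]
    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        labels = [str(l).strip() for l in self.labels]
        n = len(labels)
        if x.shape != (n, n):
            raise AhpError(f"matrix shape {x.shape} does not match {n} labels")
        if n < 2:
            raise AhpError("judgment matrix needs at least 2 elements")
        if (x <= 0).any():
            raise AhpError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(x), 1.0, atol=1e-12):
            raise AhpError("judgment matrix diagonal must be exactly 1")
        prod = x * x.T
        if not np.allclose(prod, 1.0, rtol=RECIPROCITY_RTOL):
            i, j = np.unravel_index(np.argmax(np.abs(prod - 1.0)), prod.shape)
            raise AhpError(
                f"matrix is not reciprocal: x[{labels[i]},{labels[j]}] * "
                f"x[{labels[j]},{labels[i]}] = {prod[i, j]:.6f}"
            )
        lo, hi = 1.0 / 9.0 - SCALE_EPS, 9.0 + SCALE_EPS
        if ((x < lo) | (x > hi)).any():
            raise AhpError("entries outside the 1/9..9 Saaty scale")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_upper_triangle(
        cls, labels: list[str], upper: dict[tuple[int, int], float]
    ) -> "JudgmentMatrix":
        """Build an exactly reciprocal matrix from upper-triangle ratios."""
        n = len(labels)
        x = np.eye(n)
        for (i, j), v in upper.items():
            x[i, j] = v
            x[j, i] = 1.0 / v
        return cls(labels=labels, x=x)


@dataclass
class AhpResult:
    """Priority weights and consistency statistics for one matrix."""

    labels: list[str]
    weights: np.ndarray
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool
    method: str = "sum_product"

    def weight_of(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.labels, name="weight")


def _sum_product_weights(x: np.ndarray) -> np.ndarray:
    col_normalized = x / x.sum(axis=0, keepdims=True)
    w = col_normalized.mean(axis=1)
    return w / w.sum()


def _power_iteration(x: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000):
    """Dominant eigenpair of a positive matrix (Perron-Frobenius)."""
    n = x.shape[0]
    w = np.full(n, 1.0 / n)
    lam = float("nan")
    for _ in range(max_iter):
        y = x @ w
        lam_new = y.sum()          # since w sums to 1
        y = y / y.sum()
        if np.allclose(y, w, rtol=0, atol=tol) and abs(lam_new - lam) < tol * n:
            w = y
            lam = lam_new
            break
        w, lam = y, lam_new
    return w, float(lam)


def consistency_check(lambda_max: float, n: int) -> tuple[float, float, bool]:
    """CI, CR and the CR < 0.1 verdict for a given principal eigenvalue.

    Orders 1 and 2 are always consistent (RI = 0 makes CR = CI/RI undefined,
    and a 2x2 reciprocal matrix is exactly consistent), so CR is defined 0.
    """
    if n not in RANDOM_INDEX:
        raise AhpError(
            f"no packaged random index for n = {n}; supply RI explicitly "
            f"(packaged orders: 1..{max(RANDOM_INDEX)})"
        )
    if n <= 2:
        return 0.0, 0.0, True
    ci = (lambda_max - n) / (n - 1)
    ri = RANDOM_INDEX[n]
    cr = ci / ri
    return ci, cr, cr < 0.1


def derive_weights(m: JudgmentMatrix, method: str = "sum_product") -> AhpResult:
    """Derive priority weights and consistency statistics.

    ``sum_product`` is the primary route; ``power_iteration`` computes the
    exact dominant eigenpair (to 1e-12) and serves as a cross-check.  In
    both cases lambda_max is the mean of the componentwise Rayleigh ratios
    (Xw)_i / w_i, which for the exact eigenvector equals the eigenvalue.
    """
    if method == "sum_product":
        w = _sum_product_weights(m.x)
    elif method == "power_iteration":
        w, _ = _power_iteration(m.x)
    else:
        raise AhpError(f"unknown weighting method {method!r}")
    lambda_max = float(np.mean((m.x @ w) / w))
    ci, cr, ok = consistency_check(lambda_max, m.n)
    ri = RANDOM_INDEX[m.n]
    return AhpResult(
        labels=list(m.labels), weights=w, lambda_max=lambda_max,
        ci=ci, ri=ri, cr=cr, consistent=ok, method=method,
    )


# ---------------------------------------------------------------------------
# Hierarchical weight tree
# ---------------------------------------------------------------------------

@dataclass
class WeightTree:
    """Two-level weight hierarchy: secondary groups and tertiary indicators.

    ``global_weights[i] = secondary[group(i)] * local[group(i)][i]``; the
    global weights sum to 1 and, within each group, to that group's
    secondary weight.
    """

    secondary: dict[str, float]
    local: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        sec_sum = sum(self.secondary.values())
        if abs(sec_sum - 1.0) > 1e-9:
            raise AhpError(f"secondary weights sum to {sec_sum}, expected 1")
        for g, ws in self.local.items():
            if g not in self.secondary:
                raise AhpError(f"local weights for unknown group {g!r}")
            s = sum(ws.values())
            if abs(s - 1.0) > 1e-9:
                raise AhpError(f"local weights in group {g!r} sum to {s}, expected 1")
        missing = set(self.secondary) - set(self.local)
        if missing:
            raise AhpError(f"groups without local weights: {sorted(missing)}")

    @property
    def global_weights(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for g, ws in self.local.items():
            for ind, w in ws.items():
                if ind in out:
                    raise AhpError(f"indicator {ind!r} appears in more than one group")
                out[ind] = self.secondary[g] * w
        return out

    @property
    def group_of(self) -> dict[str, str]:
        return {ind: g for g, ws in self.local.items() for ind in ws}

    @property
    def groups(self) -> list[str]:
        return list(self.secondary)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "secondary_weight": self.secondary[g],
                "indicator": ind,
                "local_weight": lw,
                "global_weight": self.secondary[g] * lw,
            }
            for g, ws in self.local.items()
            for ind, lw in ws.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_global_weights(
        cls, global_weights: dict[str, float], group_of: dict[str, str]
    ) -> "WeightTree":
        """Back out a tree from global tertiary weights (secondary weight =
        group sum, local weight = global/secondary)."""
        secondary: dict[str, float] = {}
        for ind, w in global_weights.items():
            secondary[group_of[ind]] = secondary.get(group_of[ind], 0.0) + w
        local = {
            g: {
                ind: global_weights[ind] / secondary[g]
                for ind, gg in group_of.items() if gg == g
            }
            for g in secondary
        }
        return cls(secondary=secondary, local=local)


def build_weight_tree(
    secondary_m: JudgmentMatrix,
    tertiary_ms: dict[str, JudgmentMatrix],
    method: str = "sum_product",
) -> WeightTree:
    """Derive the full weight hierarchy, refusing any inconsistent matrix.

    Every matrix (secondary and per-group tertiary) must pass CR < 0.1;
    otherwise the offending matrix is reported so it can be adjusted.
    """
    failures: list[str] = []
    sec = derive_weights(secondary_m, method=method)
    if not sec.consistent:
        failures.append(f"secondary (CR = {sec.cr:.4f})")
    missing = set(secondary_m.labels) - set(tertiary_ms)
    if missing:
        raise AhpError(f"no tertiary matrix for group(s): {sorted(missing)}")
    local: dict[str, dict[str, float]] = {}
    for g in secondary_m.labels:
        res = derive_weights(tertiary_ms[g], method=method)
        if not res.consistent:
            failures.append(f"tertiary {g!r} (CR = {res.cr:.4f})")
        local[g] = dict(zip(res.labels, res.weights))
    if failures:
        raise AhpError(
            "judgment matrix fails the consistency test (CR >= 0.1) and "
            "needs to be adjusted: " + "; ".join(failures)
        )
    secondary = dict(zip(sec.labels, sec.weights))
    return WeightTree(secondary=secondary, local=local)


def read_judgment_matrix(path: str | Path) -> JudgmentMatrix:
    """Read a labeled square CSV (header row and first column are labels)."""
    df = pd.read_csv(path, index_col=0, comment="#")
    labels = [str(c).strip() for c in df.columns]
    row_labels = [str(r).strip() for r in df.index]
    if labels != row_labels:
        raise AhpError(
            f"row labels {row_labels} do not match column labels {labels}"
        )
    return JudgmentMatrix(labels=labels, x=df.to_numpy(dtype=float))
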