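"""Global/local Moran's I against brute-force and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hra.io_panel import RegionPartition, SpatialWeights
from hra.spatial import (
    SpatialError,
    lisa_summary,
    moran_global,
    moran_local,
)


def ring(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return SpatialWeights(units=[f"u{i}" for i in range(n)], w=w)


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return SpatialWeights(units=[f"u{i}" for i in range(n)], w=w)


def random_graph(n, rng, p=0.4):
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = w[j, i] = 1.0
    if w.sum() == 0:
        w[0, 1] = w[1, 0] = 1.0
    return SpatialWeights(units=[f"u{i}" for i in range(n)], w=w)


def moran_brute(x, w):
    """Double-loop evaluation of (n/S0) * sum_ij w_ij z_i z_j / sum z^2."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = sum(
        w[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return (n / w.sum()) * num / (z @ z)


class TestGlobal:
    def test_checkerboard_ring_is_perfect_dispersion(self):
        res = moran_global([1.0, -1.0, 1.0, -1.0], ring(4), n_permutations=0)
        assert res.i == pytest.approx(-1.0, abs=1e-12)

    def test_expected_value_closed_form(self):
        res = moran_global(
            np.arange(31, dtype=float), ring(31), n_permutations=0
        )
        assert res.expected_i == -1.0 / 30

    def test_matches_brute_force_on_random_graphs(self, rng):
        for n in (5, 9, 14):
            w = random_graph(n, rng)
            x = rng.normal(size=n)
            res = moran_global(x, w, n_permutations=0)
            assert res.i == pytest.approx(moran_brute(x, w.w), abs=1e-12)
            res_rs = moran_global(x, w.row_standardize(), n_permutations=0)
            assert res_rs.i == pytest.approx(
                moran_brute(x, w.row_standardize().w), abs=1e-12
            )

    def test_two_blocks_cluster_significantly(self):
        # adjacent identical-value blocks on a path: strong positive I
        w = path_graph(10)
        x = np.array([5.0] * 5 + [1.0] * 5) + np.linspace(0, 0.1, 10)
        res = moran_global(x, w, n_permutations=999, seed=1)
        assert res.i > 0
        assert res.pseudo_p <= 0.05
        assert res.z_score > 0

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """Sampled pseudo-p converges to the exact directional tail share
        over all n! relabelings (n = 6)."""
        w = path_graph(6)
        x = np.array([3.0, 2.5, 2.0, 0.5, 0.2, 0.1])
        obs = moran_brute(x, w.w)
        e_i = -1.0 / 5
        stats = [
            moran_brute(x[list(p)], w.w)
            for p in itertools.permutations(range(6))
        ]
        if obs >= e_i:
            exact = np.mean([s >= obs - 1e-12 for s in stats])
        else:
            exact = np.mean([s <= obs + 1e-12 for s in stats])
        res = moran_global(x, w, n_permutations=999, seed=9)
        se = math.sqrt(exact * (1 - exact) / 999)
        assert res.pseudo_p_directional == pytest.approx(exact, abs=4 * se + 1e-3)

    def test_affine_invariance(self, rng):
        w = random_graph(8, rng)
        x = rng.normal(size=8)
        a = moran_global(x, w, n_permutations=99, seed=3)
        b = moran_global(3.5 * x + 7.0, w, n_permutations=99, seed=3)
        assert a.i == pytest.approx(b.i, abs=1e-12)
        assert a.pseudo_p == b.pseudo_p

    def test_analytic_and_permutation_inference_agree_in_sign(self, rng):
        for _ in range(10):
            w = random_graph(10, rng)
            x = rng.normal(size=10)
            res = moran_global(x, w, n_permutations=199, seed=17)
            if res.pseudo_p <= 0.05:
                assert (res.i > res.expected_i) == (res.z_score > 0)

    def test_constant_values_rejected(self):
        with pytest.raises(SpatialError, match="constant"):
            moran_global([2.0, 2.0, 2.0, 2.0], ring(4), n_permutations=0)

    def test_seed_required_for_permutations(self):
        with pytest.raises(SpatialError, match="seed"):
            moran_global([1.0, 2.0, 3.0, 4.0], ring(4), n_permutations=99)

    def test_normality_and_randomization_variances_differ(self, rng):
        w = random_graph(9, rng)
        x = rng.exponential(size=9)  # skewed: kurtosis term matters
        res = moran_global(x, w, n_permutations=0, assumption="normality")
        assert res.variance == res.var_normality != res.var_randomization


def lisa_oracle(x, w: SpatialWeights, n_permutations, seed, alpha):
    """Loop re-implementation of local Moran, sign typing and the
    documented conditional-permutation scheme."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    zs = z / math.sqrt((z @ z) / n)
    labels = []
    for i in range(n):
        wrow = w.w[i]
        if wrow.sum() == 0 and w.w[:, i].sum() == 0:
            labels.append("undefined")
            continue
        lag = sum(wrow[j] * zs[j] for j in range(n) if j != i)
        local_i = zs[i] * lag
        others = [zs[j] for j in range(n) if j != i]
        wother = [wrow[j] for j in range(n) if j != i]
        rng = np.random.default_rng([seed, i])
        keys = rng.random((n_permutations, n - 1))
        count = 0
        e_i = -zs[i] ** 2 * sum(wother) / (n - 1)
        for r in range(n_permutations):
            order = np.argsort(keys[r], kind="stable")
            lag_star = sum(others[order[k]] * wother[k] for k in range(n - 1))
            i_star = zs[i] * lag_star
            if local_i >= e_i:
                count += i_star >= local_i
            else:
                count += i_star <= local_i
        p2 = min(1.0, 2.0 * (1 + count) / (n_permutations + 1))
        if p2 <= alpha:
            labels.append(("H" if zs[i] >= 0 else "L") + ("H" if lag >= 0 else "L"))
        else:
            labels.append("NS")
    return labels


class TestLocal:
    def test_checkerboard_sign_patterns_alternate(self):
        res = moran_local([1.0, -1.0, 1.0, -1.0], ring(4),
                          n_permutations=99, seed=0)
        pattern = list(zip(res.frame["mean_comparison"], res.frame["lag_comparison"]))
        assert pattern == [("high", "low"), ("low", "high")] * 2
        # at n = 4 nothing can reach significance at alpha 0.05
        assert (res.frame["label"] == "NS").all()

    def test_clique_of_high_units_labelled_hh(self, rng):
        n = 20
        w = np.zeros((n, n))
        for i in range(n - 1):          # path backbone
            w[i, i + 1] = w[i + 1, i] = 1.0
        for i in range(4):              # units 0-3 mutually adjacent
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = 1.0
        sw = SpatialWeights(units=[f"u{i}" for i in range(n)], w=w)
        x = np.r_[np.full(4, 10.0), np.zeros(n - 4)] + rng.normal(0, 0.1, n)
        res = moran_local(x, sw, n_permutations=999, seed=4, alpha=0.05)
        assert (res.frame.loc[:3, "label"] == "HH").all()

    def test_sum_of_local_equals_n_times_global(self, rng):
        """Under row-standardized W and n-divisor standardization."""
        for n in (6, 10, 15):
            w = random_graph(n, rng).row_standardize()
            x = rng.normal(size=n)
            local = moran_local(x, w, n_permutations=0)
            glob = moran_global(x, w, n_permutations=0)
            assert local.frame["local_I"].sum() == pytest.approx(
                n * glob.i, abs=1e-10
            )

    def test_determinism_same_seed(self, rng):
        w = random_graph(12, rng)
        x = rng.normal(size=12)
        a = moran_local(x, w, n_permutations=199, seed=8)
        b = moran_local(x, w, n_permutations=199, seed=8)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_labels_match_brute_force_oracle(self, rng):
        for n in (5, 9, 12, 15):
            w = random_graph(n, rng)
            x = rng.normal(size=n)
            res = moran_local(x, w, n_permutations=199, seed=21, alpha=0.05)
            assert list(res.frame["label"]) == lisa_oracle(x, w, 199, 21, 0.05)

    def test_isolated_unit_undefined(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        sw = SpatialWeights(units=list("abcd"), w=w)
        res = moran_local([1.0, 2.0, 3.0, 4.0], sw, n_permutations=99, seed=0)
        assert res.frame.set_index("unit").loc["d", "label"] == "undefined"
        assert np.isnan(res.frame.set_index("unit").loc["d", "local_I"])


class TestLisaSummary:
    def test_counts_by_label_and_region(self):
        frame = pd.DataFrame({
            "unit": ["a", "b", "c", "d"],
            "local_I": [1.0, 0.1, 2.0, 0.2],
            "pseudo_p": [0.01, 0.5, 0.01, 0.5],
            "mean_comparison": ["high", "high", "low", "low"],
            "lag_comparison": ["high", "low", "low", "high"],
            "label": ["HH", "NS", "LL", "NS"],
        })
        from hra.spatial import LisaResult
        l = LisaResult(frame=frame, alpha=0.05, n_permutations=99, seed=0)
        part = RegionPartition(
            assignment={"a": "w", "b": "w", "c": "e", "d": "e"},
            group_order=["w", "e"],
        )
        out = lisa_summary(l, part).set_index("region")
        assert out.loc["w", "HH"] == 1 and out.loc["e", "LL"] == 1
        assert out["total"].sum() == 2

    def test_empty_significant_set(self):
        frame = pd.DataFrame({
            "unit": ["a", "b"], "local_I": [0.1, 0.2], "pseudo_p": [0.9, 0.8],
            "mean_comparison": ["high", "low"], "lag_comparison": ["low", "high"],
            "label": ["NS", "NS"],
        })
        from hra.spatial import LisaResult
        l = LisaResult(frame=frame, alpha=0.05, n_permutations=99, seed=0)
        part = RegionPartition(assignment={"a": "w", "b": "w"})
        out = lisa_summary(l, part)
        assert out[["HH", "HL", "LH", "LL"]].to_numpy().sum() == 0

    def test_two_block_geometry_separates_hh_ll(self, tree):
        from hra.scoring import score_panel
        from hra.synth import SyntheticConfig, generate_panel
        cfg = SyntheticConfig(
            n_units=20, group_sizes=(10, 10), group_names=("west", "east"),
            region_effects=(2.0, -2.0), noise_sd=1.0, rho=0.0, trend=0.0,
            n_indicators=1, n_years=1, adjacency_spec="two_block", seed=13,
        )
        panel, part, w, _ = generate_panel(cfg)
        x = panel.data.set_index("unit")["value"]
        res = moran_local(x, w.row_standardize(), n_permutations=499, seed=13)
        sig = res.significant()
        regions = part.labels_for(sig["unit"].tolist())
        for label, region in zip(sig["label"], regions):
            if label == "HH":
                assert region == "west"
            if label == "LL":
                assert region == "east"
        assert (sig["label"] == "HH").sum() >= 1
        assert (sig["label"] == "LL").sum() >= 1
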