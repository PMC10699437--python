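"""AHP weight derivation and consistency testing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hra.ahp import (
    AhpError,
    JudgmentMatrix,
    WeightTree,
    build_weight_tree,
    consistency_check,
    derive_weights,
)
from hra.fixtures import secondary_judgment_matrix


def ratio_matrix(v):
    """Fully consistent matrix x_ij = v_i / v_j (rank-1 ratio structure)."""
    v = np.asarray(v, dtype=float)
    return JudgmentMatrix(
        labels=[f"e{i}" for i in range(len(v))], x=np.outer(v, 1.0 / v)
    )


class TestDeriveWeights:
    def test_worked_example_weights_to_4dp(self):
        res = derive_weights(secondary_judgment_matrix())
        assert np.allclose(res.weights.round(4), [0.3324, 0.3596, 0.3080])
        assert res.consistent

    def test_printed_form_same_weights(self):
        res = derive_weights(secondary_judgment_matrix(form="printed"))
        assert np.allclose(res.weights.round(4), [0.3324, 0.3596, 0.3080])

    def test_all_ones_matrix_fully_consistent(self):
        m = JudgmentMatrix(labels=["a", "b", "c"], x=np.ones((3, 3)))
        res = derive_weights(m)
        assert np.allclose(res.weights, 1 / 3)
        assert res.lambda_max == pytest.approx(3.0, abs=1e-12)
        assert res.ci == 0.0 and res.cr == 0.0

    @pytest.mark.parametrize("v", [(0.5, 0.3, 0.2), (0.4, 0.25, 0.2, 0.15)])
    def test_consistent_matrix_recovers_weights_exactly(self, v):
        res = derive_weights(ratio_matrix(v))
        assert np.allclose(res.weights, v, atol=1e-12)
        assert res.cr == pytest.approx(0.0, abs=1e-9)

    def test_methods_agree_on_near_consistent_matrix(self):
        m = secondary_judgment_matrix()
        sp = derive_weights(m, method="sum_product")
        pi = derive_weights(m, method="power_iteration")
        assert sp.lambda_max == pytest.approx(pi.lambda_max, abs=1e-3)
        assert np.allclose(sp.weights, pi.weights, atol=1e-3)

    def test_unknown_method_rejected(self):
        with pytest.raises(AhpError, match="method"):
            derive_weights(secondary_judgment_matrix(), method="geometric")


class TestConsistency:
    def test_worked_example_ci_cr(self):
        # printed lambda_max reproduces the printed CI and CR
        ci, cr, ok = consistency_check(3.000752, 3)
        assert ci == pytest.approx(0.000376, abs=5e-7)
        assert cr == pytest.approx(0.000648, abs=5e-6)
        assert ok

    def test_perfect_consistency(self):
        ci, cr, ok = consistency_check(5.0, 5)
        assert ci == 0.0 and cr == 0.0 and ok

    def test_maximally_cyclic_matrix_inconsistent(self):
        # x12 = 9, x23 = 9, x13 = 1/9: worst cyclic violation of transitivity
        m = JudgmentMatrix.from_upper_triangle(
            ["a", "b", "c"], {(0, 1): 9.0, (0, 2): 1 / 9.0, (1, 2): 9.0}
        )
        res = derive_weights(m)
        assert not res.consistent and res.cr > 0.1
        # oracle: direct eigen-solve of the same matrix
        lam = max(np.linalg.eigvals(m.x).real)
        assert res.lambda_max == pytest.approx(lam, rel=1e-2)
        ci, cr, _ = consistency_check(lam, 3)
        assert cr > 0.1

    def test_order_two_defined_consistent(self):
        m = JudgmentMatrix(labels=["a", "b"], x=np.array([[1.0, 3.0], [1 / 3, 1.0]]))
        res = derive_weights(m)
        assert res.ci == 0.0 and res.cr == 0.0 and res.consistent

    def test_order_outside_packaged_ri_table(self):
        with pytest.raises(AhpError, match="supply RI"):
            consistency_check(12.0, 11)


class TestValidation:
    def test_non_reciprocal_rejected(self):
        x = np.array([[1.0, 2.0], [0.3, 1.0]])
        with pytest.raises(AhpError, match="reciprocal"):
            JudgmentMatrix(labels=["a", "b"], x=x)

    def test_printed_rounding_tolerated(self):
        # 0.9500 vs 1.0526 multiply to 0.99997; must pass validation
        secondary_judgment_matrix(form="printed")

    def test_nonpositive_entry_rejected(self):
        x = np.array([[1.0, -2.0], [-0.5, 1.0]])
        with pytest.raises(AhpError, match="positive"):
            JudgmentMatrix(labels=["a", "b"], x=x)

    def test_bad_diagonal_rejected(self):
        x = np.array([[2.0, 1.0], [1.0, 1.0]])
        with pytest.raises(AhpError, match="diagonal"):
            JudgmentMatrix(labels=["a", "b"], x=x)

    def test_entry_outside_saaty_scale_rejected(self):
        with pytest.raises(AhpError, match="scale"):
            JudgmentMatrix.from_upper_triangle(["a", "b"], {(0, 1): 12.0})


class TestWeightTree:
    def test_secondary_times_local_gives_published_globals(self):
        tree = WeightTree(
            secondary={"HF": 0.3324, "HP": 0.3596, "HB": 0.3080},
            local={
                "HF": {"h1": 0.1100 / 0.3324, "h2": 0.1145 / 0.3324,
                        "h3": 0.1079 / 0.3324},
                "HP": {"p1": 0.1114 / 0.3596, "p2": 0.1284 / 0.3596,
                        "p3": 0.1198 / 0.3596},
                "HB": {"b1": 0.1050 / 0.3080, "b2": 0.0993 / 0.3080,
                        "b3": 0.1037 / 0.3080},
            },
        )
        gw = tree.global_weights
        assert round(gw["h1"], 4) == 0.1100
        assert round(gw["p2"], 4) == 0.1284
        assert sum(gw.values()) == pytest.approx(1.0, abs=1e-9)
        # group sums equal secondary weights
        for g, sec in tree.secondary.items():
            assert sum(v for k, v in gw.items() if tree.group_of[k] == g) == \
                pytest.approx(sec, abs=1e-9)

    def test_single_indicator_group_inherits_secondary_weight(self):
        tree = WeightTree(secondary={"A": 0.6, "B": 0.4},
                          local={"A": {"a1": 1.0}, "B": {"b1": 1.0}})
        assert tree.global_weights == pytest.approx({"a1": 0.6, "b1": 0.4})

    def test_build_from_matrices(self):
        sec = ratio_matrix((0.5, 0.3, 0.2))
        sec = JudgmentMatrix(labels=["A", "B", "C"], x=sec.x)
        terts = {
            g: JudgmentMatrix(labels=[f"{g}1", f"{g}2"],
                              x=np.array([[1.0, 2.0], [0.5, 1.0]]))
            for g in "ABC"
        }
        tree = build_weight_tree(sec, terts)
        gw = tree.global_weights
        assert sum(gw.values()) == pytest.approx(1.0, abs=1e-9)
        assert gw["A1"] == pytest.approx(0.5 * 2 / 3, abs=1e-9)

    def test_inconsistent_tertiary_refused(self):
        sec = JudgmentMatrix(labels=["A", "B"], x=np.ones((2, 2)))
        bad = JudgmentMatrix.from_upper_triangle(
            ["x", "y", "z"], {(0, 1): 9.0, (0, 2): 1 / 9.0, (1, 2): 9.0}
        )
        good = JudgmentMatrix(labels=["u", "v"], x=np.ones((2, 2)))
        with pytest.raises(AhpError, match="adjust"):
            build_weight_tree(sec, {"A": bad, "B": good})

    def test_missing_tertiary_matrix(self):
        sec = JudgmentMatrix(labels=["A", "B"], x=np.ones((2, 2)))
        with pytest.raises(AhpError, match="no tertiary"):
            build_weight_tree(sec, {"A": sec})


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    st.lists(st.floats(min_value=0.2, max_value=5.0), min_size=3, max_size=6)
)
def test_consistent_ratio_matrices_recovered(v):
    """Any rank-1 ratio matrix yields exact recovery and lambda_max = n."""
    v = np.array(v) / np.sum(v)
    # keep all pairwise ratios within the Saaty 1/9..9 scale
    if v.max() / v.min() > 8.9:
        return
    res = derive_weights(ratio_matrix(v))
    assert np.allclose(res.weights, v, atol=1e-10)
    assert res.lambda_max == pytest.approx(len(v), abs=1e-9)


def test_perturbation_never_decreases_cr(rng):
    """Multiplying one off-diagonal pair by k and 1/k (k > 1) cannot make a
    consistent matrix look more consistent."""
    for _ in range(25):
        v = rng.uniform(0.5, 2.0, size=4)
        base = np.outer(v, 1.0 / v)
        cr0 = derive_weights(JudgmentMatrix(labels=list("abcd"), x=base)).cr
        k = rng.uniform(1.1, 2.0)
        x = base.copy()
        x[0, 1] *= k
        x[1, 0] /= k
        cr1 = derive_weights(JudgmentMatrix(labels=list("abcd"), x=x)).cr
        assert cr1 >= cr0 - 1e-12
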