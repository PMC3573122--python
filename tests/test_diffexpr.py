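import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirseed.diffexpr import (
    THRESHOLDS_ALTERED,
    CategorySets,
    Thresholds,
    bh_adjust,
    categorize,
    collapse_probes,
    differential,
    quantile_normalize,
    relative_expression_ddct,
)
from mirseed.formats import SampleSheet


def bh_bruteforce(p):
    """Step-up definition: adj_i = min over sorted ranks j>=rank(i) of m*p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, m + 1)
    adj_sorted = np.array(
        [min(1.0, np.min(m * sorted_p[i:] / ranks[i:])) for i in range(m)]
    )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def make_sheet(n_per_group, conditions=("control", "treatment")):
    return SampleSheet.from_records(
        [
            (f"{cond}_{r}", cond, r)
            for cond in conditions
            for r in range(1, n_per_group + 1)
        ]
    )


def make_matrix(data, n_per_group, features=None):
    cols = [f"control_{r}" for r in range(1, n_per_group + 1)] + [
        f"treatment_{r}" for r in range(1, n_per_group + 1)
    ]
    features = features or [f"f{i}" for i in range(len(data))]
    return pd.DataFrame(data, index=features, columns=cols)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [1.0, 3.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_two_column_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_columns_share_sorted_vector(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_single_column_errors(self):
        with pytest.raises(ValueError, match="2 columns"):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_labels_preserved(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(3, 2)), index=["x", "y", "z"], columns=["s1", "s2"]
        )
        out = quantile_normalize(df)
        assert list(out.index) == ["x", "y", "z"]
        assert list(out.columns) == ["s1", "s2"]


class TestDifferential:
    def test_identical_groups(self):
        matrix = make_matrix([[5.0] * 6, [2.0] * 6], 3)
        de = differential(matrix, make_sheet(3), ("treatment", "control"))
        assert de.loc["f0", "logFC"] == 0
        assert de.loc["f0", "t_mod"] == 0
        assert de.loc["f0", "p"] == 1

    def test_aveexpr_mean_over_all_samples(self):
        matrix = make_matrix(
            [[7.0, 7.0, 7.0, 9.0, 9.0, 9.0], [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], 3
        )
        de = differential(matrix, make_sheet(3), ("treatment", "control"))
        assert de.loc["f0", "AveExpr"] == pytest.approx(8.0)
        assert de.loc["f0", "logFC"] == pytest.approx(2.0)

    def test_prior_df_zero_matches_pooled_t_oracle(self, rng):
        """With no shrinkage the statistic equals the textbook pooled t."""
        data = rng.normal(8, 1, size=(50, 6))
        matrix = make_matrix(data, 3)
        de = differential(matrix, make_sheet(3), ("treatment", "control"), prior_df=0)
        res = stats.ttest_ind(data[:, 3:], data[:, :3], axis=1, equal_var=True)
        np.testing.assert_allclose(de["t_mod"].to_numpy(), res.statistic, atol=1e-12)
        np.testing.assert_allclose(de["p"].to_numpy(), res.pvalue, atol=1e-12)

    def test_sign_consistency(self, rng):
        data = rng.normal(8, 1, size=(80, 8))
        matrix = make_matrix(data, 4)
        de = differential(matrix, make_sheet(4), ("treatment", "control"))
        nz = de["t_mod"] != 0
        assert (np.sign(de.loc[nz, "logFC"]) == np.sign(de.loc[nz, "t_mod"])).all()
        assert ((de["adjP"] >= de["p"] - 1e-15) & (de["adjP"] <= 1)).all()

    def test_contrast_string_form(self, rng):
        data = rng.normal(size=(5, 6))
        matrix = make_matrix(data, 3)
        a = differential(matrix, make_sheet(3), "treatment:control")
        b = differential(matrix, make_sheet(3), ("treatment", "control"))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_condition_errors(self, rng):
        matrix = make_matrix(rng.normal(size=(3, 6)), 3)
        with pytest.raises(ValueError, match="unknown condition"):
            differential(matrix, make_sheet(3), ("nope", "control"))

    def test_too_few_replicates(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["f"], columns=["control_1", "control_2", "treatment_1"]
        )
        sheet = SampleSheet.from_records(
            [("control_1", "control", 1), ("control_2", "control", 2),
             ("treatment_1", "treatment", 1)]
        )
        with pytest.raises(ValueError, match="2 replicates"):
            differential(matrix, sheet, ("treatment", "control"))

    def test_degenerate_zero_variance_shift(self):
        matrix = make_matrix([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], 3)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            de = differential(
                matrix, make_sheet(3), ("treatment", "control"),
                prior_df=4, prior_var=0.0,
            )
        assert de.loc["f0", "t_mod"] == np.inf
        assert de.loc["f0", "p"] == 0.0


class TestBhAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_bruteforce_random_vectors(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 1001))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_with_ties_and_extremes(self):
        p = np.array([0.0, 1.0, 0.5, 0.5, 0.001])
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-15)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([-0.1])

    def test_series_index_preserved(self):
        s = pd.Series([0.04, 0.01], index=["b", "a"])
        out = bh_adjust(s)
        assert list(out.index) == ["b", "a"]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_property_monotone_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCategorize:
    def make_detable(self, rows):
        return pd.DataFrame(
            rows, columns=["AveExpr", "logFC", "t_mod", "p", "adjP"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_cav1_like_row_is_down(self):
        # AveExpr 15.28 / logFC -1.78 / small adjP under (7.0, 0.7, 0.05)
        de = self.make_detable([[15.28, -1.78, -10.0, 1e-4, 1e-3]])
        cats = categorize(de, THRESHOLDS_ALTERED)
        assert "g0" in cats.down

    def test_logfc_boundary_strict(self):
        de = self.make_detable([[10.0, -0.7, -5.0, 1e-4, 1e-3]])
        cats = categorize(de, THRESHOLDS_ALTERED)
        assert "g0" not in cats.down and "g0" not in cats.up
        assert "g0" in cats.background

    def test_adjp_boundary_strict(self):
        de = self.make_detable([[10.0, -2.0, -5.0, 0.04, 0.05]])
        cats = categorize(de, THRESHOLDS_ALTERED)
        assert "g0" not in cats.down

    def test_aveexpr_boundary_inclusive(self):
        de = self.make_detable(
            [[6.9, -2.0, -5.0, 1e-4, 1e-3], [7.0, -2.0, -5.0, 1e-4, 1e-3]]
        )
        cats = categorize(de, THRESHOLDS_ALTERED)
        assert "g0" not in cats.background
        assert "g1" in cats.background and "g1" in cats.down

    def test_up_symmetric(self):
        de = self.make_detable([[10.0, 1.2, 5.0, 1e-4, 1e-3]])
        cats = categorize(de, THRESHOLDS_ALTERED)
        assert "g0" in cats.up

    def test_empty_detable_errors(self):
        with pytest.raises(ValueError, match="empty"):
            categorize(self.make_detable([]), THRESHOLDS_ALTERED)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            CategorySets(
                up=frozenset({"a"}), down=frozenset({"a"}), background=frozenset({"a"})
            )


class TestThresholds:
    def test_validation(self):
        with pytest.raises(ValueError):
            Thresholds(7.0, -0.1, 0.05)
        with pytest.raises(ValueError):
            Thresholds(7.0, 0.7, 0.0)


class TestDdct:
    @pytest.mark.parametrize(
        "ct_target,ct_ref,expected", [(25.0, 22.0, 0.125), (22.0, 22.0, 1.0), (21.0, 22.0, 2.0)]
    )
    def test_examples(self, ct_target, ct_ref, expected):
        assert relative_expression_ddct(ct_target, ct_ref) == pytest.approx(expected)

    def test_vectorized(self):
        out = relative_expression_ddct([25.0, 22.0], [22.0, 22.0])
        np.testing.assert_allclose(out, [0.125, 1.0])

    def test_non_finite_errors(self):
        with pytest.raises(ValueError, match="finite"):
            relative_expression_ddct(np.nan, 22.0)


def test_collapse_probes_keeps_max_aveexpr():
    de = pd.DataFrame(
        {
            "AveExpr": [5.0, 9.0, 7.0],
            "logFC": [-1.0, -2.0, -3.0],
            "t_mod": [-1.0, -2.0, -3.0],
            "p": [0.1, 0.01, 0.001],
            "adjP": [0.1, 0.02, 0.003],
        },
        index=["probe1", "probe2", "probe3"],
    )
    collapsed = collapse_probes(de, {"probe1": "CAV1", "probe2": "CAV1", "probe3": "PXN"})
    assert list(collapsed.index) == ["CAV1", "PXN"]
    assert collapsed.loc["CAV1", "AveExpr"] == 9.0
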