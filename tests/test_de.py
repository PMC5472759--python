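import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rccpipe import (
    ExpressionMatrix,
    bh_adjust,
    call_de,
    log2_with_pseudocount,
    median_center_genes,
    overlap_counts,
    top_variable_genes,
    upper_quartile_normalize,
    welch_t,
)
from rccpipe.errors import ValidationError


def _counts(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "counts")


def _log2(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2")


class TestUpperQuartile:
    def test_scaled_sample_equalised(self):
        a = np.array([1.0, 5.0, 10.0, 0.0, 3.0])
        m = _counts(np.column_stack([a, 2 * a]))
        out = upper_quartile_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_single_sample_unchanged(self):
        m = _counts([[1.0], [5.0], [9.0]])
        out = upper_quartile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_nonzero_upper_quartiles_equal_after(self, small_counts):
        out = upper_quartile_normalize(small_counts)
        uqs = [
            np.percentile(col[col > 0], 75) for col in out.values.T
        ]
        np.testing.assert_allclose(uqs, uqs[0])

    def test_idempotent(self, small_counts):
        once = upper_quartile_normalize(small_counts)
        twice = upper_quartile_normalize(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_all_zero_sample_rejected(self):
        m = _counts([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="s1"):
            upper_quartile_normalize(m)


class TestLogAndCentering:
    def test_log2_known_values(self):
        m = _counts([[0.0], [3.0]])
        out = log2_with_pseudocount(m, 1.0)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 2.0])
        assert out.scale == "log2"

    @given(
        values=st.lists(st.floats(0, 1e6), min_size=2, max_size=8, unique=True)
    )
    def test_log2_monotone(self, values):
        ordered = np.sort(np.array(values))
        m = _counts(ordered[:, None])
        out = log2_with_pseudocount(m, 1.0)
        assert (np.diff(out.values[:, 0]) >= 0).all()

    def test_median_center_constant_gene_zero(self):
        m = _log2([[5.0, 5.0, 5.0]])
        np.testing.assert_allclose(median_center_genes(m).values, 0.0)

    def test_median_center_idempotent(self, small_log2):
        once = median_center_genes(small_log2)
        twice = median_center_genes(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_median_center_odd_count_hits_zero(self):
        m = _log2([[1.0, 2.0, 3.0, 4.0, 5.0]])
        out = median_center_genes(m)
        assert (out.values == 0).sum() == 1


class TestWelch:
    def test_hand_computed_example(self):
        m = _log2([[0, 1, 2, 3, 4, 5]], samples=list("abcdef"))
        t = welch_t(m, ["a", "b", "c"], ["d", "e", "f"])
        assert t.iloc[0] == pytest.approx(3 / math.sqrt(2 / 3), rel=1e-12)

    def test_identical_constant_groups_give_zero(self):
        m = _log2([[2, 2, 2, 2]], samples=list("abcd"))
        assert welch_t(m, ["a", "b"], ["c", "d"]).iloc[0] == 0.0

    def test_constant_groups_unequal_means_give_inf(self):
        m = _log2([[1, 1, 3, 3]], samples=list("abcd"))
        assert welch_t(m, ["a", "b"], ["c", "d"]).iloc[0] == np.inf
        assert welch_t(m, ["c", "d"], ["a", "b"]).iloc[0] == -np.inf

    def test_antisymmetric_under_label_swap(self, small_log2):
        s = small_log2.sample_ids
        t1 = welch_t(small_log2, s[:3], s[3:])
        t2 = welch_t(small_log2, s[3:], s[:3])
        np.testing.assert_allclose(t1.to_numpy(), -t2.to_numpy())

    def test_matches_scipy_on_random_data(self, small_log2):
        import scipy.stats

        s = small_log2.sample_ids
        t = welch_t(small_log2, s[:3], s[3:])
        ref = scipy.stats.ttest_ind(
            small_log2.data[s[3:]], small_log2.data[s[:3]],
            axis=1, equal_var=False,
        ).statistic
        np.testing.assert_allclose(t.to_numpy(), ref, rtol=1e-10)

    def test_group_overlap_rejected(self, small_log2):
        s = small_log2.sample_ids
        with pytest.raises(ValidationError):
            welch_t(small_log2, s[:3], s[2:5])


def _bh_brute_force(p):
    """Literal step-up: q_(i) = min_{j>=i} m p_(j) / j, clipped to 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_step_up_definition(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)


class TestCallDE:
    def test_planted_four_fold_gene_called_up(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(50, 20)).astype(float)
        base[0, 10:] *= 4  # planted 4-fold gene
        m = _counts(base)
        result = call_de(m, [f"s{i}" for i in range(10)],
                         [f"s{i}" for i in range(10, 20)])
        assert result.loc["g0", "call"] == "up"

    def test_small_fold_change_never_called(self):
        # 1.5-fold with essentially no noise: significant p but below the
        # two-fold threshold, so the call must stay "none"
        values = np.ones((5, 20)) * 100
        values[0, 10:] = 150
        values += np.random.default_rng(1).normal(0, 0.5, values.shape)
        m = _counts(np.clip(values, 0, None))
        result = call_de(m, [f"s{i}" for i in range(10)],
                         [f"s{i}" for i in range(10, 20)])
        assert result.loc["g0", "q"] < 0.05
        assert result.loc["g0", "call"] == "none"

    def test_invariant_under_gene_order(self, small_counts):
        s = small_counts.sample_ids
        r1 = call_de(small_counts, s[:2], s[2:])
        shuffled = ExpressionMatrix(
            small_counts.data.iloc[::-1], "counts"
        )
        r2 = call_de(shuffled, s[:2], s[2:])
        pd.testing.assert_frame_equal(r1.sort_index(), r2.sort_index())


class TestOverlapAndVariance:
    def test_identical_lists_zero_exclusive(self):
        venn = overlap_counts({"a", "b"}, {"c"}, {"a", "b"}, {"c"})
        assert venn.loc["up", "a_only"] == 0
        assert venn.loc["up", "both"] == 2
        assert venn.loc["down", "b_only"] == 0

    def test_disjoint_lists_zero_intersection(self):
        venn = overlap_counts({"a"}, set(), {"b"}, set())
        assert venn.loc["up", "both"] == 0

    def test_gene_in_up_and_down_rejected(self):
        with pytest.raises(ValidationError):
            overlap_counts({"a"}, {"a"}, set(), set())

    @given(st.integers(0, 2**31 - 1))
    def test_counts_equal_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(30)]
        a_up = set(rng.choice(pool, 10, replace=False))
        b_up = set(rng.choice(pool, 10, replace=False))
        a_down = set(rng.choice(sorted(set(pool) - a_up), 5, replace=False))
        b_down = set(rng.choice(sorted(set(pool) - b_up), 5, replace=False))
        venn = overlap_counts(a_up, a_down, b_up, b_down)
        assert venn.loc["up", "both"] == len(a_up & b_up)
        assert venn.loc["down", "a_only"] == len(a_down - b_down)

    def test_fraction_one_returns_all(self, small_log2):
        assert set(top_variable_genes(small_log2, 1.0)) == set(small_log2.gene_ids)

    def test_zero_variance_gene_excluded(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 5))
        values[4] = 1.0  # constant gene
        m = _log2(values)
        top = top_variable_genes(m, 0.5)
        assert "g4" not in top

    def test_matches_brute_force_sort(self, small_log2):
        top = top_variable_genes(small_log2, 0.3)
        var = small_log2.data.var(axis=1, ddof=1)
        expected = sorted(
            small_log2.gene_ids, key=lambda g: (-var[g], g)
        )[: len(top)]
        assert top == expected
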