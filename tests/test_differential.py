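"""Moderated-difference test, fudge factor, rank-sum screen, BH, Ig filter."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bcellsig as b
from bcellsig.containers import ConfigurationError
from conftest import matrix_from_array, two_group_annotation


def _oracle_d(X, a_cols, b_cols, s0):
    """Plain-formula moderated difference, independent of the implementation."""
    A, B = X[:, a_cols], X[:, b_cols]
    n1, n2 = len(a_cols), len(b_cols)
    ma, mb = A.mean(1), B.mean(1)
    ss = ((A - ma[:, None]) ** 2).sum(1) + ((B - mb[:, None]) ** 2).sum(1)
    s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return (ma - mb) / (s + s0)


class TestSam:
    def test_equal_group_means_give_d_zero(self, tiny):
        matrix, annotation = tiny
        expressed = b.filter_expressed(matrix, annotation).matrix
        res = b.sam_test(expressed, annotation, n_perm=50, seed=0)
        assert res.table.loc["TP006_at", "d"] == 0.0
        assert res.table.loc["TP006_at", "q"] > 0.5

    def test_permutation_p_matches_exact_enumeration(self):
        """3-vs-3: sampled-null p equals enumeration over all 20 splits."""
        rng = np.random.default_rng(4)
        X = rng.normal(7, 1, (15, 6))
        X[0, 3:] += 2.5  # one shifted gene
        m = matrix_from_array(X)
        ann = two_group_annotation(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        res = b.sam_test(m, ann, n_perm=50, seed=0)
        assert res.exact and res.n_permutations == 20

        d_obs = _oracle_d(X, [0, 1, 2], [3, 4, 5], res.s0)
        expected = np.zeros(15)
        for a_cols in itertools.combinations(range(6), 3):
            b_cols = [c for c in range(6) if c not in a_cols]
            d_perm = _oracle_d(X, list(a_cols), b_cols, res.s0)
            expected += np.abs(d_perm) >= np.abs(d_obs) - 1e-12
        expected /= 20
        assert np.allclose(res.table["p_perm"].values, expected)

    def test_d_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(8)
        m = matrix_from_array(rng.normal(6, 1, (30, 10)))
        a, bb = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        ann = two_group_annotation(a, bb)
        r1 = b.sam_test(m, ann, n_perm=100, seed=0)
        r2 = b.sam_test(m, ann, group_a="control", group_b="patient", n_perm=100, seed=0)
        assert np.allclose(r1.table["d"].values, -r2.table["d"].values)

    def test_small_group_rejected(self):
        m = matrix_from_array(np.ones((5, 3)) * 6)
        ann = two_group_annotation(["s0"], ["s1", "s2"])
        with pytest.raises(ConfigurationError):
            b.sam_test(m, ann)

    def test_n_called_non_increasing_in_delta(self, small_expressed, small_study):
        _, _, annotation, _, _, _ = small_study
        res = b.sam_test(small_expressed, annotation, n_perm=100, seed=5)
        g = res.delta_grid.sort_values("delta")
        assert (g["n_called"].diff().dropna() <= 0).all()
        assert res.table["q"].between(0, 1).all()
        # q is monotone non-increasing in |d|
        t = res.table.sort_values("d", key=np.abs)
        assert (t["q"].diff().dropna() <= 1e-12).all()


class TestS0:
    def test_all_equal_s_returns_common_value(self):
        s = np.full(50, 0.7)
        assert b.compute_s0(np.linspace(-1, 1, 50), s) == 0.7
        assert b.compute_s0(np.linspace(-1, 1, 50), np.zeros(50)) == 0.0

    def test_zero_s0_reduces_to_plain_ratio(self):
        rng = np.random.default_rng(3)
        diff = rng.normal(0, 1, 40)
        s = rng.uniform(0.5, 1.5, 40)
        assert np.allclose(diff / (s + 0.0), diff / s)

    def test_within_one_grid_step_of_fine_search(self):
        """Coarse 5%-grid choice sits next to an exhaustive 1%-grid optimum."""
        rng = np.random.default_rng(12)
        n = 2000
        s = rng.gamma(2.0, 0.15, n)
        diff = rng.normal(0, 1, n) * (s + 0.1)  # heteroscedastic differences
        chosen = b.compute_s0(diff, s)

        def cv_of(s0, n_windows=n // 10):
            d = diff / (s + s0)
            edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
            w = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
            med = np.array(
                [np.median(np.abs(d[w == i])) for i in range(n_windows)]
            )
            return med.std(ddof=1) / med.mean()

        fine = np.percentile(s, np.arange(0, 101, 1))
        best_fine = fine[np.argmin([cv_of(v) for v in fine])]
        coarse = np.percentile(s, np.arange(0, 101, 5))
        step = np.max(np.abs(np.diff(coarse)))
        assert abs(chosen - best_fine) <= step + 1e-12


class TestWilcoxon:
    def test_exact_p_for_separated_triples(self):
        m = matrix_from_array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        ann = two_group_annotation(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        p = b.wilcoxon_screen(m, ann, alternative="less")
        assert np.isclose(p.iloc[0], 1 / 20)

    def test_constant_gene_p_one(self):
        m = matrix_from_array([[5.0] * 6])
        ann = two_group_annotation(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert b.wilcoxon_screen(m, ann).iloc[0] == 1.0

    def test_label_swap_leaves_two_sided_p(self):
        rng = np.random.default_rng(17)
        m = matrix_from_array(rng.normal(6, 1, (25, 8)))
        a, bb = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        p1 = b.wilcoxon_screen(m, two_group_annotation(a, bb))
        p2 = b.wilcoxon_screen(m, two_group_annotation(bb, a))
        assert np.allclose(p1.values, p2.values)


class TestBhFdr:
    def test_hand_example(self):
        q = b.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_cases(self):
        assert (b.bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()
        assert np.isclose(b.bh_fdr([0.3])[0], 0.3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_tail_minimum(self, pvals):
        """q_(i) = min_{j>=i} p_(j) * m / j, computed the slow way."""
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            tail = [
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            ]
            brute[idx] = min(1.0, min(tail))
        assert np.allclose(b.bh_fdr(p), brute)


class TestIgStripping:
    @pytest.mark.parametrize(
        "symbol,removed",
        [
            ("IGHG1", True),
            ("ighm", True),
            ("IGKC", True),
            ("IGLV1-44", True),
            ("IGJ", True),
            ("IG@", True),
            ("IGF1", False),
            ("IGSF3", False),
            ("", False),
            ("EGR1", False),
        ],
    )
    def test_pattern(self, symbol, removed):
        assert b.is_ig_symbol(symbol) is removed

    def test_table_split_records_removed(self):
        t = pd.DataFrame({"gene_symbol": ["IGHG1", "EGR1", "", "IGKV4-1"], "d": range(4)})
        with pytest.warns(UserWarning):
            kept, removed = b.strip_ig_genes(t)
        assert list(kept["gene_symbol"]) == ["EGR1", ""]
        assert list(removed["gene_symbol"]) == ["IGHG1", "IGKV4-1"]
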