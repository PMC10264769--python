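"""Paired tests, ANOVA + LSD letters, OLS/SMA, PCA, hull overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydrotrait import comparative
from hydrotrait.exceptions import ComputationError, InputError


def make_table(flower, leaf, trait="x"):
    rows = []
    for i, (f, l) in enumerate(zip(flower, leaf)):
        rows.append({"species": f"sp{i:02d}", "organ": "flower", trait: f})
        rows.append({"species": f"sp{i:02d}", "organ": "leaf", trait: l})
    return comparative.TraitTable(pd.DataFrame(rows).set_index(["species", "organ"]))


class TestPairedT:
    def test_identical_organs(self):
        t = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = comparative.paired_t(t, "x")
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed_differences(self):
        # differences (1, 2, 0): mean 1, sd 1, t = sqrt(3), df 2
        t = make_table([2.0, 4.0, 3.0], [1.0, 2.0, 3.0])
        res = comparative.paired_t(t, "x")
        assert res.t == pytest.approx(math.sqrt(3.0), rel=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(2 * stats.t.sf(math.sqrt(3), 2), rel=1e-12)

    def test_antisymmetric_under_organ_swap(self):
        t = make_table([2.0, 4.0, 3.0], [1.0, 2.0, 3.5])
        a = comparative.paired_t(t, "x", "flower", "leaf")
        b = comparative.paired_t(t, "x", "leaf", "flower")
        assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)

    def test_equals_one_sample_t_on_differences(self, rng):
        f = rng.normal(5, 1, 10)
        l = rng.normal(4, 1, 10)
        res = comparative.paired_t(make_table(f, l), "x")
        ref = stats.ttest_1samp(f - l, 0.0)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_nonzero_differences_undefined(self):
        t = make_table([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        with pytest.raises(ComputationError):
            comparative.paired_t(t, "x")

    def test_missing_values_reduce_pairs(self):
        t = make_table([2.0, 4.0, float("nan"), 5.0], [1.0, 2.0, 3.0, 1.0])
        assert comparative.paired_t(t, "x").n == 3


class TestAnovaLSD:
    def test_two_separated_groups_get_distinct_letters(self):
        res = comparative.anova_lsd({"lo": [10, 11, 12], "hi": [100, 101, 102]})
        assert res.letters["hi"] == "a" and res.letters["lo"] == "b"

    def test_identical_distributions_share_letter(self, rng):
        g = {k: rng.normal(0, 1, 8) for k in "abc"}
        res = comparative.anova_lsd({k: v.copy() for k, v in g.items()})
        if res.p >= 0.05:  # protected LSD: no post hoc when omnibus is null
            assert len(set(res.letters.values())) == 1

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        res = comparative.anova_lsd({"a": a, "b": b})
        t = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_letters_invariant_to_input_order(self, rng):
        groups = {
            "fern": rng.normal(11, 1, 6), "gym": rng.normal(175, 10, 6),
            "leaf": rng.normal(13, 1, 6), "flower": rng.normal(9.4, 1, 6),
        }
        a = comparative.anova_lsd(groups)
        b = comparative.anova_lsd(dict(reversed(list(groups.items()))))
        assert a.letters == b.letters

    def test_intermediate_group_shares_letters(self):
        # lo and hi differ; mid straddles both
        res = comparative.anova_lsd(
            {"lo": [1.0, 1.2, 0.8], "mid": [2.0, 2.4, 1.8], "hi": [3.1, 2.9, 3.3]},
            alpha=0.01,
        )
        sig = res.pairwise_p
        if sig.loc["lo", "hi"] < 0.01 and sig.loc["lo", "mid"] >= 0.01 and sig.loc["mid", "hi"] >= 0.01:
            assert set(res.letters["mid"]) & set(res.letters["lo"])
            assert set(res.letters["mid"]) & set(res.letters["hi"])
            assert not set(res.letters["lo"]) & set(res.letters["hi"])

    def test_small_group_raises(self):
        with pytest.raises(InputError):
            comparative.anova_lsd({"a": [1.0], "b": [1.0, 2.0]})


class TestRegression:
    def test_ols_exact_line(self):
        x = np.arange(10.0)
        res = comparative.ols(x, 3 * x + 1)
        assert res.slope == pytest.approx(3.0) and res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_r2_symmetric(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        assert comparative.ols(x, y).r2 == pytest.approx(comparative.ols(y, x).r2, rel=1e-12)

    def test_ols_slope_recovery(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=1000)
        y = 2 * x + rng.normal(size=1000)
        assert 1.9 < comparative.ols(x, y).slope < 2.1

    def test_sma_exact_line(self):
        x = np.array([1.0, 2, 3, 4])
        res = comparative.sma(x, 2 * x)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(0.0)
        assert res.r2 == pytest.approx(1.0)

    def test_sma_negative_correlation_closed_form(self, rng):
        x = rng.normal(0, 1.0, 200)
        y = -3.0 * x + rng.normal(0, 0.3, 200)
        res = comparative.sma(x, y)
        assert res.slope == pytest.approx(-np.std(y, ddof=1) / np.std(x, ddof=1), rel=1e-12)
        assert res.slope < 0

    def test_sma_identities_on_random_data(self, rng):
        """|slope| = sd_y/sd_x; reciprocity; SMA = OLS/|r| — 100 datasets."""
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(rng.normal(), abs(rng.normal()) + 0.5, n)
            y = rng.normal() * x + rng.normal(0, abs(rng.normal()) + 0.5, n)
            s = comparative.sma(x, y)
            assert abs(s.slope) == pytest.approx(np.std(y, ddof=1) / np.std(x, ddof=1), rel=1e-9)
            assert s.slope * comparative.sma(y, x).slope == pytest.approx(1.0, rel=1e-9)
            o = comparative.ols(x, y)
            r = np.corrcoef(x, y)[0, 1]
            assert s.slope == pytest.approx(o.slope / abs(r), rel=1e-9)
            assert np.sign(s.slope) == np.sign(r)

    def test_zero_variance_raises(self):
        with pytest.raises(InputError):
            comparative.sma([1, 1, 1, 1], [1, 2, 3, 4])


class TestPCA:
    def _table(self, X, traits):
        idx = pd.MultiIndex.from_tuples(
            [(f"sp{i:02d}", "flower" if i % 2 else "leaf") for i in range(len(X))],
            names=["species", "organ"],
        )
        return comparative.TraitTable(pd.DataFrame(X, index=idx, columns=traits))

    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=20)
        res = comparative.pca(self._table(np.column_stack([x, 3 * x]), ["a", "b"]))
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(15, 6))
        res = comparative.pca(self._table(X, list("abcdef")))
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_equal_fractions(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(4000, 3))
        res = comparative.pca(self._table(X, list("abc")))
        assert np.allclose(res.explained, 1 / 3, atol=0.05)

    def test_reconstruction_from_all_pcs(self, rng):
        X = rng.normal(size=(12, 5))
        t = self._table(X, list("abcde"))
        res = comparative.pca(t)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Z).max() < 1e-10

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(20, 4))
        L = comparative.pca(self._table(X, list("abcd"))).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)

    def test_missing_rows_dropped_and_logged(self, rng):
        X = rng.normal(size=(10, 3))
        X[2, 1] = np.nan
        res = comparative.pca(self._table(X, list("abc")))
        assert len(res.dropped) == 1 and len(res.scores) == 9

    def test_constant_column_named(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 2] = 4.2
        with pytest.raises(InputError, match="c"):
            comparative.pca(self._table(X, list("abc")))


class TestHullOverlap:
    def test_identical_sets(self):
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [1, 1]], float)
        res = comparative.hull_overlap(np.vstack([pts, pts]), ["a"] * 5 + ["b"] * 5)
        assert res.iou == pytest.approx(1.0)

    def test_disjoint_clusters(self, rng):
        a = rng.normal(0, 0.1, (10, 2))
        b = rng.normal(100, 0.1, (10, 2))
        res = comparative.hull_overlap(np.vstack([a, b]), ["a"] * 10 + ["b"] * 10)
        assert res.iou == 0.0

    def test_offset_unit_squares_analytic(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        shifted = sq + [0.5, 0.0]
        res = comparative.hull_overlap(np.vstack([sq, shifted]), ["a"] * 4 + ["b"] * 4)
        assert res.iou == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_collinear_group_flagged(self):
        line = np.array([[0, 0], [1, 1], [2, 2]], float)
        tri = np.array([[0, 1], [1, 0], [2, 3]], float)
        res = comparative.hull_overlap(np.vstack([line, tri]), ["a"] * 3 + ["b"] * 3)
        assert res.degenerate == ["a"] and res.iou == 0.0
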