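"""Spearman screening, BH-FDR adjustment and follow-up group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ffqpipe import bh_adjust, group_tests, linear_by_linear, spearman_screen


# --------------------------------------------------------------------------
# bh_adjust
# --------------------------------------------------------------------------


def stepup_reject(p, m, alpha):
    """Textbook BH step-up: largest k with p_(k) <= k*alpha/m; reject all
    smaller p. Independent of the q-value path."""
    p = np.asarray(p)
    order = np.argsort(p)
    k_star = 0
    for k, idx in enumerate(order, start=1):
        if p[idx] <= k * alpha / m:
            k_star = k
    reject = np.zeros(p.size, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04], 3), [0.03, 0.03, 0.04]
        )

    def test_single_p_is_identity(self):
        assert bh_adjust([0.05], 1)[0] == pytest.approx(0.05)

    def test_capped_at_one(self):
        assert bh_adjust([0.5], 10)[0] == 1.0

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5], 2)
        with pytest.raises(ValueError):
            bh_adjust([1.5], 1)

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], 1)

    def test_matches_stepup_oracle_on_random_vectors(self):
        """q <= alpha reproduces the step-up reject set on 500 random
        p-vectors, including families larger than the vector."""
        rng = np.random.default_rng(2024)
        for _ in range(500):
            k = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1.0, size=k)
            m = k + rng.integers(0, 20)
            alpha = rng.choice([0.01, 0.05, 0.1])
            q = bh_adjust(p, m)
            np.testing.assert_array_equal(q <= alpha, stepup_reject(p, m, alpha))

    def test_matches_statsmodels_when_family_equals_vector(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, 50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p, 50), q_sm, rtol=1e-12)

    def test_q_dominates_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1, 30)
        assert (bh_adjust(p, 40) >= p - 1e-15).all()


# --------------------------------------------------------------------------
# spearman_screen
# --------------------------------------------------------------------------


class TestSpearmanScreen:
    def test_perfect_monotone(self):
        cov = pd.DataFrame({"x": [1, 2, 3, 4, 5]}, index=list("abcde"))
        diet = pd.DataFrame({"y": [2, 4, 6, 8, 10]}, index=list("abcde"))
        t = spearman_screen(cov, diet).table
        assert t.loc[0, "rho"] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        cov = pd.DataFrame({"x": [1, 2, 3]}, index=list("abc"))
        diet = pd.DataFrame({"y": [3, 2, 1]}, index=list("abc"))
        assert spearman_screen(cov, diet).table.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_variable_gives_missing(self):
        cov = pd.DataFrame({"x": [1, 1, 1, 1]}, index=list("abcd"))
        diet = pd.DataFrame({"y": [1, 2, 3, 4]}, index=list("abcd"))
        t = spearman_screen(cov, diet).table
        assert np.isnan(t.loc[0, "rho"])

    def test_pairwise_deletion(self):
        cov = pd.DataFrame({"x": [1, 2, np.nan, 4, 5]}, index=list("abcde"))
        diet = pd.DataFrame({"y": [5, 4, 3, 2, 1]}, index=list("abcde"))
        t = spearman_screen(cov, diet).table
        assert t.loc[0, "n_pairs"] == 4
        assert t.loc[0, "rho"] == pytest.approx(-1.0)

    @given(
        sign=st.sampled_from([1.0, -1.0]),
        transform=st.sampled_from(["exp", "cube", "rank"]),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_monotone_transforms(self, sign, transform, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.8, size=30)
        f = {"exp": np.exp, "cube": lambda v: v**3,
             "rank": lambda v: stats.rankdata(v)}[transform]
        r1 = stats.spearmanr(x, y).statistic
        cov = pd.DataFrame({"x": sign * f(x)}, index=range(30))
        diet = pd.DataFrame({"y": y}, index=range(30))
        r2 = spearman_screen(cov, diet).table.loc[0, "rho"]
        assert r2 == pytest.approx(sign * r1, abs=1e-9)

    def test_external_family_size_inflates_q(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"x": rng.normal(size=40)})
        diet = pd.DataFrame({"y": rng.normal(size=40)})
        small = spearman_screen(cov, diet, total_tests=1).table.loc[0, "q"]
        large = spearman_screen(cov, diet, total_tests=100).table.loc[0, "q"]
        assert large >= small


# --------------------------------------------------------------------------
# group tests
# --------------------------------------------------------------------------


class TestGroupTests:
    def test_planted_binary_contrast_detected(self):
        """Zero-inflated consumption in one group vs all-zero in the other,
        mirroring a smoking vs sugary-drink contrast."""
        rng = np.random.default_rng(3)
        x = pd.Series([0] * 100 + [1] * 25, name="smoking")
        y0 = np.zeros(100)
        y1 = np.where(rng.random(25) < 0.5, rng.uniform(10, 80, 25), 0.0)
        y = pd.Series(np.concatenate([y0, y1]), name="sugary")
        res = group_tests(x, y, "binary")
        assert res.test == "Mann-Whitney U"
        assert res.p < 0.05
        g = res.groups.set_index("group")
        assert g.loc[0, "median"] == 0.0

    def test_null_rejection_rate_near_alpha(self):
        """Identical distributions in two groups of 50: rejection at 0.05
        happens for about 5% of 1,000 seeded replicates."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            y = pd.Series(rng.normal(size=100))
            x = pd.Series([0] * 50 + [1] * 50)
            if group_tests(x, y, "binary").p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07

    def test_kruskal_detects_shifted_group(self):
        rng = np.random.default_rng(4)
        x = pd.Series([0] * 40 + [1] * 40 + [2] * 40, name="level")
        y = pd.Series(
            np.concatenate(
                [rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)]
            )
        )
        res = group_tests(x, y, "multilevel")
        assert res.test == "Kruskal-Wallis"
        assert res.p < 0.01
        assert len(res.groups) == 3

    def test_fisher_on_2x2(self):
        x = pd.Series([0] * 20 + [1] * 20)
        y = pd.Series([0] * 18 + [1] * 2 + [0] * 6 + [1] * 14)
        res = group_tests(x, y, "categorical_outcome")
        assert res.test == "Fisher exact"
        assert res.p < 0.001

    def test_empty_group_is_skipped(self):
        x = pd.Series([0, 0, 0], name="g")
        y = pd.Series([1.0, 2.0, 3.0], name="v")
        res = group_tests(x, y, "binary")
        assert res.test == "skipped"

    def test_linear_by_linear_matches_known_value(self):
        # 2x3 table with a clear trend; M^2 = (N-1) * r^2
        table = np.array([[20, 10, 5], [5, 10, 20]])
        m2, p = linear_by_linear(table)
        n = table.sum()
        # independent computation of the score correlation
        rows = np.repeat([0, 1], table.sum(axis=1))
        cols = np.concatenate(
            [np.repeat([0, 1, 2], table[0]), np.repeat([0, 1, 2], table[1])]
        )
        r = np.corrcoef(rows, cols)[0, 1]
        assert m2 == pytest.approx((n - 1) * r**2)
        assert p < 0.001


class TestTypeIError:
    def test_null_screen_q_below_alpha_rate(self):
        """Under a global null the share of cells with q < 0.05 stays at or
        below 0.05 (within Monte-Carlo error) over 1,000 replicates."""
        rng = np.random.default_rng(99)
        n, cells_per_rep, reps = 60, 8, 1000
        flagged = total = 0
        for _ in range(reps):
            cov = pd.DataFrame(
                {
                    "bin": rng.integers(0, 2, n),
                    "ord": rng.integers(0, 4, n),
                }
            )
            diet = pd.DataFrame(rng.normal(size=(n, cells_per_rep // 2)))
            t = spearman_screen(cov, diet).table
            flagged += int((t["q"] < 0.05).sum())
            total += len(t)
        rate = flagged / total
        # MC error on 8000 cells is ~0.25 pp; the BH bound makes the true
        # per-cell rate far below alpha under the global null
        assert rate <= 0.05 + 0.005
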