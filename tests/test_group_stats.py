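"""Rank-based omnibus and post hoc machinery, letters, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microclim.errors import DegenerateDataError, ValidationError
from microclim.group_stats import (
    compact_letters,
    kruskal_wallis,
    nemenyi_posthoc,
    paired_t_test,
    shapiro_wilk,
    table1_analogue,
)


class TestShapiro:
    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([3.0] * 10)

    def test_bimodal_sample_rejected_at_1pct(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.normal(-4, 0.5, 50), rng.normal(4, 0.5, 50)])
        w, p = shapiro_wilk(x)
        assert p < 0.01

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(23)
        rejections = sum(
            shapiro_wilk(rng.normal(0, 1, 40))[1] < 0.05 for _ in range(300)
        )
        assert 4 <= rejections <= 30  # ~15 expected at alpha 5%


class TestKruskalWallis:
    def test_hand_ranking_oracle(self):
        groups = [[1.0, 2.0, 3.0], [11.0, 12.0, 13.0], [21.0, 22.0, 23.0]]
        h, df, p = kruskal_wallis(groups)
        # brute force: ranks are 1..9 in group order, no ties
        n, N = 3, 9
        mean_ranks = [2.0, 5.0, 8.0]
        h_oracle = 12 / (N * (N + 1)) * sum(n * r**2 for r in mean_ranks) - 3 * (N + 1)
        assert h == pytest.approx(h_oracle, abs=1e-12)
        assert df == 2

    def test_two_identical_groups_give_zero_h(self):
        h, df, p = kruskal_wallis([[4.0, 4.0, 4.0], [4.0, 4.0, 4.0]])
        assert h == 0.0 and p == 1.0

    def test_group_size_validation(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0, 2.0]])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        groups = [rng.normal(i, 1, 15) for i in range(3)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(41)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 12) for _ in range(3)]
            _, _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 6 <= rejections <= 40  # ~20 expected


class TestNemenyi:
    def test_identical_groups_give_p_near_one(self):
        res = nemenyi_posthoc([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert res.p_matrix.iloc[0, 1] > 0.95

    def test_well_separated_groups_all_significant(self):
        # rank statistics saturate: with k=4 groups an adjacent pair needs
        # n of order 10^2 before its Nemenyi p can cross 0.001, however far
        # apart the groups are on the raw scale
        rng = np.random.default_rng(6)
        groups = [rng.normal(50 * i, 1, 80) for i in range(4)]
        res = nemenyi_posthoc(groups)
        off = res.p_matrix.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off < 0.001).all()

    def test_matrix_symmetric_with_nan_diagonal(self):
        rng = np.random.default_rng(7)
        res = nemenyi_posthoc([rng.normal(i, 1, 10) for i in range(3)])
        P = res.p_matrix.to_numpy()
        assert np.isnan(np.diag(P)).all()
        assert np.allclose(P, P.T, equal_nan=True)

    def test_agrees_with_permutation_null(self):
        # family-wise (max-q) permutation null of the same rank statistic
        rng = np.random.default_rng(19)
        k, n = 4, 20
        groups = [rng.normal(0.55 * i, 1, n) for i in range(k)]
        res = nemenyi_posthoc(groups)
        pooled = np.concatenate(groups)
        N = k * n
        se = np.sqrt(N * (N + 1) / 12.0 * (2.0 / n))
        n_perm = 3000
        maxq = np.empty(n_perm)
        for b in range(n_perm):
            r = stats.rankdata(pooled[rng.permutation(N)]).reshape(k, n).mean(axis=1)
            maxq[b] = (r.max() - r.min()) / se
        for i in range(k):
            for j in range(i + 1, k):
                p_perm = float((maxq >= res.statistic.iloc[i, j]).mean())
                assert res.p_matrix.iloc[i, j] == pytest.approx(p_perm, abs=0.04)

    def test_chisq_variant_is_more_conservative_than_tukey_here(self):
        rng = np.random.default_rng(29)
        groups = [rng.normal(0.8 * i, 1, 15) for i in range(3)]
        tukey = nemenyi_posthoc(groups, method="tukey")
        chisq = nemenyi_posthoc(groups, method="chisq")
        assert (
            chisq.p_matrix.iloc[0, 1] != tukey.p_matrix.iloc[0, 1]
        )  # distinct reference distributions


def _pm(mat, labels=None):
    labels = labels or [f"g{i}" for i in range(len(mat))]
    return pd.DataFrame(np.asarray(mat, dtype=float), index=labels, columns=labels)


class TestCompactLetters:
    def test_all_pairs_significant_get_distinct_letters(self):
        P = _pm([[np.nan, 0.0001, 0.0001], [0.0001, np.nan, 0.0001],
                 [0.0001, 0.0001, np.nan]])
        letters = compact_letters(P, alpha=0.001)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_no_pair_significant_shares_single_letter(self):
        P = _pm([[np.nan, 0.5, 0.9], [0.5, np.nan, 0.7], [0.9, 0.7, np.nan]])
        assert set(compact_letters(P, alpha=0.001).values()) == {"a"}

    def test_chain_case_middle_group_carries_two_letters(self):
        # A~B and B~C but A is different from C
        P = _pm([[np.nan, 0.5, 0.0001], [0.5, np.nan, 0.5], [0.0001, 0.5, np.nan]],
                labels=["A", "B", "C"])
        letters = compact_letters(P, alpha=0.001)
        assert len(letters["B"]) == 2
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])

    @given(st.integers(min_value=2, max_value=7), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=120, deadline=None)
    def test_iff_sharing_contract_on_random_matrices(self, k, seed):
        rng = np.random.default_rng(seed)
        P = np.full((k, k), np.nan)
        iu = np.triu_indices(k, 1)
        vals = rng.choice([1e-6, 0.0005, 0.002, 0.5], size=len(iu[0]))
        P[iu] = vals
        P[(iu[1], iu[0])] = vals
        letters = compact_letters(_pm(P), alpha=0.001)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(letters[f"g{i}"]) & set(letters[f"g{j}"]))
                assert share == (P[i, j] >= 0.001)


class TestPairedT:
    def test_identical_columns_defined_degenerate(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = paired_t_test(x, x)
        assert res.p == 1.0 and res.mean_diff == 0.0

    def test_constant_nonzero_shift_degenerate_error(self):
        with pytest.raises(DegenerateDataError):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_shift_with_noise_detected_at_n31(self):
        rng = np.random.default_rng(37)
        x = rng.normal(10, 1, 31)
        y = x + 1.0 + rng.normal(0, 0.3, 31)
        res = paired_t_test(x, y)
        assert res.p < 0.001 and res.mean_diff > 0.5

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(43)
        pvals = []
        for _ in range(800):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            pvals.append(paired_t_test(x, y).p)
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_length_validation(self):
        with pytest.raises(ValidationError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTable1:
    def _daily(self, values, start="2022-03-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.DataFrame(
            {
                "t_mean": values,
                "t_min": np.asarray(values) - 2,
                "t_max": np.asarray(values) + 2,
                "drt": np.full(len(values), 4.0),
                "rh_mean": 50.0,
                "rh_min": 40.0,
                "n_obs": 6,
            },
            index=idx,
        )

    def test_single_vegetation_type_gets_letter_a(self):
        rng = np.random.default_rng(3)
        daily = {"s1": self._daily(rng.normal(8, 2, 365))}
        out = table1_analogue(daily, {"s1": "NotDomb"})
        assert list(out.index) == ["NotDomb"]
        assert out.loc["NotDomb", "mdt_365d_letters"] == "a"

    def test_identical_types_share_a_letter(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(8, 2, 365)
        daily = {"s1": self._daily(vals), "s2": self._daily(vals)}
        out = table1_analogue(daily, {"s1": "A", "s2": "B"})
        assert set(out.loc["A", "mdt_365d_letters"]) & set(
            out.loc["B", "mdt_365d_letters"]
        )

    def test_well_separated_types_differ(self):
        rng = np.random.default_rng(5)
        daily = {
            "s1": self._daily(rng.normal(0, 1, 365)),
            "s2": self._daily(rng.normal(12, 1, 365)),
        }
        out = table1_analogue(daily, {"s1": "cold", "s2": "warm"})
        assert not (
            set(out.loc["cold", "mdt_365d_letters"])
            & set(out.loc["warm", "mdt_365d_letters"])
        )
        assert out.loc["warm", "mdt_365d_mean"] > out.loc["cold", "mdt_365d_mean"]

    def test_site_unit_option_uses_per_site_means(self):
        rng = np.random.default_rng(6)
        daily = {f"s{i}": self._daily(rng.normal(8, 2, 365)) for i in range(4)}
        veg = {f"s{i}": "A" if i < 2 else "B" for i in range(4)}
        out = table1_analogue(daily, veg, unit="sites")
        assert len(out) == 2 and np.isfinite(out.mdt_365d_mean).all()
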