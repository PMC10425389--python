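"""Rank-based group comparison: KW, Dunn/BH, letter display, correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from turfscreen import (
    GroupSample,
    PairwiseTable,
    bh_adjust,
    dunn_test,
    kruskal_wallis,
    letter_display,
    pearson_r,
    rank_letter_table,
)
from turfscreen.errors import ConfigError, UndefinedStatisticError


def groups_of(*samples, prefix="g"):
    return [GroupSample(f"{prefix}{i}", s) for i, s in enumerate(samples, 1)]


class TestKruskalWallis:
    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(0)
        groups = groups_of(*[rng.normal(size=4) for _ in range(20)])
        assert kruskal_wallis(groups).df == 19

    def test_hand_computed_h_without_ties(self):
        # ranks 1..6, mean ranks 2 and 5: H = (12/42)·(3·2.25·2) = 27/7
        res = kruskal_wallis(groups_of([1, 2, 3], [4, 5, 6]))
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_give_zero_h_unit_p(self):
        res = kruskal_wallis(groups_of([1, 2, 3], [1, 2, 3]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_all_constant_degenerate(self):
        with pytest.warns(UserWarning):
            res = kruskal_wallis(groups_of([5.0, 5.0], [5.0, 5.0]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_permutation_mode_same_h_valid_p(self):
        rng = np.random.default_rng(1)
        groups = groups_of(*[rng.normal(size=4) for _ in range(5)])
        chi = kruskal_wallis(groups)
        perm = kruskal_wallis(groups, method="permutation", n_permutations=499,
                              seed=2)
        assert perm.statistic == pytest.approx(chi.statistic)
        assert 0.0 < perm.p_value <= 1.0

    def test_permutation_agrees_with_chi_square_at_moderate_n(self):
        rng = np.random.default_rng(3)
        groups = groups_of(*[rng.normal(loc=m, size=30) for m in (0, 0.5, 1.0)])
        chi = kruskal_wallis(groups)
        perm = kruskal_wallis(groups, method="permutation",
                              n_permutations=4999, seed=4)
        assert perm.p_value == pytest.approx(chi.p_value, abs=0.02)

    def test_chi_square_conservative_at_tiny_group_size(self):
        # known small-sample behavior: rejection below nominal alpha
        rng = np.random.default_rng(5)
        rejections = 0
        n_sims = 600
        for _ in range(n_sims):
            groups = groups_of(*[rng.normal(size=4) for _ in range(20)])
            rejections += kruskal_wallis(groups).p_value < 0.05
        assert rejections / n_sims < 0.05


class TestDunn:
    def test_pair_count(self):
        rng = np.random.default_rng(0)
        res = dunn_test(groups_of(*[rng.normal(size=4) for _ in range(3)]))
        assert len(res.table) == 3

    def test_hand_computed_z_without_ties(self):
        # mean ranks 2.5, 6.5, 10.5; z(1,3) = -8 / sqrt(13·0.5)
        res = dunn_test(groups_of([1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]))
        z13 = res.table.set_index(["group1", "group2"]).loc[("g1", "g3"), "z"]
        assert z13 == pytest.approx(-8 / np.sqrt(6.5), abs=1e-9)

    def test_identical_groups_z_zero_p_one(self):
        res = dunn_test(groups_of([1, 2, 3], [1, 2, 3]))
        assert res.table.z.iloc[0] == pytest.approx(0.0)
        assert res.table.p_raw.iloc[0] == pytest.approx(1.0)

    def test_adjusted_p_lookup_symmetric(self):
        res = dunn_test(groups_of([1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]))
        assert res.adjusted_p("g1", "g3") == res.adjusted_p("g3", "g1")


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_uniform_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_step_up_properties(self, ps):
        adj = bh_adjust(ps)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        # never below the raw p (step-up minimum starts at m·p/m = p)
        assert (np.asarray(adj) >= np.asarray(ps) - 1e-12).all()


def synthetic_pairwise(means, significant):
    """Build a PairwiseTable directly from a significance relation."""
    names = tuple(means)
    rows = [
        {
            "group1": a,
            "group2": b,
            "z": 0.0,
            "p_raw": 0.001 if frozenset((a, b)) in significant else 0.9,
            "p_adj": 0.001 if frozenset((a, b)) in significant else 0.9,
        }
        for a, b in itertools.combinations(names, 2)
    ]
    return PairwiseTable(groups=names, table=pd.DataFrame(rows))


class TestLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        disp = letter_display(synthetic_pairwise(means, set()), 0.05, means)
        assert set(disp.letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        means = {f"g{i}": float(-i) for i in range(4)}
        sig = {frozenset(p) for p in itertools.combinations(means, 2)}
        disp = letter_display(synthetic_pairwise(means, sig), 0.05, means)
        assert sorted(disp.letters.values()) == ["a", "b", "c", "d"]

    def test_chain_structure_gives_overlapping_letters(self):
        means = {"hi": 3.0, "mid": 2.0, "lo": 1.0}
        sig = {frozenset(("hi", "lo"))}
        disp = letter_display(synthetic_pairwise(means, sig), 0.05, means)
        assert disp.letters == {"hi": "a", "mid": "ab", "lo": "b"}

    def test_soundness_on_random_consistent_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            k = int(rng.integers(3, 9))
            means = {f"g{i}": float(v) for i, v in
                     enumerate(np.sort(rng.uniform(0, 10, k))[::-1])}
            cut = float(rng.uniform(0.5, 6.0))
            sig = {
                frozenset((a, b))
                for a, b in itertools.combinations(means, 2)
                if abs(means[a] - means[b]) > cut
            }
            pairwise = synthetic_pairwise(means, sig)
            disp = letter_display(pairwise, 0.05, means)
            for a, b in itertools.combinations(means, 2):
                share = bool(set(disp.letters[a]) & set(disp.letters[b]))
                assert share == (pairwise.adjusted_p(a, b) >= 0.05), (
                    f"groups {a},{b}: share={share}, "
                    f"p_adj={pairwise.adjusted_p(a, b)}"
                )


class TestPearson:
    def test_perfect_linear(self):
        x = [1, 2, 3, 4, 5]
        r, r2, p = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0]
        r, _, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, r2, p = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert r2 == pytest.approx(0.64)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            pearson_r([1, 2, 3], [1, 2])


class TestPowerAndRanking:
    def test_omnibus_has_real_power_against_one_shifted_group(self):
        # one group displaced by 3 pooled sd: rejection well above alpha
        rng = np.random.default_rng(13)
        n_sims, rejections = 200, 0
        for _ in range(n_sims):
            data = rng.standard_normal((20, 4))
            data[0] += 3.0
            groups = groups_of(*data)
            rejections += kruskal_wallis(groups).p_value < 0.05
        assert rejections / n_sims >= 0.15  # >= 3x the nominal level

    def test_rank_letter_table_sorted_by_descending_mean(self):
        rng = np.random.default_rng(2)
        groups = groups_of(*[rng.normal(loc=m, size=4) for m in (0, 3, 6)])
        table = rank_letter_table(groups, alpha=0.05)
        assert list(table.columns) == ["germplasm", "mean", "sd", "letters"]
        assert (table["mean"].diff().dropna() <= 0).all()
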