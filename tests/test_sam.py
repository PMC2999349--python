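"""Moderated t statistic, fudge factor, permutation null, FDR and q-values."""

import warnings
from math import comb

import numpy as np
import pandas as pd
import pytest

from pcnkit.sam import (
    SAMTwoClass,
    balanced_assignments,
    choose_s0,
    default_delta_grid,
    delta_scan,
    permutation_null,
    q_values,
    sam_statistic,
    select_degs,
)


def brute_force_d(control, treated, s0):
    """Independent direct-formula oracle for the moderated t."""
    control, treated = np.asarray(control), np.asarray(treated)
    n_c, n_t = len(control), len(treated)
    num = treated.mean() - control.mean()
    pooled_var = (
        ((control - control.mean()) ** 2).sum() + ((treated - treated.mean()) ** 2).sum()
    ) / (n_c + n_t - 2)
    s = np.sqrt(pooled_var * (1 / n_c + 1 / n_t))
    return num / (s + s0)


class TestStatistic:
    def test_identical_groups_give_zero(self):
        assert sam_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], s0=0.5) == 0.0

    def test_hand_computed_zero_variance_case(self):
        # constant groups: s = 0, d = (2-1)/(0+0.5) = 2
        d = sam_statistic([1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0], s0=0.5)
        assert d == pytest.approx(2.0)

    def test_swapping_groups_negates_d(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 4), rng.normal(1, 1, 4)
        assert sam_statistic(a, b, 0.1) == pytest.approx(-sam_statistic(b, a, 0.1))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1.0], [2.0, 3.0], 0.1)

    def test_matches_direct_formula_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_c, n_t = rng.integers(2, 7, size=2)
            c, t = rng.normal(0, 1, n_c), rng.normal(0.5, 1.2, n_t)
            s0 = float(rng.uniform(0, 1))
            assert sam_statistic(c, t, s0) == pytest.approx(
                brute_force_d(c, t, s0), abs=1e-12
            )


class TestChooseS0:
    def test_all_s_equal_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert choose_s0(np.ones(200), np.random.default_rng(0).normal(0, 1, 200)) == 0.0

    def test_near_zero_variance_genes_push_s0_positive(self):
        # bimodal s: many near-zero-variance genes whose d would explode
        rng = np.random.default_rng(1)
        s = np.concatenate([np.full(300, 1e-4), rng.uniform(0.5, 1.5, 700)])
        num = rng.normal(0, 0.2, 1000)
        assert choose_s0(s, num) > 0.0

    def test_s0_scales_with_the_data(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.01, 2.0, 500)
        num = rng.normal(0, 1, 500) * s
        s0 = choose_s0(s, num)
        s0_scaled = choose_s0(10.0 * s, 10.0 * num)
        assert s0_scaled == pytest.approx(10.0 * s0, rel=1e-9)


class TestPermutationNull:
    def test_four_vs_four_enumerates_seventy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (50, 8))
        mask = np.array([False] * 4 + [True] * 4)
        null = permutation_null(X, mask, s0=0.1, n_permutations="auto")
        assert null.shape == (comb(8, 4), 50)

    def test_observed_labeling_is_one_of_the_assignments(self):
        masks = balanced_assignments(8, 4, observed=(4, 5, 6, 7), n_permutations="auto")
        observed_row = np.array([False] * 4 + [True] * 4)
        assert any((row == observed_row).all() for row in masks)
        # and the observed assignment reproduces the observed d
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 8))
        null = permutation_null(X, observed_row, s0=0.2)
        d_obs = np.array([brute_force_d(X[g, :4], X[g, 4:], 0.2) for g in range(30)])
        assert any(np.allclose(row, d_obs) for row in null)

    def test_sampled_permutations_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 16))
        mask = np.array([False] * 8 + [True] * 8)  # C(16,8) = 12870 > 1000
        a = permutation_null(X, mask, 0.1, seed=5)
        b = permutation_null(X, mask, 0.1, seed=5)
        assert a.shape[0] == 1000
        assert np.array_equal(a, b)

    def test_invalid_permutation_count_rejected(self):
        X = np.zeros((5, 8))
        mask = np.array([False] * 4 + [True] * 4)
        with pytest.raises(ValueError):
            permutation_null(X, mask, 0.1, n_permutations=0)


class TestDeltaScan:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(7)
        X = rng.normal(8, 0.3, (8, 300))
        X[4:, :30] += 1.5  # some real signal
        return SAMTwoClass(control_label="c", random_state=7).fit(X, ["c"] * 4 + ["t"] * 4)

    def test_n_called_non_increasing_in_delta(self, fitted):
        n_called = fitted.delta_table_["n_called"].to_numpy()
        assert (np.diff(n_called) <= 0).all()

    def test_large_delta_calls_nothing_with_zero_fdr(self, fitted):
        table = delta_scan(fitted.d_, fitted.null_d_, [1e6])
        assert table["n_called"].iloc[0] == 0
        assert table["fdr"].iloc[0] == 0.0

    def test_empty_delta_grid_rejected(self, fitted):
        with pytest.raises(ValueError):
            delta_scan(fitted.d_, fitted.null_d_, [])

    def test_delta_zero_on_pure_null_gives_fdr_near_one(self):
        # exchangeable null: at delta 0 nearly everything is called and the
        # estimated FDR saturates
        fdrs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(0, 1, (8, 500))
            sam = SAMTwoClass(control_label="c", random_state=seed).fit(
                X, ["c"] * 4 + ["t"] * 4
            )
            fdrs.append(sam.delta_table_["fdr"].iloc[0])
        assert min(fdrs) > 0.8


class TestQValues:
    def test_most_extreme_gene_has_minimum_q(self):
        rng = np.random.default_rng(11)
        X = rng.normal(8, 0.3, (8, 400))
        X[4:, 0] += 3.0  # one overwhelming gene
        sam = SAMTwoClass(control_label="c", random_state=0).fit(X, ["c"] * 4 + ["t"] * 4)
        assert sam.q_values_[0] == sam.q_values_.min()

    def test_duplicated_gene_rows_share_q(self):
        rng = np.random.default_rng(13)
        X = rng.normal(8, 0.3, (8, 100))
        X = np.hstack([X, X[:, :1]])  # gene 100 duplicates gene 0
        sam = SAMTwoClass(control_label="c", random_state=0).fit(X, ["c"] * 4 + ["t"] * 4)
        assert sam.q_values_[100] == pytest.approx(sam.q_values_[0])

    def test_null_data_yields_almost_no_small_q(self):
        # fraction of q < 0.05 on exchangeable null: median over 20 seeds ≤ 0.01
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(8, 0.3, (8, 2000))
            sam = SAMTwoClass(control_label="c", random_state=seed).fit(
                X, ["c"] * 4 + ["t"] * 4
            )
            fracs.append(float((sam.q_values_ < 0.05).mean()))
        assert np.median(fracs) <= 0.01

    def test_q_monotone_in_displacement(self):
        rng = np.random.default_rng(17)
        X = rng.normal(8, 0.3, (8, 300))
        X[4:, :40] += rng.uniform(0.5, 2.5, 40)
        sam = SAMTwoClass(control_label="c", random_state=0).fit(X, ["c"] * 4 + ["t"] * 4)
        order = np.argsort(sam.d_)
        disp = np.empty_like(sam.d_)
        disp[order] = np.sort(sam.d_) - sam.expected_d_
        by_disp = sam.q_values_[np.argsort(np.abs(disp))]
        assert (np.diff(by_disp) <= 1e-12).all()


class TestSelectDegs:
    def _results(self):
        return pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "d": [3.0, 2.5, -4.0],
                "fold_change": [2.5, 1.9, 3.0],
                "q_value": [0.01, 0.001, 0.2],
                "direction": ["up", "up", "down"],
            }
        )

    def test_filters_are_conjunctive(self):
        degs = select_degs(self._results(), "d1")
        # a: FC 2.5, q 0.01 -> in; b: FC 1.9 -> out; c: q 0.2 -> out
        assert degs.gene_ids == {"a"}
        assert degs.direction["a"] == "up"

    def test_empty_input_gives_empty_set(self):
        empty = self._results().iloc[:0]
        assert len(select_degs(empty, "d1")) == 0

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            select_degs(self._results(), "d1", min_fold_change=0.0)

    def test_stricter_q_gives_nested_deg_sets(self):
        rng = np.random.default_rng(19)
        X = rng.normal(8, 0.3, (8, 500))
        X[4:, :60] += rng.uniform(1.0, 2.5, 60)
        sam = SAMTwoClass(control_label="c", random_state=0).fit(X, ["c"] * 4 + ["t"] * 4)
        loose = sam.select_degs("d", max_q=0.05).gene_ids
        strict = sam.select_degs("d", max_q=0.01).gene_ids
        assert strict <= loose
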