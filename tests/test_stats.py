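import numpy as np
import pytest
from hypothesis import given, strategies as st

from dtflow import anova, bonferroni, mann_whitney, movement_control, subsample_match
from dtflow.containers import TrialTable

from conftest import make_trial_table


class TestMannWhitney:
    def test_fully_separated_groups_give_extreme_u(self):
        # all 9 cross pairs favour B: U for A-over-B orientation is 0
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=0.01)  # exact 2/C(6,3)*... small-n

    def test_identical_groups_not_significant(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.99

    def test_order_of_observations_irrelevant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        b = rng.normal(size=10)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(rng.permutation(a), rng.permutation(b))
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_or_tied_samples_use_normal_approximation(self):
        a = [1.0, 1.0, 2.0]
        b = [2.0, 3.0, 3.0]
        res = mann_whitney(a, b)
        assert "asymptotic" in res.test_name


class TestAnova:
    def test_all_equal_values_give_zero_f(self):
        res = anova([1.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_group_f_equals_squared_t(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        res = anova(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert np.isclose(res.statistic, t**2, atol=1e-10)

    def test_balanced_two_way_matches_hand_computed_sums_of_squares(self):
        # 2x3 balanced design, 2 observations per cell
        cells = {
            ("a", "x"): [3.0, 5.0],
            ("a", "y"): [6.0, 8.0],
            ("a", "z"): [7.0, 9.0],
            ("b", "x"): [2.0, 4.0],
            ("b", "y"): [5.0, 5.0],
            ("b", "z"): [8.0, 10.0],
        }
        values, f1, f2 = [], [], []
        for (l1, l2), vals in cells.items():
            for v in vals:
                values.append(v)
                f1.append(l1)
                f2.append(l2)
        res = anova(values, f1, f2)
        # explicit SS decomposition (balanced, so Type II == classic)
        y = np.array(values)
        grand = y.mean()
        ss_a = sum(
            6 * (np.mean([v for (l1, _), vs in cells.items() for v in vs if l1 == lev]) - grand) ** 2
            for lev in ("a", "b")
        )
        cell_means = {k: np.mean(v) for k, v in cells.items()}
        ss_within = sum((v - cell_means[k]) ** 2 for k, vs in cells.items() for v in vs)
        ms_a = ss_a / 1
        ms_within = ss_within / 6  # 12 obs - 6 cells
        assert np.isclose(res.statistic, ms_a / ms_within, atol=1e-10)

    def test_level_with_single_observation_rejected(self):
        with pytest.raises(ValueError):
            anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_post_hoc_table_is_bonferroni_adjusted(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(1, 1, 8), rng.normal(2, 1, 8)]
        )
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = anova(values, labels, post_hoc_factor="factor1")
        assert len(res.post_hoc) == 3
        assert (res.post_hoc["p_adj"] >= res.post_hoc["p_raw"] - 1e-15).all()
        assert (res.post_hoc["p_adj"] <= 1.0).all()


class TestBonferroni:
    @given(st.floats(0.0, 1.0), st.integers(1, 50))
    def test_adjusted_p_at_least_raw_and_at_most_one(self, p, m):
        adj = bonferroni(p, m)
        assert adj >= p
        assert adj <= 1.0


class TestSubsampleMatch:
    def test_study_counts_match_minority_totals(self, study_table):
        matched = subsample_match(study_table, seed=0)
        assert matched.n_correct == 117
        assert matched.n_incorrect == 117
        # matched per subject, not just in total
        for _, sub in matched.data.groupby("subject"):
            assert (sub.outcome == "correct").sum() == (sub.outcome == "incorrect").sum()

    def test_balanced_table_returned_unchanged_up_to_order(self):
        table = make_trial_table(counts=[(5, 5), (4, 4)])
        matched = subsample_match(table, seed=1)
        assert sorted(matched.data.trial) == sorted(table.data.trial)

    def test_same_seed_same_selection(self, study_table):
        m1 = subsample_match(study_table, seed=42)
        m2 = subsample_match(study_table, seed=42)
        assert m1 == m2

    def test_subject_missing_one_group_excluded_with_warning(self):
        table = make_trial_table(counts=[(5, 3), (4, 0)])
        with pytest.warns(UserWarning, match="lacks"):
            matched = subsample_match(table)
        assert set(matched.data.subject) == {1}


class TestMovementControl:
    def test_outcome_independent_kinematics_not_significant(self, study_table):
        res = movement_control(study_table, by="outcome")
        assert set(res) == {"speed", "duration"}
        # kinematics were drawn independently of outcome
        assert res["speed"].p_value > 0.05
        assert res["duration"].p_value > 0.05

    def test_duplicated_group_gives_p_near_one(self):
        table = make_trial_table(counts=[(6, 0)])
        import pandas as pd

        dup = table.data.copy()
        dup["outcome"] = "incorrect"
        dup["trial"] += 100
        both = TrialTable(pd.concat([table.data, dup], ignore_index=True))
        res = movement_control(both, by="outcome")
        assert res["speed"].p_value > 0.99

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            movement_control(make_trial_table(counts=[]))
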