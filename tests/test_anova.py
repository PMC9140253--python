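"""Split-plot ANOVA arithmetic, Greenhouse-Geisser epsilon, pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from startlehab import (CohortConfig, GenerativeParams, default_generative_params,
                        greenhouse_geisser_epsilon, make_tdt20_table, mixed_anova,
                        pairwise_times, rm_anova_per_group, simulate_cohort)


def table_from_matrix(y, groups, times=None):
    """Long table from an (n_subjects x k_times) matrix."""
    n, k = y.shape
    times = times or [f"t{j + 1}" for j in range(k)]
    rows = [(f"f{i}", groups[i], times[j], y[i, j])
            for i in range(n) for j in range(k)]
    return pd.DataFrame(rows, columns=["fish_id", "group", "test_time", "tdt20"])


def split_plot_oracle(y, group_labels):
    """Brute-force split-plot sums of squares via explicit loops."""
    n, k = y.shape
    grand = y.mean()
    groups = sorted(set(group_labels))
    ss_total = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_bs = sum(k * (np.mean(y[i]) - grand) ** 2 for i in range(n))
    ss_group = 0.0
    for g in groups:
        members = [i for i in range(n) if group_labels[i] == g]
        gmean = np.mean([y[i, j] for i in members for j in range(k)])
        ss_group += k * len(members) * (gmean - grand) ** 2
    ss_subj = ss_bs - ss_group
    ss_time = sum(n * (np.mean(y[:, j]) - grand) ** 2 for j in range(k))
    ss_cells = 0.0
    for g in groups:
        members = [i for i in range(n) if group_labels[i] == g]
        for j in range(k):
            cmean = np.mean([y[i, j] for i in members])
            ss_cells += len(members) * (cmean - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_bs - ss_time - ss_inter
    G = len(groups)
    F_group = (ss_group / (G - 1)) / (ss_subj / (n - G))
    F_time = (ss_time / (k - 1)) / (ss_resid / ((n - G) * (k - 1)))
    F_inter = (ss_inter / ((G - 1) * (k - 1))) / (ss_resid / ((n - G) * (k - 1)))
    return dict(group=F_group, time=F_time, inter=F_inter,
                ss=dict(group=ss_group, subj=ss_subj, time=ss_time,
                        inter=ss_inter, resid=ss_resid, total=ss_total))


class TestMixedAnova:
    def test_tiny_design_matches_hand_arithmetic(self):
        """2 fish/group x 2 times, worked through the split-plot sums of
        squares by hand: SS_group=36.125, SS_subj=10.25, SS_time=3.125,
        SS_int=0.125, SS_res=0.25 -> F_group=7.048780..., F_time=25, F_int=1."""
        y = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 9.0]])
        res = mixed_anova(table_from_matrix(y, ["a", "a", "b", "b"]))
        assert res.ss_table["group"] == pytest.approx(36.125)
        assert res.ss_table["subjects(group)"] == pytest.approx(10.25)
        assert res.ss_table["time"] == pytest.approx(3.125)
        assert res.ss_table["group:time"] == pytest.approx(0.125)
        assert res.ss_table["residual"] == pytest.approx(0.25)
        assert res.effects["group"].F == pytest.approx(36.125 / 5.125)
        assert res.effects["time"].F == pytest.approx(25.0)
        assert res.effects["group:time"].F == pytest.approx(1.0)

    def test_matches_loop_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        y = rng.normal(30, 5, size=(14, 6)) + rng.normal(0, 3, size=(14, 1))
        labels = ["a"] * 6 + ["b"] * 8
        res = mixed_anova(table_from_matrix(y, labels))
        oracle = split_plot_oracle(y, labels)
        assert res.effects["group"].F == pytest.approx(oracle["group"], rel=1e-10)
        assert res.effects["time"].F == pytest.approx(oracle["time"], rel=1e-10)
        assert res.effects["group:time"].F == pytest.approx(oracle["inter"], rel=1e-10)

    def test_sums_of_squares_partition(self):
        rng = np.random.default_rng(11)
        y = rng.normal(10, 2, size=(20, 6))
        labels = ["a"] * 10 + ["b"] * 10
        res = mixed_anova(table_from_matrix(y, labels))
        parts = (res.ss_table["group"] + res.ss_table["subjects(group)"]
                 + res.ss_table["time"] + res.ss_table["group:time"]
                 + res.ss_table["residual"])
        assert parts == pytest.approx(res.ss_table["total"], rel=1e-8)

    def test_df_identities_at_study_size(self, default_cohort):
        res = mixed_anova(make_tdt20_table(default_cohort))
        g = res.effects["group"]
        assert (g.df_num, g.df_den) == (1, 142)
        t = res.effects["time"]
        assert (t.df_num, t.df_den) == (5, 710)
        assert t.df_num_gg == pytest.approx(res.gg_epsilon * 5)
        assert t.df_den_gg == pytest.approx(res.gg_epsilon * 710)
        assert 0.2 <= res.gg_epsilon <= 1.0

    def test_agrees_with_pingouin(self, default_cohort):
        pg = pytest.importorskip("pingouin")
        table = make_tdt20_table(default_cohort)
        res = mixed_anova(table)
        aov = pg.mixed_anova(data=table, dv="tdt20", within="test_time",
                             subject="fish_id", between="group")
        aov = aov.set_index("Source")
        assert res.effects["group"].F == pytest.approx(
            aov.loc["group", "F"], rel=1e-6)
        assert res.effects["time"].F == pytest.approx(
            aov.loc["test_time", "F"], rel=1e-6)
        assert res.effects["group:time"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-6)

    def test_unbalanced_table_rejected(self):
        y = np.arange(12.0).reshape(4, 3)
        table = table_from_matrix(y, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="unbalanced|missing"):
            mixed_anova(table.iloc[:-1])

    def test_degenerate_zero_variance_rejected(self):
        y = np.ones((6, 3))
        with pytest.raises(ValueError, match="degenerate|variance"):
            mixed_anova(table_from_matrix(y, ["a"] * 3 + ["b"] * 3))


class TestRmAnova:
    def test_df_arithmetic_at_study_size(self, default_cohort):
        table = make_tdt20_table(default_cohort)
        res = rm_anova_per_group(table[table["group"] == "control"])
        e = res.effects["time"]
        assert (e.df_num, e.df_den) == (5, 355)
        assert e.df_den_gg == pytest.approx(res.gg_epsilon * 355)

    def test_two_timepoint_F_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        y = rng.normal(20, 4, size=(15, 2))
        table = table_from_matrix(y, ["a"] * 15)
        res = rm_anova_per_group(table)
        t_stat = sps.ttest_rel(y[:, 1], y[:, 0]).statistic
        assert res.effects["time"].F == pytest.approx(t_stat ** 2, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            rm_anova_per_group(table_from_matrix(np.ones((5, 3)), ["a"] * 5))

    def test_multiple_groups_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="one group"):
            rm_anova_per_group(make_tdt20_table(default_cohort))

    def test_growth_effect_power(self):
        """The calibrated developmental growth of TDT20 toward 24 h makes
        the time effect detectable in >= 80% of simulated control cohorts."""
        p = default_generative_params()
        ctrl = GenerativeParams(
            cells={k: v for k, v in p.cells.items()},
            fish_sd=p.fish_sd, sigma=p.sigma)
        hits = 0
        n_sims = 200
        for s in range(n_sims):
            cohort = simulate_cohort(CohortConfig(
                n_fish_per_group_per_session=24, n_sessions=1, params=ctrl,
                seed=40_000 + s, groups=("control",)))
            table = make_tdt20_table(cohort)
            res = rm_anova_per_group(table)
            hits += res.effects["time"].p_gg < 0.05
        assert hits / n_sims >= 0.80


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_epsilon_one(self):
        k = 6
        cov = np.full((k, k), 2.0) + np.eye(k) * 3.0
        eps, warn = greenhouse_geisser_epsilon(cov)
        assert eps == pytest.approx(1.0)
        assert not warn

    def test_rank_one_dominant_gives_lower_bound(self):
        k = 6
        v = np.linspace(1, 6, k)[:, None]
        cov = v @ v.T + 1e-9 * np.eye(k)
        eps, _ = greenhouse_geisser_epsilon(cov)
        assert eps == pytest.approx(0.2, abs=1e-3)

    def test_singular_centered_covariance_warns(self):
        eps, warn = greenhouse_geisser_epsilon(np.full((6, 6), 5.0))
        assert eps == 0.2
        assert warn

    def test_fixture_matches_direct_formula(self):
        """8-subject fixture: epsilon from the eigen/trace route equals the
        classical direct formula on the double-centred covariance."""
        rng = np.random.default_rng(17)
        y = rng.normal(0, 1, size=(8, 6)) @ np.diag([3, 2, 1.5, 1, 1, 0.5])
        S = np.cov(y, rowvar=False)
        k = 6
        s_bar = S.mean()
        s_diag = np.trace(S) / k
        row_means = S.mean(axis=1)
        num = k ** 2 * (s_diag - s_bar) ** 2
        den = (k - 1) * ((S ** 2).sum() - 2 * k * (row_means ** 2).sum()
                         + k ** 2 * s_bar ** 2)
        expected = num / den
        eps, _ = greenhouse_geisser_epsilon(S)
        assert eps == pytest.approx(np.clip(expected, 0.2, 1.0), rel=1e-10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            greenhouse_geisser_epsilon(np.ones((3, 4)))


class TestPairwise:
    def test_identical_means_give_unit_adjusted_p(self):
        rng = np.random.default_rng(5)
        base = rng.normal(30, 5, size=(12, 1))
        y = np.repeat(base, 4, axis=1) + rng.normal(0, 1, size=(12, 4))
        y -= y.mean(axis=0) - 30.0  # equalise all time means exactly
        res = pairwise_times(table_from_matrix(y, ["a"] * 12))
        assert np.all(res.frame["mean_diff"].abs() < 1e-12)
        assert np.all(res.frame["p_adjusted"] == 1.0)

    def test_adjustment_is_monotone(self, default_cohort):
        table = make_tdt20_table(default_cohort)
        sub = table[table["group"] == "concussed"]
        res = pairwise_times(sub, correction="bonferroni")
        assert np.all(res.frame["p_adjusted"] >= res.frame["p"] - 1e-15)
        assert len(res.frame) == 15  # all 6-choose-2 contrasts

    def test_concussed_acute_exceeds_70min(self, default_cohort):
        """The calibrated concussed cohort reproduces the published
        direction: mean TDT20 higher at 5 min than at 70 min post-injury."""
        table = make_tdt20_table(default_cohort)
        sub = table[table["group"] == "concussed"]
        res = pairwise_times(sub, correction="bonferroni",
                             time_order=["baseline", "5min", "40min",
                                         "70min", "5h", "24h"])
        row = res.frame[(res.frame["time_i"] == "5min")
                        & (res.frame["time_j"] == "70min")].iloc[0]
        assert row["mean_diff"] < 0  # 70min minus 5min: decrease

    def test_unknown_correction_rejected(self, default_cohort):
        table = make_tdt20_table(default_cohort)
        sub = table[table["group"] == "control"]
        with pytest.raises(ValueError, match="correction"):
            pairwise_times(sub, correction="bogus")


class TestNullCalibration:
    def test_group_effect_type_one_error(self):
        """With the two groups generated from identical parameters, the
        group-effect rejection rate at alpha=0.05 stays inside the binomial
        95% interval around 0.05 over 500 simulated cohorts."""
        p = default_generative_params()
        cells = dict(p.cells)
        for tt in ("baseline", "5min", "40min", "70min", "5h", "24h"):
            cells[("concussed", tt)] = cells[("control", tt)]
        null = GenerativeParams(cells=cells, fish_sd=p.fish_sd, sigma=p.sigma)
        n_sims, rejections = 500, 0
        for s in range(n_sims):
            cohort = simulate_cohort(CohortConfig(
                n_fish_per_group_per_session=12, n_sessions=1, params=null,
                seed=50_000 + s))
            res = mixed_anova(make_tdt20_table(cohort))
            rejections += res.effects["group"].p_raw < 0.05
        rate = rejections / n_sims
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) <= half_width
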