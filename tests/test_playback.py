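"""Playback battery: sign test, confound check, Box-Cox, contrasts, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parapatry import (ComputationError, PlaybackGenConfig, ValidationError,
                       anova_tukey, boxcox_mle, check_response_to_conspecific,
                       cohens_d, generate_playback_trials, kruskal_dunn,
                       segregation_scaled_power, temporal_covariate_check)


def _trials_from_groups(groups, response="min_distance_m"):
    rows = []
    for t, values in groups.items():
        for v in values:
            rows.append({"trial_id": len(rows), "treatment": t, response: v})
    return pd.DataFrame(rows)


class TestSignTest:
    def _trials(self, pre, during):
        return pd.DataFrame({"pre_distance_m": pre, "min_distance_m": during})

    def test_all_closer_matches_exact_binomial(self):
        trials = self._trials(np.arange(10, 20.0), np.arange(1, 11.0))
        res = check_response_to_conspecific(trials)
        # 10/10 successes: two-sided exact p = 2 * (1/2)^10
        assert res.extras["exact_p"] == pytest.approx(2 * 0.5 ** 10, rel=1e-9)
        assert res.statistic > 2.0
        assert res.p_value < 0.01

    def test_symmetric_outcome_is_null(self):
        pre = np.r_[np.full(5, 10.0), np.full(5, 1.0)]
        during = np.r_[np.full(5, 1.0), np.full(5, 10.0)]
        res = check_response_to_conspecific(self._trials(pre, during))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        pre = np.r_[np.full(8, 10.0), np.full(4, 5.0)]
        during = np.r_[np.full(8, 2.0), np.full(4, 5.0)]
        res = check_response_to_conspecific(self._trials(pre, during))
        assert res.extras["n_pairs"] == 8
        assert res.extras["n_closer"] == 8

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ComputationError):
            check_response_to_conspecific(self._trials([], []))
        with pytest.raises(ComputationError):
            check_response_to_conspecific(self._trials([3.0] * 5, [1.0] * 5))

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ComputationError):
            check_response_to_conspecific(
                self._trials([5.0] * 8, [5.0] * 8))


class TestTemporalCheck:
    def _trials(self, n, response, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "month": rng.integers(3, 8, n),
            "hour": rng.integers(7, 17, n),
            "min_distance_m": response})

    def test_pure_signal_detected(self):
        rng = np.random.default_rng(1)
        months = rng.integers(3, 8, 60)
        trials = pd.DataFrame({"month": months,
                               "hour": rng.integers(7, 17, 60),
                               "min_distance_m": 2.0 * months})
        table = temporal_covariate_check(trials, "min_distance_m")
        p_month = table.set_index("term").loc["month", "p_value"]
        assert p_month < 1e-10

    def test_single_month_rejected(self):
        trials = pd.DataFrame({"month": [5] * 20,
                               "hour": np.tile([8, 12], 10),
                               "min_distance_m": np.random.default_rng(0).random(20)})
        with pytest.raises(ValidationError):
            temporal_covariate_check(trials, "min_distance_m")

    def test_type_one_error_calibrated(self):
        """Under independence the month p-value is uniform: its rejection
        rate at 0.05 stays within +-0.03 over 200 replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            trials = self._trials(200, rng.standard_normal(200), seed=rep)
            table = temporal_covariate_check(trials, "min_distance_m")
            p = table.set_index("term").loc["month", "p_value"]
            hits += p < 0.05
        assert abs(hits / n_rep - 0.05) <= 0.03


class TestBoxCox:
    def test_lognormal_data_recover_log_transform(self):
        rng = np.random.default_rng(3)
        y = np.exp(rng.standard_normal(2_000))
        assert abs(boxcox_mle(y).lmbda) < 0.1

    def test_normal_data_leave_identity(self):
        rng = np.random.default_rng(14)
        y = rng.normal(10.0, 2.0, 2_000)
        assert 0.5 < boxcox_mle(y).lmbda < 1.5

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        y = rng.gamma(2.0, 3.0, 500)
        mine = boxcox_mle(y)
        _, ref = stats.boxcox(y)
        assert mine.lmbda == pytest.approx(ref, abs=1e-3)
        np.testing.assert_allclose(mine.transformed,
                                   stats.boxcox(y, lmbda=mine.lmbda), rtol=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            boxcox_mle(np.full(10, 3.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            boxcox_mle(np.array([1.0, 2.0, 0.0, 3.0, 4.0]))

    def test_transform_preserves_group_ranks(self):
        """Box-Cox is strictly monotone, so rank-based results are invariant."""
        trials = generate_playback_trials(PlaybackGenConfig(n_per_group=15, seed=6))
        raw = kruskal_dunn(trials, "min_distance_m")
        bc = boxcox_mle(trials["min_distance_m"].to_numpy())
        transformed = kruskal_dunn(trials.assign(min_distance_m=bc.transformed),
                                   "min_distance_m")
        assert raw.statistic == pytest.approx(transformed.statistic, abs=1e-10)


class TestAnovaTukey:
    def test_all_equal_gives_zero_f(self):
        trials = _trials_from_groups({t: [7.0] * 4 for t in
                                      ("conspecific", "congener", "control")})
        res = anova_tukey(trials)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert all(c.p_value == 1.0 for c in res.pairwise)

    def test_identical_groups_give_zero_f(self):
        trials = _trials_from_groups({t: [1.0, 2.0, 3.0] for t in
                                      ("conspecific", "congener", "control")})
        assert anova_tukey(trials).statistic == pytest.approx(0.0, abs=1e-12)

    def test_textbook_example_matches_sums_of_squares_oracle(self):
        groups = {"conspecific": [6, 8, 4, 5, 3, 4],
                  "congener": [8, 12, 9, 11, 6, 8],
                  "control": [13, 9, 11, 8, 7, 12]}
        trials = _trials_from_groups(groups)
        res = anova_tukey(trials)
        # independent two-pass computation
        allv = np.concatenate([np.asarray(v, float) for v in groups.values()])
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v, float) - np.mean(v)) ** 2).sum()
                  for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 15)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-6)
        assert res.p_value == pytest.approx(stats.f.sf(f_oracle, 2, 15), abs=1e-9)
        # Tukey q from the brute-force pairwise formula
        msw = ssw / 15
        by_name = {(c.group_a, c.group_b): c for c in res.pairwise}
        for (a, b), c in by_name.items():
            q = abs(np.mean(groups[a]) - np.mean(groups[b])) / np.sqrt(msw / 6)
            assert c.statistic == pytest.approx(q, abs=1e-9)

    def test_tukey_p_agrees_with_statsmodels(self):
        sm_mc = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(8)
        groups = {"conspecific": rng.normal(5, 2, 12),
                  "congener": rng.normal(8, 2, 12),
                  "control": rng.normal(9, 2, 12)}
        trials = _trials_from_groups(groups)
        res = anova_tukey(trials)
        endog = trials["min_distance_m"].to_numpy()
        ref = sm_mc.pairwise_tukeyhsd(endog, trials["treatment"].to_numpy())
        ref_p = {tuple(sorted((r[0], r[1]))): float(r[3])
                 for r in ref.summary().data[1:]}
        for c in res.pairwise:
            key = tuple(sorted((c.group_a, c.group_b)))
            assert c.p_value == pytest.approx(ref_p[key], abs=1e-3)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(9)
        groups = {"conspecific": rng.normal(5, 2, 10),
                  "control": rng.normal(7, 2, 14)}
        trials = _trials_from_groups(groups)
        res = anova_tukey(trials)
        t, _ = stats.ttest_ind(groups["conspecific"], groups["control"])
        assert res.statistic == pytest.approx(t ** 2, rel=1e-10)

    def test_single_group_rejected(self):
        trials = _trials_from_groups({"conspecific": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            anova_tukey(trials)

    def test_type_one_error_of_full_distance_path(self):
        """Box-Cox + ANOVA on null playback data rejects at ~nominal rate."""
        hits = 0
        n_rep = 200
        means = {t: (20.0, 100.0) for t in
                 ("conspecific", "congener", "control")}
        for rep in range(n_rep):
            cfg = PlaybackGenConfig(n_per_group=12, sigma_log=0.5,
                                    group_means=means, seed=50_000 + rep)
            trials = generate_playback_trials(cfg)
            bc = boxcox_mle(trials["min_distance_m"].to_numpy())
            res = anova_tukey(trials.assign(d=bc.transformed), "d")
            hits += res.p_value < 0.05
        assert abs(hits / n_rep - 0.05) <= 0.04


class TestKruskalDunn:
    def test_identical_groups_give_zero_h(self):
        trials = _trials_from_groups({t: [3.0, 3.0] for t in
                                      ("conspecific", "congener", "control")},
                                     response="latency_s")
        res = kruskal_dunn(trials)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_fully_ordered_groups_match_rank_formula(self):
        groups = {"conspecific": [1.0, 2.0], "congener": [3.0, 4.0],
                  "control": [5.0, 6.0]}
        trials = _trials_from_groups(groups, response="latency_s")
        res = kruskal_dunn(trials)
        # direct formula: 12/(N(N+1)) * sum n_j (rbar_j - rbar)^2
        h_oracle = 12.0 / (6 * 7) * (2 * (1.5 - 3.5) ** 2
                                     + 2 * (3.5 - 3.5) ** 2
                                     + 2 * (5.5 - 3.5) ** 2)
        assert res.statistic == pytest.approx(h_oracle, abs=1e-12)

    def test_heavy_ties_match_correction_oracle(self):
        groups = {"conspecific": [2.0, 2.0, 2.0], "congener": [2.0, 2.0, 2.0],
                  "control": [2.0, 2.0, 9.0]}
        trials = _trials_from_groups(groups, response="latency_s")
        res = kruskal_dunn(trials)
        values = trials["latency_s"].to_numpy()
        all_ranks = stats.rankdata(values)  # mid-ranks
        rbar = all_ranks.mean()
        h = 12.0 / (9 * 10) * sum(
            len(v) * (all_ranks[trials["treatment"] == t].mean() - rbar) ** 2
            for t, v in groups.items())
        ties = np.array([8, 1])
        correction = 1.0 - ((ties ** 3 - ties).sum()) / (9 ** 3 - 9)
        assert res.statistic == pytest.approx(h / correction, abs=1e-8)

    def test_dunn_z_against_direct_formula(self):
        rng = np.random.default_rng(10)
        groups = {"conspecific": rng.random(8), "congener": rng.random(10),
                  "control": rng.random(9)}
        trials = _trials_from_groups(groups, response="latency_s")
        res = kruskal_dunn(trials)
        values = trials["latency_s"].to_numpy()
        ranks = stats.rankdata(values)
        N = len(values)
        mean_ranks = {t: ranks[trials["treatment"] == t].mean() for t in groups}
        for c in res.pairwise:
            na = len(groups[c.group_a])
            nb = len(groups[c.group_b])
            var = N * (N + 1) / 12.0 * (1 / na + 1 / nb)  # no ties here
            z = (mean_ranks[c.group_a] - mean_ranks[c.group_b]) / np.sqrt(var)
            assert c.statistic == pytest.approx(z, abs=1e-10)
            assert c.p_value == pytest.approx(
                2 * stats.norm.sf(abs(z)), abs=1e-10)

    def test_holm_adjustment_orders_p_values(self):
        rng = np.random.default_rng(11)
        groups = {"conspecific": rng.random(8) + 1.0,
                  "congener": rng.random(8),
                  "control": rng.random(8) + 0.5}
        trials = _trials_from_groups(groups, response="latency_s")
        raw = kruskal_dunn(trials, adjust="none")
        holm = kruskal_dunn(trials, adjust="holm")
        for c_raw, c_holm in zip(raw.pairwise, holm.pairwise):
            assert c_holm.p_value >= c_raw.p_value - 1e-12


class TestEffectSizeAndPower:
    def test_equal_means_zero_d(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]).d == 0.0

    def test_unit_effect_constructed_exactly(self):
        z = np.tile([-1.0, 1.0], 5)
        z = z / z.std(ddof=1)
        g1 = 10.0 + 2.0 * z
        g2 = 8.0 + 2.0 * z
        eff = cohens_d(g1, g2)
        assert eff.pooled_sd == pytest.approx(2.0, rel=1e-12)
        assert eff.d == pytest.approx(1.0, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.random(10), rng.random(12) + 0.3
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d, rel=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ComputationError):
            cohens_d([2.0, 2.0], [3.0, 3.0])

    def test_null_effect_power_equals_alpha(self):
        res = segregation_scaled_power(0.0, 0.9, 20, 20, alpha=0.07)
        assert res.power == 0.07
        assert not res.adequate

    def test_huge_effect_saturates(self):
        res = segregation_scaled_power(5.0, 1.0, 20, 20)
        assert res.power > 0.999
        assert res.adequate

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            segregation_scaled_power(1.0, 0.9, 10, 10, alpha=1.5)

    def test_matches_monte_carlo_oracle(self):
        """Noncentral-t power at (d=1, C=0.9, n=25/25) vs. simulated t tests."""
        res = segregation_scaled_power(1.0, 0.9, 25, 25, alpha=0.05)
        rng = np.random.default_rng(99)
        n_sim = 100_000
        n = 25
        x = rng.standard_normal((n_sim, n)) + 0.9
        y = rng.standard_normal((n_sim, n))
        mx, my = x.mean(axis=1), y.mean(axis=1)
        vx = x.var(axis=1, ddof=1)
        vy = y.var(axis=1, ddof=1)
        sp = np.sqrt((vx + vy) / 2)
        t = (mx - my) / (sp * np.sqrt(2 / n))
        tcrit = stats.t.ppf(0.975, 2 * n - 2)
        mc_power = (np.abs(t) > tcrit).mean()
        assert res.power == pytest.approx(mc_power, abs=0.01)

    def test_power_monotone_in_effect_sample_size_and_segregation(self):
        base = segregation_scaled_power(0.8, 0.7, 15, 15).power
        assert segregation_scaled_power(1.2, 0.7, 15, 15).power > base
        assert segregation_scaled_power(0.8, 0.9, 15, 15).power > base
        assert segregation_scaled_power(0.8, 0.7, 30, 30).power > base
        grid = [segregation_scaled_power(0.8, c, 15, 15).power
                for c in np.linspace(0.0, 1.0, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(grid, grid[1:]))
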