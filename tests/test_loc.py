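"""Psychometrics and the score-behaviour statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctrltask import cohort
from ctrltask.loc import (cronbach_alpha, exclusion_screen, fdr_correct,
                          outcome_measures, permutation_corr_test,
                          power_correlation, rf_importance, score_levenson,
                          shuffle_necessity, varimax_factor_analysis)


class TestScoring:
    def test_floor_and_ceiling(self):
        assert score_levenson(np.zeros(24, int)) == {"I": 0, "C": 0, "P": 0}
        top = score_levenson(np.full(24, 5))
        assert top == {"I": 40, "C": 40, "P": 40}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_levenson(np.full(24, 6))

    def test_i_score_tracks_generating_factor(self):
        profiles = cohort.sample_population(500, seed=0, scenario="null")
        z = np.array([p.factors[0] for p in profiles])
        i_scores = np.array([score_levenson(p.item_responses)["I"]
                             for p in profiles])
        assert np.corrcoef(z, i_scores)[0, 1] > 0.7


class TestCronbach:
    def test_identical_items_give_alpha_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=(30, 1)), (1, 5))
        a, _ = cronbach_alpha(x, n_boot=50, seed=0)
        assert a == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self):
        x = np.random.default_rng(1).normal(size=(2000, 6))
        a, _ = cronbach_alpha(x, n_boot=50, seed=0)
        assert abs(a) < 0.1

    def test_toy_matrix_matches_formula(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 3.0, 5.0, 4.0],
                      [0.0, 1.0, 2.0, 2.0]])
        k = 4
        expected = k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum()
                                  / x.sum(axis=1).var(ddof=1))
        a, (lo, hi) = cronbach_alpha(x, n_boot=200, seed=2)
        assert a == pytest.approx(expected)
        assert lo <= a <= hi

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        x = np.random.default_rng(3).normal(size=(40, 8))
        x += x[:, :1] * 0.5  # induce consistency
        a, _ = cronbach_alpha(x, n_boot=10, seed=0)
        ref = pg.cronbach_alpha(pd.DataFrame(x))[0]
        assert a == pytest.approx(ref, abs=1e-9)


@pytest.fixture(scope="module")
def three_factor_items():
    rng = np.random.default_rng(4)
    n = 1000
    z = rng.normal(size=(n, 3))
    lam = 0.8
    items = np.empty((n, 24))
    for s in range(3):
        e = rng.normal(0, np.sqrt(1 - lam**2), size=(n, 8))
        items[:, s * 8:(s + 1) * 8] = lam * z[:, [s]] + e
    return items, z


class TestFactorAnalysis:

    def test_recovers_known_structure(self, three_factor_items):
        items, z = three_factor_items
        res = varimax_factor_analysis(items, n_factors=3)
        # each generating factor aligns with exactly one rotated factor
        congruence = np.abs(np.corrcoef(z.T, res["scores"].T)[:3, 3:])
        assert (congruence.max(axis=1) > 0.9).all()
        assert sorted(congruence.argmax(axis=1).tolist()) == [0, 1, 2]

    def test_scores_nearly_orthogonal(self, three_factor_items):
        items, _ = three_factor_items
        res = varimax_factor_analysis(items, n_factors=3)
        c = np.corrcoef(res["scores"].T)
        off = c[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_rotation_preserves_communalities(self, three_factor_items):
        items, _ = three_factor_items
        from sklearn.decomposition import FactorAnalysis

        sd = items.std(axis=0, ddof=1)
        Z = (items - items.mean(axis=0)) / sd
        raw = FactorAnalysis(n_components=3, rotation=None, random_state=0)
        raw.fit(Z)
        h_raw = (raw.components_.T**2).sum(axis=1)
        res = varimax_factor_analysis(items, n_factors=3)
        assert np.allclose(res["communalities"], h_raw, atol=1e-6)

    def test_singular_input_rejected(self):
        x = np.ones((20, 5))
        with pytest.raises(np.linalg.LinAlgError):
            varimax_factor_analysis(x, 2)


class TestPermutationTest:
    def test_identical_vectors_extreme_p(self):
        x = np.arange(10.0)
        r, p, _ = permutation_corr_test(x, x, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for k in range(150):
            x = rng.normal(size=35)
            y = rng.normal(size=35)
            _, p, _ = permutation_corr_test(x, y, n_perm=199, seed=k)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_agrees_with_parametric_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=35)
        y = 0.5 * x + rng.normal(size=35)
        r, p_perm, _ = permutation_corr_test(x, y, n_perm=10_000, seed=0)
        _, p_param = stats.pearsonr(x, y)
        assert abs(p_perm - p_param) < 0.02

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            permutation_corr_test(np.ones(10), np.arange(10.0))


class TestShuffleNecessity:
    def test_identity_permutation_reproduces_effect(self):
        est = np.arange(8.0)
        frac = shuffle_necessity(est, lambda e: float(e.sum()), n_sets=5,
                                 seed=0)
        assert frac == 1.0  # the statistic ignores order entirely

    def test_irrelevant_parameter_sits_near_half(self):
        # if the parameter has no behavioural weight the observed effect
        # is itself a draw from the null
        rng = np.random.default_rng(7)
        scores = rng.normal(size=20)
        behaviour = rng.normal(size=20)

        def effect(est):
            return float(np.corrcoef(scores, behaviour + 0.0 * est)[0, 1])
        frac = shuffle_necessity(rng.normal(size=20), effect, n_sets=50,
                                 seed=1)
        assert 0.2 < frac <= 1.0

    def test_linked_parameter_is_necessary(self, task_design):
        # strong-link cohort: shuffling the failure learning rate across
        # subjects destroys the I-score / g+ frequency correlation
        profiles = cohort.sample_population(28, seed=30,
                                            scenario="strong-link")
        i_scores = np.array([p.loc_scores["I"] for p in profiles])
        high_blocks = [b for b in task_design.blocks if b.influence == "high"]
        sub_design = type(task_design)(
            blocks=high_blocks,
            trials=[t for t in task_design.trials if t.block.influence == "high"],
            gamma_levels=task_design.gamma_levels, seed=task_design.seed)
        counter = {"n": 0}

        def effect(eps_l_vector):
            counter["n"] += 1
            freqs = []
            for k, (p, e) in enumerate(zip(profiles, eps_l_vector)):
                prof = cohort.SubjectProfile(
                    subject_id=k, dgt_model=p.dgt_model, sgt_model=p.sgt_model,
                    params_high=p.params_high.with_(eps_l=float(e)),
                    params_low=p.params_low, press_rate=p.press_rate,
                    factors=p.factors, item_responses=p.item_responses,
                    loc_scores=p.loc_scores)
                df = cohort.simulate_subject(prof, sub_design,
                                             seed=1000 * counter["n"] + k)
                dgt = df[df.phase == "DGT"]
                freqs.append((dgt.chosen_goal == 1).mean())
            return float(np.corrcoef(i_scores, freqs)[0, 1])

        eps = np.array([p.params_high.eps_l for p in profiles])
        frac = shuffle_necessity(eps, effect, n_sets=99, seed=2)
        assert frac < 0.05

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError):
            shuffle_necessity(np.arange(5.0), lambda e: np.nan, n_sets=3)


class TestRfImportance:
    def test_positive_and_negative_controls(self):
        rng = np.random.default_rng(8)
        n = 60
        signal = rng.normal(size=n)
        X = pd.DataFrame({"signal": signal,
                          "noise1": rng.normal(size=n),
                          "noise2": rng.normal(size=n)})
        y = signal + 0.3 * rng.normal(size=n)
        imp = rf_importance(X, y, n_repeats=10, seed=0)
        assert imp.importance.idxmax() == "signal"
        assert imp.loc["noise1", "importance"] < 0.3 * imp.loc["signal",
                                                               "importance"]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(size=30)
        a = rf_importance(X, y, n_repeats=5, seed=4)
        b = rf_importance(X, y, n_repeats=5, seed=4)
        assert np.allclose(a.importance, b.importance)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            rf_importance(np.random.default_rng(0).normal(size=(10, 2)),
                          np.ones(10))


class TestPower:
    def test_null_rho_gives_alpha(self):
        assert power_correlation(35, 0.0, 0.05) == pytest.approx(0.05)

    def test_large_n_approaches_one(self):
        assert power_correlation(2000, 0.2, 0.05) > 0.99

    def test_design_anchor(self):
        # the published sample size justification: n = 35 gives ~0.8 power
        # for correlations around 0.45
        assert power_correlation(35, 0.45, 0.05) == pytest.approx(0.8,
                                                                  abs=0.02)

    def test_simulation_cross_check(self):
        analytic = power_correlation(35, 0.45, 0.05)
        mc = power_correlation(35, 0.45, 0.05, method="simulation",
                               n_sim=4000, seed=0)
        assert abs(analytic - mc) < 0.03

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_correlation(3, 0.4)
        with pytest.raises(ValueError):
            power_correlation(35, 1.2)


class TestOutcomeMeasures:
    def test_hand_counted_toy_log(self, small_cohort):
        df = small_cohort["trials"]
        one = df[(df.subject_id == 0) & (df.influence == "high")]
        om = outcome_measures(one)
        dgt = one[one.phase == "DGT"]
        assert om.gplus_frequency == pytest.approx(
            (dgt.chosen_goal == 1).mean())
        assert om.money == one.payoff.sum()
        assert om.losses == (~one.success).sum()
        wins_value = one.loc[one.success, "payoff"].sum()
        assert om.money == wins_value - 15 * om.losses

    def test_degenerate_all_v1_gplus_log(self, toy_dgt_frame):
        df = toy_dgt_frame.copy()
        df["chosen_vehicle"] = 1
        df["chosen_goal"] = 1
        df["trial_type"] = ["t1", "Catch", "t2"]
        om = outcome_measures(df)
        assert om.gplus_frequency == 1.0
        assert om.v1_on_gplus_frequency == 1.0
        assert om.catch_accuracy == 1.0

    def test_empty_condition_rejected(self, toy_dgt_frame):
        with pytest.raises(ValueError):
            outcome_measures(toy_dgt_frame, condition="low")


class TestExclusionScreen:
    def test_homogeneous_cohort_keeps_everyone(self):
        rng = np.random.default_rng(10)
        acc = 0.7 + 0.05 * rng.normal(size=30)
        i_scores = 25 + 3 * rng.normal(size=30)
        assert exclusion_screen(acc, i_scores) == []

    def test_planted_catch_outlier_flagged(self):
        acc = np.full(30, 0.9)
        acc += 0.02 * np.random.default_rng(11).normal(size=30)
        acc[7] = 0.05
        flagged = exclusion_screen(acc, np.full(30, 25.0)
                                   + np.random.default_rng(1).normal(size=30))
        assert (7, "catch_irrationality") in flagged

    def test_planted_i_score_outlier_flagged(self):
        rng = np.random.default_rng(12)
        acc = 0.8 + 0.05 * rng.normal(size=30)
        i_scores = 25 + 2 * rng.normal(size=30)
        i_scores[3] = 60.0
        flagged = exclusion_screen(acc, i_scores)
        assert (3, "i_score_outlier") in flagged


class TestFdr:
    def test_all_small_all_significant(self):
        assert fdr_correct([0.001] * 6, q=0.05).all()

    def test_all_large_none_significant(self):
        assert not fdr_correct([0.9] * 6, q=0.05).any()

    def test_step_up_hand_example(self):
        # sorted p: .001 .008 .039 .041 .042 against i/m*q = .01 .02 .03
        # .04 .05 -> the largest i with p_(i) <= i q/m is i=5, so all pass
        p = [0.041, 0.001, 0.039, 0.042, 0.008]
        assert fdr_correct(p, q=0.05).all()
        # drop the rescuing last value: now only the first two survive
        p2 = [0.041, 0.001, 0.039, 0.08, 0.008]
        assert fdr_correct(p2, q=0.05).tolist() == [False, True, False,
                                                    False, True]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])
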