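"""Likelihoods, fitting, WAIC and LOSO."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_dgt_frame
from ctrltask.inference import (fit_subject, laplace_draws, loso,
                                negative_log_likelihood, waic)
from ctrltask.models import ParamSet


def unrolled_nll(params):
    """Hand-unrolled likelihood of the 3-trial toy log (see toy_dgt_frame).

    Written out term by term, independently of the package's replay code.
    Option order: (v1,g-), (v1,g+), (v2,g-), (v2,g+); D0=44, R0=100.
    """
    a_d, a_r, a_H, e_w, e_l, h1 = (params["alpha_d"], params["alpha_r"],
                                   params["alpha_H"], params["eps_w"],
                                   params["eps_l"], params["H_1"])
    gh = 0.5  # prior-mean guidability estimate before any press evidence

    def softmax_logp(vals, k):
        m = max(vals)
        return vals[k] - (m + math.log(sum(math.exp(v - m) for v in vals)))

    total = 0.0
    H = [h1, h1]
    a_v = params.get("alpha_v", 0.0)

    # trial 1: d = (12,60,36,36), r = (20,80), chose (v2,g+), lost
    vals = [-a_d * 12 / 44 + a_v * gh + a_r * 20 / 100,
            -a_d * 60 / 44 + a_v * gh + a_r * 80 / 100 + a_H * H[0],
            -a_d * 36 / 44 + a_v * gh + a_r * 20 / 100,
            -a_d * 36 / 44 + a_v * gh + a_r * 80 / 100 + a_H * H[1]]
    total += softmax_logp(vals, 3)
    H[1] = H[1] + e_l * (-1 - H[1])
    gh2 = ((4 * ((50 + 4 * 0.625) / (100 + 4)) - 1) / 3)  # v2: 50/100 matches

    # trial 2: d = (20,52,36,36), r = (25,75), chose (v2,g+), won g+
    vals = [-a_d * 20 / 44 + a_v * gh + a_r * 25 / 100,
            -a_d * 52 / 44 + a_v * gh + a_r * 75 / 100 + a_H * H[0],
            -a_d * 36 / 44 + a_v * gh2 + a_r * 25 / 100,
            -a_d * 36 / 44 + a_v * gh2 + a_r * 75 / 100 + a_H * H[1]]
    total += softmax_logp(vals, 3)
    H[1] = H[1] + e_w * (1 - H[1])
    gh2 = ((4 * ((110 + 4 * 0.625) / (200 + 4)) - 1) / 3)  # v2: 110/200

    # trial 3: d = (28,44,36,36), r = (30,70), chose (v1,g-), won g-
    vals = [-a_d * 28 / 44 + a_v * gh + a_r * 30 / 100,
            -a_d * 44 / 44 + a_v * gh + a_r * 70 / 100 + a_H * H[0],
            -a_d * 36 / 44 + a_v * gh2 + a_r * 30 / 100,
            -a_d * 36 / 44 + a_v * gh2 + a_r * 70 / 100 + a_H * H[1]]
    total += softmax_logp(vals, 0)
    return -total


class TestNegativeLogLikelihood:
    def test_uniform_policy_gives_n_log4(self, toy_dgt_frame):
        nll = negative_log_likelihood(toy_dgt_frame, "vehicle_rw", ParamSet(),
                                      condition="high")
        assert nll == pytest.approx(3 * math.log(4))

    @pytest.mark.parametrize("params", [
        dict(alpha_d=1.0, alpha_r=0.5, alpha_H=2.0, eps_w=0.3, eps_l=0.5,
             H_1=0.2),
        dict(alpha_d=0.3, alpha_r=1.4, alpha_v=0.8, alpha_H=1.0, eps_w=0.1,
             eps_l=0.9, H_1=-0.5),
    ])
    def test_matches_hand_unrolled_product(self, toy_dgt_frame, params):
        full = {"alpha_v": 0.0, **params}
        nll = negative_log_likelihood(toy_dgt_frame, "vehicle_rw",
                                      ParamSet(**full), condition="high")
        assert nll == pytest.approx(unrolled_nll(full), rel=1e-9)

    def test_order_dependence_with_learning(self, toy_dgt_frame):
        params = ParamSet(alpha_d=1.0, alpha_H=2.0, eps_l=0.6, H_1=0.5)
        base = negative_log_likelihood(toy_dgt_frame, "vehicle_rw", params,
                                       condition="high")
        permuted = toy_dgt_frame.copy()
        permuted["index_in_block"] = [3, 1, 2]
        alt = negative_log_likelihood(permuted, "vehicle_rw", params,
                                      condition="high")
        assert abs(base - alt) > 1e-6

    def test_per_trial_values_nonpositive(self, small_cohort):
        df = small_cohort["trials"]
        one = df[df.subject_id == 0]
        fit = fit_subject(one, "vehicle_rw", "high", seed=0)
        assert np.all(fit.loglik <= 0)

    def test_missing_condition_raises(self, toy_dgt_frame):
        with pytest.raises(ValueError):
            negative_log_likelihood(toy_dgt_frame, "vehicle_rw", ParamSet(),
                                    condition="low")


class TestFitSubject:
    def test_map_is_deterministic(self, small_cohort):
        df = small_cohort["trials"]
        one = df[df.subject_id == 1]
        a = fit_subject(one, "vehicle_rw", "high", seed=3)
        b = fit_subject(one, "vehicle_rw", "high", seed=3)
        assert np.allclose(a.x, b.x)
        assert a.params == b.params

    def test_eps_w_dropped_without_low_influence_wins(self, small_cohort):
        df = small_cohort["trials"].copy()
        one = df[df.subject_id == 2].copy()
        # force the no-win regime the low-influence condition is designed for
        mask = (one.influence == "low") & (one.chosen_goal == 1)
        one.loc[mask, "success"] = False
        one.loc[mask, "payoff"] = -15
        fit = fit_subject(one, "vehicle_rw", "low", seed=0)
        assert "eps_w" in fit.dropped
        assert "eps_w" not in fit.params

    def test_recovers_strong_preferences(self, task_design):
        # data simulated from a strongly distance-averse subject should
        # yield a clearly positive recovered distance sensitivity
        from ctrltask.cohort import SubjectProfile, simulate_subject

        params = ParamSet(alpha_d=4.0, alpha_r=1.0, alpha_H=1.5, eps_w=0.3,
                          eps_l=0.4, H_1=0.2, beta_d=2.0, beta_v=1.0)
        profile = SubjectProfile(
            subject_id=0, dgt_model="vehicle_rw", sgt_model="sgt_interaction",
            params_high=params, params_low=params, press_rate=8.0,
            factors=np.zeros(3), item_responses=np.zeros(24, int),
            loc_scores={"I": 0, "C": 0, "P": 0})
        df = simulate_subject(profile, task_design, seed=10)
        fit = fit_subject(df, "vehicle_rw", "high", seed=1)
        assert fit.params["alpha_d"] > 1.0

    def test_mcmc_runs_and_attaches_draws(self, small_cohort):
        df = small_cohort["trials"]
        one = df[df.subject_id == 0]
        fit = fit_subject(one, "additive", "high", method="mcmc", seed=0,
                          mcmc_steps=80, n_draws=40)
        assert fit.draws is not None and fit.loglik_draws.shape[0] == 40


class TestWaic:
    def test_single_draw_degenerates_to_deviance(self):
        ll = np.log([[0.5, 0.25, 0.1]])
        assert waic(ll) == pytest.approx(-2 * ll.sum())

    def test_toy_matrix_matches_hand_computation(self):
        # draws x trials = 2 x 2, worked by hand:
        # lppd = sum_t log(mean_s p_st); p_waic = sum_t var_s(log p_st)
        ll = np.log(np.array([[0.5, 0.2], [0.25, 0.4]]))
        lppd = math.log((0.5 + 0.25) / 2) + math.log((0.2 + 0.4) / 2)
        p_waic = (np.var([math.log(0.5), math.log(0.25)])
                  + np.var([math.log(0.2), math.log(0.4)]))
        assert waic(ll) == pytest.approx(-2 * (lppd - p_waic))

    def test_invariant_to_draw_replication(self):
        rng = np.random.default_rng(0)
        ll = -rng.exponential(1.0, size=(10, 7))
        assert waic(np.vstack([ll, ll])) == pytest.approx(waic(ll))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            waic(np.array([[0.0, -np.inf]]))

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        ll = np.log(rng.uniform(0.05, 0.95, size=(50, 12)))
        idata = az.from_dict(log_likelihood={"y": ll[np.newaxis]})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = az.waic(idata, scale="deviance")
        assert waic(ll) == pytest.approx(float(ref.elpd_waic), rel=1e-6)


class TestLoso:
    def _uniform_cohort(self, n_subjects=4, n_trials=6):
        frames = []
        rng = np.random.default_rng(0)
        for sid in range(n_subjects):
            rows = []
            for i in range(n_trials):
                rows.append((1, i + 1, 20, 52, 36, 36, 25, 75,
                             int(rng.integers(1, 3)), int(rng.integers(0, 2)),
                             False, 10, 40))
            df = make_dgt_frame(rows)
            df["subject_id"] = sid
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_uniform_cohort_scores_quarter(self):
        # additive model on choice-free data collapses to the uniform
        # policy, whose per-trial predictive probability is 1/4
        trials = self._uniform_cohort()
        scores, mean = loso(trials, "additive", "high", seed=0)
        assert mean == pytest.approx(0.25, abs=0.02)

    def test_identical_subjects_match_within_sample_probability(self):
        base = self._uniform_cohort(n_subjects=1, n_trials=8)
        frames = []
        for sid in range(3):
            df = base.copy()
            df["subject_id"] = sid
            frames.append(df)
        trials = pd.concat(frames, ignore_index=True)
        scores, mean = loso(trials, "additive", "high", seed=0)
        fit = fit_subject(trials[trials.subject_id == 0], "additive", "high",
                          seed=0)
        assert mean == pytest.approx(fit.mean_choice_prob, abs=1e-6)

    def test_requires_three_subjects(self):
        trials = self._uniform_cohort(n_subjects=2)
        with pytest.raises(ValueError):
            loso(trials, "additive", "high")


class TestH16CarryOver:
    def test_replay_matches_generative_truth(self, small_cohort):
        # replaying the generative parameters must reproduce the h16
        # columns the simulator recorded
        from ctrltask.inference import h16_from_params

        df = small_cohort["trials"]
        profile = small_cohort["profiles"][0]
        one = df[(df.subject_id == 0) & (df.influence == "high")]
        h16 = h16_from_params(one, profile.params_high)
        sgt = one[one.phase == "SGT"]
        for block_id, (h1, h2) in h16.items():
            rows = sgt[sgt.block == block_id]
            assert rows.h16_v1.iloc[0] == pytest.approx(h1)
            assert rows.h16_v2.iloc[0] == pytest.approx(h2)

    def test_attach_h16_enables_sgt_fitting(self, small_cohort):
        from ctrltask.inference import attach_h16

        df = small_cohort["trials"]
        one = df[(df.subject_id == 1) & (df.influence == "high")].copy()
        one[["h16_v1", "h16_v2"]] = np.nan
        dgt_fit = fit_subject(one, "vehicle_rw", "high", seed=0)
        restored = attach_h16(one, dgt_fit.params)
        fit = fit_subject(restored, "sgt_interaction", "high", seed=0)
        assert np.isfinite(fit.nll)


class TestLaplace:
    def test_draw_shapes_and_determinism(self, small_cohort):
        df = small_cohort["trials"]
        one = df[df.subject_id == 3]
        fit = laplace_draws(fit_subject(one, "additive", "high", seed=0),
                            n_draws=30, seed=5)
        fit2 = laplace_draws(fit_subject(one, "additive", "high", seed=0),
                             n_draws=30, seed=5)
        assert fit.draws.shape == (30, len(fit.param_names))
        assert np.allclose(fit.draws, fit2.draws)
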