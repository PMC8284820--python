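import numpy as np
import pandas as pd
import pytest

from ctrltask import cohort as cohort_mod
from ctrltask.design import DEFAULT_GAMMA_LEVELS, build_task


@pytest.fixture(scope="session")
def gamma_levels():
    """Pre-calibrated guidability levels (diagonal geometry anchors)."""
    return DEFAULT_GAMMA_LEVELS


@pytest.fixture(scope="session")
def task_design(gamma_levels):
    return build_task(gamma_levels=gamma_levels, seed=11)


@pytest.fixture(scope="session")
def small_cohort(task_design):
    """8 paper-like subjects with trial logs, profiles and ground truth."""
    profiles = cohort_mod.sample_population(8, seed=42, scenario="paper-like")
    trials = cohort_mod.simulate_cohort(profiles, task_design, seed=43)
    return {"profiles": profiles, "trials": trials,
            "subjects": cohort_mod.profiles_frame(profiles),
            "truth": cohort_mod.truth_frame(profiles)}


def make_dgt_frame(rows, influence="high"):
    """Hand-built double-goal trial log for likelihood oracles.

    Each row: (block, index_in_block, d_v1_gm, d_v1_gp, d_v2_gm, d_v2_gp,
    r_gm, r_gp, chosen_vehicle, chosen_goal, success, n_matched, n_executed).
    """
    cols = ["block", "index_in_block", "d_v1_gm", "d_v1_gp", "d_v2_gm",
            "d_v2_gp", "r_gm", "r_gp", "chosen_vehicle", "chosen_goal",
            "success", "n_matched", "n_executed"]
    df = pd.DataFrame(rows, columns=cols)
    df["phase"] = "DGT"
    df["influence"] = influence
    df["subject_id"] = 0
    df["trial_type"] = "t1"
    won = np.where(df.chosen_goal == 1, df.r_gp, df.r_gm)
    df["payoff"] = np.where(df.success, won, -15)
    return df


@pytest.fixture
def toy_dgt_frame():
    """Three sequential trials in one block exercising every outcome."""
    return make_dgt_frame([
        # b idx d11 d12 d21 d22 rgm rgp veh goal success match exec
        (1, 1, 12, 60, 36, 36, 20, 80, 2, 1, False, 50, 100),
        (1, 2, 20, 52, 36, 36, 25, 75, 2, 1, True, 60, 100),
        (1, 3, 28, 44, 36, 36, 30, 70, 1, 0, True, 40, 80),
    ])
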