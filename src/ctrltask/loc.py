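"""Questionnaire psychometrics and the statistics linking scores to behaviour.

Covers Levenson-scale scoring (three 8-item subscales on a 0-5 Likert
range), internal consistency (Cronbach's alpha with a percentile
bootstrap CI), varimax-rotated factor analysis, model-agnostic outcome
measures from the trial logs, exclusion screening, permutation
correlation tests with empirical nulls, the parameter-shuffle necessity
analysis, random-forest permutation importance on out-of-bag error,
Benjamini-Hochberg FDR control, and the Fisher-z power calculation for
Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FactorAnalysis
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.multitest import multipletests

from .cohort import ITEMS_PER_SCALE, LIKERT_MAX, N_ITEMS, SUBSCALES

DEFAULT_KEY_MAP = {s: tuple(range(i * ITEMS_PER_SCALE,
                                  (i + 1) * ITEMS_PER_SCALE))
                   for i, s in enumerate(SUBSCALES)}


# ---------------------------------------------------------------------------
# Questionnaire
# ---------------------------------------------------------------------------

def score_levenson(item_responses, key_map=None) -> dict:
    """Subscale sums (I, C, P) from 24 Likert responses."""
    key_map = key_map or DEFAULT_KEY_MAP
    r = np.asarray(item_responses)
    if r.shape[-1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} responses, got {r.shape[-1]}")
    if np.any((r < 0) | (r > LIKERT_MAX)):
        raise ValueError("responses outside the Likert range")
    return {s: int(r[list(idx)].sum()) for s, idx in key_map.items()}


def cronbach_alpha(item_matrix, n_boot: int = 1000, seed: int = 0,
                   ci: float = 0.95) -> tuple:
    """Cronbach's alpha with a percentile bootstrap CI over respondents.

    alpha = k/(k-1) * (1 - sum(item variances) / variance of the sum).
    """
    X = np.asarray(item_matrix, dtype=float)
    n, k = X.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 items and >= 3 respondents")

    def _alpha(M):
        total_var = M.sum(axis=1).var(ddof=1)
        if total_var == 0:
            raise ValueError("zero total variance")
        return k / (k - 1) * (1.0 - M.var(axis=0, ddof=1).sum() / total_var)

    a = _alpha(X)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(_alpha(X[idx]))
        except ValueError:
            continue
    lo, hi = np.percentile(boots, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return float(a), (float(lo), float(hi))


def varimax_factor_analysis(item_matrix, n_factors: int = 4) -> dict:
    """Varimax-rotated factor analysis of standardized item responses.

    Returns rotated loadings (items x factors), respondent scores,
    communalities, the variance explained per factor, and the chi-square
    goodness-of-fit p-value of the unrotated solution.
    """
    X = np.asarray(item_matrix, dtype=float)
    n, k = X.shape
    if n_factors >= k:
        raise ValueError("n_factors must be smaller than the item count")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise np.linalg.LinAlgError("constant item; correlation matrix singular")
    Z = (X - X.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=n_factors, rotation="varimax",
                        random_state=0)
    scores = fa.fit_transform(Z)
    loadings = fa.components_.T                      # items x factors
    communal = (loadings**2).sum(axis=1)
    var_explained = (loadings**2).sum(axis=0) / k
    # likelihood-ratio test of the m-factor model against the saturated one
    R = np.corrcoef(Z, rowvar=False)
    Sigma = loadings @ loadings.T + np.diag(fa.noise_variance_)
    sign, logdet_S = np.linalg.slogdet(Sigma)
    _, logdet_R = np.linalg.slogdet(R)
    m = n_factors
    dof = ((k - m)**2 - (k + m)) / 2
    chi2 = ((n - 1 - (2 * k + 4 * m + 5) / 6)
            * (logdet_S - logdet_R
               + np.trace(np.linalg.solve(Sigma, R)) - k))
    p = float(stats.chi2.sf(max(chi2, 0.0), dof)) if dof > 0 else np.nan
    return {"loadings": loadings, "scores": scores,
            "communalities": communal, "variance_explained": var_explained,
            "cumulative_variance": float(var_explained.sum()),
            "chi2": float(chi2), "chi2_dof": dof, "chi2_p": p}


# ---------------------------------------------------------------------------
# Outcome measures, exclusions
# ---------------------------------------------------------------------------

@dataclass
class OutcomeMeasures:
    gplus_frequency: float        # proportion of DGT attempts on g+
    v1_on_gplus_frequency: float  # g+ attempts made with the more guidable v1
    catch_accuracy: float         # (v1, g+) choices on catch trials
    closer_vehicle_frequency: float  # SGT choices of the closer vehicle
    money: int                    # summed payoffs (pence)
    losses: int


def outcome_measures(df: pd.DataFrame, condition: str | None = None,
                     ) -> OutcomeMeasures:
    """Model-agnostic readouts from one subject's trial log."""
    if condition is not None:
        df = df[df.influence == condition]
    if len(df) == 0:
        raise ValueError("empty trial log for the requested condition")
    dgt = df[df.phase == "DGT"]
    sgt = df[df.phase == "SGT"]
    gplus = dgt.chosen_goal == 1
    v1_on_gp = float((gplus & (dgt.chosen_vehicle == 1)).sum() / max(gplus.sum(), 1))
    catch = dgt[dgt.trial_type == "Catch"]
    catch_acc = float(((catch.chosen_vehicle == 1)
                       & (catch.chosen_goal == 1)).mean()) if len(catch) else np.nan
    if len(sgt):
        closer = np.where(sgt.d_v1_g <= sgt.d_v2_g, 1, 2)
        closer_freq = float((sgt.chosen_vehicle.to_numpy() == closer).mean())
    else:
        closer_freq = np.nan
    return OutcomeMeasures(
        gplus_frequency=float(gplus.mean()),
        v1_on_gplus_frequency=v1_on_gp,
        catch_accuracy=catch_acc,
        closer_vehicle_frequency=closer_freq,
        money=int(df.payoff.sum()),
        losses=int((~df.success.astype(bool)).sum()))


def cohort_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (sid, cond), sdf in trials.groupby(["subject_id", "influence"]):
        om = outcome_measures(sdf)
        rows.append({"subject_id": sid, "condition": cond, **om.__dict__})
    return pd.DataFrame(rows)


def exclusion_screen(catch_accuracy, i_scores, catch_sd: float = 4.0,
                     iscore_sd: float = 3.0) -> list:
    """Outlier subjects by leave-one-out z-scores.

    Flags catch-trial irrationality (1 - accuracy) more than ``catch_sd``
    SDs above the remaining subjects' mean, and I-scores more than
    ``iscore_sd`` SDs from the remaining subjects' mean.
    """
    catch_accuracy = np.asarray(catch_accuracy, dtype=float)
    i_scores = np.asarray(i_scores, dtype=float)
    n = len(catch_accuracy)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    flagged = []
    for i in range(n):
        rest = np.delete(1.0 - catch_accuracy, i)
        sd = rest.std(ddof=1)
        if sd > 0 and (1.0 - catch_accuracy[i] - rest.mean()) / sd > catch_sd:
            flagged.append((i, "catch_irrationality"))
            continue
        rest_i = np.delete(i_scores, i)
        sd_i = rest_i.std(ddof=1)
        if sd_i > 0 and abs(i_scores[i] - rest_i.mean()) / sd_i > iscore_sd:
            flagged.append((i, "i_score_outlier"))
    return flagged


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def permutation_corr_test(x, y, n_perm: int = 10_000, seed: int = 0) -> tuple:
    """Pearson r with an empirical two-sided permutation p-value.

    p = (1 + #{|r_perm| >= |r|}) / (n_perm + 1), with the null built by
    shuffling y across subjects.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = xc @ rng.permutation(yc) / len(x)
    p = (1.0 + np.sum(np.abs(null) >= abs(r))) / (n_perm + 1.0)
    return r, float(p), null


def shuffle_necessity(estimates, effect_fn, n_sets: int = 200, seed: int = 0,
                      ) -> float:
    """Necessity of a fitted parameter for an observed cohort effect.

    ``estimates`` is the per-subject vector of the parameter under test;
    ``effect_fn`` maps a permuted copy of it to the (signed) effect size
    after regenerating synthetic behaviour under the permutation. Returns
    the fraction of permutation-null effects at least as large in
    magnitude as the observed one (identity labelling).
    """
    estimates = np.asarray(estimates, dtype=float)
    observed = effect_fn(estimates)
    if not np.isfinite(observed):
        raise ValueError("effect_fn returned a non-finite observed effect")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sets):
        eff = effect_fn(rng.permutation(estimates))
        if not np.isfinite(eff):
            raise ValueError("effect_fn returned a non-finite null effect")
        if abs(eff) >= abs(observed):
            count += 1
    return count / n_sets


def rf_importance(param_matrix, target_scores, n_repeats: int = 50,
                  n_trees: int = 200, seed: int = 0, max_features=0.7,
                  ) -> pd.DataFrame:
    """Out-of-bag permutation importance of parameters for score prediction.

    A bootstrap ensemble of regression trees is grown; for every tree,
    each predictor is shuffled within that tree's out-of-bag rows and the
    increase in OOB squared error is recorded. The whole procedure is
    repeated ``n_repeats`` times; importances are means with standard
    errors across repeats.
    """
    X = np.asarray(param_matrix, dtype=float)
    y = np.asarray(target_scores, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if y.std() == 0:
        raise ValueError("constant target")
    cols = (list(param_matrix.columns) if isinstance(param_matrix, pd.DataFrame)
            else [f"x{i}" for i in range(p)])
    rng = np.random.default_rng(seed)
    per_repeat = np.zeros((n_repeats, p))
    for rep in range(n_repeats):
        incr = np.zeros(p)
        counts = np.zeros(p)
        for _ in range(max(n_trees // 10, 20)):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) < 2:
                continue
            tree = DecisionTreeRegressor(
                max_features=max_features,
                random_state=int(rng.integers(2**31 - 1)))
            tree.fit(X[boot], y[boot])
            base = np.mean((y[oob] - tree.predict(X[oob]))**2)
            for j in range(p):
                Xp = X[oob].copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                err = np.mean((y[oob] - tree.predict(Xp))**2)
                incr[j] += err - base
                counts[j] += 1
        per_repeat[rep] = incr / np.maximum(counts, 1)
    return pd.DataFrame({
        "parameter": cols,
        "importance": per_repeat.mean(axis=0),
        "se": per_repeat.std(axis=0, ddof=1) / np.sqrt(n_repeats),
    }).set_index("parameter")


def power_correlation(n: int, rho: float, alpha: float = 0.05,
                      method: str = "fisher", n_sim: int = 20_000,
                      seed: int = 0) -> float:
    """Two-sided power to detect a Pearson correlation of size rho.

    Fisher-z approximation: Phi(sqrt(n-3) * atanh(rho) - z_{1-alpha/2});
    ``method="simulation"`` cross-checks by Monte Carlo.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1,1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if method == "fisher":
        z_crit = stats.norm.ppf(1 - alpha / 2)
        delta = np.sqrt(n - 3) * np.arctanh(abs(rho))
        return float(stats.norm.cdf(delta - z_crit)
                     + stats.norm.cdf(-delta - z_crit))
    if method == "simulation":
        rng = np.random.default_rng(seed)
        hits = 0
        cov = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(cov)
        for _ in range(n_sim):
            xy = rng.standard_normal((n, 2)) @ L.T
            _, p = stats.pearsonr(xy[:, 0], xy[:, 1])
            hits += p < alpha
        return hits / n_sim
    raise ValueError(f"unknown method {method!r}")


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
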