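"""Likelihoods, per-subject fitting, WAIC and leave-one-subject-out scores.

Choices are modelled with the same components in both influence
conditions but each condition gets its own parameter set and is fit
separately. Double-goal likelihoods are softmax over 4 options and
evolve the latent learner state (achievability trace and guidability
estimate) from the *realized* outcomes and press-match counts in the
log; single-goal likelihoods are softmax over the 2 vehicles given the
carried-over achievability ``H_16``.

Fitting is per subject: MAP via multi-start bounded quasi-Newton
optimization on transformed parameters (logit for [0,1] supports, atanh
for [-1,1], identity elsewhere) under weakly-informative priors
(Normal(0,2) on sensitivities, Beta(1.1,1.1) on learning rates,
Uniform(-1,1) on the initial achievability). Posterior draws come from a
Laplace approximation around the MAP by default, or from an
affine-invariant ensemble sampler (emcee) when ``method="mcmc"``.

In low-influence data the success learning rate ``eps_w`` is dropped
from the fit by default whenever the subject recorded no g+ win in that
condition (there is nothing to inform it), matching how the winning
model is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .models import D0, R0, ModelSpec, SYM_PARAMS, UNIT_PARAMS, get_model

_OUT_WON_GP, _OUT_WON_GM, _OUT_LOST = 0, 1, 2
_OUTCOME_CODE = {"won_gplus": 0, "won_gminus": 1, "lost": 2}

_PRIOR_SD = 2.0          # Normal prior sd on unbounded sensitivities
_BETA_A = _BETA_B = 1.1  # Beta prior on learning rates


# ---------------------------------------------------------------------------
# Compiled per-subject data
# ---------------------------------------------------------------------------

@dataclass
class _BlockDGT:
    dists: np.ndarray      # (T,4) distances per option / D0
    rews: np.ndarray       # (T,4) rewards per option / R0
    opt_vehicle: np.ndarray  # (4,) vehicle index (0/1) per option
    gplus: np.ndarray      # (4,) 1.0 where the option's goal is g+
    chosen: np.ndarray     # (T,) chosen option index 0..3
    outcome: np.ndarray    # (T,) outcome code
    chosen_vehicle: np.ndarray  # (T,) 0/1
    matched: np.ndarray    # (T,)
    total: np.ndarray      # (T,)


@dataclass
class _BlockSGT:
    feats_d: np.ndarray    # (T,2) distances / D0
    gammas: np.ndarray     # (2,) true guidabilities
    h16: np.ndarray        # (2,) carried-over achievability
    reach: np.ndarray      # (T,2) reach probabilities (0 where unused)
    chosen: np.ndarray     # (T,) chosen vehicle 0/1


@dataclass
class CompiledSubject:
    phase: str
    blocks: list
    n_trials: int


def _outcome_code(row) -> int:
    if not row.success:
        return _OUT_LOST
    if row.phase == "SGT" or row.chosen_goal == 0:
        return _OUT_WON_GM
    return _OUT_WON_GP


def compile_dgt(df) -> CompiledSubject:
    """Flatten one subject-condition's DGT rows into replayable arrays."""
    blocks = []
    n = 0
    for _, bdf in df[df.phase == "DGT"].groupby("block", sort=True):
        bdf = bdf.sort_values("index_in_block")
        T = len(bdf)
        dists = np.column_stack([
            bdf.d_v1_gm, bdf.d_v1_gp, bdf.d_v2_gm, bdf.d_v2_gp]) / D0
        rews = np.column_stack([
            bdf.r_gm, bdf.r_gp, bdf.r_gm, bdf.r_gp]) / R0
        chosen = (2 * (bdf.chosen_vehicle.to_numpy() - 1)
                  + bdf.chosen_goal.to_numpy()).astype(int)
        outcome = np.array([_outcome_code(r) for r in bdf.itertuples()])
        blocks.append(_BlockDGT(
            dists=dists, rews=rews,
            opt_vehicle=np.array([0, 0, 1, 1]),
            gplus=np.array([0.0, 1.0, 0.0, 1.0]),
            chosen=chosen, outcome=outcome,
            chosen_vehicle=(bdf.chosen_vehicle.to_numpy() - 1).astype(int),
            matched=bdf.n_matched.to_numpy().astype(float),
            total=bdf.n_executed.to_numpy().astype(float)))
        n += T
    return CompiledSubject(phase="DGT", blocks=blocks, n_trials=n)


def compile_sgt(df, reach_prob=None) -> CompiledSubject:
    """Flatten SGT rows; requires h16_v1/h16_v2 columns (generative truth
    or a replay of the subject's fitted double-goal model)."""
    blocks = []
    n = 0
    for _, bdf in df[df.phase == "SGT"].groupby("block", sort=True):
        bdf = bdf.sort_values("index_in_block")
        gammas = np.array([bdf.gamma_v1.iloc[0], bdf.gamma_v2.iloc[0]])
        h16 = np.array([bdf.h16_v1.iloc[0], bdf.h16_v2.iloc[0]])
        feats_d = np.column_stack([bdf.d_v1_g, bdf.d_v2_g]) / D0
        cap = bdf.cap_hz.iloc[0]
        if reach_prob is not None:
            reach = np.column_stack([
                [reach_prob(int(d * D0), gammas[0], cap) for d in feats_d[:, 0]],
                [reach_prob(int(d * D0), gammas[1], cap) for d in feats_d[:, 1]]])
        else:
            reach = np.zeros_like(feats_d)
        blocks.append(_BlockSGT(
            feats_d=feats_d, gammas=gammas, h16=h16, reach=reach,
            chosen=(bdf.chosen_vehicle.to_numpy() - 1).astype(int)))
        n += len(bdf)
    return CompiledSubject(phase="SGT", blocks=blocks, n_trials=n)


# ---------------------------------------------------------------------------
# Log-likelihood
# ---------------------------------------------------------------------------

def _gamma_hat(matched, total, prior_strength=4.0, prior_mean=0.625):
    m = (matched + prior_strength * prior_mean) / (total + prior_strength)
    return min(max((4.0 * m - 1.0) / 3.0, 0.0), 1.0)


def loglik_trials(compiled: CompiledSubject, model: ModelSpec, p: dict,
                  ) -> np.ndarray:
    """Per-trial log choice probabilities under the model (values <= 0)."""
    if compiled.phase != model.phase:
        raise ValueError(f"model {model.name} does not fit {compiled.phase} data")
    if compiled.phase == "DGT":
        return _loglik_dgt(compiled, model, p)
    return _loglik_sgt(compiled, model, p)


def _loglik_dgt(compiled, model, p):
    shared = model.name == "vehicle_independent_rw"
    has_rw = "alpha_H" in model.params
    has_bias = "bias_gplus" in model.params
    has_wsls = "kappa_wsls" in model.params
    a_d = p.get("alpha_d", 0.0)
    a_r = p.get("alpha_r", 0.0)
    a_v = p.get("alpha_v", 0.0)
    a_H = p.get("alpha_H", 0.0)
    e_w = p.get("eps_w", 0.0)
    e_l = p.get("eps_l", 0.0)
    e_g = p.get("eps_g", 0.0)
    out = []
    for blk in compiled.blocks:
        H = [p.get("H_1", 0.0), p.get("H_1", 0.0)]
        cnt_m = [0.0, 0.0]
        cnt_t = [0.0, 0.0]
        s_prev = 0.0
        T = len(blk.chosen)
        for t in range(T):
            gh = (_gamma_hat(cnt_m[0], cnt_t[0]),
                  _gamma_hat(cnt_m[1], cnt_t[1]))
            v = (-a_d * blk.dists[t]
                 + a_r * blk.rews[t]
                 + a_v * np.array([gh[0], gh[0], gh[1], gh[1]]))
            if has_bias or has_wsls or has_rw:
                extra = 0.0
                if has_bias:
                    extra += p.get("bias_gplus", 0.0)
                if has_wsls:
                    extra += p.get("kappa_wsls", 0.0) * s_prev
                if has_rw:
                    v[1] += a_H * H[0] + extra
                    v[3] += a_H * H[1] + extra
                else:
                    v[1] += extra
                    v[3] += extra
            m = v.max()
            lse = m + math.log(np.exp(v - m).sum())
            out.append(v[blk.chosen[t]] - lse)
            # state transition from the realized outcome
            cv = blk.chosen_vehicle[t]
            oc = blk.outcome[t]
            cnt_m[cv] += blk.matched[t]
            cnt_t[cv] += blk.total[t]
            if oc == _OUT_WON_GP:
                if shared:
                    H[0] += e_w * (1.0 - H[0])
                    H[1] += e_w * (1.0 - H[1])
                else:
                    H[cv] += e_w * (1.0 - H[cv])
                s_prev = 1.0
            elif oc == _OUT_LOST:
                if shared:
                    H[0] += e_l * (-1.0 - H[0])
                    H[1] += e_l * (-1.0 - H[1])
                else:
                    H[cv] += e_l * (-1.0 - H[cv])
                s_prev = -1.0
            else:
                if e_g > 0.0:
                    if shared:
                        H[0] += e_g * (1.0 - H[0])
                        H[1] += e_g * (1.0 - H[1])
                    else:
                        H[cv] += e_g * (1.0 - H[cv])
                s_prev = 1.0
    return np.array(out)


def _loglik_sgt(compiled, model, p):
    out = []
    for blk in compiled.blocks:
        v = np.full_like(blk.feats_d, 0.0)
        v += p.get("beta_H", 0.0) * blk.h16[None, :]
        if "beta_d" in model.params:
            v += (-p.get("beta_d", 0.0) * blk.feats_d
                  + p.get("beta_v", 0.0) * blk.gammas[None, :])
        if "beta_dv" in model.params:
            v += p.get("beta_dv", 0.0) * blk.feats_d * blk.gammas[None, :]
        if "beta_p" in model.params:
            v += p.get("beta_p", 0.0) * blk.reach
        m = v.max(axis=1, keepdims=True)
        lse = (m[:, 0] + np.log(np.exp(v - m).sum(axis=1)))
        out.append(v[np.arange(len(v)), blk.chosen] - lse)
    return np.concatenate(out)


def h16_from_params(df, params, shared: bool = False) -> dict:
    """Replay a subject's double-goal trials under fitted parameters and
    return the per-block end-of-learning achievability {block: (H1, H2)}.

    Used to populate the ``h16_v1``/``h16_v2`` columns before fitting
    single-goal models when no generative truth is available.
    """
    p = params.as_dict() if hasattr(params, "as_dict") else dict(params)
    out = {}
    for block_id, bdf in df[df.phase == "DGT"].groupby("block", sort=True):
        bdf = bdf.sort_values("index_in_block")
        H = [p.get("H_1", 0.0), p.get("H_1", 0.0)]
        for row in bdf.itertuples():
            cv = int(row.chosen_vehicle) - 1
            oc = _outcome_code(row)
            idx = (0, 1) if shared else (cv,)
            for i in idx:
                if oc == _OUT_WON_GP:
                    H[i] += p.get("eps_w", 0.0) * (1.0 - H[i])
                elif oc == _OUT_LOST:
                    H[i] += p.get("eps_l", 0.0) * (-1.0 - H[i])
                elif p.get("eps_g", 0.0) > 0.0:
                    H[i] += p["eps_g"] * (1.0 - H[i])
        out[block_id] = (H[0], H[1])
    return out


def attach_h16(df, params, shared: bool = False):
    """Return a copy of the trial log with h16 columns recomputed from a
    fitted double-goal parameter set."""
    h16 = h16_from_params(df, params, shared=shared)
    out = df.copy()
    for block_id, (h1, h2) in h16.items():
        mask = (out.block == block_id) & (out.phase == "SGT")
        out.loc[mask, "h16_v1"] = h1
        out.loc[mask, "h16_v2"] = h2
    return out


def negative_log_likelihood(df, model, params, condition: str | None = None,
                            reach_prob=None) -> float:
    """Summed -log P(choice) over one subject's trials of a condition.

    ``params`` may be a ParamSet or a plain dict; ``df`` is the flat
    trial log (one subject).
    """
    model = get_model(model) if isinstance(model, str) else model
    if condition is not None:
        df = df[df.influence == condition]
    p = params.as_dict() if hasattr(params, "as_dict") else dict(params)
    compiled = (compile_dgt(df) if model.phase == "DGT"
                else compile_sgt(df, reach_prob=reach_prob))
    if compiled.n_trials == 0:
        raise ValueError("no trials for the requested condition/phase")
    return float(-loglik_trials(compiled, model, p).sum())


# ---------------------------------------------------------------------------
# Parameter transforms and priors
# ---------------------------------------------------------------------------

def to_unconstrained(name: str, value: float) -> float:
    if name in UNIT_PARAMS:
        return float(logit(np.clip(value, 1e-9, 1 - 1e-9)))
    if name in SYM_PARAMS:
        return float(np.arctanh(np.clip(value, -1 + 1e-9, 1 - 1e-9)))
    return float(value)


def to_natural(name: str, x: float) -> float:
    if name in UNIT_PARAMS:
        return float(expit(x))
    if name in SYM_PARAMS:
        return float(np.tanh(x))
    return float(x)


def _log_prior(names, x) -> float:
    """Log prior density on the unconstrained scale (Jacobian included)."""
    lp = 0.0
    for name, xi in zip(names, x):
        if name in UNIT_PARAMS:
            e = min(max(float(expit(xi)), 1e-300), 1.0 - 1e-16)
            # Beta(1.1,1.1) on eps plus d eps / dx = eps(1-eps)
            lp += (_BETA_A - 1) * math.log(e) + (_BETA_B - 1) * math.log1p(-e)
            lp += math.log(e) + math.log1p(-e)
        elif name in SYM_PARAMS:
            h = min(abs(math.tanh(xi)), 1.0 - 1e-16)
            lp += math.log1p(-h * h)  # Uniform(-1,1) plus Jacobian
        else:
            lp += -0.5 * (xi / _PRIOR_SD) ** 2
    return lp


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    subject_id: object
    model: str
    condition: str
    params: dict                  # natural-scale point estimates
    param_names: tuple
    x: np.ndarray                 # unconstrained MAP / posterior mean
    nll: float                    # -log likelihood at the point estimate
    loglik: np.ndarray            # per-trial log-likelihoods at the point
    n_trials: int
    method: str
    converged: bool
    draws: np.ndarray | None = None         # (S, P) unconstrained draws
    loglik_draws: np.ndarray | None = None  # (S, T)
    dropped: tuple = ()

    @property
    def mean_choice_prob(self) -> float:
        return float(np.exp(self.loglik.mean()))


def _free_params(model: ModelSpec, df, condition: str, drop_eps_w: bool):
    names = list(model.params)
    dropped = []
    if (drop_eps_w and "eps_w" in names and condition == "low"):
        wins = ((df.influence == "low") & (df.phase == "DGT")
                & df.success & (df.chosen_goal == 1)).sum()
        if wins == 0:
            names.remove("eps_w")
            dropped.append("eps_w")
    return tuple(names), tuple(dropped)


def fit_subject(df, model, condition: str, method: str = "map",
                seed: int = 0, n_starts: int = 4, reach_prob=None,
                drop_eps_w: bool = True, mcmc_steps: int = 600,
                n_draws: int = 200, subject_id=None) -> FitResult:
    """Fit one subject's trials of one influence condition."""
    model = get_model(model) if isinstance(model, str) else model
    sub = df[df.influence == condition]
    if subject_id is None:
        subject_id = sub.subject_id.iloc[0] if "subject_id" in sub else None
    names, dropped = _free_params(model, df, condition, drop_eps_w)
    compiled = (compile_dgt(sub) if model.phase == "DGT"
                else compile_sgt(sub, reach_prob=reach_prob))
    if compiled.n_trials == 0:
        raise ValueError(f"no {model.phase} trials in condition {condition!r}")

    def unpack(x):
        return {n: to_natural(n, xi) for n, xi in zip(names, x)}

    def nlp(x):
        ll = loglik_trials(compiled, model, unpack(x)).sum()
        return -(ll + _log_prior(names, x))

    rng = np.random.default_rng(seed)
    best = None
    starts = [np.zeros(len(names))]
    starts += [rng.normal(0.0, 1.0, len(names)) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(nlp, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    x_map = best.x
    p_map = unpack(x_map)
    ll_vec = loglik_trials(compiled, model, p_map)

    draws = loglik_draws = None
    if method == "map":
        converged = bool(best.success)
    elif method == "mcmc":
        import emcee

        ndim = len(names)
        nwalk = max(2 * ndim + 2, 8)
        p0 = x_map + 0.05 * rng.normal(size=(nwalk, ndim))
        sampler = emcee.EnsembleSampler(
            nwalk, ndim, lambda x: -nlp(x))
        state = emcee.State(p0, random_state=np.random.RandomState(seed))
        sampler.run_mcmc(state, mcmc_steps, progress=False)
        chain = sampler.get_chain(discard=mcmc_steps // 2, flat=True)
        idx = rng.choice(len(chain), size=min(n_draws, len(chain)),
                         replace=False)
        draws = chain[idx]
        x_map = draws.mean(axis=0)
        p_map = unpack(x_map)
        ll_vec = loglik_trials(compiled, model, p_map)
        converged = bool(np.all(np.isfinite(draws)))
    else:
        raise ValueError(f"unknown method {method!r}")

    fit = FitResult(subject_id=subject_id, model=model.name,
                    condition=condition, params=p_map, param_names=names,
                    x=x_map, nll=float(-ll_vec.sum()), loglik=ll_vec,
                    n_trials=compiled.n_trials, method=method,
                    converged=converged, draws=draws, dropped=dropped)
    if draws is not None:
        fit.loglik_draws = np.stack(
            [loglik_trials(compiled, model, unpack(d)) for d in draws])
    fit._compiled = compiled
    fit._model = model
    return fit


def laplace_draws(fit: FitResult, n_draws: int = 200, seed: int = 0,
                  eps: float = 1e-4) -> FitResult:
    """Attach Gaussian posterior draws around the MAP (Laplace method).

    The Hessian of the negative log posterior is estimated by central
    finite differences and ridge-regularized to positive definiteness.
    """
    compiled, model = fit._compiled, fit._model
    names = fit.param_names

    def unpack(x):
        return {n: to_natural(n, xi) for n, xi in zip(names, x)}

    def nlp(x):
        ll = loglik_trials(compiled, model, unpack(x)).sum()
        return -(ll + _log_prior(names, x))

    n = len(names)
    x0 = fit.x
    H = np.zeros((n, n))
    f0 = nlp(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            if i == j:
                H[i, i] = (nlp(x0 + ei) - 2 * f0 + nlp(x0 - ei)) / eps**2
            else:
                val = (nlp(x0 + ei + ej) - nlp(x0 + ei - ej)
                       - nlp(x0 - ei + ej) + nlp(x0 - ei - ej)) / (4 * eps**2)
                H[i, j] = H[j, i] = val
    # regularize to PD
    w = np.linalg.eigvalsh(H)
    ridge = max(0.0, 1e-6 - w.min())
    cov = np.linalg.inv(H + (ridge + 1e-10) * np.eye(n))
    cov = (cov + cov.T) / 2
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(x0, cov, size=n_draws,
                                    method="eigh")
    fit.draws = draws
    fit.loglik_draws = np.stack(
        [loglik_trials(compiled, model, unpack(d)) for d in draws])
    fit._cov = cov
    return fit


def posterior_correlations(fit: FitResult) -> np.ndarray:
    """Correlation matrix of the posterior draws (param order as fit)."""
    if fit.draws is None:
        raise ValueError("fit has no draws; run laplace_draws or mcmc first")
    return np.corrcoef(fit.draws, rowvar=False)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def waic(loglik_draws: np.ndarray) -> float:
    """WAIC = -2 (lppd - p_waic) from an (S draws x T trials) matrix."""
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 1:
        raise ValueError("loglik_draws must be a (draws x trials) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood draws")
    S = ll.shape[0]
    m = ll.max(axis=0)
    lppd = (m + np.log(np.exp(ll - m).mean(axis=0))).sum()
    p_waic = ll.var(axis=0, ddof=0).sum() if S > 1 else 0.0
    return float(-2.0 * (lppd - p_waic))


def cohort_waic(trials: "pd.DataFrame", model, condition: str,
                method: str = "map", n_draws: int = 100, seed: int = 0,
                reach_prob=None) -> tuple:
    """Summed WAIC over subjects, with the per-subject fits."""
    model = get_model(model) if isinstance(model, str) else model
    fits = []
    total = 0.0
    for k, (sid, sdf) in enumerate(trials.groupby("subject_id", sort=True)):
        fit = fit_subject(sdf, model, condition, method=method,
                          seed=seed + 17 * k, reach_prob=reach_prob,
                          n_draws=n_draws, subject_id=sid)
        if fit.loglik_draws is None:
            fit = laplace_draws(fit, n_draws=n_draws, seed=seed + 31 * k)
        total += waic(fit.loglik_draws)
        fits.append(fit)
    return total, fits


def loso(trials: "pd.DataFrame", model, condition: str, seed: int = 0,
         reach_prob=None, fits: list | None = None) -> tuple:
    """Leave-one-subject-out predictive score.

    Every subject is fit once (MAP); each is then scored under the mean
    (in the unconstrained space) of the *other* subjects' estimates. The
    per-subject score is the geometric-mean per-trial predictive
    probability, so scores live in (0,1); higher is better.
    """
    subject_ids = sorted(trials.subject_id.unique())
    if len(subject_ids) < 3:
        raise ValueError("LOSO requires at least 3 subjects")
    model = get_model(model) if isinstance(model, str) else model
    if fits is None:
        fits = [fit_subject(trials[trials.subject_id == sid], model,
                            condition, seed=seed + 17 * k, subject_id=sid,
                            reach_prob=reach_prob)
                for k, sid in enumerate(subject_ids)]
    # free-parameter sets can differ across subjects (e.g. eps_w dropped
    # for subjects without low-influence wins): pool per parameter name
    values = {}
    for f in fits:
        for n, xi in zip(f.param_names, f.x):
            values.setdefault(n, []).append((f.subject_id, xi))
    scores = {}
    for sid, fit in zip(subject_ids, fits):
        p_group = {}
        for n in fit.param_names:
            others = [xi for s, xi in values[n] if s != sid]
            x_mean = np.mean(others) if others else dict(values[n])[sid]
            p_group[n] = to_natural(n, x_mean)
        ll = loglik_trials(fit._compiled, fit._model, p_group)
        scores[sid] = float(np.exp(ll.mean()))
    return scores, float(np.mean(list(scores.values())))


def compare_models(trials: "pd.DataFrame", models, condition: str,
                   seed: int = 0, n_draws: int = 100, reach_prob=None,
                   ) -> "pd.DataFrame":
    """WAIC and LOSO comparison table across a model family."""
    import pandas as pd

    rows = []
    for model in models:
        spec = get_model(model) if isinstance(model, str) else model
        total, fits = cohort_waic(trials, spec, condition, n_draws=n_draws,
                                  seed=seed, reach_prob=reach_prob)
        _, loso_mean = loso(trials, spec, condition, seed=seed,
                            reach_prob=reach_prob, fits=fits)
        rows.append({"model": spec.name, "WAIC": total, "LOSO": loso_mean})
    out = pd.DataFrame(rows).set_index("model")
    out["waic_rank"] = out.WAIC.rank().astype(int)
    out["loso_rank"] = out.LOSO.rank(ascending=False).astype(int)
    return out
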