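"""Trial-by-trial choice and learning models.

Double-goal trials (DGTs) are modelled as a softmax choice over the four
(vehicle, goal) options, with value built from additive sensitivities to
vehicle-goal distance, estimated vehicular guidability and reward size,
plus — in the richer variants — terms that favour or discourage the
riskier, more rewarding goal ``g+``: a fixed bias, a win-stay/lose-shift
signal, or a Rescorla-Wagner *achievability* trace ``H``.

The achievability trace H(v) lives in [-1, 1] and summarises the history
of achievement with vehicle v: it rises towards +1 when g+ is achieved
with v (learning rate ``eps_w``), falls towards -1 on *any* loss with v
(learning rate ``eps_l``), and is untouched by wins of the easier goal
g- or by outcomes of the other vehicle. The "vehicle-independent" variant
ties the trace across both vehicles. H resets to its prior H_1 at each
block start (vehicles change between blocks).

Single-goal trials (SGTs) are a softmax choice between the two vehicles;
variants combine distance, (known) guidability, their interaction, the
pure probability of reaching the goal, and the carried-over achievability
H_16(v) from the block's final double-goal trial.

Distances are normalized by D0 = 44 (the single-goal design distance)
and rewards by R0 = 100 pence so sensitivities are comparable; the
softmax temperature is fixed to 1 (its scale is absorbed into the
sensitivities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

D0 = 44.0     # distance normalizer (steps)
R0 = 100.0    # reward normalizer (pence)

OUTCOMES = ("won_gplus", "won_gminus", "lost", "none")

#: [0,1]-supported parameters (fit on the logit scale)
UNIT_PARAMS = ("eps_w", "eps_l", "eps_g")
#: [-1,1]-supported parameters (fit on the atanh scale)
SYM_PARAMS = ("H_1",)


@dataclass
class ParamSet:
    """Named parameters; each model variant uses a declared subset."""

    alpha_d: float = 0.0     # distance sensitivity (DGT)
    alpha_r: float = 0.0     # reward sensitivity
    alpha_v: float = 0.0     # guidability sensitivity
    alpha_H: float = 0.0     # learning gain (weight on H)
    eps_w: float = 0.0       # learning rate from success, in [0,1]
    eps_l: float = 0.0       # learning rate from failure, in [0,1]
    eps_g: float = 0.0       # optional g- achievement learning rate
    H_1: float = 0.0         # initial achievability, in [-1,1]
    bias_gplus: float = 0.0  # absolute g+ propensity
    kappa_wsls: float = 0.0  # weight on the previous-outcome signal
    beta_d: float = 0.0      # SGT distance sensitivity
    beta_v: float = 0.0      # SGT guidability sensitivity
    beta_dv: float = 0.0     # SGT distance x guidability interaction
    beta_H: float = 0.0      # SGT weight on carried-over H_16
    beta_p: float = 0.0      # SGT weight on reach probability

    def __post_init__(self):
        for name in UNIT_PARAMS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in SYM_PARAMS:
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1,1], got {v}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def subset(self, names) -> dict:
        return {n: getattr(self, n) for n in names}

    def with_(self, **kw) -> "ParamSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    phase: str                # "DGT" | "SGT"
    params: tuple             # free parameter names
    parent: str | None = None  # immediate nesting parent

    def null_of_extras(self, parent_spec: "ModelSpec") -> dict:
        """Values of the extra parameters at which this model collapses
        onto its parent."""
        return {p: 0.0 for p in self.params if p not in parent_spec.params}


_ADD = ("alpha_d", "alpha_r", "alpha_v")
_RW = _ADD + ("alpha_H", "eps_w", "eps_l", "H_1")

DGT_MODELS = {
    "additive": ModelSpec("additive", "DGT", _ADD),
    "gplus_bias": ModelSpec("gplus_bias", "DGT", _ADD + ("bias_gplus",),
                            parent="additive"),
    "wsls": ModelSpec("wsls", "DGT", _ADD + ("bias_gplus", "kappa_wsls"),
                      parent="gplus_bias"),
    "vehicle_independent_rw": ModelSpec("vehicle_independent_rw", "DGT", _RW,
                                        parent="additive"),
    "vehicle_rw": ModelSpec("vehicle_rw", "DGT", _RW,
                            parent="vehicle_independent_rw"),
    # optional variant with a separate learning rate for g- achievements
    "vehicle_rw_gm": ModelSpec("vehicle_rw_gm", "DGT", _RW + ("eps_g",),
                               parent="vehicle_rw"),
}

SGT_MODELS = {
    "sgt_additive": ModelSpec("sgt_additive", "SGT",
                              ("beta_d", "beta_v", "beta_H")),
    "sgt_interaction": ModelSpec("sgt_interaction", "SGT",
                                 ("beta_d", "beta_v", "beta_dv", "beta_H"),
                                 parent="sgt_additive"),
    "sgt_additive_prob": ModelSpec("sgt_additive_prob", "SGT",
                                   ("beta_d", "beta_v", "beta_dv", "beta_p",
                                    "beta_H"),
                                   parent="sgt_interaction"),
    "sgt_prob": ModelSpec("sgt_prob", "SGT", ("beta_p", "beta_H")),
}

MODELS = {**DGT_MODELS, **SGT_MODELS}

ALIASES = {
    "bias": "gplus_bias",
    "win_stay_lose_shift": "wsls",
    "rw_common": "vehicle_independent_rw",
    "vehicle_dependent_rw": "vehicle_rw",
}


def get_model(name: str) -> ModelSpec:
    key = ALIASES.get(name, name)
    if key not in MODELS:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODELS)}")
    return MODELS[key]


# ---------------------------------------------------------------------------
# Latent state
# ---------------------------------------------------------------------------

#: Beta-style prior on the press-match probability used by the guidability
#: estimator: prior mean corresponds to gamma = 0.5 via the mixture law.
GAMMA_PRIOR_MEAN_MATCH = (1.0 + 3 * 0.5) / 4.0
GAMMA_PRIOR_STRENGTH = 4.0


@dataclass
class LatentState:
    """Per-block learner state evolved across trials."""

    H: np.ndarray = field(default_factory=lambda: np.zeros(2))
    matched: np.ndarray = field(default_factory=lambda: np.zeros(2))
    total: np.ndarray = field(default_factory=lambda: np.zeros(2))
    s_prev: float = 0.0       # +1 after a win, -1 after a loss, 0 at start
    prior_strength: float = GAMMA_PRIOR_STRENGTH
    prior_mean_match: float = GAMMA_PRIOR_MEAN_MATCH

    @classmethod
    def fresh(cls, H_1: float = 0.0, **kw) -> "LatentState":
        return cls(H=np.full(2, float(H_1)), **kw)

    def gamma_hat(self, vehicle: int) -> float:
        i = vehicle - 1
        return update_guidability_estimate(
            self.matched[i], self.total[i],
            prior_strength=self.prior_strength,
            prior_mean_match=self.prior_mean_match)

    def observe_presses(self, vehicle: int, matched: int, total: int) -> None:
        i = vehicle - 1
        self.matched[i] += matched
        self.total[i] += total

    def observe_outcome(self, outcome: str, vehicle: int, params: ParamSet,
                        shared: bool = False) -> None:
        self.H = update_achievability(self.H, outcome, vehicle,
                                      params.eps_w, params.eps_l,
                                      eps_g=params.eps_g, shared=shared)
        if outcome in ("won_gplus", "won_gminus"):
            self.s_prev = 1.0
        elif outcome == "lost":
            self.s_prev = -1.0


def update_achievability(H_prev, outcome: str, vehicle_used: int,
                         eps_w: float, eps_l: float, eps_g: float = 0.0,
                         shared: bool = False) -> np.ndarray:
    """Rescorla-Wagner update of the achievability trace.

    Wins of g+ pull the used vehicle's H towards +1 at rate eps_w; any
    loss pulls it towards -1 at rate eps_l; wins of g- leave H unchanged
    (unless the optional eps_g rate is used). The unchosen vehicle's H is
    never touched; with ``shared=True`` both entries are updated jointly
    (the vehicle-independent variant).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"invalid outcome {outcome!r}")
    H = np.array(H_prev, dtype=float, copy=True)
    if np.any(np.abs(H) > 1.0):
        raise ValueError("H must lie in [-1,1]")
    if outcome == "none":
        return H
    idx = slice(None) if shared else vehicle_used - 1
    if outcome == "won_gplus":
        H[idx] += eps_w * (1.0 - H[idx])
    elif outcome == "lost":
        H[idx] += eps_l * (-1.0 - H[idx])
    elif outcome == "won_gminus" and eps_g > 0.0:
        H[idx] += eps_g * (1.0 - H[idx])
    return H


def update_guidability_estimate(matched: float, total: float,
                                prior_strength: float = GAMMA_PRIOR_STRENGTH,
                                prior_mean_match: float = GAMMA_PRIOR_MEAN_MATCH,
                                ) -> float:
    """Posterior-mean match fraction mapped through the inverse mixture law.

    The probability that a press is matched by the realized move is
    ``m = gamma + (1 - gamma)/4``, so ``gamma = (4 m - 1)/3`` (clipped to
    [0,1]). The match probability is estimated with a Beta-style prior of
    mean ``prior_mean_match`` and weight ``prior_strength`` pseudo-presses.
    """
    if matched < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    denom = total + prior_strength
    if denom == 0:
        raise ValueError("no presses and zero prior strength")
    m = (matched + prior_strength * prior_mean_match) / denom
    return float(np.clip((4.0 * m - 1.0) / 3.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Values and the choice rule
# ---------------------------------------------------------------------------

#: DGT option order: (vehicle, goal) with goal 0 = g-, 1 = g+.
DGT_OPTIONS = ((1, 0), (1, 1), (2, 0), (2, 1))


def dgt_values(model: ModelSpec, params: ParamSet, state: LatentState,
               trial) -> np.ndarray:
    """Values of the four (vehicle, goal) options of a double-goal trial."""
    if model.phase != "DGT":
        raise ValueError(f"model {model.name} is not a DGT model")
    shared = model.name == "vehicle_independent_rw"
    has_rw = "alpha_H" in model.params
    has_bias = "bias_gplus" in model.params
    has_wsls = "kappa_wsls" in model.params
    values = np.empty(4)
    for k, (v, g) in enumerate(DGT_OPTIONS):
        val = (-params.alpha_d * trial.distance(v, g) / D0
               + params.alpha_v * state.gamma_hat(v)
               + params.alpha_r * trial.rewards[g] / R0)
        if g == 1:
            if has_bias:
                val += params.bias_gplus
            if has_wsls:
                val += params.kappa_wsls * state.s_prev
            if has_rw:
                val += params.alpha_H * state.H[v - 1]
        values[k] = val
    return values


def sgt_values(model: ModelSpec, params: ParamSet, trial, H_16,
               gammas, reach_prob=None, cap_hz: float | None = None,
               ) -> np.ndarray:
    """Values of the two vehicles in a single-goal trial.

    ``H_16`` carries the per-vehicle achievability from the block's final
    double-goal trial; ``gammas`` are the true guidabilities (assumed
    known by the time of the SGTs); ``reach_prob`` is a callable
    ``(distance, gamma, press_rate) -> p`` for the probability variants.
    """
    if model.phase != "SGT":
        raise ValueError(f"model {model.name} is not an SGT model")
    if H_16 is None:
        raise ValueError("missing H_16 carry-over state")
    cap = cap_hz if cap_hz is not None else trial.block.cap_hz
    values = np.empty(2)
    for i, v in enumerate((1, 2)):
        d = trial.distance(v, 0) / D0
        gam = gammas[i]
        val = params.beta_H * H_16[i]
        if "beta_d" in model.params:
            val += -params.beta_d * d + params.beta_v * gam
        if "beta_dv" in model.params:
            val += params.beta_dv * d * gam
        if "beta_p" in model.params:
            if reach_prob is None:
                raise ValueError(f"model {model.name} needs a reach_prob table")
            val += params.beta_p * reach_prob(trial.distance(v, 0), gam, cap)
        values[i] = val
    return values


def choice_probabilities(values) -> np.ndarray:
    """Unit-temperature softmax over option values."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    z = v - v.max()
    e = np.exp(z)
    return e / e.sum()


def classify_outcome(phase: str, chosen_goal: int, success: bool) -> str:
    """Map a realized trial result onto the achievability outcome tags."""
    if not success:
        return "lost"
    if phase == "SGT":
        return "won_gminus"   # single goals carry no g+ evidence
    return "won_gplus" if chosen_goal == 1 else "won_gminus"
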