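"""Vehicle kinematics, trial execution, reach probabilities, calibration.

Each key press intends one of the four cardinal unit moves. The vehicle
follows the intended direction with probability gamma (its guidability)
and otherwise moves in a direction drawn uniformly at random over the
four cardinals — so the marginal probability that the realized move
equals the pressed key is ``gamma + (1 - gamma)/4``.

Influence caps the number of *executed* moves per second (8 Hz in high,
4 Hz in low influence); presses beyond the cap are ignored. A trial lasts
14 s and succeeds if the vehicle touches the goal in time; failure costs
a fixed 15 pence.

The canvas is an unbounded integer lattice. The canonical geometry for a
"distance d" reach problem splits the deficit evenly over both axes
(diagonal placement), the default for calibration and design probability
tables; it is configurable because the drift of the greedy walk depends
on whether one or both axes carry deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import FAILURE_PENALTY, TRIAL_DURATION, TrialSpec

#: Cardinal directions, index order (+x, -x, +y, -y).
KEYS = ("right", "left", "up", "down")
_MOVES = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)], dtype=int)


@dataclass(frozen=True)
class PressEvent:
    time: float            # seconds within [0, 14]
    key: int               # index into KEYS
    executed: bool         # survived the influence cap
    realized_move: int | None  # direction index actually taken, or None


@dataclass
class TrialRecord:
    trial: TrialSpec
    chosen_vehicle: int
    chosen_goal: int            # 0 = g- (or single goal), 1 = g+
    success: bool
    payoff: int                 # pence
    press_rate: float           # Hz
    n_presses: int = 0
    n_executed: int = 0
    n_matched: int = 0          # realized move equalled the pressed key
    presses: list = field(default_factory=list)  # optional PressEvent trace


def step(position, key: int, gamma: float, rng) -> tuple:
    """One executed press: follow ``key`` w.p. gamma, else a uniform move."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0,1], got {gamma}")
    if key not in range(4):
        raise ValueError(f"invalid key {key!r}")
    if rng.random() < gamma:
        move = key
    else:
        move = int(rng.integers(0, 4))
    dx, dy = _MOVES[move]
    return (position[0] + dx, position[1] + dy), move


def greedy_policy(position, goal) -> int:
    """Key that strictly reduces Manhattan distance to the goal.

    Ties break to the axis with the larger absolute deficit, then x before y.
    """
    dx, dy = goal[0] - position[0], goal[1] - position[1]
    if dx == 0 and dy == 0:
        raise ValueError("greedy_policy called at the goal")
    if abs(dx) >= abs(dy) and dx != 0:
        return 0 if dx > 0 else 1
    return 2 if dy > 0 else 3


def run_trial(trial: TrialSpec, chosen_vehicle: int, chosen_goal: int,
              gamma: float, press_rate: float, rng,
              policy=None, record_presses: bool = False) -> TrialRecord:
    """Execute the movement phase of one trial and settle the payoff."""
    if press_rate <= 0:
        raise ValueError("press_rate must be positive")
    cap = trial.block.cap_hz
    n_presses = int(round(press_rate * TRIAL_DURATION))
    n_exec = int(round(min(press_rate, cap) * TRIAL_DURATION))
    goal = trial.goal_positions[chosen_goal]
    pos = tuple(trial.vehicle_positions[chosen_vehicle - 1])
    policy = policy or greedy_policy

    events = []
    matched = executed = 0
    success = pos == goal
    dt = 1.0 / press_rate
    for i in range(n_presses):
        if success or executed >= n_exec:
            break
        key = policy(pos, goal)
        pos, move = step(pos, key, gamma, rng)
        executed += 1
        matched += int(move == key)
        if record_presses:
            events.append(PressEvent(time=(i + 1) * dt, key=key,
                                     executed=True, realized_move=move))
        success = pos == goal
    reward = trial.rewards[chosen_goal]
    payoff = int(reward) if success else -FAILURE_PENALTY
    return TrialRecord(trial=trial, chosen_vehicle=chosen_vehicle,
                       chosen_goal=chosen_goal, success=success, payoff=payoff,
                       press_rate=press_rate, n_presses=n_presses,
                       n_executed=executed, n_matched=matched, presses=events)


def diagonal_start(distance: int) -> tuple:
    """Default reach geometry: deficit split evenly across both axes."""
    half = distance // 2
    return (distance - half, half)


def _simulate_reach(start, gamma: float, n_moves: int, n_sim: int, rng) -> np.ndarray:
    """Vectorized greedy random walks; True where the goal was reached."""
    dx = np.full(n_sim, start[0], dtype=np.int64)
    dy = np.full(n_sim, start[1], dtype=np.int64)
    done = (dx == 0) & (dy == 0)
    for _ in range(n_moves):
        if done.all():
            break
        key_x = np.abs(dx) >= np.abs(dy)
        follow = rng.random(n_sim) < gamma
        rand_dir = rng.integers(0, 4, n_sim)
        gx = np.where(key_x, -np.sign(dx), 0)
        gy = np.where(key_x, 0, -np.sign(dy))
        rx = np.where(rand_dir == 0, 1, np.where(rand_dir == 1, -1, 0))
        ry = np.where(rand_dir == 2, 1, np.where(rand_dir == 3, -1, 0))
        mx = np.where(follow, gx, rx)
        my = np.where(follow, gy, ry)
        act = ~done
        dx = np.where(act, dx + mx, dx)
        dy = np.where(act, dy + my, dy)
        done |= (dx == 0) & (dy == 0)
    return done


def estimate_success_probability(distance: int, gamma: float,
                                 press_rate: float, duration: float = TRIAL_DURATION,
                                 n_sim: int = 100_000, seed=None,
                                 start=None) -> tuple:
    """Monte-Carlo greedy-policy success probability with binomial s.e."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    n_moves = int(round(press_rate * duration))
    start = diagonal_start(distance) if start is None else start
    done = _simulate_reach(start, gamma, n_moves, n_sim, rng)
    p = done.mean()
    se = math.sqrt(max(p * (1 - p), 1.0 / n_sim) / n_sim)
    return float(p), float(se)


def calibrate_gamma(target_prob: float, distance: int = 36,
                    press_rate: float = 8.0, duration: float = TRIAL_DURATION,
                    tol: float = 0.01, n_sim: int = 100_000, seed: int = 0,
                    start=None, max_iter: int = 40) -> float:
    """Bisect gamma until the MC success estimate matches ``target_prob``.

    Uses common random numbers (the same RNG stream at every evaluation)
    so the estimated success curve is monotone in gamma and the bisection
    is deterministic given the seed.
    """
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must lie in (0,1)")
    n_moves = int(round(press_rate * duration))
    start = diagonal_start(distance) if start is None else start

    def success(gamma):
        rng = np.random.default_rng(seed)  # common random numbers
        return _simulate_reach(start, gamma, n_moves, n_sim, rng).mean()

    lo, hi = 0.0, 1.0
    p_lo, p_hi = success(0.0), success(1.0)
    if not p_lo - tol <= target_prob <= p_hi + tol:
        raise ValueError(
            f"target {target_prob} unreachable in [{p_lo:.4f}, {p_hi:.4f}] "
            f"for distance {distance} at {press_rate} Hz")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = success(mid)
        if abs(p - target_prob) <= tol * 0.5 and hi - lo < 0.01:
            break
        if p < target_prob:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_levels(targets=(0.2, 0.5, 0.8), distance: int = 36,
                     press_rate: float = 8.0, duration: float = TRIAL_DURATION,
                     tol: float = 0.01, n_sim: int = 100_000, seed: int = 0):
    """Calibrate the Low/Medium/High guidability levels to design anchors.

    Targets are the success probabilities of a greedy agent pressing at
    the high-influence cap from the central distance, in increasing order
    (Low, Medium, High).
    """
    from .design import GuidabilityLevels

    lo, me, hi = (calibrate_gamma(t, distance=distance, press_rate=press_rate,
                                  duration=duration, tol=tol, n_sim=n_sim,
                                  seed=seed)
                  for t in targets)
    return GuidabilityLevels(low=lo, medium=me, high=hi)


class ReachTable:
    """Memoised reach probabilities P(reach | distance, gamma, cap).

    Backs the probability-based single-goal-trial models; estimates are
    Monte-Carlo with a fixed per-entry seed so the table is reproducible.
    """

    def __init__(self, duration: float = TRIAL_DURATION, n_sim: int = 20_000,
                 seed: int = 12345):
        self.duration = duration
        self.n_sim = n_sim
        self.seed = seed
        self._cache = {}

    def __call__(self, distance: int, gamma: float, press_rate: float) -> float:
        key = (int(distance), round(float(gamma), 6), float(press_rate))
        if key not in self._cache:
            entry_seed = (self.seed + hash(key)) % (2**31 - 1)
            p, _ = estimate_success_probability(
                key[0], key[1], key[2], self.duration,
                n_sim=self.n_sim, seed=entry_seed)
            self._cache[key] = p
        return self._cache[key]
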