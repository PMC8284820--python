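"""Generation of the 160-trial experiment structure.

The task is organised in 8 blocks of 20 trials. The first 16 trials of a
block are double-goal trials (DGTs): two vehicles, two goals (a nearer,
less rewarding ``g-`` and a farther, more rewarding ``g+``, except on the
obvious-goal type ``OG`` where the reward ordering is reversed). One
vehicle is always placed centrally, at Manhattan distance 36 from both
goals. The last 4 trials are single-goal trials (SGTs) pitting a farther,
more guidable vehicle (always 44 steps from the goal) against a closer,
less guidable one whose distance shrinks as a power of the guidability
ratio. Each influence condition (high: 8 Hz move cap; low: 4 Hz) spans
four blocks whose vehicle pairs cover the guidability combinations
(M,M), (M,H), (L,M), (L,H) exactly once.

Coordinates live on an abstract integer lattice in vehicle-step units;
there is no pixel geometry. The per-type reward/distance schedule of the
double-goal design is a configurable stand-in obeying the published
constraints (the closer a vehicle is to g-, the less rewarding g- and the
more rewarding g+ are; rewards in integer pence; 15p failure penalty).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

# Design anchors (vehicle-step / pence units)
CENTRAL_DISTANCE = 36        # central vehicle to either DGT goal
SGT_GUIDABLE_DISTANCE = 44   # the more guidable vehicle's SGT distance
SGT_EQUAL_DISTANCES = (44, 38)
SGT_REWARDS = (50, 60, 70, 80)
FAILURE_PENALTY = 15         # pence lost on any failure
TRIAL_DURATION = 14.0        # seconds of the movement phase
INFLUENCE_CAPS = {"high": 8.0, "low": 4.0}   # executed moves per second

DGT_TYPES = ("t1", "t2", "t3", "t4", "t5", "t6", "Catch", "OG")

# Stand-in DGT schedule: (d(v_other, g-), d(v_other, g+), r(g-), r(g+)).
# The central vehicle is always at 36/36. d- + d+ = 72 for all regular
# types so that every layout fits one lattice template (goal separation
# 48). Reward ordering follows the published theme.
DEFAULT_DGT_SCHEDULE = {
    "t1": (12, 60, 20, 80),
    "t2": (20, 52, 25, 75),
    "t3": (28, 44, 30, 70),
    "t4": (36, 36, 35, 65),
    "t5": (44, 28, 40, 60),
    "t6": (52, 20, 45, 55),
    "Catch": (36, 36, 30, 70),
    # OG: closer-vehicle distance is sampled; r(g-) > r(g+) by design.
    "OG": (None, None, 65, 35),
}
DEFAULT_OG_DISTANCES = (20, 24, 28, 32)

GOAL_SEPARATION = 48  # Manhattan distance between the two DGT goals

GUIDABILITY_PAIRS = (("M", "M"), ("M", "H"), ("L", "M"), ("L", "H"))


@dataclass(frozen=True)
class GuidabilityLevel:
    """A named guidability level and its per-press follow probability."""

    label: str            # "Low" | "Medium" | "High"
    gamma: float

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0,1], got {self.gamma}")


@dataclass(frozen=True)
class GuidabilityLevels:
    low: float
    medium: float
    high: float

    def __post_init__(self):
        if not self.low < self.medium < self.high:
            raise ValueError("guidability levels must satisfy Low < Medium < High")

    def __getitem__(self, code: str) -> float:
        return {"L": self.low, "M": self.medium, "H": self.high}[code]

    def as_dict(self) -> dict:
        return {"low": self.low, "medium": self.medium, "high": self.high}


#: Uncalibrated default levels (diagonal geometry, 8 Hz, 14 s, distance 36
#: success anchors 0.8 / 0.5 / 0.2). Recompute with movement.calibrate_levels.
DEFAULT_GAMMA_LEVELS = GuidabilityLevels(low=0.2457, medium=0.3196, high=0.3912)


@dataclass(frozen=True)
class BlockSpec:
    index: int                 # 1..8
    influence: str             # "high" | "low"
    pair: tuple                # guidability codes for (v1, v2), e.g. ("L", "H")

    def __post_init__(self):
        if self.influence not in INFLUENCE_CAPS:
            raise ValueError(f"unknown influence {self.influence!r}")
        if tuple(self.pair) not in GUIDABILITY_PAIRS:
            raise ValueError(f"invalid guidability pair {self.pair!r}")

    @property
    def cap_hz(self) -> float:
        return INFLUENCE_CAPS[self.influence]


@dataclass(frozen=True)
class TrialSpec:
    block: BlockSpec
    index_in_block: int        # 1..20
    phase: str                 # "DGT" | "SGT"
    trial_type: str            # t1..t6 | Catch | OG | S_n1..S_n4 | S_eq
    vehicle_positions: tuple   # ((x1,y1),(x2,y2)) lattice coordinates
    goal_positions: tuple      # DGT: (g-, g+); SGT: (g,)
    rewards: tuple             # DGT: (r(g-), r(g+)); SGT: (r(g),)
    central_vehicle: int | None  # 1|2 for DGT, None for SGT
    rotation: int              # degrees, multiple of 90
    occurrence: int            # 1|2 for DGT types, 1 for SGT

    def distance(self, vehicle: int, goal: int) -> int:
        """Manhattan distance from vehicle (1|2) to goal (0-based index)."""
        vx, vy = self.vehicle_positions[vehicle - 1]
        gx, gy = self.goal_positions[goal]
        return abs(vx - gx) + abs(vy - gy)


@dataclass
class TaskDesign:
    blocks: list
    trials: list
    gamma_levels: GuidabilityLevels
    seed: int
    dgt_schedule: dict = field(default_factory=lambda: dict(DEFAULT_DGT_SCHEDULE))

    def trials_of(self, *, phase: str | None = None, influence: str | None = None):
        out = []
        for t in self.trials:
            if phase is not None and t.phase != phase:
                continue
            if influence is not None and t.block.influence != influence:
                continue
            out.append(t)
        return out

    # -- serialization ----------------------------------------------------
    def to_records(self) -> list:
        recs = []
        for t in self.trials:
            recs.append({
                "block": t.block.index,
                "influence": t.block.influence,
                "pair": "".join(t.block.pair),
                "index_in_block": t.index_in_block,
                "phase": t.phase,
                "trial_type": t.trial_type,
                "vehicle_positions": [list(p) for p in t.vehicle_positions],
                "goal_positions": [list(p) for p in t.goal_positions],
                "rewards": list(t.rewards),
                "central_vehicle": t.central_vehicle,
                "rotation": t.rotation,
                "occurrence": t.occurrence,
            })
        return recs

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "gamma_levels": self.gamma_levels.as_dict(),
            "coordinate_convention": "integer lattice, vehicle-step units, 0-based",
            "trials": self.to_records(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in self.trials:
            row = {
                "block": t.block.index,
                "influence": t.block.influence,
                "pair": "".join(t.block.pair),
                "index_in_block": t.index_in_block,
                "phase": t.phase,
                "trial_type": t.trial_type,
                "central_vehicle": t.central_vehicle,
                "rotation": t.rotation,
                "occurrence": t.occurrence,
            }
            if t.phase == "DGT":
                row.update({
                    "d_v1_gm": t.distance(1, 0), "d_v1_gp": t.distance(1, 1),
                    "d_v2_gm": t.distance(2, 0), "d_v2_gp": t.distance(2, 1),
                    "r_gm": t.rewards[0], "r_gp": t.rewards[1],
                })
            else:
                row.update({
                    "d_v1_g": t.distance(1, 0), "d_v2_g": t.distance(2, 0),
                    "r_g": t.rewards[0],
                })
            rows.append(row)
        return pd.DataFrame(rows)


def _rotate(point, rotation, pivot=(24, 0)):
    """Rotate a lattice point by a multiple of 90 degrees about a pivot."""
    if rotation % 90 != 0:
        raise ValueError("rotation must be a multiple of 90 degrees")
    x, y = point[0] - pivot[0], point[1] - pivot[1]
    for _ in range((rotation // 90) % 4):
        x, y = -y, x
    return (x + pivot[0], y + pivot[1])


def layout_dgt(trial_type: str, occurrence: int, rotation: int,
               schedule: dict | None = None, og_distance: int | None = None):
    """Coordinates for one double-goal layout.

    Goals sit at (0,0) (``g-``) and (48,0) (``g+``). The central vehicle
    occupies (24,12) — Manhattan distance 36 to both goals — and the other
    vehicle is placed at negative y according to the type's (d-, d+) cell.
    On occurrence 2 the two vehicles exchange coordinates; the whole canvas
    is then rotated (an isometry of the Manhattan metric).

    Returns ``(vehicle_positions, goal_positions, rewards, central_vehicle)``.
    """
    schedule = schedule if schedule is not None else DEFAULT_DGT_SCHEDULE
    if trial_type not in schedule:
        raise ValueError(f"unknown DGT type {trial_type!r}")
    d_gm, d_gp, r_gm, r_gp = schedule[trial_type]
    central = (24, 12)
    if trial_type == "Catch":
        other = (24, -12)   # also 36/36: both vehicles central
    elif trial_type == "OG":
        if og_distance is None:
            og_distance = DEFAULT_OG_DISTANCES[0]
        other = (-og_distance, 0)  # og_distance from g-, 48+og_distance from g+
    else:
        x = (d_gm - d_gp + GOAL_SEPARATION) // 2
        other = (x, -(d_gm - x))
    v1, v2 = (other, central) if occurrence == 1 else (central, other)
    central_vehicle = 2 if occurrence == 1 else 1
    if trial_type == "Catch":
        central_vehicle = None  # both central; no unique central vehicle
    pos = tuple(_rotate(p, rotation) for p in (v1, v2))
    goals = tuple(_rotate(p, rotation) for p in ((0, 0), (GOAL_SEPARATION, 0)))
    return pos, goals, (r_gm, r_gp), central_vehicle


def layout_sgt(gamma1: float, gamma2: float, n: int, rng=None):
    """SGT distances (d1, d2) for the (more, less) guidable vehicle.

    d1 is always 44; d2 = round(44 * (gamma2/gamma1)**n). When the two
    vehicles are equally guidable the distances are a random assignment
    of {44, 38}.
    """
    if not (gamma1 >= gamma2 > 0):
        raise ValueError("require gamma1 >= gamma2 > 0")
    if n not in (1, 2, 3, 4):
        raise ValueError(f"exponent n must be in 1..4, got {n}")
    if gamma1 == gamma2:
        rng = np.random.default_rng() if rng is None else rng
        d1, d2 = SGT_EQUAL_DISTANCES if rng.random() < 0.5 else SGT_EQUAL_DISTANCES[::-1]
        return d1, d2
    d2 = round(SGT_GUIDABLE_DISTANCE * (gamma2 / gamma1) ** n)
    return SGT_GUIDABLE_DISTANCE, d2


def assign_rewards(trial_type: str, rng, schedule: dict | None = None):
    """Reward map in pence for one trial.

    SGT rewards are uniform over {50,60,70,80}; DGT rewards follow the
    configured schedule (r(g+) > r(g-) except OG, where the ordering is
    deliberately reversed).
    """
    schedule = schedule if schedule is not None else DEFAULT_DGT_SCHEDULE
    if trial_type.startswith("S_"):
        return (int(rng.choice(SGT_REWARDS)),)
    if trial_type not in schedule:
        raise ValueError(f"unknown trial type {trial_type!r}")
    _, _, r_gm, r_gp = schedule[trial_type]
    return (r_gm, r_gp)


def block_gammas(block: BlockSpec, levels: GuidabilityLevels):
    """True guidabilities (gamma_v1, gamma_v2); v1 is the more guidable."""
    a, b = levels[block.pair[0]], levels[block.pair[1]]
    return (max(a, b), min(a, b))


def _diag_coords(distance: int):
    """Diagonal lattice offset realising a given Manhattan distance."""
    half = distance // 2
    return (distance - half, half)


def build_task(gamma_levels: GuidabilityLevels | None = None,
               seed: int = 0,
               schedule: dict | None = None,
               og_distances=DEFAULT_OG_DISTANCES) -> TaskDesign:
    """Generate a complete randomized 160-trial task design.

    Stochastic elements (all driven by ``seed``): block order, trial order
    within blocks (the 16th DGT is always a Catch trial), canvas rotations,
    OG distances, SGT ordering and rewards, equal-pair SGT distance
    assignment. The multiset of trial types per block is fixed by design.
    """
    gamma_levels = gamma_levels or DEFAULT_GAMMA_LEVELS
    schedule = schedule if schedule is not None else dict(DEFAULT_DGT_SCHEDULE)
    rng = np.random.default_rng(seed)

    # Influence conditions alternate; which starts, and the pair order
    # within each condition, are randomized by seed.
    first = "high" if rng.random() < 0.5 else "low"
    order = [first, ("low" if first == "high" else "high")] * 4
    pair_orders = {}
    for cond in ("high", "low"):
        pairs = list(GUIDABILITY_PAIRS)
        rng.shuffle(pairs)
        pair_orders[cond] = pairs

    blocks, trials = [], []
    for b in range(8):
        cond = order[b]
        pair = tuple(pair_orders[cond].pop())
        block = BlockSpec(index=b + 1, influence=cond, pair=pair)
        blocks.append(block)

        # --- DGTs: each of the 8 types twice (occurrence 2 swaps vehicles).
        dgt_items = [(tt, occ) for tt in DGT_TYPES for occ in (1, 2)]
        # one Catch trial is pinned to slot 16; the other is shuffled in
        catch_last = ("Catch", int(rng.integers(1, 3)))
        dgt_items.remove(catch_last)
        rng.shuffle(dgt_items)
        dgt_items.append(catch_last)

        for i, (tt, occ) in enumerate(dgt_items, start=1):
            rotation = int(rng.integers(0, 4)) * 90
            og_d = int(rng.choice(og_distances)) if tt == "OG" else None
            pos, goals, rewards, central = layout_dgt(
                tt, occ, rotation, schedule=schedule, og_distance=og_d)
            trials.append(TrialSpec(
                block=block, index_in_block=i, phase="DGT", trial_type=tt,
                vehicle_positions=pos, goal_positions=goals, rewards=rewards,
                central_vehicle=central, rotation=rotation, occurrence=occ))

        # --- SGTs: exponents 1..4 (or four equal-pair trials), shuffled.
        # v1 is by convention the more guidable vehicle of the block.
        g1, g2 = block_gammas(block, gamma_levels)
        exponents = [1, 2, 3, 4]
        rng.shuffle(exponents)
        for j, n in enumerate(exponents, start=17):
            if g1 == g2:
                tt = "S_eq"
                d1, d2 = layout_sgt(g1, g2, n, rng=rng)
            else:
                tt = f"S_n{n}"
                d1, d2 = layout_sgt(g1, g2, n)
            rotation = int(rng.integers(0, 4)) * 90
            goal = (0, 0)
            p1 = _diag_coords(d1)
            dx2, dy2 = _diag_coords(d2)
            p2 = (-dx2, dy2)  # opposite side of the goal
            pos = tuple(_rotate(p, rotation, pivot=(0, 0)) for p in (p1, p2))
            rewards = assign_rewards(tt, rng, schedule=schedule)
            trials.append(TrialSpec(
                block=block, index_in_block=j, phase="SGT", trial_type=tt,
                vehicle_positions=pos, goal_positions=(goal,), rewards=rewards,
                central_vehicle=None, rotation=rotation, occurrence=1))

    return TaskDesign(blocks=blocks, trials=trials, gamma_levels=gamma_levels,
                      seed=seed, dgt_schedule=schedule)
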