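#!/usr/bin/env python
"""Generate one randomized 160-trial task design and check its anatomy.

Uses the calibrated guidability levels from step 01 if present. Writes
results/design.json (full structure) and results/design.csv (one row
per trial), and prints the structural counts that define the task:
8 blocks x (16 double-goal + 4 single-goal) trials, two catch trials per
block with the 16th pinned, the 36-step central distance and the 44-step
single-goal distance for the more guidable vehicle.
"""

import json
from pathlib import Path

from ctrltask.design import GuidabilityLevels, build_task

SEED = 2027
OUT = Path("results")


def main():
    OUT.mkdir(exist_ok=True)
    levels = None
    levels_path = OUT / "gamma_levels.json"
    if levels_path.exists():
        levels = GuidabilityLevels(**json.loads(levels_path.read_text()))
    design = build_task(gamma_levels=levels, seed=SEED)
    design.to_json(OUT / "design.json")
    design.to_frame().to_csv(OUT / "design.csv", index=False)

    dgt = design.trials_of(phase="DGT")
    sgt = design.trials_of(phase="SGT")
    central = {d for t in dgt if t.central_vehicle
               for d in (t.distance(t.central_vehicle, 0),
                         t.distance(t.central_vehicle, 1))}
    guidable = {t.distance(1, 0) for t in sgt if t.trial_type != "S_eq"}
    print(f"{len(design.trials)} trials: {len(dgt)} double-goal, "
          f"{len(sgt)} single-goal across {len(design.blocks)} blocks")
    print(f"central-vehicle distances: {sorted(central)} (design: 36)")
    print(f"guidable-vehicle SGT distances: {sorted(guidable)} (design: 44)")
    catches = [sum(t.trial_type == 'Catch' and t.block is b for t in dgt)
               for b in design.blocks]
    print(f"catch trials per block: {catches}")


if __name__ == "__main__":
    main()
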