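"""End-to-end pipeline: calibrate -> design -> simulate -> fit -> compare
-> recover -> analyze, with per-stage seeding and provenance metadata.

Configuration is a plain dataclass serializable to/from YAML; every
stochastic stage derives its RNG from a named sub-seed of the global
seed, so a run is reproducible from the config alone (MAP mode).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__

log = logging.getLogger("ctrltask")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    # calibration
    calibration_targets: tuple = (0.2, 0.5, 0.8)   # Low, Medium, High
    calibration_distance: int = 36
    calibration_rate: float = 8.0
    calibration_n_sim: int = 100_000
    calibration_tol: float = 0.01
    # cohort
    n_subjects: int = 12
    scenario: str = "paper-like"
    # fitting / comparison
    fit_method: str = "map"
    dgt_models: tuple = ("additive", "gplus_bias", "wsls",
                         "vehicle_independent_rw", "vehicle_rw")
    sgt_models: tuple = ("sgt_additive", "sgt_interaction",
                         "sgt_additive_prob", "sgt_prob")
    conditions: tuple = ("high", "low")
    waic_draws: int = 60
    # recovery (scaled-down defaults)
    recovery_models: tuple = ("additive", "vehicle_rw")
    recovery_datasets: int = 6
    recovery_cohort_size: int = 4
    param_recovery_datasets: int = 15
    # analysis
    n_perm: int = 2000

    def sub_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True,
                       default=str).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; artifacts are written under config.out_dir."""
    from .cohort import load_cohort, make_fixture
    from .inference import compare_models
    from .loc import cohort_outcomes, permutation_corr_test
    from .movement import ReachTable, calibrate_levels
    from .recovery import model_recovery, parameter_recovery

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"version": __version__, "config_hash": config.config_hash(),
                  "seed": config.seed, "stages": {}}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        t0 = time.time()
        log.info("stage %s ...", name)

        def done(extra=None):
            provenance["stages"][name] = {
                "seconds": round(time.time() - t0, 2),
                "seed": config.sub_seed(name), **(extra or {})}
            (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
        return done

    try:
        done = stage("calibrate")
        if not config.calibration_targets:
            raise ValueError("missing calibration targets")
        levels = calibrate_levels(
            config.calibration_targets, distance=config.calibration_distance,
            press_rate=config.calibration_rate, tol=config.calibration_tol,
            n_sim=config.calibration_n_sim, seed=config.sub_seed("calibrate"))
        (out / "gamma_levels.json").write_text(json.dumps(levels.as_dict(), indent=1))
        done({"levels": levels.as_dict()})
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage 'calibrate': {err}") from err

    try:
        done = stage("simulate")
        cohort_dir = make_fixture(config.n_subjects, config.scenario,
                                  config.sub_seed("simulate"), out / "cohort",
                                  gamma_levels=levels)
        cohort = load_cohort(cohort_dir)
        done({"n_subjects": config.n_subjects, "scenario": config.scenario})
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage 'simulate': {err}") from err

    try:
        done = stage("compare")
        reach = ReachTable(seed=config.sub_seed("reach"))
        tables = {}
        for cond in config.conditions:
            tables[f"dgt_{cond}"] = compare_models(
                cohort["trials"], config.dgt_models, cond,
                seed=config.sub_seed("compare"), n_draws=config.waic_draws)
            tables[f"sgt_{cond}"] = compare_models(
                cohort["trials"], config.sgt_models, cond,
                seed=config.sub_seed("compare"), n_draws=config.waic_draws,
                reach_prob=reach)
        for name, tbl in tables.items():
            tbl.to_csv(out / f"comparison_{name}.csv")
        done()
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage 'compare': {err}") from err

    try:
        done = stage("recover")
        mr = model_recovery(config.recovery_models,
                            n_datasets_per_model=config.recovery_datasets,
                            cohort_size=config.recovery_cohort_size,
                            seed=config.sub_seed("recover"), gamma_levels=levels)
        mr.confusion.to_csv(out / "model_recovery_confusion.csv")
        pr = parameter_recovery(n_datasets=config.param_recovery_datasets,
                                seed=config.sub_seed("recover") + 1,
                                gamma_levels=levels)
        pr.r2.to_csv(out / "parameter_recovery_r2.csv")
        done()
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage 'recover': {err}") from err

    try:
        done = stage("analyze")
        outcomes = cohort_outcomes(cohort["trials"])
        outcomes.to_csv(out / "outcomes.csv", index=False)
        merged = outcomes.merge(cohort["subjects"], on="subject_id")
        rows = []
        for cond in config.conditions:
            sub = merged[merged.condition == cond]
            r, p, _ = permutation_corr_test(sub.I, sub.gplus_frequency,
                                            n_perm=config.n_perm,
                                            seed=config.sub_seed("analyze"))
            rows.append({"condition": cond, "measure": "gplus_frequency",
                         "score": "I", "r": r, "p_perm": p})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "loc_correlations.csv", index=False)
        done()
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage 'analyze': {err}") from err

    return out
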