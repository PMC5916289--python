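"""YAML (de)serialization of simulation configurations.

The config file has five blocks: ``reaction_norm``, ``state``, ``fitness``,
``environment`` and ``run``.  Round-trips are lossless for the numerical
content; ``run.seed`` is mandatory for simulation.
"""

from __future__ import annotations

import numpy as np
import yaml

from .environment import EnvironmentModel
from .evolve import SimulationConfig
from .fitness import FitnessSpec
from .model import PopulationState, ReactionNormSpec

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "reaction_norm": config.spec.to_dict(),
        "state": {
            "mean": config.state.mean.tolist(),
            "G_aug": config.state.G_aug.tolist(),
            "P_aug": config.state.P_aug.tolist(),
            "resid_cov": config.state.resid_cov.tolist(),
        },
        "fitness": config.fitness.to_dict(),
        "environment": config.environment.to_dict(),
        "run": {
            "n_individuals": int(config.n_individuals),
            "n_generations": int(config.n_generations),
            "seed": int(config.seed),
            "notes": {str(k): v for k, v in config.notes.items()},
        },
    }


def config_from_dict(d: dict) -> SimulationConfig:
    missing = [k for k in ("reaction_norm", "state", "fitness", "environment", "run")
               if k not in d]
    if missing:
        raise ValueError(f"config is missing blocks: {', '.join(missing)}")
    run = d["run"]
    if "seed" not in run:
        raise ValueError("run.seed is mandatory")
    st = d["state"]
    state = PopulationState(
        mean=np.asarray(st["mean"], dtype=float),
        G_aug=np.asarray(st["G_aug"], dtype=float),
        P_aug=np.asarray(st["P_aug"], dtype=float),
        resid_cov=np.asarray(st["resid_cov"], dtype=float),
    )
    return SimulationConfig(
        spec=ReactionNormSpec.from_dict(d["reaction_norm"]),
        state=state,
        fitness=FitnessSpec.from_dict(d["fitness"]),
        environment=EnvironmentModel.from_dict(d["environment"]),
        n_individuals=int(run["n_individuals"]),
        n_generations=int(run["n_generations"]),
        seed=int(run["seed"]),
        notes=dict(run.get("notes", {})),
    )


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path} does not contain a config mapping")
    return config_from_dict(d)
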