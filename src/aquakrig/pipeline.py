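"""End-to-end pipeline: sample -> label -> filter/split/train -> validate ->
simulate -> analyze, with config hashing so completed stages are skipped on
rerun.

Every stage writes its artifacts into a working directory together with a
sidecar ``<stage>.hash`` recording a digest of the configuration subset that
stage depends on (including upstream stages); a rerun recomputes a stage
only when its digest changes or an artifact is missing.  The full config and
per-stage RNG seeds are embedded in the trained-model manifest, so artifacts
are reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from .analysis import internal_coordinate_distributions, rdf
from .geometry import seed_configuration
from .io import (
    read_configurations,
    read_labelled_csv,
    write_configurations,
    write_frames,
    write_labelled_csv,
)
from .kriging import PSOSettings, mae, s_curve
from .md import WaterForceField, initialize_cluster, run_simulation
from .models import WaterModelSet
from .sampling import EnsembleFilterPolicy, filter_ensemble, sample_configurations, split_train_validation
from .surrogate import SurrogateParameters, label_ensemble

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("aquakrig")


@dataclasses.dataclass
class RunConfig:
    """All pipeline knobs with defaults matching the study conditions."""

    # sampling
    n_samples: int = 3000
    max_distortion: float = 0.20
    sampling_seed: int = 1

    # labelling
    labelling_seed: int = 2

    # filtering / training
    charge_tolerance: float = 0.001          # e
    lomega_threshold: float = 5e-5           # Ha
    n_trn: int = 50
    n_validation: int = 1000
    optimize_p: bool = False
    pso_swarm: int = 40
    pso_iterations: int = 300
    moment_pso_swarm: int = 16
    moment_pso_iterations: int = 60
    training_seed: int = 3

    # simulation
    n_mol: int = 25
    rank: int = 1
    n_steps: int = 1000
    dt: float = 1.0                          # fs
    temperature: float = 300.0               # K
    collision_rate: float = 0.01             # 1/fs (10 ps^-1)
    rigid: bool = False
    simulation_seed: int = 4
    traj_every: int = 10

    # analysis
    rdf_r_max: float = 10.0
    rdf_bin_width: float = 0.05
    equilibration_fraction: float = 0.25

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        doc = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def save_yaml(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _digest(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


class _Stage:
    def __init__(self, workdir: pathlib.Path, name: str, payload: dict, outputs: list):
        self.name = name
        self.hash_file = workdir / f"{name}.hash"
        self.digest = _digest(payload)
        self.outputs = [workdir / o for o in outputs]

    def is_current(self) -> bool:
        return (
            self.hash_file.exists()
            and self.hash_file.read_text().strip() == self.digest
            and all(o.exists() for o in self.outputs)
        )

    def mark(self) -> None:
        self.hash_file.write_text(self.digest)


def run_pipeline(config: RunConfig, workdir: str | pathlib.Path) -> dict:
    """Execute every stage under ``workdir``; returns artifact paths."""
    wd = pathlib.Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    config.save_yaml(wd / "config.yaml")
    cfg = config.to_dict()
    artifacts: dict = {}

    def sub(*keys):
        return {k: cfg[k] for k in keys}

    # 1. sample ------------------------------------------------------------
    stage = _Stage(wd, "sample", sub("n_samples", "max_distortion", "sampling_seed"),
                   ["ensemble.xyz"])
    if not stage.is_current():
        log.info("stage sample: %d configurations", config.n_samples)
        configs = sample_configurations(
            seed_configuration(), config.n_samples, config.max_distortion,
            rng_seed=config.sampling_seed,
        )
        write_configurations(wd / "ensemble.xyz", configs)
        stage.mark()
    else:
        log.info("stage sample: up to date, skipping")
    artifacts["ensemble"] = wd / "ensemble.xyz"

    # 2. label -------------------------------------------------------------
    prev = stage.digest
    stage = _Stage(wd, "label", {"prev": prev, **sub("labelling_seed")}, ["labels.csv"])
    if not stage.is_current():
        log.info("stage label")
        configs = read_configurations(wd / "ensemble.xyz")
        labelled = label_ensemble(configs, config.labelling_seed, SurrogateParameters())
        write_labelled_csv(wd / "labels.csv", labelled)
        stage.mark()
    else:
        log.info("stage label: up to date, skipping")
    artifacts["labels"] = wd / "labels.csv"

    # 3. filter / split / train ---------------------------------------------
    prev = stage.digest
    train_keys = sub(
        "charge_tolerance", "lomega_threshold", "n_trn", "optimize_p",
        "pso_swarm", "pso_iterations", "moment_pso_swarm",
        "moment_pso_iterations", "training_seed",
    )
    stage = _Stage(wd, "train", {"prev": prev, **train_keys}, ["models/manifest.json"])
    if not stage.is_current():
        log.info("stage train: N_trn = %d", config.n_trn)
        labelled = read_labelled_csv(wd / "labels.csv")
        policy = EnsembleFilterPolicy(config.charge_tolerance, config.lomega_threshold)
        kept = filter_ensemble(labelled, policy)
        log.info("filter kept %d / %d configurations", len(kept), len(labelled))
        tr, _ = split_train_validation(kept, config.n_trn, rng_seed=config.training_seed)
        models = WaterModelSet.train(
            tr,
            optimize_p=config.optimize_p,
            pso=PSOSettings(config.pso_swarm, config.pso_iterations),
            moment_pso=PSOSettings(config.moment_pso_swarm, config.moment_pso_iterations),
            rng_seed=config.training_seed,
            provenance={"config": cfg, "stage_digest": stage.digest},
        )
        models.save(wd / "models")
        stage.mark()
    else:
        log.info("stage train: up to date, skipping")
    artifacts["models"] = wd / "models"

    # 4. validate ------------------------------------------------------------
    prev = stage.digest
    stage = _Stage(wd, "validate", {"prev": prev, **sub("n_validation")},
                   ["validation.json", "scurve_energy.csv"])
    if not stage.is_current():
        log.info("stage validate")
        labelled = read_labelled_csv(wd / "labels.csv")
        policy = EnsembleFilterPolicy(config.charge_tolerance, config.lomega_threshold)
        kept = filter_ensemble(labelled, policy)
        _, va = split_train_validation(kept, config.n_trn, rng_seed=config.training_seed)
        va = va[: config.n_validation]
        models = WaterModelSet.load(wd / "models")
        charge_models = [atom[0] for atom in models.moments]
        e_mae = mae(models.energy, va, "energy")
        q_mae = mae(charge_models, va, "charge")
        sc = s_curve(models.energy, va, "energy")
        pd.DataFrame(
            {"abs_error_kjmol": sc.errors, "cumulative_percent": sc.cumulative_percent}
        ).to_csv(wd / "scurve_energy.csv", index=False)
        (wd / "validation.json").write_text(
            json.dumps(
                {
                    "n_validation": len(va),
                    "mae_energy_kjmol": e_mae,
                    "mae_charge_me": q_mae,
                    "stage_digest": stage.digest,
                },
                indent=1,
            )
        )
        log.info("validation MAE: %.4f kJ/mol, %.4f me", e_mae, q_mae)
        stage.mark()
    else:
        log.info("stage validate: up to date, skipping")
    artifacts["validation"] = wd / "validation.json"

    # 5. simulate ------------------------------------------------------------
    prev = stage.digest
    sim_keys = sub("n_mol", "rank", "n_steps", "dt", "temperature",
                   "collision_rate", "rigid", "simulation_seed", "traj_every")
    stage = _Stage(wd, "simulate", {"prev": prev, **sim_keys},
                   ["trajectory.xyz", "energies.csv"])
    if not stage.is_current():
        log.info("stage simulate: %d molecules, L = %d, %d steps",
                 config.n_mol, config.rank, config.n_steps)
        models = WaterModelSet.load(wd / "models")
        ff = WaterForceField(models, L=config.rank, flexible=not config.rigid)
        state = initialize_cluster(
            config.n_mol, rng_seed=config.simulation_seed, temperature=config.temperature
        )
        frames, logdf = run_simulation(
            ff, state, config.n_steps, dt=config.dt,
            temperature=config.temperature, collision_rate=config.collision_rate,
            rng_seed=config.simulation_seed, rigid=config.rigid,
            traj_every=config.traj_every,
        )
        write_frames(wd / "trajectory.xyz", frames, ["O", "H", "H"] * config.n_mol)
        logdf.to_csv(wd / "energies.csv", index=False)
        stage.mark()
    else:
        log.info("stage simulate: up to date, skipping")
    artifacts["trajectory"] = wd / "trajectory.xyz"
    artifacts["energies"] = wd / "energies.csv"

    # 6. analyze -------------------------------------------------------------
    prev = stage.digest
    stage = _Stage(wd, "analyze",
                   {"prev": prev, **sub("rdf_r_max", "rdf_bin_width",
                                        "equilibration_fraction")},
                   ["rdf.csv", "geometry.csv"])
    if not stage.is_current():
        log.info("stage analyze")
        from .io import read_frames

        frames, _ = read_frames(wd / "trajectory.xyz")
        skip = int(len(frames) * config.equilibration_fraction)
        prod = frames[skip:] if len(frames) > skip + 1 else frames
        tables = []
        for pair in ("OO", "OH", "HH"):
            res = rdf(prod, pair, r_max=config.rdf_r_max, bin_width=config.rdf_bin_width)
            tables.append(
                pd.DataFrame(
                    {"pair": pair, "r": res.bin_centers, "g": res.g,
                     "normalization": res.normalization}
                )
            )
        pd.concat(tables).to_csv(wd / "rdf.csv", index=False)
        dist = internal_coordinate_distributions(prod)
        n = max(len(dist.bond_centers), len(dist.angle_centers_deg))
        pad = lambda a: np.pad(a.astype(float), (0, n - len(a)), constant_values=np.nan)  # noqa: E731
        pd.DataFrame(
            {
                "bond_r": pad(dist.bond_centers),
                "bond_density": pad(dist.bond_density),
                "angle_deg": pad(dist.angle_centers_deg),
                "angle_density": pad(dist.angle_density),
            }
        ).to_csv(wd / "geometry.csv", index=False)
        stage.mark()
    else:
        log.info("stage analyze: up to date, skipping")
    artifacts["rdf"] = wd / "rdf.csv"
    artifacts["geometry"] = wd / "geometry.csv"
    return artifacts
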