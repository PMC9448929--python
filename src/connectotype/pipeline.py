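"""End-to-end orchestration: generate -> cluster -> metrics -> simulate ->
lesion -> report, from a single config with one master seed.

Every stage writes plain CSV/TSV artifacts into the output directory and a
``run_manifest.json`` records the config, derived seeds and file hashes, so
a run is reproducible and auditable.  Stage functions are plain functions
over the library; the CLI and the numbered analysis drivers are thin
wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    ModularityConfig,
    PopulationSpec,
    crossval_accuracy,
    find_min_gamma,
    generate_population,
    metrics_table,
    rank_nodes,
    reparcellate,
    similarity_matrix,
    subset_accuracy,
    vectorize_edges,
)
from .kuramoto import coupling_sweep, sweep_summary, sweep_table
from .lesion import DEFAULT_LEVELS, lesion_experiment
from .parcellation import YEO7_SYSTEMS
from .stats import module_report, report_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a full run.  Defaults give a desk-scale demonstration
    (small population, short simulations, coarse coupling grid)."""

    outdir: str = "results/run"
    seed: int = 0
    # generator
    n_per_group: int = 10
    fine_nodes: int = 100
    contrast: float = None  # None -> calibrated default
    sigma: float = None
    edge_mean_target: float = 1e-4
    # clustering
    gamma_min: float = 0.5
    gamma_max: float = 1.5
    gamma_step: float = 0.01
    folds: int = 5
    n_restarts: int = 10
    # dynamics
    K_min: float = 0.0
    K_max: float = 2.0
    K_step: float = 0.1
    T: float = 10.0
    dt: float = 1e-4
    burn_in: float = 2.0
    n_reps: int = 1
    # lesioning
    levels: tuple = DEFAULT_LEVELS
    measure: str = "strength"
    run_lesion_dynamics: bool = False
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def population_spec(self) -> PopulationSpec:
        kw = {}
        if self.contrast is not None:
            kw["contrast"] = self.contrast
        if self.sigma is not None:
            kw["subject_noise_sigma"] = self.sigma
        from .parcellation import default_fine_parcellation

        return PopulationSpec(
            n_per_group=self.n_per_group,
            fine_parcellation=default_fine_parcellation(self.fine_nodes),
            edge_mean_target=self.edge_mean_target,
            seed=self.seed,
            **kw,
        )

    def modularity_config(self) -> ModularityConfig:
        grid = tuple(
            np.round(
                np.arange(self.gamma_min, self.gamma_max + self.gamma_step / 2,
                          self.gamma_step),
                6,
            )
        )
        return ModularityConfig(
            n_restarts=self.n_restarts, seed=self.seed, gamma_grid=grid
        )

    def K_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.K_min + self.K_step, self.K_max + self.K_step / 2,
                      self.K_step),
            6,
        )


def _write_csv(df: pd.DataFrame, path: Path, meta: dict):
    header = "# " + json.dumps(meta, sort_keys=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_cluster(subjects, labels, spec, mcfg, folds=5, seed=0):
    """Per-sex whole-network clustering: similarity, gamma search,
    cross-validation.  Returns a partition table and an accuracy report."""
    rows, accuracy = [], {}
    partitions = {}
    for sex in spec.sexes:
        idx = labels.index[labels.sex == sex].to_numpy()
        vecs = [
            vectorize_edges(reparcellate(subjects[i], spec.coarse_parcellation))
            for i in idx
        ]
        sim = similarity_matrix(vecs)
        gamma, part = find_min_gamma(sim, mcfg)
        acc, info = crossval_accuracy(
            sim, folds, mcfg, seed=seed, reference=part
        )
        accuracy[sex] = {"crossval_accuracy": acc, **info, "gamma": gamma}
        partitions[sex] = (sim, part)
        for i in idx:
            sid = labels.loc[i, "subject_id"]
            rows.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "module": part.assignment[sid],
                    "gamma": gamma,
                    "Q": part.Q,
                }
            )
    return pd.DataFrame(rows), accuracy, partitions


def stage_subsets(subjects, labels, spec, mcfg, partitions):
    """Subset-accuracy table over all within- and between-system subsets."""
    specs = [f"within:{s}" for s in YEO7_SYSTEMS] + [
        f"between:{a}/{b}"
        for i, a in enumerate(YEO7_SYSTEMS)
        for b in YEO7_SYSTEMS[i + 1 :]
    ]
    rows = []
    for sex in spec.sexes:
        idx = labels.index[labels.sex == sex].to_numpy()
        pop = [subjects[i] for i in idx]
        _, reference = partitions[sex]
        for sub in specs:
            res = subset_accuracy(pop, sub, reference, mcfg)
            rows.append(
                {
                    "sex": sex,
                    "subset": sub,
                    "status": res.status,
                    "accuracy": res.accuracy,
                    "gamma": res.gamma,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.population_spec()
    mcfg = config.modularity_config()
    meta = {"seed": config.seed, "stage": None}
    artifacts = {}

    logger.info("generating population")
    subjects, labels = generate_population(spec)
    from .synth import write_population

    write_population(subjects, labels, out / "population")
    artifacts["population"] = str(out / "population" / "manifest.csv")

    logger.info("clustering architectures")
    part_df, accuracy, partitions = stage_cluster(
        subjects, labels, spec, mcfg, folds=config.folds, seed=config.seed
    )
    _write_csv(part_df, out / "partition.csv", {**meta, "stage": "cluster"})
    (out / "accuracy.json").write_text(json.dumps(accuracy, indent=2))
    artifacts["partition"] = str(out / "partition.csv")

    logger.info("graph metrics")
    mdf = metrics_table(subjects)
    _write_csv(mdf, out / "metrics.csv", {**meta, "stage": "metrics"})
    artifacts["metrics"] = str(out / "metrics.csv")

    logger.info("coupling sweeps")
    K_grid = config.K_grid()
    sweeps = [
        coupling_sweep(
            cm,
            K_grid,
            T=config.T,
            dt=config.dt,
            burn_in=config.burn_in,
            seed=config.seed + 977 * i,
            n_reps=config.n_reps,
        )
        for i, cm in enumerate(subjects)
    ]
    _write_csv(sweep_table(sweeps), out / "sweeps.csv",
               {**meta, "stage": "simulate"})
    sw_sum = sweep_summary(sweeps)
    _write_csv(sw_sum, out / "sweep_summary.csv",
               {**meta, "stage": "simulate"})
    artifacts["sweeps"] = str(out / "sweeps.csv")

    logger.info("lesioning")
    plan = rank_nodes(subjects, measure=config.measure)
    km = dict(
        K_grid=K_grid, T=config.T, dt=config.dt, burn_in=config.burn_in,
        seed=config.seed, n_reps=config.n_reps,
    )
    lesion_metrics, lesion_sweeps = lesion_experiment(
        subjects,
        plan,
        levels=config.levels,
        km_settings=km,
        run_dynamics=config.run_lesion_dynamics,
    )
    _write_csv(lesion_metrics, out / "lesion_metrics.csv",
               {**meta, "stage": "lesion"})
    if lesion_sweeps is not None:
        _write_csv(lesion_sweeps, out / "lesion_sweeps.csv",
                   {**meta, "stage": "lesion"})
    artifacts["lesion_metrics"] = str(out / "lesion_metrics.csv")

    logger.info("statistics report")
    report = module_report(
        part_df,
        metrics_df=mdf,
        sweep_summary_df=sw_sum,
        lesion_metrics_df=lesion_metrics,
        alpha=config.alpha,
    )
    rep_df = report_table(report)
    _write_csv(rep_df, out / "report.csv", {**meta, "stage": "report"})
    artifacts["report"] = str(out / "report.csv")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "artifacts": {
            k: {"path": v, "sha256": _hash(Path(v))}
            for k, v in artifacts.items()
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
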