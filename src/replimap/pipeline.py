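"""Experiment orchestration: tasks × sorts × k × metrics × nulls.

`run_experiment` drives the full pseudo-replicate analysis over a set of
tasks, producing a tidy record table (one row per task/sort/k/metric/
threshold cell), per-(task, k) null curves, the per-pair measurables design
rows, and per-k peak pools for the peak-height logistic fit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import measurables as meas
from .groupmodel import group_z_from_stack, subject_map
from .nulls import NullPool, fit_null_model, null_map_pool
from .resampling import SplitPlan, iterate_pseudo_pairs, make_split_plan
from .similarity import (
    ReplicabilityRecord,
    classify_peaks,
    jaccard_signed,
    peak_hit_rate,
    pearson_similarity,
)
from .statmap import GroupMap
from .synthetic import (
    SyntheticDataset,
    SyntheticDatasetSpec,
    generate_subject_maps,
    load_dataset,
)
from .thresholding import (
    ClusterSet,
    ThresholdSpec,
    cluster_threshold_grf,
    proportion_threshold,
)

logger = logging.getLogger("replimap")

ALL_METRICS = ("pearson", "jaccard_voxel", "jaccard_cluster", "peak_hit")
THRESHOLD_LABELS = ("liberal", "conservative")

__all__ = [
    "TaskConfig",
    "ExperimentConfig",
    "ExperimentResult",
    "load_config",
    "run_full_sample_reference",
    "run_experiment",
    "summarize_curves",
]


@dataclass
class TaskConfig:
    name: str
    synthetic: SyntheticDatasetSpec | None = None
    data_dir: str | None = None
    shared_group: str | None = None
    full_liberal_z: float = 3.1
    full_conservative_z: float = 4.5
    cluster_p: float = 0.01
    pq_liberal_z: float = 1.96
    pq_conservative_z: float = 2.81

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ValueError(
                f"task {self.name!r}: exactly one of synthetic/data_dir required"
            )
        for z in (self.full_liberal_z, self.full_conservative_z,
                  self.pq_liberal_z, self.pq_conservative_z):
            if z <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class ExperimentConfig:
    tasks: list[TaskConfig]
    k_grid: tuple[int, ...] = (16, 25, 36, 49, 64, 81, 100, 121)
    n_sorts: int = 500
    n_null_maps: int = 1000
    seed: int = 0
    out_dir: str | None = None
    metrics: tuple[str, ...] = ALL_METRICS
    keep_maps: bool = False  # persist every group z map as NIfTI

    def __post_init__(self) -> None:
        bad = [m for m in self.metrics if m not in ALL_METRICS]
        if bad:
            raise ValueError(f"unknown metrics {bad}")


@dataclass
class ExperimentResult:
    records: pd.DataFrame  # task, sort_index, k, metric, threshold_label, value
    null_curves: pd.DataFrame  # task, k, metric, threshold_label, value
    measurable_rows: pd.DataFrame
    reference_proportions: dict[str, dict[str, float]]
    peak_pools: dict[tuple[int, str], list[tuple[float, int]]]
    null_models: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def peak_logistic_fits(self) -> dict[str, dict]:
        """Pooled peak-height logistic fit per (k, threshold label)."""
        from .similarity import peak_height_logistic

        fits: dict[str, dict] = {}
        for (k, label), pool in sorted(self.peak_pools.items()):
            key = f"k{k}_{label}"
            try:
                fit = peak_height_logistic(pool)
            except ValueError as exc:
                fits[key] = {"n_peaks": len(pool), "error": str(exc)}
                continue
            fits[key] = {
                "intercept": fit.intercept,
                "slope": fit.slope,
                "separation": fit.separation,
                "n_peaks": fit.n_peaks,
            }
        return fits

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.null_curves.to_csv(out / "null_curves.csv", index=False)
        self.measurable_rows.to_csv(out / "measurables_rows.csv", index=False)
        with open(out / "reference_proportions.json", "w") as fh:
            json.dump(self.reference_proportions, fh, indent=2)
        with open(out / "null_models.json", "w") as fh:
            json.dump(self.null_models, fh, indent=2)
        with open(out / "peak_logistic.json", "w") as fh:
            json.dump(self.peak_logistic_fits(), fh, indent=2)
        with open(out / "failures.json", "w") as fh:
            json.dump(self.failures, fh, indent=2)


# ------------------------------------------------------------------ config
def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from YAML (fields mirror the dataclasses)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tasks = []
    for t in raw.pop("tasks"):
        synth = t.pop("synthetic", None)
        if synth is not None:
            from .synthetic import Blob, DesignSpec, TruthSpec

            truth_raw = synth.pop("truth", {})
            blobs = tuple(
                Blob(center=tuple(b["center"]), fwhm=b["fwhm"],
                     amplitude=b["amplitude"], sign=b.get("sign", 1))
                for b in truth_raw.pop("blobs", [])
            )
            if "grid_shape" in truth_raw:
                truth_raw["grid_shape"] = tuple(truth_raw["grid_shape"])
            if "mask_axes" in truth_raw:
                truth_raw["mask_axes"] = tuple(truth_raw["mask_axes"])
            truth = TruthSpec(blobs=blobs, **truth_raw)
            design = DesignSpec(**synth.pop("design", {}))
            synth = SyntheticDatasetSpec(truth=truth, design=design, **synth)
        tasks.append(TaskConfig(synthetic=synth, **t))
    if "k_grid" in raw:
        raw["k_grid"] = tuple(raw["k_grid"])
    if "metrics" in raw:
        raw["metrics"] = tuple(raw["metrics"])
    return ExperimentConfig(tasks=tasks, **raw)


# ------------------------------------------------------------ task loading
@dataclass
class _TaskData:
    config: TaskConfig
    dataset: SyntheticDataset
    stack: np.ndarray  # (n_subjects, nx, ny, nz) subject-level maps
    mask: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.stack.shape[0]


def _load_task(task: TaskConfig) -> _TaskData:
    if task.synthetic is not None:
        dataset = generate_subject_maps(task.synthetic)
    else:
        dataset = load_dataset(task.data_dir)
    subject_maps = [
        subject_map(dataset.subject_runs(sid)) for sid in dataset.subject_ids
    ]
    stack = np.stack([m.data for m in subject_maps])
    mask = np.logical_and.reduce([m.mask for m in subject_maps])
    return _TaskData(config=task, dataset=dataset, stack=stack, mask=mask)


def _group(task: _TaskData, ids: Sequence[int], label: str) -> GroupMap:
    ids = tuple(int(i) for i in ids)
    return group_z_from_stack(
        task.stack[list(ids)], task.mask, member_ids=ids, label=label
    )


# ------------------------------------------------------------- full sample
def run_full_sample_reference(task: _TaskData) -> dict[str, float]:
    """Full-sample GRF cluster thresholding at the task's liberal and
    conservative z thresholds; returns the suprathreshold proportion per
    threshold (the targets for proportion-matched thresholding)."""
    gmap = _group(task, range(task.n_subjects), "full")
    out = {}
    for label, z_crit in (
        ("liberal", task.config.full_liberal_z),
        ("conservative", task.config.full_conservative_z),
    ):
        spec = ThresholdSpec(
            mode="cluster_grf", z_crit=z_crit, cluster_p=task.config.cluster_p,
            label=label,
        )
        cs = cluster_threshold_grf(gmap, spec)
        proportion = cs.suprathreshold_proportion
        if proportion == 0.0:
            logger.warning(
                "task %s: empty full-sample thresholded map at %s threshold",
                task.config.name, label,
            )
        out[label] = proportion
    return out


def _task_measurables(task: _TaskData) -> meas.MeasurableSet:
    ds = task.dataset
    sids = ds.subject_ids
    motion, cpower, hat, within = [], [], [], []
    for sid in sids:
        runs = ds.subject_runs(sid)
        motion.append(float(np.mean([r.motion_rms for r in runs])))
        cpower.append(
            float(np.mean([
                meas.contrast_power(r.design_matrix, r.contrast_vector)
                for r in runs
            ]))
        )
        hat.append(
            float(np.mean([meas.hat_outlier_count(r.design_matrix) for r in runs]))
        )
        within.append(meas.within_subject_similarity([r.map for r in runs]))
    subject_maps = [subject_map(ds.subject_runs(sid)) for sid in sids]
    between = meas.between_subject_similarity(subject_maps)
    return meas.MeasurableSet(
        motion=np.asarray(motion),
        contrast_power=np.asarray(cpower),
        hat_outliers=np.asarray(hat),
        within=np.asarray(within),
        between=between,
    )


# -------------------------------------------------------------- experiment
def _plan_seed(base_seed: int, group_id: str) -> int:
    return int(np.random.SeedSequence(
        [base_seed, zlib.crc32(group_id.encode())]
    ).generate_state(1)[0])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pseudo-replicate experiment described by ``config``."""
    records: list[ReplicabilityRecord] = []
    null_rows: list[dict] = []
    null_models: list[dict] = []
    maps_dir: Path | None = None
    if config.keep_maps:
        if config.out_dir is None:
            raise ValueError("keep_maps requires an output directory")
        maps_dir = Path(config.out_dir) / "maps"
        maps_dir.mkdir(parents=True, exist_ok=True)
    meas_rows: list[dict] = []
    failures: list[dict] = []
    reference: dict[str, dict[str, float]] = {}
    peak_pools: dict[tuple[int, str], list[tuple[float, int]]] = {}
    plans: dict[str, SplitPlan] = {}

    thresholded_metrics = [m for m in config.metrics if m != "pearson"]

    for task_cfg in config.tasks:
        task = _load_task(task_cfg)
        name = task_cfg.name
        logger.info("task %s: %d subjects", name, task.n_subjects)

        proportions = run_full_sample_reference(task)
        reference[name] = proportions

        gid = task_cfg.shared_group or name
        k_grid = tuple(k for k in config.k_grid if k <= task.n_subjects // 2)
        if gid not in plans:
            plans[gid] = make_split_plan(
                task.n_subjects, config.n_sorts, k_grid,
                seed=_plan_seed(config.seed, gid),
            )
        plan = plans[gid]
        if plan.n_total != task.n_subjects:
            raise ValueError(
                f"shared group {gid!r}: participant counts differ across tasks"
            )

        grf_specs = {
            "liberal": ThresholdSpec(
                mode="cluster_grf", z_crit=task_cfg.pq_liberal_z,
                cluster_p=task_cfg.cluster_p, label="liberal",
            ),
            "conservative": ThresholdSpec(
                mode="cluster_grf", z_crit=task_cfg.pq_conservative_z,
                cluster_p=task_cfg.cluster_p, label="conservative",
            ),
        }

        ms = _task_measurables(task) if "pearson" in config.metrics else None

        # per-k collections for null fitting
        real_maps: dict[int, list[GroupMap]] = {k: [] for k in k_grid}
        real_voxel_cs: dict[tuple[int, str], list[ClusterSet]] = {}
        real_cluster_cs: dict[tuple[int, str], list[ClusterSet]] = {}

        for pair in iterate_pseudo_pairs(plan):
            sort, k = pair.sort_index, pair.k
            try:
                gP = _group(task, pair.P_ids, "P")
                gQ = _group(task, pair.Q_ids, "Q")
                real_maps[k].extend([gP, gQ])
                if maps_dir is not None:
                    for gm in (gP, gQ):
                        gm.zmap.save(
                            maps_dir / f"{name}_{sort:04d}_{gm.label}_k{k}.nii.gz"
                        )

                if "pearson" in config.metrics:
                    value = pearson_similarity(gP, gQ)
                    records.append(ReplicabilityRecord(name, sort, k,
                                                       "pearson", "none", value))
                    if ms is not None:
                        meas_rows.append(
                            meas.expand_to_pair_level(ms, pair, value, task=name)
                        )

                for label in THRESHOLD_LABELS:
                    if "jaccard_voxel" in config.metrics:
                        csP = proportion_threshold(gP, proportions[label])
                        csQ = proportion_threshold(gQ, proportions[label])
                        real_voxel_cs.setdefault((k, label), []).extend([csP, csQ])
                        records.append(ReplicabilityRecord(
                            name, sort, k, "jaccard_voxel", label,
                            jaccard_signed(csP, csQ)))
                    if "jaccard_cluster" in config.metrics or "peak_hit" in config.metrics:
                        gcP = cluster_threshold_grf(gP, grf_specs[label])
                        gcQ = cluster_threshold_grf(gQ, grf_specs[label])
                        real_cluster_cs.setdefault((k, label), []).extend([gcP, gcQ])
                        if "jaccard_cluster" in config.metrics:
                            records.append(ReplicabilityRecord(
                                name, sort, k, "jaccard_cluster", label,
                                jaccard_signed(gcP, gcQ)))
                        if "peak_hit" in config.metrics:
                            records.append(ReplicabilityRecord(
                                name, sort, k, "peak_hit", label,
                                peak_hit_rate(gcP, gcQ)))
                            pool = peak_pools.setdefault((k, label), [])
                            pool.extend(classify_peaks(gcP, gcQ.signed_mask))
                            pool.extend(classify_peaks(gcQ, gcP.signed_mask))
            except Exception as exc:  # keep going, log the cell
                logger.exception("task %s sort %d k %d failed", name, sort, k)
                failures.append(
                    {"task": name, "sort_index": sort, "k": k, "error": str(exc)}
                )

        # ---------------------------------------------------------- nulls
        null_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, zlib.crc32(name.encode()), 7])
        )
        for k in k_grid:
            maps_k = real_maps[k]
            if len(maps_k) < 2:
                continue
            model = fit_null_model(maps_k, n_null_maps=config.n_null_maps,
                                   task=name, k=k)
            null_models.append(dataclasses.asdict(model))
            pool = NullPool(null_map_pool(
                model, task.stack.shape[1:], task.mask, null_rng,
                n=config.n_null_maps,
            ))
            if "pearson" in config.metrics:
                stats_ = [pool.pearson_statistic(gm) for gm in maps_k]
                null_rows.append({"task": name, "k": k, "metric": "pearson",
                                  "threshold_label": "none",
                                  "value": float(np.mean(stats_))})
            for label in THRESHOLD_LABELS:
                if "jaccard_voxel" in config.metrics:
                    stats_ = [pool.thresholded_statistic(cs, "jaccard_voxel")
                              for cs in real_voxel_cs.get((k, label), [])]
                    if stats_:
                        null_rows.append({"task": name, "k": k,
                                          "metric": "jaccard_voxel",
                                          "threshold_label": label,
                                          "value": float(np.mean(stats_))})
                for metric in ("jaccard_cluster", "peak_hit"):
                    if metric in config.metrics:
                        stats_ = [pool.thresholded_statistic(cs, metric)
                                  for cs in real_cluster_cs.get((k, label), [])]
                        if stats_:
                            null_rows.append({"task": name, "k": k,
                                              "metric": metric,
                                              "threshold_label": label,
                                              "value": float(np.mean(stats_))})

    records_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    result = ExperimentResult(
        records=records_df,
        null_curves=pd.DataFrame(null_rows),
        measurable_rows=pd.DataFrame(meas_rows),
        reference_proportions=reference,
        peak_pools=peak_pools,
        null_models=null_models,
        failures=failures,
    )
    if config.out_dir:
        result.save(config.out_dir)
    return result


# --------------------------------------------------------------- summaries
def summarize_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Per-task per-k mean/SD over sorts, plus across-task rows (task="ALL")
    holding the mean of task means and the mean of within-task SDs.

    SDs are qualitative descriptions of sort-to-sort spread, not inferential
    error bars.
    """
    per_task = (
        records.groupby(["task", "metric", "threshold_label", "k"])["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    across = (
        per_task.groupby(["metric", "threshold_label", "k"])[["mean", "sd"]]
        .mean()
        .reset_index()
    )
    across.insert(0, "task", "ALL")
    return pd.concat([per_task, across], ignore_index=True)
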