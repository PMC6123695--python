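"""Explanatory "measurables" and the orthogonalized task-wise regression.

Five base variables are computed per participant (or participant pair):
motion, contrast power, hat-matrix leverage outliers, within-individual
similarity, and between-individual similarity.  Each is expanded to four
pair-level regressors (mean/absolute difference of the P and Q
pseudo-replicate means and SDs), joined by sample size, and regressed
against the unthresholded Pearson outcome, task by task.  Per-variable
effect sizes and ΔR² are aggregated across tasks by MAP shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit, logit

from .resampling import PseudoPair
from .statmap import StatMap

__all__ = [
    "BASE_VARIABLES",
    "EXPANSIONS",
    "MeasurableSet",
    "TaskRegressionResult",
    "contrast_power",
    "hat_outlier_count",
    "within_subject_similarity",
    "between_subject_similarity",
    "expand_to_pair_level",
    "fit_task_regression",
    "block_effect_size",
    "block_delta_r2",
    "map_aggregate",
    "measurables_report",
]

BASE_VARIABLES = ("motion", "contrast_power", "hat_outliers", "within", "between")
EXPANSIONS = ("mean_of_means", "absdiff_of_means", "mean_of_sds", "absdiff_of_sds")

#: regressor order: sample size first, then the five expanded blocks
def regressor_names() -> list[str]:
    names = ["sample_size"]
    for base in BASE_VARIABLES:
        names.extend(f"{base}__{ex}" for ex in EXPANSIONS)
    return names


# ---------------------------------------------------------- base variables
def _check_full_rank(X: np.ndarray) -> None:
    X = np.asarray(X, dtype=np.float64)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        dependent = sorted(piv[np.sum(diag > tol):].tolist())
        raise ValueError(f"design matrix rank deficient; dependent columns {dependent}")


def contrast_power(X: np.ndarray, c: np.ndarray) -> float:
    """Reciprocal of the contrast precision c·(X′X)⁻¹·c′ for one run."""
    X = np.asarray(X, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if c.shape[0] != X.shape[1]:
        raise ValueError("contrast length must equal design columns")
    _check_full_rank(X)
    precision = float(c @ np.linalg.solve(X.T @ X, c))
    return 1.0 / precision


def hat_outlier_count(X: np.ndarray) -> int:
    """Count of hat-matrix diagonal entries exceeding 2·rank(hat)/nrows(hat)."""
    X = np.asarray(X, dtype=np.float64)
    _check_full_rank(X)
    Q, _ = np.linalg.qr(X)
    leverages = np.sum(Q**2, axis=1)
    threshold = 2.0 * X.shape[1] / X.shape[0]
    return int(np.sum(leverages > threshold))


def _masked_corr(a: StatMap, b: StatMap) -> float:
    m = a.mask & b.mask
    return float(np.corrcoef(a.data[m], b.data[m])[0, 1])


def within_subject_similarity(run_maps: Sequence[StatMap]) -> float:
    """Mean over all unordered run pairs of the in-mask Pearson correlation.

    Undefined for a single run (returns NaN; downstream the four derived
    regressors are dropped for tasks where all subjects have one run)."""
    n = len(run_maps)
    if n < 2:
        return float("nan")
    vals = [
        _masked_corr(run_maps[i], run_maps[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def between_subject_similarity(subject_maps: Sequence[StatMap]) -> np.ndarray:
    """Symmetric matrix of whole-brain correlations for every subject pair
    (diagonal NaN)."""
    n = len(subject_maps)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mask = np.logical_and.reduce([m.mask for m in subject_maps])
    mat = np.stack([m.data[mask] for m in subject_maps])
    mat = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1)
    corr = (mat @ mat.T) / np.outer(norms, norms)
    np.fill_diagonal(corr, np.nan)
    return corr


@dataclass
class MeasurableSet:
    """Per-task base measurables: per-participant vectors indexed by
    participant id, plus the between-participant correlation matrix."""

    motion: np.ndarray
    contrast_power: np.ndarray
    hat_outliers: np.ndarray
    within: np.ndarray  # NaN when a subject has a single run
    between: np.ndarray  # (n, n) symmetric, diagonal NaN

    def per_subject(self, base: str) -> np.ndarray:
        if base == "between":
            raise ValueError("between is a pair-level variable")
        return getattr(self, base)


# ------------------------------------------------------ pair-level design
def _group_stats(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def expand_to_pair_level(
    ms: MeasurableSet,
    pair: PseudoPair,
    outcome: float,
    task: str = "",
) -> dict:
    """One regression row: for each base variable, the pair mean and absolute
    difference of the P/Q pseudo-replicate means and (n−1)-denominator SDs.

    ``between`` aggregates over the participant pairs fully inside each
    pseudo-replicate.  Missing base values flag the row incomplete.
    """
    row: dict = {
        "task": task,
        "sort_index": pair.sort_index,
        "k": pair.k,
        "sample_size": float(pair.k),
        "outcome": outcome,
        "incomplete": False,
    }
    p_idx = np.asarray(pair.P_ids)
    q_idx = np.asarray(pair.Q_ids)
    for base in BASE_VARIABLES:
        if base == "between":
            iu = np.triu_indices(len(p_idx), k=1)
            p_vals = ms.between[np.ix_(p_idx, p_idx)][iu]
            q_vals = ms.between[np.ix_(q_idx, q_idx)][iu]
        else:
            vec = ms.per_subject(base)
            p_vals = vec[p_idx]
            q_vals = vec[q_idx]
        if np.isnan(p_vals).any() or np.isnan(q_vals).any():
            row["incomplete"] = True
            for ex in EXPANSIONS:
                row[f"{base}__{ex}"] = float("nan")
            continue
        mp, sp = _group_stats(p_vals)
        mq, sq = _group_stats(q_vals)
        row[f"{base}__mean_of_means"] = 0.5 * (mp + mq)
        row[f"{base}__absdiff_of_means"] = abs(mp - mq)
        row[f"{base}__mean_of_sds"] = 0.5 * (sp + sq)
        row[f"{base}__absdiff_of_sds"] = abs(sp - sq)
    return row


# ------------------------------------------------------------- regression
@dataclass
class TaskRegressionResult:
    task: str
    columns: list[str]
    beta: np.ndarray
    design: np.ndarray
    outcome: np.ndarray
    ssr: float
    r2: float
    dropped: list[str] = field(default_factory=list)

    @property
    def xtx_inv(self) -> np.ndarray:
        return np.linalg.inv(self.design.T @ self.design)


_VAR_TOL = 1e-12


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return y
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def fit_task_regression(rows: pd.DataFrame, task: str = "") -> TaskRegressionResult:
    """Orthogonalized OLS of the Pearson outcome on the expanded regressors
    for one task.

    Steps: drop the task's largest sample size; demean everything;
    orthogonalize the within block against the motion/contrast-power/
    hat-outlier blocks and the between block against those plus the
    orthogonalized within block; drop degenerate or collinear columns; OLS.
    """
    df = rows.copy()
    ks = sorted(df["k"].unique())
    if len(ks) < 3:
        raise ValueError("need >= 2 distinct k values after removing the largest")
    df = df[df["k"] != ks[-1]]
    if "incomplete" in df.columns:
        df = df[~df["incomplete"].astype(bool)]

    names = regressor_names()
    dropped: list[str] = []

    y = df["outcome"].to_numpy(dtype=np.float64)
    y = y - y.mean()

    cols: dict[str, np.ndarray] = {}
    for name in names:
        col = df[name].to_numpy(dtype=np.float64)
        if np.isnan(col).any() or np.std(col) <= _VAR_TOL * max(1.0, np.abs(col).max()):
            dropped.append(name)
            continue
        cols[name] = col - col.mean()

    def block(base: str) -> list[str]:
        return [n for n in cols if n.startswith(base + "__")]

    anchor_names = block("motion") + block("contrast_power") + block("hat_outliers")
    anchor = (
        np.column_stack([cols[n] for n in anchor_names])
        if anchor_names
        else np.empty((len(y), 0))
    )
    for name in block("within"):
        cols[name] = _residualize(cols[name], anchor)
    within_mat = (
        np.column_stack([cols[n] for n in block("within")])
        if block("within")
        else np.empty((len(y), 0))
    )
    anchor16 = np.column_stack([anchor, within_mat])
    for name in block("between"):
        cols[name] = _residualize(cols[name], anchor16)

    # orthogonalization can zero out a column entirely; drop those too
    for name in list(cols):
        col = cols[name]
        if np.std(col) <= _VAR_TOL * max(1.0, np.abs(col).max(), 1e-300):
            dropped.append(name)
            del cols[name]

    if not cols:
        raise ValueError("all regressors degenerate")

    kept = [n for n in names if n in cols]
    X = np.column_stack([cols[n] for n in kept])

    # remove residual collinearity by pivoted QR
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    n_keep = int(np.sum(diag > tol))
    if n_keep < X.shape[1]:
        discard = {kept[i] for i in piv[n_keep:]}
        dropped.extend(sorted(discard))
        kept = [n for n in kept if n not in discard]
        X = np.column_stack([cols[n] for n in kept])

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(y @ y)
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return TaskRegressionResult(
        task=task,
        columns=kept,
        beta=beta,
        design=X,
        outcome=y,
        ssr=ssr,
        r2=r2,
        dropped=dropped,
    )


def block_effect_size(result: TaskRegressionResult, base_variable: str) -> float:
    """Signed max-|d| over the variable's surviving expansions, with
    d_i = β_i / √(σ²_err · [(X′X)⁻¹]_ii) and σ²_err the sum of squared
    residuals (no degrees-of-freedom division)."""
    if base_variable == "sample_size":
        idxs = [i for i, n in enumerate(result.columns) if n == "sample_size"]
    else:
        idxs = [
            i
            for i, n in enumerate(result.columns)
            if n.startswith(base_variable + "__")
        ]
    if not idxs:
        return float("nan")
    xtx_inv = result.xtx_inv
    ds = [
        result.beta[i] / np.sqrt(result.ssr * xtx_inv[i, i])
        for i in idxs
    ]
    return float(max(ds, key=abs))


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(y @ y)
    return 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0


def block_delta_r2(result: TaskRegressionResult, base_variable: str) -> float:
    """R²(full) − R²(full minus the variable's surviving expansions),
    floored at 0."""
    if base_variable == "sample_size":
        keep = [i for i, n in enumerate(result.columns) if n != "sample_size"]
    else:
        keep = [
            i
            for i, n in enumerate(result.columns)
            if not n.startswith(base_variable + "__")
        ]
    if len(keep) == len(result.columns):
        return 0.0  # nothing from this block survived
    reduced = result.design[:, keep]
    return max(0.0, result.r2 - _r2(reduced, result.outcome))


def measurables_report(rows: pd.DataFrame) -> dict:
    """Fit the task-wise regressions and aggregate per-block effect sizes and
    ΔR² across tasks by MAP shrinkage.

    Returns a JSON-ready dict with per-task and aggregate values plus the
    priors used (an interpretive choice, recorded in the output).
    """
    blocks = ("sample_size",) + BASE_VARIABLES
    per_task: dict[str, dict] = {}
    for task, df in rows.groupby("task"):
        res = fit_task_regression(df, task=task)
        per_task[task] = {
            "r2": res.r2,
            "dropped": res.dropped,
            "effect_size": {b: block_effect_size(res, b) for b in blocks},
            "delta_r2": {b: block_delta_r2(res, b) for b in blocks},
        }
    aggregate: dict[str, dict] = {"effect_size": {}, "delta_r2": {}}
    for b in blocks:
        ds = [per_task[t]["effect_size"][b] for t in per_task]
        rs = [per_task[t]["delta_r2"][b] for t in per_task]
        ds = [d for d in ds if np.isfinite(d)]
        rs = [r for r in rs if np.isfinite(r)]
        aggregate["effect_size"][b] = (
            map_aggregate(ds, "effect_size") if len(ds) >= 2 else float("nan")
        )
        aggregate["delta_r2"][b] = (
            map_aggregate(rs, "delta_r2") if len(rs) >= 2 else float("nan")
        )
    return {
        "per_task": per_task,
        "aggregate": aggregate,
        "priors": {
            "effect_size": {"family": "normal", "mean": 0.0, "variance": 1.0},
            "delta_r2_logit": {"family": "normal", "mean": -20.0, "sd": 10.0},
            "likelihood": "normal with plug-in across-task sample variance",
        },
    }


# ------------------------------------------------------------ aggregation
def map_aggregate(values: Sequence[float], kind: str) -> float:
    """MAP shrinkage of the across-task average.

    ``effect_size``: values ~ Normal(μ, s²) with plug-in across-task sample
    variance s² and prior μ ~ Normal(0, 1) → posterior mean
    (n·x̄/s²)/(n/s² + 1).  ``delta_r2``: logit-transform (values clamped to
    [1e−8, 1−1e−8]), same posterior mean with prior Normal(−20, 10²) in the
    transformed scale, then inverse-logit.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=np.float64)
    if len(vals) < 2:
        raise ValueError("need >= 2 task values (across-task variance undefined)")
    if kind == "effect_size":
        prior_mean, prior_var = 0.0, 1.0
        x = vals
    elif kind == "delta_r2":
        prior_mean, prior_var = -20.0, 100.0
        x = logit(np.clip(vals, 1e-8, 1.0 - 1e-8))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    n = len(x)
    s2 = float(np.var(x, ddof=1))
    if s2 == 0.0:
        post = float(np.mean(x))  # data exactly agree; likelihood dominates
    else:
        post = (n * np.mean(x) / s2 + prior_mean / prior_var) / (
            n / s2 + 1.0 / prior_var
        )
    if kind == "delta_r2":
        return float(expit(post))
    return float(post)
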