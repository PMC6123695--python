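"""Smoothness-matched null models and null curves.

For each (task, k) the observed per-map smoothness (geometric-mean FWHM) and
robust intensity range (2nd/98th in-mask percentiles) are parameterized as
normal distributions.  Null maps are smoothed white noise with FWHM and
robust range drawn from those distributions.  Each real map's null statistic
is the 95th percentile of its metric against the pool of null maps, and the
null curve is the average of those per-map values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .similarity import classify_peaks, jaccard_signed_masks
from .statmap import GroupMap, StatMap
from .synthetic import FWHM_TO_SIGMA
from .thresholding import ClusterSet, estimate_fwhm, proportion_signed_mask

__all__ = [
    "NullModel",
    "NullCurve",
    "fit_null_model",
    "sample_null_map",
    "null_map_pool",
    "NullPool",
    "null_statistic_for_map",
    "null_curves",
]

DEFAULT_N_NULL = 1000
_MIN_FWHM = 0.5


@dataclass(frozen=True)
class NullModel:
    fwhm_mean: float
    fwhm_sd: float
    rmin_mean: float
    rmin_sd: float
    rmax_mean: float
    rmax_sd: float
    n_null_maps: int = DEFAULT_N_NULL
    task: str = ""
    k: int = 0

    def __post_init__(self) -> None:
        if self.fwhm_mean <= 0:
            raise ValueError("fwhm_mean must be > 0")
        if not self.rmax_mean > self.rmin_mean:
            raise ValueError("rmax_mean must exceed rmin_mean")
        for name in ("fwhm_mean", "fwhm_sd", "rmin_mean", "rmin_sd",
                     "rmax_mean", "rmax_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class NullCurve:
    task: str
    k: int
    metric: str
    threshold_label: str
    value: float


def fit_null_model(
    real_maps: Sequence[GroupMap],
    n_null_maps: int = DEFAULT_N_NULL,
    task: str = "",
    k: int = 0,
) -> NullModel:
    """Normal parameterization (sample mean/SD) of the per-map geometric-mean
    FWHM and robust min/max (2nd and 98th in-mask percentiles)."""
    if len(real_maps) < 2:
        raise ValueError("need >= 2 real maps to fit a null model")
    fwhms, rmins, rmaxs = [], [], []
    for gm in real_maps:
        fwhms.append(estimate_fwhm(gm.zmap).fwhm_geo)
        vals = gm.zmap.in_mask_values()
        rmins.append(float(np.percentile(vals, 2)))
        rmaxs.append(float(np.percentile(vals, 98)))
    fwhms = np.asarray(fwhms)
    rmins = np.asarray(rmins)
    rmaxs = np.asarray(rmaxs)
    return NullModel(
        fwhm_mean=float(fwhms.mean()),
        fwhm_sd=float(fwhms.std(ddof=1)),
        rmin_mean=float(rmins.mean()),
        rmin_sd=float(rmins.std(ddof=1)),
        rmax_mean=float(rmaxs.mean()),
        rmax_sd=float(rmaxs.std(ddof=1)),
        n_null_maps=n_null_maps,
        task=task,
        k=k,
    )


def sample_null_map(
    model: NullModel,
    grid_shape: Sequence[int],
    mask: np.ndarray,
    rng: np.random.Generator,
) -> StatMap:
    """One smoothness-matched null map.

    Standard-normal noise smoothed with a sampled FWHM (truncated at 0.5
    voxel), then linearly rescaled so its own 2nd/98th in-mask percentiles
    equal a sampled robust min/max (max redrawn with min until max > min)."""
    fwhm = max(_MIN_FWHM, rng.normal(model.fwhm_mean, model.fwhm_sd))
    noise = rng.standard_normal(tuple(grid_shape))
    noise = gaussian_filter(noise, sigma=fwhm * FWHM_TO_SIGMA)

    rmin = rmax = 0.0
    for _ in range(100):
        rmin = rng.normal(model.rmin_mean, model.rmin_sd)
        rmax = rng.normal(model.rmax_mean, model.rmax_sd)
        if rmax > rmin:
            break
    else:
        raise ValueError("could not sample a nondegenerate robust range")

    vals = noise[mask]
    p2, p98 = np.percentile(vals, [2, 98])
    if p98 <= p2:
        raise ValueError("degenerate simulated noise percentiles")
    data = (noise - p2) / (p98 - p2) * (rmax - rmin) + rmin
    data[~mask] = 0.0
    return StatMap(data=data, mask=np.asarray(mask, dtype=bool))


def null_map_pool(
    model: NullModel,
    grid_shape: Sequence[int],
    mask: np.ndarray,
    rng: np.random.Generator,
    n: int | None = None,
) -> list[StatMap]:
    n = model.n_null_maps if n is None else n
    return [sample_null_map(model, grid_shape, mask, rng) for _ in range(n)]


def _null_signed_mask(null_map: StatMap, proportion: float) -> np.ndarray:
    return proportion_signed_mask(null_map, proportion)


def null_statistic_for_map(
    real: GroupMap | ClusterSet,
    model: NullModel,
    metric: str,
    rng: np.random.Generator | None = None,
    null_maps: Sequence[StatMap] | None = None,
) -> float:
    """95th percentile over the null-map pool of the metric between the real
    map and each null map.

    ``real`` is a :class:`GroupMap` for ``pearson`` and a thresholded
    :class:`ClusterSet` for the thresholded metrics, whose own suprathreshold
    proportion sets the (two-tailed) proportion threshold applied to every
    null map.  A real map with no suprathreshold voxels scores 0.
    """
    if metric not in ("pearson", "jaccard_voxel", "jaccard_cluster", "peak_hit"):
        raise ValueError(f"unknown metric {metric!r}")
    if null_maps is None:
        if rng is None:
            raise ValueError("provide either null_maps or rng")
        if metric == "pearson":
            grid, mask = real.zmap.shape, real.zmap.mask
        else:
            grid, mask = real.signed_mask.shape, real.analysis_mask
        null_maps = null_map_pool(model, grid, mask, rng)

    if metric == "pearson":
        rv = real.zmap.in_mask_values()
        rv = rv - rv.mean()
        rn = np.linalg.norm(rv)
        stats_ = []
        for nm in null_maps:
            nv = nm.data[real.zmap.mask]
            nv = nv - nv.mean()
            stats_.append(float(rv @ nv / (rn * np.linalg.norm(nv))))
    else:
        if real.n_suprathreshold == 0:
            return 0.0
        proportion = real.suprathreshold_proportion
        stats_ = []
        for nm in null_maps:
            nmask = _null_signed_mask(nm, proportion)
            if metric in ("jaccard_voxel", "jaccard_cluster"):
                stats_.append(jaccard_signed_masks(real.signed_mask, nmask))
            else:  # peak_hit: classify the real map's peaks against the null
                hits = classify_peaks(real, nmask)
                stats_.append(float(np.mean([h for _, h in hits])) if hits else 0.0)
    return float(np.percentile(stats_, 95))


class NullPool:
    """Precomputed view of a null-map pool for fast repeated thresholding.

    Stores, per null map, the in-mask voxels ranked by (|value| desc, linear
    index asc) — the exact order :func:`proportion_signed_mask` uses — plus
    sign and rank lookups, so proportion-matched null statistics for many
    real maps reuse one sort per null map.
    """

    def __init__(self, null_maps: Sequence[StatMap]):
        if not null_maps:
            raise ValueError("empty null pool")
        self.mask = null_maps[0].mask
        self.shape = null_maps[0].shape
        lin = np.flatnonzero(self.mask.ravel())
        self.n_mask = len(lin)
        n_vox = int(np.prod(self.shape))
        n = len(null_maps)

        self.sign_flat = np.empty((n, n_vox), dtype=np.int8)
        self.orders: list[np.ndarray] = []
        self.ranks = np.full((n, n_vox), n_vox, dtype=np.int32)
        vals = np.empty((n, self.n_mask))
        for i, nm in enumerate(null_maps):
            flat = nm.data.ravel()
            self.sign_flat[i] = np.where(flat >= 0, 1, -1)
            absz = np.abs(flat[lin])
            order = lin[np.lexsort((lin, -absz))]
            self.orders.append(order)
            self.ranks[i, order] = np.arange(len(order), dtype=np.int32)
            vals[i] = flat[lin]
        vals = vals - vals.mean(axis=1, keepdims=True)
        self.std_vals = vals / np.linalg.norm(vals, axis=1, keepdims=True)

    def __len__(self) -> int:
        return len(self.orders)

    # ------------------------------------------------------------- metrics
    def pearson_statistic(self, real: GroupMap) -> float:
        rv = real.zmap.data.ravel()[np.flatnonzero(self.mask.ravel())]
        rv = rv - rv.mean()
        rv = rv / np.linalg.norm(rv)
        corrs = self.std_vals @ rv
        return float(np.percentile(corrs, 95))

    def thresholded_statistic(self, real: ClusterSet, metric: str) -> float:
        """Proportion-matched null statistic for a thresholded real map."""
        n_sel = real.n_suprathreshold
        if n_sel == 0:
            return 0.0
        n_target = int(np.floor(real.suprathreshold_proportion * self.n_mask + 0.5))
        real_flat = real.signed_mask.ravel()
        stats_ = np.empty(len(self))
        if metric in ("jaccard_voxel", "jaccard_cluster"):
            nnz_real = int(np.count_nonzero(real_flat))
            for i in range(len(self)):
                idx = self.orders[i][:n_target]
                rvals = real_flat[idx]
                inter = int(np.count_nonzero(rvals == self.sign_flat[i, idx]))
                overlap = int(np.count_nonzero(rvals))
                union = nnz_real + n_target - overlap
                stats_[i] = inter / union if union else 0.0
        elif metric == "peak_hit":
            peaks = [
                (np.ravel_multi_index(c.peak_voxel, self.shape), c.sign)
                for c in real.clusters
            ]
            if not peaks:
                return 0.0
            plin = np.asarray([p[0] for p in peaks])
            psign = np.asarray([p[1] for p in peaks])
            for i in range(len(self)):
                hit = (self.ranks[i, plin] < n_target) & (
                    self.sign_flat[i, plin] == psign
                )
                stats_[i] = float(hit.mean())
        else:
            raise ValueError(f"unknown thresholded metric {metric!r}")
        return float(np.percentile(stats_, 95))


def null_curves(
    per_map_statistics: Sequence[float],
    task: str,
    k: int,
    metric: str,
    threshold_label: str,
) -> NullCurve:
    """Average of per-real-map null statistics for one (task, k, metric,
    threshold) cell."""
    if len(per_map_statistics) == 0:
        raise ValueError("no per-map null statistics supplied")
    return NullCurve(
        task=task,
        k=k,
        metric=metric,
        threshold_label=threshold_label,
        value=float(np.mean(per_map_statistics)),
    )
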