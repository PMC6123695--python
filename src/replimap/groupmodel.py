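"""Group-level mapping: subject-level run combination and one-sample t→z maps.

The group map is a one-sample t statistic on subject-level mean maps,
converted to z by matching cumulative probability between the t(df) and
standard normal distributions.  This is a documented stand-in for a
mixed-effects group model: the downstream similarity metrics consume any
group z map.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .statmap import GroupMap, StatMap
from .synthetic import SubjectRunMap

__all__ = [
    "Z_CLAMP",
    "subject_map",
    "t_to_z",
    "group_z_from_stack",
    "compute_group_zmap",
    "common_mask",
]

# double-precision safe range for the normal quantile
Z_CLAMP = 38.0


def subject_map(runs: Sequence[SubjectRunMap]) -> StatMap:
    """Voxelwise arithmetic mean of one subject's run maps (simplified
    fixed-effects combination; runs equally weighted)."""
    if len(runs) < 1:
        raise ValueError("need at least one run")
    shape = runs[0].map.shape
    for r in runs:
        if r.map.shape != shape:
            raise ValueError("run map shapes differ")
    data = np.mean([r.map.data for r in runs], axis=0)
    mask = np.logical_and.reduce([r.map.mask for r in runs])
    return StatMap(data=data, mask=mask, voxel_size=runs[0].map.voxel_size)


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t(df) values to standard-normal z of equal cumulative probability.

    Computed symmetrically through the survival function so large |t| stays
    accurate; |z| clamped at ``Z_CLAMP``.
    """
    t = np.asarray(t, dtype=np.float64)
    sf = stats.t.sf(np.abs(t), df)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(sf)
    z = np.minimum(z, Z_CLAMP)
    return np.sign(t) * z


def group_z_from_stack(
    stack: np.ndarray,
    mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    member_ids: Sequence[int] = (),
    label: str = "P",
) -> GroupMap:
    """Group z map from a (k, nx, ny, nz) stack of subject-level maps."""
    k = stack.shape[0]
    if k < 4:
        raise ValueError("group z map requires k >= 4")
    shape = stack.shape[1:]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)

    z = np.zeros(shape)
    degenerate = mask & (sd == 0)
    ok = mask & (sd > 0)
    t = mean[ok] / (sd[ok] / np.sqrt(k))
    z[ok] = t_to_z(t, df=k - 1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} in-mask voxels with zero SD; "
            "z set to signed clamp value",
            RuntimeWarning,
            stacklevel=2,
        )
        z[degenerate] = np.where(mean[degenerate] >= 0, Z_CLAMP, -Z_CLAMP)

    zmap = StatMap(data=z, mask=mask, voxel_size=voxel_size)
    return GroupMap(zmap=zmap, k=k, member_ids=member_ids, label=label)


def compute_group_zmap(
    maps: Sequence[StatMap],
    k: int | None = None,
    member_ids: Sequence[int] = (),
    label: str = "P",
) -> GroupMap:
    """One-sample t = mean/(sd/√k) with df = k−1, mapped to z.

    The mask is the intersection of member masks.  In-mask voxels with zero
    sample SD get the clamp value with the mean's sign (with a warning).
    """
    if k is None:
        k = len(maps)
    if k != len(maps):
        raise ValueError(f"k={k} does not match number of maps ({len(maps)})")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("map shapes differ")
    mask = np.logical_and.reduce([m.mask for m in maps])
    stack = np.stack([m.data for m in maps])
    return group_z_from_stack(
        stack,
        mask,
        voxel_size=maps[0].voxel_size,
        member_ids=member_ids,
        label=label,
    )


def common_mask(a: StatMap, b: StatMap) -> np.ndarray:
    """Boolean AND of both masks, restricted to voxels nonzero in both maps."""
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    out = a.mask & b.mask & (a.data != 0) & (b.data != 0)
    if not out.any():
        raise ValueError("common mask is empty: no comparable voxels")
    return out
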