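"""Core volumetric containers: :class:`StatMap` and :class:`GroupMap`.

A :class:`StatMap` is the universal currency of the pipeline: a 3D array of
statistic (or contrast-estimate) values together with a boolean analysis mask
and the voxel geometry.  Values outside the mask are identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["StatMap", "GroupMap"]


@dataclass
class StatMap:
    """A 3D statistic image with its mask and voxel size (mm).

    Invariants: ``data`` and ``mask`` share one 3D shape, ``data`` is finite
    inside the mask and exactly zero outside it.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got shape {self.data.shape}")
        if self.data.shape != self.mask.shape:
            raise ValueError(
                f"data shape {self.data.shape} != mask shape {self.mask.shape}"
            )
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside mask")
        # enforce the outside-mask-zero invariant rather than erroring on it
        self.data = np.where(self.mask, self.data, 0.0)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask_values(self) -> np.ndarray:
        """Vector of data values at in-mask voxels (C order)."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "StatMap":
        """New StatMap sharing this map's mask and geometry."""
        return StatMap(data=data, mask=self.mask, voxel_size=self.voxel_size)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float64), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, mask: np.ndarray | None = None) -> "StatMap":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        if mask is None:
            mask = np.ones(data.shape, dtype=bool)
        return cls(data=data, mask=np.asarray(mask, dtype=bool), voxel_size=voxel_size)


@dataclass
class GroupMap:
    """A group-level z map for ``k`` participants of one pseudo-replicate."""

    zmap: StatMap
    k: int
    member_ids: Sequence[int] = field(default_factory=tuple)
    label: str = "P"

    def __post_init__(self) -> None:
        self.member_ids = tuple(int(i) for i in self.member_ids)
        if self.member_ids and len(self.member_ids) != self.k:
            raise ValueError(
                f"len(member_ids)={len(self.member_ids)} does not match k={self.k}"
            )
        if self.label not in ("P", "Q", "full"):
            raise ValueError(f"label must be 'P', 'Q' or 'full', got {self.label!r}")
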