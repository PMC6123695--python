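"""Map smoothness estimation, proportion and GRF cluster-extent thresholding,
signed component labeling, peaks, and the full-sample threshold scaling rule.

Conventions pinned for determinism:

* cluster connectivity is 26-neighbor;
* peak ties break to the smallest linear voxel index (C order);
* proportion thresholding ranks by (|z| desc, linear index asc) and cuts at
  the exact requested count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn

from .statmap import GroupMap, StatMap

__all__ = [
    "SmoothnessEstimate",
    "ThresholdSpec",
    "Cluster",
    "ClusterSet",
    "estimate_fwhm",
    "proportion_signed_mask",
    "proportion_threshold",
    "label_components",
    "grf_cluster_pvalue",
    "cluster_threshold_grf",
    "find_cluster_peaks",
    "scaled_full_sample_threshold",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)
_MIN_FWHM = 0.5


# ------------------------------------------------------------------- types
@dataclass(frozen=True)
class SmoothnessEstimate:
    fwhm_per_axis: tuple[float, float, float]
    fwhm_geo: float
    resels: float

    @classmethod
    def from_fwhm(
        cls, fwhm_per_axis: Sequence[float], n_mask_voxels: int
    ) -> "SmoothnessEstimate":
        fwhm = tuple(float(f) for f in fwhm_per_axis)
        if any(f <= 0 for f in fwhm):
            raise ValueError("FWHM entries must be positive")
        geo = float(np.prod(fwhm) ** (1.0 / 3.0))
        return cls(
            fwhm_per_axis=fwhm,
            fwhm_geo=geo,
            resels=float(n_mask_voxels) / float(np.prod(fwhm)),
        )


@dataclass(frozen=True)
class ThresholdSpec:
    mode: str  # "proportion" | "cluster_grf"
    target_proportion: float | None = None
    z_crit: float | None = None
    cluster_p: float | None = None
    two_tailed: bool = True
    label: str = "none"

    def __post_init__(self) -> None:
        if self.mode == "proportion":
            if self.target_proportion is None or not (
                0.0 <= self.target_proportion <= 1.0
            ):
                raise ValueError("target_proportion must lie in [0, 1]")
        elif self.mode == "cluster_grf":
            if self.z_crit is None or self.z_crit <= 0:
                raise ValueError("z_crit must be > 0")
            if self.cluster_p is None or not (0.0 < self.cluster_p < 1.0):
                raise ValueError("cluster_p must lie in (0, 1)")
        else:
            raise ValueError(f"unknown threshold mode {self.mode!r}")


@dataclass
class Cluster:
    voxels: np.ndarray  # (n, 3) integer voxel indices
    sign: int
    size: int
    peak_voxel: tuple[int, int, int]
    peak_z: float
    p_cluster: float | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    signed_mask: np.ndarray  # int8 array in {-1, 0, +1}
    spec: ThresholdSpec
    source: GroupMap | None = None
    analysis_mask: np.ndarray | None = None

    @property
    def n_suprathreshold(self) -> int:
        return int(np.count_nonzero(self.signed_mask))

    @property
    def suprathreshold_proportion(self) -> float:
        if self.analysis_mask is None:
            raise ValueError("analysis mask not recorded")
        n = int(self.analysis_mask.sum())
        return self.n_suprathreshold / n if n else 0.0


# -------------------------------------------------------------- smoothness
def estimate_fwhm(statmap: StatMap) -> SmoothnessEstimate:
    """Per-axis FWHM from the lag-1 autocorrelation of the standardized map.

    With in-mask variance σ² and first-difference variance var(Δ) along an
    axis, the lag-1 autocorrelation is ρ = 1 − var(Δ)/(2σ²); for a
    Gaussian-kernel-smoothed field ρ(1) = exp(−2·ln2 / FWHM²), so
    FWHM = √(2·ln2 / (−ln ρ)).  Estimates are clamped to ≥ 0.5 voxel.
    """
    vals = statmap.in_mask_values()
    var = float(vals.var())
    if var == 0.0:
        raise ValueError("constant map: smoothness undefined")
    mean = float(vals.mean())
    data = (statmap.data - mean) / np.sqrt(var)
    mask = statmap.mask

    fwhm = []
    for axis in range(3):
        if statmap.shape[axis] < 2:
            raise ValueError("need >= 2 in-mask voxels along each axis")
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if pair_mask.sum() < 2:
            raise ValueError("need >= 2 in-mask voxel pairs along each axis")
        diffs = (data[tuple(sl_a)] - data[tuple(sl_b)])[pair_mask]
        rho = 1.0 - float(np.mean(diffs**2)) / 2.0
        if rho <= 0.0:
            fwhm.append(_MIN_FWHM)
            continue
        f = float(np.sqrt(2.0 * np.log(2.0) / (-np.log(rho))))
        fwhm.append(max(f, _MIN_FWHM))
    return SmoothnessEstimate.from_fwhm(fwhm, statmap.n_mask_voxels)


# ------------------------------------------------------------- thresholding
def label_components(signed_mask: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """26-connectivity components, computed separately within the +1 voxels
    and within the −1 voxels.  Returns ``(sign, (n,3) voxel array)`` tuples."""
    signed_mask = np.asarray(signed_mask)
    if not np.isin(signed_mask, (-1, 0, 1)).all():
        raise ValueError("signed mask values must lie in {-1, 0, +1}")
    out: list[tuple[int, np.ndarray]] = []
    for sign in (1, -1):
        labels, n = ndimage.label(signed_mask == sign, structure=_STRUCTURE_26)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            out.append((sign, vox))
    return out


def _make_cluster(
    sign: int, voxels: np.ndarray, z: np.ndarray, p_cluster: float | None = None
) -> Cluster:
    zvals = z[tuple(voxels.T)]
    order = np.abs(zvals)
    # ties on |z| break to smallest linear index (voxels arrive sorted C-order)
    best = int(np.argmax(order))
    return Cluster(
        voxels=voxels,
        sign=sign,
        size=int(len(voxels)),
        peak_voxel=tuple(int(v) for v in voxels[best]),
        peak_z=float(zvals[best]),
        p_cluster=p_cluster,
    )


def proportion_signed_mask(statmap: StatMap, target_proportion: float) -> np.ndarray:
    """Signed {−1,0,+1} mask of the round(target × in-mask count) largest-|z|
    voxels; |z| ties ranked by ascending linear index and cut at the exact
    count."""
    if not (0.0 <= target_proportion <= 1.0):
        raise ValueError("target_proportion must lie in [0, 1]")
    mask = statmap.mask
    n_mask = int(mask.sum())
    n_sel = int(np.floor(target_proportion * n_mask + 0.5))

    signed = np.zeros(statmap.shape, dtype=np.int8)
    if n_sel > 0:
        lin = np.flatnonzero(mask.ravel())
        absz = np.abs(statmap.data.ravel()[lin])
        order = np.lexsort((lin, -absz))
        chosen = lin[order[:n_sel]]
        flat = signed.ravel()
        flat[chosen] = np.where(statmap.data.ravel()[chosen] >= 0, 1, -1)
        signed = flat.reshape(statmap.shape)
    return signed


def proportion_threshold(gmap: GroupMap, target_proportion: float) -> ClusterSet:
    """Two-tailed proportion thresholding: keep exactly
    round(target × in-mask count) voxels of largest |z|, recording signs.

    Selected voxels carry no per-cluster significance (``p_cluster`` unset).
    """
    zmap = gmap.zmap
    mask = zmap.mask
    signed = proportion_signed_mask(zmap, target_proportion)

    spec = ThresholdSpec(mode="proportion", target_proportion=target_proportion)
    clusters = [
        _make_cluster(sign, vox, zmap.data) for sign, vox in label_components(signed)
    ]
    return ClusterSet(
        clusters=clusters,
        signed_mask=signed,
        spec=spec,
        source=gmap,
        analysis_mask=mask,
    )


# ---------------------------------------------------------------------- GRF
def grf_cluster_pvalue(
    size: int,
    z_crit: float,
    smoothness: SmoothnessEstimate,
    search_voxels: int,
) -> float:
    """Cluster-extent p for a 3D stationary Gaussian field.

    Expected excursion-set cluster count
    ``E_m = resels · (4·ln2)^{3/2} · (z²−1) · exp(−z²/2) / (2π)²`` with the
    exponential cluster-size approximation
    ``P(n ≥ s) = exp(−β·s^{2/3})``, ``β = (Γ(5/2)/n̄)^{2/3}`` and mean
    cluster size ``n̄ = S·Φ(−z)/E_m``; then ``p = 1 − exp(−E_m·P(n ≥ s))``.
    """
    if size < 0:
        raise ValueError("size must be >= 0")
    if z_crit <= 1.0:
        raise ValueError("GRF cluster formula invalid for z_crit <= 1")
    e_m = (
        smoothness.resels
        * (4.0 * np.log(2.0)) ** 1.5
        * (z_crit**2 - 1.0)
        * np.exp(-(z_crit**2) / 2.0)
        / (2.0 * np.pi) ** 2
    )
    if e_m <= 0:
        raise ValueError("expected cluster count is nonpositive")
    n_bar = search_voxels * stats.norm.sf(z_crit) / e_m
    beta = (gamma_fn(2.5) / n_bar) ** (2.0 / 3.0)
    p_size = np.exp(-beta * float(size) ** (2.0 / 3.0))
    return float(1.0 - np.exp(-e_m * p_size))


def cluster_threshold_grf(
    gmap: GroupMap,
    spec: ThresholdSpec,
    smoothness: SmoothnessEstimate | None = None,
) -> ClusterSet:
    """Two-tailed GRF cluster-extent thresholding.

    Positive and negative excursions (z > z_crit, z < −z_crit) are labeled
    separately; components whose GRF cluster p is >= ``spec.cluster_p`` are
    removed.  Smoothness defaults to the map's own estimate.
    """
    if spec.mode != "cluster_grf":
        raise ValueError("spec.mode must be 'cluster_grf'")
    zmap = gmap.zmap
    mask = zmap.mask
    search = int(mask.sum())

    signed = np.zeros(zmap.shape, dtype=np.int8)
    clusters: list[Cluster] = []
    excursions = {
        sign: mask & (sign * zmap.data > spec.z_crit) for sign in (1, -1)
    }
    if smoothness is None and any(e.any() for e in excursions.values()):
        smoothness = estimate_fwhm(zmap)
    for sign in (1, -1):
        labels, n = ndimage.label(excursions[sign], structure=_STRUCTURE_26)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            p = grf_cluster_pvalue(len(vox), spec.z_crit, smoothness, search)
            if p < spec.cluster_p:
                clusters.append(_make_cluster(sign, vox, zmap.data, p_cluster=p))
                signed[tuple(vox.T)] = sign
    return ClusterSet(
        clusters=clusters,
        signed_mask=signed,
        spec=spec,
        source=gmap,
        analysis_mask=mask,
    )


def find_cluster_peaks(cs: ClusterSet) -> list[tuple[Cluster, tuple[int, int, int], float]]:
    """One peak per cluster (local maxima ignored): the max-|z| voxel, ties
    broken by smallest linear index."""
    return [(c, c.peak_voxel, c.peak_z) for c in cs.clusters]


# ------------------------------------------------------------ Table scaling
def scaled_full_sample_threshold(
    anchor_z: float, anchor_n: float, target_n: float
) -> float:
    """Scale a full-sample cluster-forming z threshold to another sample size
    so the threshold's power is equated: z = anchor_z·√(target_n/anchor_n),
    rounded half-up to 2 decimals."""
    if anchor_z <= 0 or anchor_n <= 0 or target_n <= 0:
        raise ValueError("all inputs must be positive")
    z = anchor_z * np.sqrt(target_n / anchor_n)
    return float(Decimal(repr(float(z))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
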