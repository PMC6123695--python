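"""Replicability statistics between paired maps.

Three map-level metrics — Pearson correlation of unthresholded maps,
sign-sensitive Jaccard overlap of thresholded maps, and the two-direction
averaged peak hit rate — plus the pooled peak-height logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .groupmodel import common_mask
from .statmap import GroupMap
from .thresholding import ClusterSet

__all__ = [
    "ReplicabilityRecord",
    "pearson_similarity",
    "jaccard_signed",
    "jaccard_signed_masks",
    "peak_hit_rate",
    "classify_peaks",
    "LogisticFit",
    "peak_height_logistic",
]


@dataclass(frozen=True)
class ReplicabilityRecord:
    task: str
    sort_index: int
    k: int
    metric: str  # pearson | jaccard_voxel | jaccard_cluster | peak_hit
    threshold_label: str  # none | liberal | conservative
    value: float


def pearson_similarity(p: GroupMap, q: GroupMap) -> float:
    """Pearson correlation of in-common-mask values of the two z maps."""
    cm = common_mask(p.zmap, q.zmap)
    x = p.zmap.data[cm]
    y = q.zmap.data[cm]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance inside common mask")
    return float(np.corrcoef(x, y)[0, 1])


def jaccard_signed_masks(a: np.ndarray, b: np.ndarray) -> float:
    """Sign-sensitive Jaccard of two signed suprathreshold masks.

    Intersection requires sign agreement; a sign-discordant voxel still
    counts once in the union.  Empty union scores 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("grids differ")
    inter = int(np.count_nonzero((a == b) & (a != 0)))
    union = int(np.count_nonzero((a != 0) | (b != 0)))
    return inter / union if union else 0.0


def jaccard_signed(a: ClusterSet, b: ClusterSet) -> float:
    return jaccard_signed_masks(a.signed_mask, b.signed_mask)


def classify_peaks(a: ClusterSet, other_signed_mask: np.ndarray) -> list[tuple[float, int]]:
    """For each cluster peak of ``a``: (peak z, replicated flag).

    A peak counts as replicated only if its voxel is suprathreshold with the
    same sign in the other mask.
    """
    out = []
    for c in a.clusters:
        hit = int(other_signed_mask[c.peak_voxel] == c.sign)
        out.append((c.peak_z, hit))
    return out


def peak_hit_rate(a: ClusterSet, b: ClusterSet) -> float:
    """Mean over both directions of the fraction of one map's cluster peaks
    that fall inside the other map's same-sign suprathreshold mask.

    A direction with zero peaks is excluded from the mean; if both maps are
    peakless the rate is 0 (an empty map is a failed replication, not a
    skipped one).
    """
    if a.signed_mask.shape != b.signed_mask.shape:
        raise ValueError("grids differ")
    rates = []
    for src, dst in ((a, b), (b, a)):
        hits = classify_peaks(src, dst.signed_mask)
        if hits:
            rates.append(float(np.mean([h for _, h in hits])))
    if not rates:
        return 0.0
    return float(np.mean(rates))


# ------------------------------------------------------- peak-height model
@dataclass
class LogisticFit:
    intercept: float
    slope: float
    separation: bool
    n_peaks: int

    def predict(self, z: np.ndarray) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(z, dtype=float))


def peak_height_logistic(peaks: Sequence[tuple[float, int]]) -> LogisticFit:
    """Maximum-likelihood logistic regression of replication on peak z,
    pooled over tasks within one sample size.

    Complete (or quasi-complete) separation is flagged and handled by an
    L2-penalized fallback fit.
    """
    peaks = list(peaks)
    zs = np.asarray([p[0] for p in peaks], dtype=float)
    ys = np.asarray([p[1] for p in peaks], dtype=int)
    if len(np.unique(zs)) < 2:
        raise ValueError("need >= 2 distinct peak z values")

    X = sm.add_constant(zs)
    one_class = len(np.unique(ys)) < 2
    if not one_class:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(ys, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
                return LogisticFit(
                    intercept=float(res.params[0]),
                    slope=float(res.params[1]),
                    separation=False,
                    n_peaks=len(peaks),
                )
        except Exception:
            pass

    # separation (or single-class outcome): penalized fallback
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0, solver="lbfgs")
    if one_class:
        # degenerate pool: constant predicted probability at the observed class
        big = 30.0 if ys[0] == 1 else -30.0
        return LogisticFit(intercept=big, slope=0.0, separation=True, n_peaks=len(peaks))
    clf.fit(zs.reshape(-1, 1), ys)
    warnings.warn("separation detected in peak-height logistic fit; "
                  "penalized-likelihood coefficients reported", RuntimeWarning,
                  stacklevel=2)
    return LogisticFit(
        intercept=float(clf.intercept_[0]),
        slope=float(clf.coef_[0, 0]),
        separation=True,
        n_peaks=len(peaks),
    )
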