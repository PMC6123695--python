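"""Synthetic multi-subject, multi-run volumetric datasets.

Generates data with the statistical structure the downstream analysis
assumes: a shared smooth truth signal, per-subject smooth deviation fields
(between-individual variability), per-run smooth noise fields
(within-individual variability), per-run motion summaries, and per-run
event designs convolved with a double-gamma HRF.

All randomness flows through one ``numpy.random.Generator`` seeded from the
dataset spec, so identical spec + seed yields a bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import gammaln

from .statmap import StatMap

__all__ = [
    "Blob",
    "TruthSpec",
    "SyntheticDatasetSpec",
    "SubjectRunMap",
    "SyntheticDataset",
    "ellipsoid_mask",
    "generate_truth_map",
    "smooth_random_field",
    "double_gamma_hrf",
    "generate_design_matrix",
    "generate_subject_maps",
    "write_dataset",
    "load_dataset",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


# --------------------------------------------------------------------- specs
@dataclass(frozen=True)
class Blob:
    """One Gaussian activation focus: peak-normalized kernel times amplitude."""

    center: tuple[int, int, int]
    fwhm: float
    amplitude: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"blob FWHM must be > 0, got {self.fwhm}")
        if self.sign not in (-1, 1):
            raise ValueError(f"blob sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class TruthSpec:
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    mask_axes: tuple[float, float, float] = (0.92, 0.92, 0.92)
    blobs: tuple[Blob, ...] = ()

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(not (0 < a <= 1) for a in self.mask_axes):
            raise ValueError("mask_axes fractions must lie in (0, 1]")
        for blob in self.blobs:
            if any(
                not (0 <= c < s) for c, s in zip(blob.center, self.grid_shape)
            ):
                raise ValueError(
                    f"blob center {blob.center} outside grid {self.grid_shape}"
                )


@dataclass(frozen=True)
class DesignSpec:
    """Event design parameters for one run family."""

    n_timepoints: int = 120
    n_events: int = 2
    events_per_regressor: int = 8
    onset_jitter_sd: float = 1.5
    tr: float = 1.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if self.n_events < 2:
            raise ValueError("need >= 2 event regressors")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    truth: TruthSpec
    n_subjects: int
    n_runs: int = 2
    sigma_between: float = 0.5
    sigma_within: float = 1.0
    noise_fwhm: float = 3.0
    motion_mean: float = 0.15
    motion_sd: float = 0.05
    motion_noise_coupling: float = 0.0
    design: DesignSpec = field(default_factory=DesignSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4 (group stats undefined below)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for name in ("sigma_between", "sigma_within", "motion_mean", "motion_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SubjectRunMap:
    subject_id: int
    run_id: int
    map: StatMap
    motion_rms: float
    design_matrix: np.ndarray
    contrast_vector: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.design_matrix, dtype=np.float64)
        c = np.asarray(self.contrast_vector, dtype=np.float64)
        if c.shape[0] != X.shape[1]:
            raise ValueError("contrast_vector length must equal design columns")
        self.design_matrix = X
        self.contrast_vector = c


@dataclass
class SyntheticDataset:
    spec: SyntheticDatasetSpec
    truth: StatMap
    runs: list[SubjectRunMap]

    def subject_runs(self, subject_id: int) -> list[SubjectRunMap]:
        return [r for r in self.runs if r.subject_id == subject_id]

    @property
    def subject_ids(self) -> list[int]:
        return sorted({r.subject_id for r in self.runs})


# ----------------------------------------------------------------- truth map
def ellipsoid_mask(
    grid_shape: Sequence[int], axis_fractions: Sequence[float]
) -> np.ndarray:
    """Boolean ellipsoid mask centred on the grid with the given semi-axis
    fractions of each half-extent."""
    shape = tuple(int(s) for s in grid_shape)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [f * s / 2.0 for f, s in zip(axis_fractions, shape)]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def generate_truth_map(spec: TruthSpec) -> StatMap:
    """Sum of peak-normalized Gaussian blobs on the grid, zero outside mask."""
    mask = ellipsoid_mask(spec.grid_shape, spec.mask_axes)
    data = np.zeros(spec.grid_shape, dtype=np.float64)
    grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
    for blob in spec.blobs:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, blob.center))
        kernel = np.exp(-4.0 * np.log(2.0) * d2 / blob.fwhm**2)
        data = data + blob.sign * blob.amplitude * kernel
    data[~mask] = 0.0
    return StatMap(data=data, mask=mask)


def smooth_random_field(
    rng: np.random.Generator,
    shape: Sequence[int],
    fwhm: float,
    mask: np.ndarray,
) -> np.ndarray:
    """White noise smoothed to `fwhm` (voxels) then rescaled to unit in-mask SD.

    Rescaling decouples field smoothness from field variance.
    """
    noise = rng.standard_normal(tuple(shape))
    if fwhm > 0:
        noise = gaussian_filter(noise, sigma=fwhm * FWHM_TO_SIGMA)
    sd = noise[mask].std()
    if sd == 0:
        raise ValueError("degenerate random field (zero in-mask SD)")
    return noise / sd


# -------------------------------------------------------------------- design
def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Peak at 6 s, undershoot at 16 s with 1/6 relative amplitude.
    """
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
        return np.exp(
            a * np.log(b) + (a - 1) * np.log(x) - b * x - gammaln(a)
        )

    out[pos] = gpdf(tp, 6.0, 1.0) - gpdf(tp, 16.0, 1.0) / 6.0
    return out


def generate_design_matrix(
    n_timepoints: int,
    event_onsets: Sequence[Sequence[float]],
    rng: np.random.Generator | None = None,
    onset_jitter_sd: float = 0.0,
    tr: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a convolved event design matrix plus intercept.

    Parameters
    ----------
    event_onsets:
        One onset list (in scan units) per event regressor; >= 2 required.
    onset_jitter_sd:
        SD of Gaussian onset jitter; zero keeps the schedule fixed, which in
        turn keeps the matrix identical across runs.

    Returns ``(X, c)`` where ``X`` has one convolved column per event type
    followed by an intercept, and ``c`` contrasts the first two event columns.
    """
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    if len(event_onsets) < 2:
        raise ValueError("need >= 2 event regressors")

    times = np.arange(n_timepoints) * tr
    hrf = double_gamma_hrf(np.arange(0, 32.0, tr))
    cols = []
    for onsets in event_onsets:
        onsets = np.asarray(onsets, dtype=np.float64)
        if onset_jitter_sd > 0:
            if rng is None:
                raise ValueError("rng required when onset_jitter_sd > 0")
            onsets = onsets + rng.normal(0.0, onset_jitter_sd, size=onsets.shape)
        if np.any(onsets < 0) or np.any(onsets >= n_timepoints * tr):
            raise ValueError(
                "event onsets fall outside the [0, n_timepoints*tr) window"
            )
        stick = np.zeros(n_timepoints)
        idx = np.floor(onsets / tr).astype(int)
        np.add.at(stick, idx, 1.0)
        cols.append(np.convolve(stick, hrf)[:n_timepoints])
    X = np.column_stack(cols + [np.ones(n_timepoints)])
    c = np.zeros(X.shape[1])
    c[0], c[1] = 1.0, -1.0
    return X, c


def _default_onsets(design: DesignSpec) -> list[np.ndarray]:
    """Interleaved evenly spaced onsets for each event type, with headroom
    for jitter at both window edges."""
    n_ev = design.n_events
    per = design.events_per_regressor
    total = n_ev * per
    lo = 4.0 * design.onset_jitter_sd + 1.0
    hi = (design.n_timepoints - 1) * design.tr - 4.0 * design.onset_jitter_sd - 1.0
    if hi <= lo:
        raise ValueError("time window too short for the requested schedule")
    slots = np.linspace(lo, hi, total)
    return [slots[i::n_ev] for i in range(n_ev)]


# ------------------------------------------------------------------- dataset
def generate_subject_maps(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Simulate every subject/run contrast map of the dataset.

    run map = truth + subject_deviation(sigma_between)
                    + run_noise(sigma_within), all fields smoothed to
    ``noise_fwhm`` and rescaled to unit in-mask SD before scaling.
    """
    rng = np.random.default_rng(spec.seed)
    truth = generate_truth_map(spec.truth)
    mask = truth.mask
    shape = truth.shape
    base_onsets = _default_onsets(spec.design)

    runs: list[SubjectRunMap] = []
    for subject in range(spec.n_subjects):
        if spec.sigma_between > 0:
            deviation = spec.sigma_between * smooth_random_field(
                rng, shape, spec.noise_fwhm, mask
            )
        else:
            deviation = 0.0
        for run in range(spec.n_runs):
            motion = max(0.0, rng.normal(spec.motion_mean, spec.motion_sd))
            sigma_run = spec.sigma_within
            if spec.motion_noise_coupling != 0.0 and spec.motion_sd > 0:
                sigma_run *= max(
                    0.0,
                    1.0
                    + spec.motion_noise_coupling
                    * (motion - spec.motion_mean)
                    / spec.motion_sd,
                )
            if sigma_run > 0:
                noise = sigma_run * smooth_random_field(
                    rng, shape, spec.noise_fwhm, mask
                )
            else:
                noise = 0.0
            data = truth.data + deviation + noise
            X, c = generate_design_matrix(
                spec.design.n_timepoints,
                base_onsets,
                rng=rng,
                onset_jitter_sd=spec.design.onset_jitter_sd,
                tr=spec.design.tr,
            )
            runs.append(
                SubjectRunMap(
                    subject_id=subject,
                    run_id=run,
                    map=StatMap(data=data, mask=mask),
                    motion_rms=motion,
                    design_matrix=X,
                    contrast_vector=c,
                )
            )
    return SyntheticDataset(spec=spec, truth=truth, runs=runs)


# ----------------------------------------------------------------------- I/O
def _spec_to_jsonable(spec: SyntheticDatasetSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["truth"]["blobs"] = [dataclasses.asdict(b) for b in spec.truth.blobs]
    return d


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict:
    """Write NIfTI run maps, the mask, sidecar CSV, design matrices and a
    JSON manifest.  Returns the manifest dict."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")

    mask_file = "mask.nii.gz"
    dataset.truth.save(directory / "truth.nii.gz")
    StatMap(
        data=dataset.truth.mask.astype(float), mask=np.ones_like(dataset.truth.mask)
    ).save(directory / mask_file)

    map_files, design_files, sidecar_rows = [], [], []
    for r in dataset.runs:
        stem = f"sub-{r.subject_id:03d}_run-{r.run_id:02d}"
        map_name = stem + ".nii.gz"
        design_name = stem + "_design.txt"
        r.map.save(directory / map_name)
        np.savetxt(directory / design_name, r.design_matrix)
        map_files.append(map_name)
        design_files.append(design_name)
        sidecar_rows.append((r.subject_id, r.run_id, r.motion_rms))

    sidecar = directory / "runs.csv"
    with open(sidecar, "w") as fh:
        fh.write("subject_id,run_id,motion_rms\n")
        for sub, run, mot in sidecar_rows:
            fh.write(f"{sub},{run},{mot:.10g}\n")

    manifest = {
        "mask": mask_file,
        "truth": "truth.nii.gz",
        "maps": map_files,
        "designs": design_files,
        "sidecar": "runs.csv",
        "contrast_vector": dataset.runs[0].contrast_vector.tolist(),
        "spec": _spec_to_jsonable(dataset.spec),
        "seed": dataset.spec.seed,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Round-trip loader for :func:`write_dataset` output."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    sd = manifest["spec"]
    truth_d = dict(sd["truth"])
    truth_d["grid_shape"] = tuple(truth_d["grid_shape"])
    truth_d["mask_axes"] = tuple(truth_d["mask_axes"])
    truth_d["blobs"] = tuple(
        Blob(center=tuple(b["center"]), fwhm=b["fwhm"],
             amplitude=b["amplitude"], sign=b["sign"])
        for b in truth_d["blobs"]
    )
    sd = dict(sd)
    sd["truth"] = TruthSpec(**truth_d)
    sd["design"] = DesignSpec(**sd["design"])
    spec = SyntheticDatasetSpec(**sd)

    mask = StatMap.load(directory / manifest["mask"]).data > 0
    truth = StatMap.load(directory / manifest["truth"], mask=mask)
    contrast = np.asarray(manifest["contrast_vector"], dtype=np.float64)

    motion: dict[tuple[int, int], float] = {}
    with open(directory / manifest["sidecar"]) as fh:
        next(fh)
        for line in fh:
            sub, run, mot = line.strip().split(",")
            motion[(int(sub), int(run))] = float(mot)

    runs = []
    for map_name, design_name in zip(manifest["maps"], manifest["designs"]):
        stem = Path(map_name).name.split(".")[0]
        sub = int(stem.split("_")[0].split("-")[1])
        run = int(stem.split("_")[1].split("-")[1])
        runs.append(
            SubjectRunMap(
                subject_id=sub,
                run_id=run,
                map=StatMap.load(directory / map_name, mask=mask),
                motion_rms=motion[(sub, run)],
                design_matrix=np.loadtxt(directory / design_name),
                contrast_vector=contrast,
            )
        )
    return SyntheticDataset(spec=spec, truth=truth, runs=runs)
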