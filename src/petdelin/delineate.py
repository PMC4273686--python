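"""Threshold-family PET delineation methods and the CT calibration regression.

Five methods are implemented, all operating on a bounding VOI that encloses
exactly one object:

* ``T40`` / ``T50`` — fixed fraction of SUVmax inside the VOI;
* ``AT40`` / ``AT50`` — adaptive: ``T = f * (SUVmax - BG) + BG`` with the mean
  background uptake BG measured in a spherical background ROI;
* ``CT`` — contrast thresholding, ``T = a * mSUV70 + b * BG``, with (a, b)
  calibrated by regressing volume-matched optimal thresholds from phantom
  acquisitions with known ground truth.

Thresholds are inclusive (voxels with value >= T are kept) and no
connected-component filtering is applied by default, so low thresholds may
sweep in background — which is exactly the failure mode the benchmark
measures.  FLAB (fuzzy locally adaptive Bayesian segmentation) is registered
as an unavailable external method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import BinaryMask, BoundingBox, VoxelVolume

__all__ = [
    "VoiStats",
    "BackgroundStats",
    "ThresholdRule",
    "CtCalibration",
    "CalibrationSample",
    "measure_background",
    "apply_threshold",
    "voi_stats",
    "delineate_fixed",
    "delineate_adaptive",
    "delineate_ct",
    "calibrate_ct",
    "flab_stub",
    "delineate",
    "METHOD_REGISTRY",
    "available_methods",
]


@dataclass(frozen=True)
class VoiStats:
    """SUVmax and mSUV70 (mean over voxels >= 0.7 SUVmax) inside a VOI."""

    suv_max: float
    m_suv70: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.m_suv70 < 0:
            raise ValueError("mSUV70 must be non-negative")
        if self.m_suv70 > self.suv_max + 1e-12:
            raise ValueError("mSUV70 cannot exceed SUVmax")


@dataclass(frozen=True)
class BackgroundStats:
    """Mean uptake in a spherical background ROI (default 20 voxels diameter)."""

    bg_mean: float
    roi_center: tuple[int, int, int]
    roi_diameter_voxels: int = 20

    def __post_init__(self) -> None:
        if self.bg_mean < 0:
            raise ValueError("background mean must be non-negative")


@dataclass(frozen=True)
class ThresholdRule:
    method: str
    threshold_value: float
    parameters: dict

    def __post_init__(self) -> None:
        if self.threshold_value < 0:
            raise ValueError("threshold must be non-negative")


@dataclass(frozen=True)
class CtCalibration:
    """Fitted contrast-threshold regression ``T = a*mSUV70 + b*BG`` (no intercept)."""

    a: float
    b: float
    fit_rmse: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("calibration needs at least two samples")

    def to_json(self) -> str:
        return json.dumps({"a": self.a, "b": self.b, "fit_rmse": self.fit_rmse,
                           "n_samples": self.n_samples})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CtCalibration":
        d = json.loads(Path(path).read_text())
        return cls(d["a"], d["b"], d["fit_rmse"], d["n_samples"])


def measure_background(image: VoxelVolume, center: Sequence[int],
                       diameter_voxels: int = 20) -> BackgroundStats:
    """Mean value in a spherical ROI of ``diameter_voxels`` (index units).

    A voxel belongs to the ROI iff its index lies within ``diameter/2`` of the
    centre index (inclusive).  The ROI must fit inside the image.
    """
    center = tuple(int(c) for c in center)
    r = diameter_voxels / 2.0
    shape = image.values.shape
    for k in range(3):
        if center[k] - r < -0.5 or center[k] + r > shape[k] - 0.5:
            raise ValueError(
                f"background ROI (centre {center}, diameter {diameter_voxels} voxels) "
                f"is clipped by the image bounds {shape}"
            )
    lo = [int(np.floor(center[k] - r)) for k in range(3)]
    hi = [int(np.ceil(center[k] + r)) + 1 for k in range(3)]
    ii, jj, kk = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    inside = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2 <= r**2
    sub = image.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return BackgroundStats(float(sub[inside].mean()), center, diameter_voxels)


def voi_stats(image: VoxelVolume, voi: BoundingBox) -> VoiStats:
    sub = image.values[voi.slices]
    if sub.size == 0:
        raise ValueError("VOI is empty")
    suv_max = float(sub.max())
    sel = sub >= 0.7 * suv_max
    return VoiStats(suv_max, float(sub[sel].mean()), int(sub.size))


def apply_threshold(image: VoxelVolume, voi: BoundingBox, threshold: float) -> BinaryMask:
    """Inclusive threshold inside the VOI; no connectivity filtering."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    sub = image.values[voi.slices]
    if sub.size == 0:
        raise ValueError("VOI is empty")
    out = np.zeros(image.values.shape, dtype=bool)
    out[voi.slices] = sub >= threshold
    return BinaryMask(out, image.grid, image.origin.copy())


def _largest_component(mask: BinaryMask) -> BinaryMask:
    lab, n = ndimage.label(mask.values)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return BinaryMask(lab == keep, mask.grid, mask.origin.copy())


def delineate_fixed(image: VoxelVolume, voi: BoundingBox, fraction: float,
                    largest_component: bool = False) -> tuple[BinaryMask, ThresholdRule]:
    """Fixed-fraction thresholding: ``T = fraction * SUVmax`` (T40/T50)."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    stats = voi_stats(image, voi)
    t = fraction * stats.suv_max
    mask = apply_threshold(image, voi, t)
    if largest_component:
        mask = _largest_component(mask)
    rule = ThresholdRule(f"T{int(round(fraction * 100))}", t, {"fraction": fraction})
    return mask, rule


def delineate_adaptive(image: VoxelVolume, voi: BoundingBox, bg: BackgroundStats,
                       fraction: float,
                       largest_component: bool = False) -> tuple[BinaryMask, ThresholdRule]:
    """Background-adaptive thresholding: ``T = fraction*(SUVmax - BG) + BG``."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    stats = voi_stats(image, voi)
    name = f"AT{int(round(fraction * 100))}"
    if stats.suv_max <= bg.bg_mean:
        warnings.warn(
            f"{name}: SUVmax ({stats.suv_max:.3g}) does not exceed background "
            f"({bg.bg_mean:.3g}); returning an empty mask", stacklevel=2)
        empty = BinaryMask(np.zeros(image.values.shape, bool), image.grid,
                           image.origin.copy())
        return empty, ThresholdRule(name, stats.suv_max, {"fraction": fraction,
                                                          "bg_mean": bg.bg_mean})
    t = fraction * (stats.suv_max - bg.bg_mean) + bg.bg_mean
    mask = apply_threshold(image, voi, t)
    if largest_component:
        mask = _largest_component(mask)
    return mask, ThresholdRule(name, t, {"fraction": fraction, "bg_mean": bg.bg_mean})


def delineate_ct(image: VoxelVolume, voi: BoundingBox, bg: BackgroundStats,
                 calib: CtCalibration,
                 largest_component: bool = False) -> tuple[BinaryMask, ThresholdRule]:
    """Contrast thresholding with a calibrated regression threshold."""
    stats = voi_stats(image, voi)
    t = calib.a * stats.m_suv70 + calib.b * bg.bg_mean
    params = {"a": calib.a, "b": calib.b, "m_suv70": stats.m_suv70,
              "bg_mean": bg.bg_mean}
    if t > stats.suv_max:
        warnings.warn(
            f"CT: calibrated threshold {t:.3g} exceeds SUVmax {stats.suv_max:.3g}; "
            "returning an empty mask", stacklevel=2)
        empty = BinaryMask(np.zeros(image.values.shape, bool), image.grid,
                           image.origin.copy())
        return empty, ThresholdRule("CT", max(t, 0.0), params)
    mask = apply_threshold(image, voi, max(t, 0.0))
    if largest_component:
        mask = _largest_component(mask)
    return mask, ThresholdRule("CT", max(t, 0.0), params)


@dataclass(frozen=True)
class CalibrationSample:
    """One phantom object with known ground truth, for CT calibration."""

    image: VoxelVolume
    voi: BoundingBox
    bg: BackgroundStats
    gt_mask: BinaryMask


def optimal_threshold(image: VoxelVolume, voi: BoundingBox, bg: BackgroundStats,
                      gt_mask: BinaryMask, n_grid: int = 200) -> float:
    """Volume-matched optimal threshold for one object.

    Searches ``n_grid`` evenly spaced thresholds between BG and SUVmax and
    returns the one whose thresholded volume is closest to the ground-truth
    volume; ties resolve to the lower threshold.
    """
    stats = voi_stats(image, voi)
    lo = min(bg.bg_mean, stats.suv_max)
    grid = np.linspace(lo, stats.suv_max, n_grid)
    sub = np.sort(image.values[voi.slices].ravel())
    # voxels >= t, via searchsorted on the sorted VOI values
    counts = sub.size - np.searchsorted(sub, grid, side="left")
    target = gt_mask.voxel_count
    return float(grid[int(np.argmin(np.abs(counts - target)))])


def calibrate_ct(samples: Sequence[CalibrationSample], allow_a_only: bool = False,
                 n_grid: int = 200) -> CtCalibration:
    """Fit (a, b) of the CT regression from phantom objects with known truth.

    For each sample the optimal threshold is found by volume matching against
    the ground-truth mask; (a, b) then solve the intercept-free least squares
    ``T_opt ~ a*mSUV70 + b*BG``.  With all-zero backgrounds the design is rank
    deficient: pass ``allow_a_only=True`` to fit the a-only model (b = 0).
    """
    if len(samples) < 2:
        raise ValueError("need at least two calibration samples")
    t_opt, design = [], []
    for s in samples:
        if not s.gt_mask.same_space(s.image):
            raise ValueError("ground-truth mask and image are on different grids")
        stats = voi_stats(s.image, s.voi)
        t_opt.append(optimal_threshold(s.image, s.voi, s.bg, s.gt_mask, n_grid))
        design.append([stats.m_suv70, s.bg.bg_mean])
    y = np.asarray(t_opt)
    X = np.asarray(design)
    rank = np.linalg.matrix_rank(X, tol=1e-10 * max(1.0, float(np.abs(X).max())))
    if rank < 2:
        if allow_a_only and np.any(X[:, 0] != 0):
            a = float(np.linalg.lstsq(X[:, :1], y, rcond=None)[0][0])
            resid = y - a * X[:, 0]
            return CtCalibration(a, 0.0, float(np.sqrt(np.mean(resid**2))), len(samples))
        raise ValueError(
            "calibration design is rank deficient (identical objects or all-zero "
            "background); cannot identify both a and b")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return CtCalibration(float(coef[0]), float(coef[1]),
                         float(np.sqrt(np.mean(resid**2))), len(samples))


def flab_stub(image: VoxelVolume = None, voi: BoundingBox = None, **kwargs):
    """Extension point for FLAB; not bundled with this package."""
    raise NotImplementedError(
        "FLAB (fuzzy locally adaptive Bayesian segmentation, Hatt et al. 2009, "
        "IEEE Trans Med Imaging 28(6):881-893) is an external method whose "
        "implementation is distributed by its authors; register your own "
        "implementation under the 'FLAB' key to enable it."
    )


#: method registry; ``available`` marks whether an implementation ships here.
METHOD_REGISTRY: dict[str, dict] = {
    "T40": {"available": True, "needs_background": False, "fraction": 0.4},
    "T50": {"available": True, "needs_background": False, "fraction": 0.5},
    "AT40": {"available": True, "needs_background": True, "fraction": 0.4},
    "AT50": {"available": True, "needs_background": True, "fraction": 0.5},
    "CT": {"available": True, "needs_background": True, "needs_calibration": True},
    "FLAB": {"available": False, "needs_background": False},
}


def available_methods() -> list[str]:
    return [m for m, info in METHOD_REGISTRY.items() if info["available"]]


def delineate(method: str, image: VoxelVolume, voi: BoundingBox,
              bg: BackgroundStats | None = None,
              calib: CtCalibration | None = None,
              largest_component: bool = False) -> tuple[BinaryMask, ThresholdRule]:
    """Dispatch a delineation by registry key."""
    if method not in METHOD_REGISTRY:
        raise KeyError(f"unknown delineation method {method!r}; have {sorted(METHOD_REGISTRY)}")
    if method == "FLAB":
        flab_stub(image, voi)
    info = METHOD_REGISTRY[method]
    if info["needs_background"] and bg is None:
        raise ValueError(f"{method} requires background statistics")
    if method in ("T40", "T50"):
        return delineate_fixed(image, voi, info["fraction"], largest_component)
    if method in ("AT40", "AT50"):
        return delineate_adaptive(image, voi, bg, info["fraction"], largest_component)
    if method == "CT":
        if calib is None:
            raise ValueError("CT requires a fitted CtCalibration")
        return delineate_ct(image, voi, bg, calib, largest_component)
    raise AssertionError("unreachable")
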