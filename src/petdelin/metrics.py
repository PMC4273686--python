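"""Validation metrics and summaries: SI, %VE, CV, necrotic-core scoring.

SI is the Dice overlap ``2|GT n PET| / (|GT| + |PET|)`` (1 is perfect),
%VE the signed volume error ``(Vol_PET - Vol_true)/Vol_true * 100`` (0 is
perfect, -100 an empty delineation), and CV the across-condition coefficient
of variation ``SD/mean`` of delineated volumes (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask

__all__ = [
    "ValidationRecord",
    "similarity_index",
    "percent_volume_error",
    "coefficient_of_variation",
    "ci95_halfwidth",
    "size_group",
    "evaluate_necrotic",
    "records_to_frame",
    "summarize",
    "quartile_table",
]


@dataclass
class ValidationRecord:
    """Per-object validation scores plus free-form condition metadata."""

    si: float
    pct_ve: float
    vol_pet_ml: float
    vol_true_ml: float
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.si <= 1.0 + 1e-12):
            raise ValueError(f"SI must lie in [0, 1], got {self.si}")
        if self.pct_ve < -100.0 - 1e-9:
            raise ValueError(f"%VE cannot be below -100, got {self.pct_ve}")

    def to_row(self) -> dict:
        row = {"si": self.si, "pct_ve": self.pct_ve,
               "vol_pet_ml": self.vol_pet_ml, "vol_true_ml": self.vol_true_ml}
        row.update(self.condition)
        return row


def similarity_index(gt: BinaryMask, pet: BinaryMask) -> float:
    """Dice overlap between ground truth and delineation; two empty masks -> 1."""
    if not gt.same_space(pet):
        raise ValueError("masks are on different grids")
    n_gt = gt.voxel_count
    n_pet = pet.voxel_count
    if n_gt == 0 and n_pet == 0:
        return 1.0  # perfect agreement on absence
    inter = int(np.count_nonzero(gt.values & pet.values))
    return 2.0 * inter / (n_gt + n_pet)


def percent_volume_error(vol_pet: float, vol_true: float) -> float:
    """Signed percentage volume error; requires a positive true volume."""
    if vol_true <= 0:
        raise ValueError(f"true volume must be positive, got {vol_true}")
    return (vol_pet - vol_true) / vol_true * 100.0


def coefficient_of_variation(volumes: Sequence[float]) -> float:
    """Sample SD over mean of a series of delineated volumes."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two volumes")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean volume ({mean})")
    return float(v.std(ddof=1)) / mean


def ci95_halfwidth(sd: float) -> float:
    """Normal-approximation 95% half-width, 1.96 x SD."""
    return 1.96 * sd


def size_group(diameter_mm: float) -> str:
    """Paper-style size stratification: <= 13 mm is 'small', larger is 'large'."""
    return "small" if diameter_mm <= 13.0 else "large"


def evaluate_necrotic(
    delineation: BinaryMask,
    shell_gt: BinaryMask,
    core_gt: BinaryMask,
    condition: Mapping | None = None,
) -> tuple[ValidationRecord, ValidationRecord]:
    """Score a delineation of a necrotic-core lesion on shell and core.

    The shell record compares the delineation directly with the hot outer
    layer.  The core estimate is the *hole* of the delineation — morphological
    fill of the delineation minus the delineation itself — compared against
    the cold-core truth, so a solid (hole-free) delineation scores core SI 0.
    """
    if not shell_gt.same_space(core_gt) or not shell_gt.same_space(delineation):
        raise ValueError("masks are on different grids")
    if np.any(shell_gt.values & core_gt.values):
        raise ValueError("shell and core ground truth must be disjoint")
    cond = dict(condition or {})
    vox_ml = delineation.grid.voxel_volume_ml

    shell_rec = ValidationRecord(
        si=similarity_index(shell_gt, delineation),
        pct_ve=percent_volume_error(delineation.voxel_count * vox_ml,
                                    shell_gt.voxel_count * vox_ml),
        vol_pet_ml=delineation.voxel_count * vox_ml,
        vol_true_ml=shell_gt.voxel_count * vox_ml,
        condition={**cond, "target": "shell"},
    )
    filled = ndimage.binary_fill_holes(delineation.values)
    core_est = BinaryMask(filled & ~delineation.values, delineation.grid,
                          delineation.origin.copy())
    core_rec = ValidationRecord(
        si=similarity_index(core_gt, core_est),
        pct_ve=percent_volume_error(core_est.voxel_count * vox_ml,
                                    core_gt.voxel_count * vox_ml),
        vol_pet_ml=core_est.voxel_count * vox_ml,
        vol_true_ml=core_gt.voxel_count * vox_ml,
        condition={**cond, "target": "core"},
    )
    return shell_rec, core_rec


def records_to_frame(records: Iterable[ValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def summarize(records: Iterable[ValidationRecord] | pd.DataFrame,
              group_by: Sequence[str] | str,
              value: str = "si") -> pd.DataFrame:
    """Per-group mean, SD (n-1), CV, n and 1.96*SD half-width of one metric.

    ``records`` may be ValidationRecords or an already-tidied DataFrame;
    ``group_by`` names condition columns.  Raises on unknown columns.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if isinstance(group_by, str):
        group_by = [group_by]
    for col in list(group_by) + [value]:
        if col not in frame.columns:
            raise KeyError(f"unknown grouping/value column {col!r}")
    if frame.empty:
        raise ValueError("no records to summarize")

    def agg(g: pd.Series) -> pd.Series:
        mean = g.mean()
        sd = g.std(ddof=1) if len(g) > 1 else 0.0
        return pd.Series({
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean > 0 else np.nan,
            "n": len(g),
            "ci95_halfwidth": ci95_halfwidth(sd),
        })

    out = frame.groupby(list(group_by))[value].apply(agg).unstack()
    out["n"] = out["n"].astype(int)
    return out


def quartile_table(records: Iterable[ValidationRecord] | pd.DataFrame,
                   group_by: Sequence[str] | str,
                   value: str = "si") -> pd.DataFrame:
    """Boxplot-style data product: quartiles and mean per group."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if isinstance(group_by, str):
        group_by = [group_by]
    for col in list(group_by) + [value]:
        if col not in frame.columns:
            raise KeyError(f"unknown grouping/value column {col!r}")
    g = frame.groupby(list(group_by))[value]
    out = pd.DataFrame({
        "q1": g.quantile(0.25),
        "median": g.quantile(0.5),
        "q3": g.quantile(0.75),
        "mean": g.mean(),
        "n": g.size(),
    })
    return out
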