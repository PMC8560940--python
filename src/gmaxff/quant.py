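"""Fat-fraction quantification of a labelled muscle between bone landmarks.

The voxelwise fat fraction is FF = F / (W + F), the ratio of the fat image to
the sum of the water and fat images.  Per-muscle metrics are computed over the
muscle *bulk* — the axial slab from the slice containing the lesser-trochanter
tip (LT) to the slice at the level of the anterior superior iliac spine
(ASIS), both boundary slices included.  The bulk restriction standardises the
measurement and keeps tendinous regions out of the average.

Reported quantities per muscle:

* ``mean_ff``       — arithmetic mean of FF over defined bulk voxels
* ``volume_ml``     — labelled bulk voxel count x voxel volume
* ``lean_volume_ml``— volume x (1 - mean FF), a contractile-tissue proxy

Volumes are additionally normalised by lean body mass (Boer formula) at the
subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

from .io import ImageGeometry, DixonStudy, LabelMap, LandmarkSet

__all__ = [
    "EmptyMuscleError",
    "FFMap",
    "MuscleMetrics",
    "Anthropometrics",
    "SubjectRecord",
    "compute_ff_map",
    "extract_bulk",
    "muscle_metrics",
    "boer_lbm",
    "assign_activity_group",
    "ohs_grade",
    "summarize_subject",
]

OHS_GRADE_NAMES = {1: "Severe", 2: "Moderate", 3: "Mild", 4: "Satisfactory"}


class EmptyMuscleError(ValueError):
    """No labelled (or no defined) voxel available for a requested muscle."""


@dataclass(frozen=True)
class FFMap:
    """Voxelwise fat-fraction volume; undefined voxels are NaN + masked."""

    ff: np.ndarray = field(repr=False)
    undefined_mask: np.ndarray = field(repr=False)
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        defined = ~self.undefined_mask
        vals = self.ff[defined]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("defined fat-fraction values must lie in [0, 1]")


@dataclass(frozen=True)
class MuscleMetrics:
    """Bulk-restricted fat-fraction and volume metrics for one muscle."""

    muscle: str
    mean_ff: float  # fraction in [0, 1]
    voxel_count: int
    undefined_count: int
    volume_ml: float
    lean_volume_ml: float
    bulk_slice_range: tuple[int, int]

    @property
    def mean_ff_pct(self) -> float:
        return 100.0 * self.mean_ff

    @property
    def fat_volume_ml(self) -> float:
        return self.volume_ml * self.mean_ff


def compute_ff_map(study: DixonStudy, signal_floor: float = 0.0) -> FFMap:
    """FF = fat / (water + fat) wherever the summed signal exceeds the floor.

    Voxels with ``water + fat <= signal_floor`` carry no usable Dixon signal
    (air, background) and are marked undefined; they are excluded from any
    average but still counted in volumes.
    """
    if signal_floor < 0:
        raise ValueError("signal_floor must be >= 0")
    denom = study.water + study.fat
    undefined = denom <= signal_floor
    ff = np.full(denom.shape, np.nan)
    np.divide(study.fat, denom, out=ff, where=~undefined)
    np.clip(ff, 0.0, 1.0, out=ff)
    ff[undefined] = np.nan
    return FFMap(ff=ff, undefined_mask=undefined, geometry=study.geometry)


def extract_bulk(label: LabelMap, landmarks: LandmarkSet, side: str) -> LabelMap:
    """Restrict a label map to the [LT, ASIS] inclusive axial slice range.

    Returns a copy with every voxel outside the range zeroed.  Raises
    :class:`EmptyMuscleError` if the requested side's muscle has no voxel
    left inside the range.
    """
    geom = label.geometry
    landmarks.validate(geom)
    lo, hi = landmarks.bulk_slice_range(side, geom)
    out = label.labels.copy()
    idx = [slice(None)] * 3
    idx[geom.si_axis] = slice(0, lo)
    out[tuple(idx)] = 0
    idx[geom.si_axis] = slice(hi + 1, None)
    out[tuple(idx)] = 0
    bulk = LabelMap(labels=out, geometry=geom, code_book=label.code_book)
    code = label.code_for_side(side)
    if not np.any(out == code):
        raise EmptyMuscleError(
            f"muscle {label.code_book[code]!r} has no voxels in bulk slices [{lo}, {hi}]"
        )
    return bulk


def muscle_metrics(
    ff_map: FFMap,
    bulk_label: LabelMap,
    muscle_code: int,
    erosion_radius: int = 0,
) -> MuscleMetrics:
    """Average the FF image over one muscle's bulk label and derive volumes.

    ``voxel_count`` counts all labelled bulk voxels (defined and undefined);
    only defined voxels enter the FF mean.  ``erosion_radius`` optionally
    erodes the mask before measuring (off by default: labels drawn inside the
    muscle have little cross-talk with intermuscular fat).
    """
    if not ff_map.geometry.matches(bulk_label.geometry):
        raise ValueError("FF map and label geometry differ")
    if muscle_code not in bulk_label.code_book:
        raise KeyError(f"muscle code {muscle_code} not in code_book")
    mask = bulk_label.labels == muscle_code
    if erosion_radius > 0:
        mask = ndimage.binary_erosion(mask, iterations=int(erosion_radius))
    voxel_count = int(mask.sum())
    if voxel_count == 0:
        raise EmptyMuscleError(
            f"no labelled voxels for {bulk_label.code_book[muscle_code]!r}"
        )
    defined = mask & ~ff_map.undefined_mask
    undefined_count = voxel_count - int(defined.sum())
    if undefined_count == voxel_count:
        raise EmptyMuscleError(
            f"all labelled voxels undefined for {bulk_label.code_book[muscle_code]!r}"
        )
    mean_ff = float(ff_map.ff[defined].mean())
    volume_ml = voxel_count * ff_map.geometry.voxel_volume_mm3 / 1000.0
    si = bulk_label.geometry.si_axis
    slices = np.unique(np.nonzero(mask)[si])
    return MuscleMetrics(
        muscle=bulk_label.code_book[muscle_code],
        mean_ff=mean_ff,
        voxel_count=voxel_count,
        undefined_count=undefined_count,
        volume_ml=volume_ml,
        lean_volume_ml=volume_ml * (1.0 - mean_ff),
        bulk_slice_range=(int(slices.min()), int(slices.max())),
    )


# Boer (1984) lean-body-mass coefficients (kg; height in cm).
_BOER = {
    "male": (0.407, 0.267, -19.2),
    "female": (0.252, 0.473, -48.3),
}


def boer_lbm(sex: str, weight_kg: float, height_cm: float) -> float:
    """Lean body mass (kg) from sex, weight and height via the Boer formula."""
    sex = str(sex).lower()
    if sex not in _BOER:
        raise ValueError(f"unknown sex code {sex!r} (expected 'male' or 'female')")
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    a, b, c = _BOER[sex]
    return a * weight_kg + b * height_cm + c


@dataclass(frozen=True)
class Anthropometrics:
    sex: str
    weight_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        # boer_lbm validates sex/weight/height
        boer_lbm(self.sex, self.weight_kg, self.height_cm)

    @property
    def bmi(self) -> float:
        h_m = self.height_cm / 100.0
        return self.weight_kg / (h_m * h_m)

    @property
    def lbm_kg(self) -> float:
        return boer_lbm(self.sex, self.weight_kg, self.height_cm)


def assign_activity_group(hours_per_week: float) -> str:
    """Activity grouping: <4 h/week Low, 4-8 h/week Mid, >8 h/week High."""
    if hours_per_week < 0:
        raise ValueError("activity hours must be >= 0")
    if hours_per_week < 4:
        return "Low"
    if hours_per_week <= 8:
        return "Mid"
    return "High"


def ohs_grade(score: int) -> int:
    """Oxford Hip Score grade: 0-19 Severe(1), 20-29 Moderate(2), 30-39 Mild(3), 40-48 Satisfactory(4)."""
    score = int(score)
    if not 0 <= score <= 48:
        raise ValueError(f"OHS score must be in [0, 48], got {score}")
    if score <= 19:
        return 1
    if score <= 29:
        return 2
    if score <= 39:
        return 3
    return 4


@dataclass(frozen=True)
class SubjectRecord:
    """Per-side muscle metrics joined with demographics for one subject."""

    subject_id: str
    left: MuscleMetrics
    right: MuscleMetrics
    anthropometrics: Anthropometrics
    age_years: float
    group: str
    activity_hours_per_week: Optional[float] = None
    ohs_score: Optional[int] = None
    pain_side: Optional[str] = None

    @property
    def side_mean_ff(self) -> float:
        return 0.5 * (self.left.mean_ff + self.right.mean_ff)

    @property
    def ohs_grade(self) -> Optional[int]:
        return None if self.ohs_score is None else ohs_grade(self.ohs_score)

    def _norm(self, value: float) -> float:
        return value / self.anthropometrics.lbm_kg

    def to_side_rows(self) -> list[dict]:
        """One tidy row per side (the statistics module's input schema)."""
        rows = []
        for side, m in (("left", self.left), ("right", self.right)):
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "side": side,
                    "group": self.group,
                    "sex": self.anthropometrics.sex,
                    "age_years": self.age_years,
                    "weight_kg": self.anthropometrics.weight_kg,
                    "height_cm": self.anthropometrics.height_cm,
                    "bmi": self.anthropometrics.bmi,
                    "lbm_kg": self.anthropometrics.lbm_kg,
                    "activity_hours_per_week": self.activity_hours_per_week,
                    "ohs_score": self.ohs_score,
                    "ohs_grade": self.ohs_grade,
                    "pain_side": self.pain_side,
                    "ff_pct": m.mean_ff_pct,
                    "voxel_count": m.voxel_count,
                    "undefined_count": m.undefined_count,
                    "volume_ml": m.volume_ml,
                    "lean_volume_ml": m.lean_volume_ml,
                    "normalized_volume": self._norm(m.volume_ml),
                    "normalized_lean_volume": self._norm(m.lean_volume_ml),
                    "bulk_slices": f"{m.bulk_slice_range[0]}-{m.bulk_slice_range[1]}",
                }
            )
        return rows


def summarize_subject(
    metrics_left: MuscleMetrics,
    metrics_right: MuscleMetrics,
    anthropometrics: Anthropometrics,
    metadata: Mapping,
) -> SubjectRecord:
    """Join both sides' metrics with demographics into a SubjectRecord.

    ``metadata`` supplies subject_id, age_years and either a patient flag
    (``group='Pain'``) or weekly activity hours used to assign Low/Mid/High.
    """
    if anthropometrics.lbm_kg <= 0:
        raise ValueError("lean body mass must be positive")
    group = metadata.get("group")
    hours = metadata.get("activity_hours_per_week")
    if group in (None, "", "auto"):
        if hours is None:
            raise ValueError("need either an explicit group or activity hours")
        group = assign_activity_group(float(hours))
    elif group != "Pain" and hours is not None and not _is_na(hours):
        expected = assign_activity_group(float(hours))
        if group != expected:
            raise ValueError(
                f"group {group!r} inconsistent with {hours} activity hours (expect {expected!r})"
            )
    ohs = metadata.get("ohs_score")
    ohs = None if ohs is None or _is_na(ohs) else int(ohs)
    pain_side = metadata.get("pain_side")
    pain_side = None if pain_side is None or _is_na(pain_side) else str(pain_side)
    return SubjectRecord(
        subject_id=str(metadata["subject_id"]),
        left=metrics_left,
        right=metrics_right,
        anthropometrics=anthropometrics,
        age_years=float(metadata["age_years"]),
        group=str(group),
        activity_hours_per_week=None if hours is None or _is_na(hours) else float(hours),
        ohs_score=ohs,
        pain_side=pain_side,
    )


def _is_na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""
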