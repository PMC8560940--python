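"""Reading and writing the imaging artifacts of a Dixon fat-fraction study.

Volumes (water, fat, optional in-phase), integer label maps and anatomical
landmarks are all kept on one voxel grid; every reader verifies geometric
consistency up front so that downstream quantification never has to guess
whether two arrays are co-registered.  No resampling is ever performed — a
geometry mismatch is an error, not a repair opportunity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

__all__ = [
    "GeometryError",
    "LandmarkError",
    "ImageGeometry",
    "DixonStudy",
    "LabelMap",
    "SideLandmarks",
    "LandmarkSet",
    "read_dixon_study",
    "read_label_map",
    "read_landmarks",
    "write_volume",
    "read_metadata_table",
    "AFFINE_TOL_MM",
]

#: channels are considered co-registered when affines agree within this (mm)
AFFINE_TOL_MM = 1e-4

_AXIS_ROLE = {"R": "LR", "L": "LR", "A": "AP", "P": "AP", "S": "SI", "I": "SI"}


class GeometryError(ValueError):
    """Raised when volumes that must share a grid do not."""


class LandmarkError(ValueError):
    """Raised for missing, out-of-grid or anatomically inconsistent landmarks."""


@dataclass(frozen=True)
class ImageGeometry:
    """Voxel grid shape plus the affine mapping voxel indices to world mm.

    ``axis_codes`` holds the anatomical direction each array axis points
    toward (e.g. ``('R', 'A', 'S')``); ``axis_roles`` derives from it and must
    cover left-right, anterior-posterior and superior-inferior exactly once.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise GeometryError(f"shape must be a positive integer triple, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or not np.all(np.isfinite(aff)):
            raise GeometryError("affine must be a finite 4x4 matrix")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError("voxel sizes must all be positive")
        roles = self.axis_roles
        if sorted(roles) != ["AP", "LR", "SI"]:
            raise GeometryError(f"axis roles must be a bijection onto LR/AP/SI, got {roles}")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def axis_codes(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    @property
    def axis_roles(self) -> tuple[str, str, str]:
        return tuple(_AXIS_ROLE[c] for c in self.axis_codes)

    @property
    def si_axis(self) -> int:
        """Array axis running superior-inferior (the axial slice axis)."""
        return self.axis_roles.index("SI")

    @property
    def si_increases_superior(self) -> bool:
        return self.axis_codes[self.si_axis] == "S"

    def matches(self, other: "ImageGeometry", tol: float = AFFINE_TOL_MM) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    @classmethod
    def from_voxel_size(
        cls, shape: tuple[int, int, int], voxel_size_mm: tuple[float, float, float]
    ) -> "ImageGeometry":
        """RAS geometry with the slice (SI) axis as the third array axis."""
        aff = np.diag(list(voxel_size_mm) + [1.0])
        return cls(shape=tuple(shape), affine=aff)

    def world_to_voxel(self, xyz_mm) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        p = np.asarray(xyz_mm, dtype=float)
        return (inv[:3, :3] @ p + inv[:3, 3])

    def voxel_to_world(self, ijk) -> np.ndarray:
        p = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ p + self.affine[:3, 3]


def _check_channel(name: str, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise GeometryError(f"{name} channel must be 3D, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{name} channel contains non-finite voxels")
    if np.any(data < 0):
        raise ValueError(f"{name} channel contains negative intensities")
    return data


@dataclass(frozen=True)
class DixonStudy:
    """Co-registered water/fat (and optional in-phase) volumes for one subject."""

    subject_id: str
    water: np.ndarray = field(repr=False)
    fat: np.ndarray = field(repr=False)
    geometry: ImageGeometry
    in_phase: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        water = _check_channel("water", self.water)
        fat = _check_channel("fat", self.fat)
        object.__setattr__(self, "water", water)
        object.__setattr__(self, "fat", fat)
        if water.shape != fat.shape:
            raise GeometryError(
                f"channel shape mismatch: water {water.shape} vs fat {fat.shape}"
            )
        if water.shape != self.geometry.shape:
            raise GeometryError("channel shape does not match geometry")
        if self.in_phase is not None:
            ip = _check_channel("in_phase", self.in_phase)
            object.__setattr__(self, "in_phase", ip)
            if ip.shape != water.shape:
                raise GeometryError("in-phase channel shape mismatch")


@dataclass(frozen=True)
class LabelMap:
    """Integer-coded 3D muscle labels with a code book naming each code."""

    labels: np.ndarray = field(repr=False)
    geometry: ImageGeometry
    code_book: Mapping[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("label volume must be integer-valued")
            lab = lab.astype(np.int32)
        if lab.shape != self.geometry.shape:
            raise GeometryError("label shape does not match geometry")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "code_book", dict(self.code_book))
        present = set(int(v) for v in np.unique(lab)) - {0}
        unknown = present - set(self.code_book)
        if unknown:
            raise ValueError(f"label codes {sorted(unknown)} absent from code_book")

    def code_for_side(self, side: str) -> int:
        """Label code whose code-book name ends in the given side."""
        side = side.lower()
        for code, name in self.code_book.items():
            if name.lower().endswith(side):
                return int(code)
        raise KeyError(f"no code_book entry for side {side!r}")


@dataclass(frozen=True)
class SideLandmarks:
    """Lesser-trochanter tip and ASIS voxel coordinates for one side."""

    lt_tip: tuple[int, int, int]
    asis: tuple[int, int, int]


@dataclass(frozen=True)
class LandmarkSet:
    """Per-side bone landmarks delimiting the muscle bulk, in voxel indices."""

    left: SideLandmarks
    right: SideLandmarks

    def side(self, which: str) -> SideLandmarks:
        which = which.lower()
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise KeyError(f"side must be 'left' or 'right', got {which!r}")

    def validate(self, geometry: ImageGeometry) -> None:
        si = geometry.si_axis
        for name, lm in (("left", self.left), ("right", self.right)):
            for pname, point in (("LT_tip", lm.lt_tip), ("ASIS", lm.asis)):
                if any(
                    not (0 <= int(point[a]) < geometry.shape[a]) for a in range(3)
                ):
                    raise LandmarkError(
                        f"{name} {pname} {tuple(point)} outside grid {geometry.shape}"
                    )
            lt_si, asis_si = int(lm.lt_tip[si]), int(lm.asis[si])
            # equality allowed: a degenerate single-slice bulk is valid
            inferior_ok = (
                lt_si <= asis_si if geometry.si_increases_superior else lt_si >= asis_si
            )
            if not inferior_ok:
                raise LandmarkError(
                    f"{name}: LT must be inferior to ASIS on the SI axis "
                    f"(LT slice {lt_si}, ASIS slice {asis_si})"
                )

    def bulk_slice_range(self, side: str, geometry: ImageGeometry) -> tuple[int, int]:
        """Inclusive [LT, ASIS] axial slice range on the SI axis."""
        lm = self.side(side)
        si = geometry.si_axis
        lo, hi = sorted((int(lm.lt_tip[si]), int(lm.asis[si])))
        return lo, hi


def _load_nifti(path) -> tuple[np.ndarray, ImageGeometry]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    geom = ImageGeometry(shape=data.shape, affine=np.asarray(img.affine, dtype=float))
    return data, geom


def write_volume(data: np.ndarray, geometry: ImageGeometry, path) -> Path:
    """Write a volume as NIfTI-1 with the geometry's affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), geometry.affine)
    nib.save(img, str(path))
    return path


def read_dixon_study(
    water_path, fat_path, in_phase_path=None, subject_id: str = "subject"
) -> DixonStudy:
    """Load and co-registration-check the water/fat (and in-phase) channels."""
    water, wgeom = _load_nifti(water_path)
    fat, fgeom = _load_nifti(fat_path)
    if water.shape != fat.shape:
        raise GeometryError(
            f"channel shape mismatch: water {water.shape} vs fat {fat.shape}"
        )
    if not wgeom.matches(fgeom):
        raise GeometryError("water and fat affines differ beyond tolerance")
    in_phase = None
    if in_phase_path is not None:
        in_phase, igeom = _load_nifti(in_phase_path)
        if not wgeom.matches(igeom):
            raise GeometryError("in-phase channel not co-registered with water")
    return DixonStudy(
        subject_id=subject_id, water=water, fat=fat, in_phase=in_phase, geometry=wgeom
    )


def read_label_map(path, expected_geometry: ImageGeometry, code_book) -> LabelMap:
    data, geom = _load_nifti(path)
    if not geom.matches(expected_geometry):
        raise GeometryError(f"label geometry of {path} does not match the study grid")
    return LabelMap(labels=data, geometry=geom, code_book=code_book)


def read_landmarks(path, geometry: ImageGeometry) -> LandmarkSet:
    """Read landmarks JSON, converting world-mm coordinates to voxel indices.

    Expected layout::

        {"convention": "voxel" | "world_mm",
         "left":  {"LT_tip": [i, j, k], "ASIS": [i, j, k]},
         "right": {"LT_tip": [i, j, k], "ASIS": [i, j, k]}}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing landmark file: {path}")
    payload = json.loads(path.read_text())
    convention = payload.get("convention", "voxel")
    if convention not in ("voxel", "world_mm"):
        raise LandmarkError(f"unknown landmark convention {convention!r}")

    def _point(side: str, name: str) -> tuple[int, int, int]:
        try:
            raw = payload[side][name]
        except KeyError as exc:
            raise LandmarkError(f"missing landmark {side}/{name}") from exc
        if convention == "world_mm":
            vox = geometry.world_to_voxel(raw)
            return tuple(int(round(v)) for v in vox)
        return tuple(int(round(v)) for v in raw)

    lm = LandmarkSet(
        left=SideLandmarks(_point("left", "LT_tip"), _point("left", "ASIS")),
        right=SideLandmarks(_point("right", "LT_tip"), _point("right", "ASIS")),
    )
    lm.validate(geometry)
    return lm


METADATA_COLUMNS = [
    "subject_id",
    "sex",
    "age_years",
    "weight_kg",
    "height_cm",
    "group",
    "activity_hours_per_week",
    "ohs_score",
    "pain_side",
]


def read_metadata_table(path):
    """Load the subject metadata CSV and check its schema."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns: {missing}")
    return df
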