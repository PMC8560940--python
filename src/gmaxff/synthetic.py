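"""Synthetic Dixon phantoms and synthetic cohorts with known ground truth.

Two generators make the whole pipeline testable without any scanner data:

* :func:`generate_phantom` builds a 3D two-channel Dixon study around a known
  voxelwise fat-fraction field.  The signal model is ``W = PD * (1 - ff)``,
  ``F = PD * ff``, so the ratio F/(W+F) reproduces the true field exactly in
  the absence of noise.  Muscles are ellipsoids (enough to exercise masking,
  landmarks and volumetrics), optionally wrapped in a subcutaneous-fat shell,
  with per-channel Gaussian or Rician noise.

* :func:`generate_cohort_table` draws tabular cohorts with the structure of
  the study population: four groups (hip-pain patients plus Low/Mid/High
  activity), gender/BMI/age covariates, a bilateral left-right asymmetry, and
  fat-fraction values generated either by direct per-group draws or by
  inverting the linear model FF ~ gender + BMI + age + activity + side with
  user-set coefficients.  The exact generating parameters are returned so
  recovery is testable.

:func:`generate_imaging_cohort` binds the two together: each tabular
subject's true FF becomes the constant FF field of their phantom.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    DixonStudy,
    ImageGeometry,
    LabelMap,
    LandmarkSet,
    SideLandmarks,
)
from .quant import ohs_grade

__all__ = [
    "FFField",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomBundle",
    "GroupSpec",
    "LinearFFModel",
    "DirectFFModel",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort_table",
    "generate_imaging_cohort",
    "DEFAULT_CODE_BOOK",
]

DEFAULT_CODE_BOOK = {1: "GMAX_left", 2: "GMAX_right"}

# Dixon voxel size of the emulated acquisition, mm
DEFAULT_VOXEL_SIZE = (0.47, 0.47, 1.95)


@dataclass(frozen=True)
class FFField:
    """True fat-fraction field inside one muscle (fractions in [0, 1]).

    kinds: ``constant`` (value ``p``), ``linear_si`` (linear gradient from
    ``p_inferior`` at slice 0 to ``p_superior`` at the top slice), or
    ``textured`` (constant ``p`` plus Gaussian texture of sd ``sd_texture``,
    clipped to [0, 1]).
    """

    kind: str = "constant"
    p: float = 0.20
    p_inferior: float = 0.10
    p_superior: float = 0.30
    sd_texture: float = 0.03

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_si", "textured"):
            raise ValueError(f"unknown FF field kind {self.kind!r}")
        for v in (self.p, self.p_inferior, self.p_superior):
            if not 0.0 <= v <= 1.0:
                raise ValueError("true FF values must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, FF fields, landmarks and noise of one synthetic subject."""

    shape: tuple[int, int, int] = (96, 96, 48)
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    # ellipsoid centres (voxel indices) and semi-axes (voxels) per side
    center_left: Optional[tuple[float, float, float]] = None
    center_right: Optional[tuple[float, float, float]] = None
    semi_axes_vox: tuple[float, float, float] = (17.0, 17.0, 15.0)
    lt_slice: int = 8
    asis_slice: int = 40
    ff_left: FFField = field(default_factory=FFField)
    ff_right: FFField = field(default_factory=FFField)
    proton_density: float = 100.0
    noise_kind: str = "none"  # none | gaussian | rician
    noise_sd: float = 0.0
    fat_shell: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_kind not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        nx, ny, nz = self.shape
        if not 0 <= self.lt_slice < self.asis_slice < nz:
            raise ValueError("need 0 <= LT slice < ASIS slice < grid depth")
        cl = self.center_left or (0.30 * nx, 0.5 * ny, 0.5 * nz)
        cr = self.center_right or (0.70 * nx, 0.5 * ny, 0.5 * nz)
        object.__setattr__(self, "center_left", tuple(float(c) for c in cl))
        object.__setattr__(self, "center_right", tuple(float(c) for c in cr))
        for name, c in (("left", self.center_left), ("right", self.center_right)):
            for ax in range(3):
                if not (
                    0 <= c[ax] - self.semi_axes_vox[ax]
                    and c[ax] + self.semi_axes_vox[ax] < self.shape[ax]
                ):
                    raise ValueError(f"{name} ellipsoid extends outside the grid")


@dataclass(frozen=True)
class MuscleTruth:
    true_mean_ff: float  # bulk-mean, fraction
    voxel_count: int  # bulk voxels
    volume_ml: float


@dataclass(frozen=True)
class PhantomTruth:
    """Exact per-muscle ground truth, recomputable from spec + seed."""

    left: MuscleTruth
    right: MuscleTruth
    seed: int
    spec: PhantomSpec


@dataclass(frozen=True)
class PhantomBundle:
    subject_id: str
    study: DixonStudy
    label_map: LabelMap
    landmarks: LandmarkSet
    truth: PhantomTruth
    metadata: dict


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _field_values(ff: FFField, shape, rng) -> np.ndarray:
    nz = shape[2]
    if ff.kind == "constant":
        return np.full(shape, ff.p)
    if ff.kind == "linear_si":
        z = np.arange(nz) / max(nz - 1, 1)
        ramp = ff.p_inferior + (ff.p_superior - ff.p_inferior) * z
        return np.broadcast_to(ramp[None, None, :], shape).copy()
    tex = ff.p + rng.normal(0.0, ff.sd_texture, size=shape)
    return np.clip(tex, 0.0, 1.0)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[DixonStudy, LabelMap, LandmarkSet, PhantomTruth]:
    """Render one synthetic Dixon subject; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    geom = ImageGeometry.from_voxel_size(spec.shape, spec.voxel_size_mm)

    mask_l = _ellipsoid_mask(spec.shape, spec.center_left, spec.semi_axes_vox)
    mask_r = _ellipsoid_mask(spec.shape, spec.center_right, spec.semi_axes_vox)
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[mask_l] = 1
    labels[mask_r] = 2

    ff_true = np.zeros(spec.shape)
    ff_true[mask_l] = _field_values(spec.ff_left, spec.shape, rng)[mask_l]
    ff_true[mask_r] = _field_values(spec.ff_right, spec.shape, rng)[mask_r]

    pd_map = np.zeros(spec.shape)
    pd_map[mask_l | mask_r] = spec.proton_density
    if spec.fat_shell:
        # in-plane annulus emulating the subcutaneous fat ring; never labelled
        nx, ny, _ = spec.shape
        gx, gy = np.ogrid[0:nx, 0:ny]
        r = np.sqrt(((gx - nx / 2) / (nx / 2)) ** 2 + ((gy - ny / 2) / (ny / 2)) ** 2)
        shell2d = (r >= 0.90) & (r <= 1.0)
        shell = np.broadcast_to(shell2d[:, :, None], spec.shape) & (labels == 0)
        pd_map = pd_map.copy()
        pd_map[shell] = spec.proton_density
        ff_true[shell] = 0.90

    water = pd_map * (1.0 - ff_true)
    fat = pd_map * ff_true
    if spec.noise_kind == "gaussian" and spec.noise_sd > 0:
        water = water + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        fat = fat + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    elif spec.noise_kind == "rician" and spec.noise_sd > 0:
        water = np.hypot(
            water + rng.normal(0.0, spec.noise_sd, size=spec.shape),
            rng.normal(0.0, spec.noise_sd, size=spec.shape),
        )
        fat = np.hypot(
            fat + rng.normal(0.0, spec.noise_sd, size=spec.shape),
            rng.normal(0.0, spec.noise_sd, size=spec.shape),
        )
    # magnitude images cannot be negative
    water = np.clip(water, 0.0, None)
    fat = np.clip(fat, 0.0, None)

    study = DixonStudy(
        subject_id=f"phantom-{spec.seed}",
        water=water,
        fat=fat,
        in_phase=water + fat,
        geometry=geom,
    )
    label_map = LabelMap(labels=labels, geometry=geom, code_book=DEFAULT_CODE_BOOK)

    def _side_landmarks(center):
        cx, cy = int(round(center[0])), int(round(center[1]))
        return SideLandmarks(
            lt_tip=(cx, cy, spec.lt_slice), asis=(cx, max(cy - 10, 0), spec.asis_slice)
        )

    landmarks = LandmarkSet(
        left=_side_landmarks(spec.center_left),
        right=_side_landmarks(spec.center_right),
    )
    landmarks.validate(geom)

    # ground truth by direct averaging of the noiseless field over the bulk
    bulk = np.zeros(spec.shape, dtype=bool)
    bulk[:, :, spec.lt_slice : spec.asis_slice + 1] = True
    vox_ml = geom.voxel_volume_mm3 / 1000.0

    def _truth(mask):
        m = mask & bulk
        n = int(m.sum())
        return MuscleTruth(
            true_mean_ff=float(ff_true[m].sum() / n) if n else float("nan"),
            voxel_count=n,
            volume_ml=n * vox_ml,
        )

    truth = PhantomTruth(left=_truth(mask_l), right=_truth(mask_r), seed=spec.seed, spec=spec)
    return study, label_map, landmarks, truth


# ---------------------------------------------------------------------------
# Tabular cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Demographic recipe for one group; defaults follow the study cohort."""

    n: int
    n_male: int
    age_range: tuple[float, float]
    bmi_mean: float
    bmi_sd: float
    height_mean_cm: float
    height_sd_cm: float
    hours_range: tuple[float, float] = (0.0, 0.0)
    has_ohs: bool = False

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 <= self.n_male <= self.n:
            raise ValueError("need n >= 1 and 0 <= n_male <= n")


@dataclass(frozen=True)
class LinearFFModel:
    """FF (in %) = intercept + male + bmi + age + group + right-side + noise."""

    intercept: float = -5.2
    beta_male: float = -3.8
    beta_bmi: float = 0.9
    beta_age: float = 0.1
    beta_group: dict = field(
        default_factory=lambda: {"Pain": 7.2, "Low": 5.2, "Mid": 1.8, "High": 0.0}
    )
    beta_side_right: float = -3.0
    sd_eps: float = 4.0


@dataclass(frozen=True)
class DirectFFModel:
    """Per-group FF draws (%); lognormal captures the right skew of FF data."""

    group_mean: dict = field(
        default_factory=lambda: {"Pain": 27.7, "Low": 19.1, "Mid": 18.0, "High": 14.7}
    )
    group_sd: dict = field(
        default_factory=lambda: {"Pain": 7.7, "Low": 5.5, "Mid": 6.3, "High": 4.7}
    )
    dist: str = "lognormal"  # lognormal | normal
    side_offset_pct: float = 3.3  # left minus right, percentage points
    side_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "normal"):
            raise ValueError(f"unknown distribution {self.dist!r}")


def _default_groups() -> dict:
    return {
        "Pain": GroupSpec(19, 7, (19, 63), 27.3, 6.0, 167.0, 9.0, (0.0, 1.5), True),
        "Low": GroupSpec(13, 8, (22, 45), 22.0, 1.9, 175.0, 11.0, (0.5, 3.9)),
        "Mid": GroupSpec(18, 7, (20, 59), 23.3, 3.4, 172.0, 12.0, (4.0, 8.0)),
        "High": GroupSpec(20, 16, (18, 45), 23.7, 2.0, 176.0, 8.0, (8.1, 14.0)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a tabular synthetic cohort (one row per subject per side)."""

    groups: dict = field(default_factory=_default_groups)
    ff_model: object = field(default_factory=LinearFFModel)
    volume_mean_ml: dict = field(
        default_factory=lambda: {"Pain": 700.0, "Low": 750.0, "Mid": 800.0, "High": 900.0}
    )
    volume_sd_ml: float = 100.0
    seed: int = 0


def _draw_ff_pct(model, row, side, rng) -> float:
    if isinstance(model, LinearFFModel):
        mu = (
            model.intercept
            + model.beta_male * row["male"]
            + model.beta_bmi * row["bmi"]
            + model.beta_age * row["age_years"]
            + model.beta_group.get(row["group"], 0.0)
            + (model.beta_side_right if side == "right" else 0.0)
        )
        return mu + rng.normal(0.0, model.sd_eps) if model.sd_eps > 0 else mu
    raise TypeError(f"unsupported FF model {type(model).__name__}")


def generate_cohort_table(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a tidy side-level cohort table plus the exact generating truth.

    Returns ``(table, truth)`` where ``truth`` echoes the FF model parameters
    actually used (coefficients for the linear model; group means, sds and
    the side offset for direct draws).
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.ff_model
    rows = []
    sid = 0
    for gname, g in spec.groups.items():
        for i in range(g.n):
            sid += 1
            male = i < g.n_male
            age = rng.uniform(*g.age_range)
            height = rng.normal(g.height_mean_cm, g.height_sd_cm)
            height = float(np.clip(height, 140.0, 210.0))
            bmi = float(np.clip(rng.normal(g.bmi_mean, g.bmi_sd), 16.0, 45.0))
            weight = bmi * (height / 100.0) ** 2
            hours = float(rng.uniform(*g.hours_range))
            ohs = int(rng.integers(5, 40)) if g.has_ohs else None
            pain_side = (
                str(rng.choice(["left", "right", "both"], p=[0.3, 0.3, 0.4]))
                if g.has_ohs
                else None
            )
            base = {
                "subject_id": f"S{sid:03d}",
                "group": gname,
                "sex": "male" if male else "female",
                "male": int(male),
                "age_years": float(age),
                "height_cm": height,
                "bmi": bmi,
                "weight_kg": float(weight),
                "activity_hours_per_week": None if g.has_ohs else hours,
                "ohs_score": ohs,
                "ohs_grade": ohs_grade(ohs) if ohs is not None else None,
                "pain_side": pain_side,
            }
            if isinstance(model, DirectFFModel):
                mean, sd = model.group_mean[gname], model.group_sd[gname]
                if model.dist == "lognormal":
                    s2 = np.log1p((sd / mean) ** 2)
                    mu_ln = np.log(mean) - s2 / 2.0
                    subject_ff = rng.lognormal(mu_ln, np.sqrt(s2))
                else:
                    subject_ff = rng.normal(mean, sd)
                ff_side = {
                    "left": subject_ff
                    + model.side_offset_pct / 2.0
                    + rng.normal(0.0, model.side_noise_sd),
                    "right": subject_ff
                    - model.side_offset_pct / 2.0
                    + rng.normal(0.0, model.side_noise_sd),
                }
            else:
                ff_side = {s: _draw_ff_pct(model, base, s, rng) for s in ("left", "right")}
            for side in ("left", "right"):
                ff = float(np.clip(ff_side[side], 0.5, 70.0))
                vol = float(
                    np.clip(
                        rng.normal(spec.volume_mean_ml[gname], spec.volume_sd_ml),
                        200.0,
                        1500.0,
                    )
                )
                rows.append(
                    {
                        **base,
                        "side": side,
                        "ff_pct": ff,
                        "volume_ml": vol,
                        "lean_volume_ml": vol * (1.0 - ff / 100.0),
                    }
                )
    table = pd.DataFrame(rows)
    # Boer LBM for volume normalisation
    from .quant import boer_lbm

    table["lbm_kg"] = [
        boer_lbm(s, w, h)
        for s, w, h in zip(table["sex"], table["weight_kg"], table["height_cm"])
    ]
    table["normalized_volume"] = table["volume_ml"] / table["lbm_kg"]
    table["normalized_lean_volume"] = table["lean_volume_ml"] / table["lbm_kg"]

    truth = {"seed": spec.seed, "model": type(model).__name__}
    truth.update(dataclasses.asdict(model))
    return table, truth


def generate_imaging_cohort(
    cohort_spec: CohortSpec,
    phantom_template: Optional[PhantomSpec] = None,
) -> tuple[list[PhantomBundle], pd.DataFrame, dict]:
    """One phantom per tabular subject, constant FF fields set to their truth.

    Each subject's phantom seed derives deterministically from the cohort
    seed; the tabular per-side FF (as a fraction) becomes the exact constant
    field of that side's ellipsoid.
    """
    template = phantom_template or PhantomSpec()
    table, truth = generate_cohort_table(cohort_spec)
    bundles = []
    for idx, (sid, sub) in enumerate(table.groupby("subject_id", sort=True)):
        by_side = sub.set_index("side")
        ff_l = float(by_side.loc["left", "ff_pct"]) / 100.0
        ff_r = float(by_side.loc["right", "ff_pct"]) / 100.0
        spec = dataclasses.replace(
            template,
            ff_left=FFField(kind="constant", p=ff_l),
            ff_right=FFField(kind="constant", p=ff_r),
            seed=int((cohort_spec.seed * 100003 + idx) % (2**31 - 1)),
        )
        study, label_map, landmarks, ptruth = generate_phantom(spec)
        meta = by_side.loc["left"].drop(
            labels=[c for c in by_side.columns if c.startswith("ff") or "volume" in c.lower()],
            errors="ignore",
        )
        metadata = {
            "subject_id": sid,
            "sex": meta["sex"],
            "age_years": float(meta["age_years"]),
            "weight_kg": float(meta["weight_kg"]),
            "height_cm": float(meta["height_cm"]),
            "group": meta["group"],
            "activity_hours_per_week": meta["activity_hours_per_week"],
            "ohs_score": meta["ohs_score"],
            "pain_side": meta["pain_side"],
        }
        bundles.append(
            PhantomBundle(
                subject_id=sid,
                study=dataclasses.replace(study, subject_id=sid),
                label_map=label_map,
                landmarks=landmarks,
                truth=ptruth,
                metadata=metadata,
            )
        )
    return bundles, table, truth
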