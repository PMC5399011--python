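"""Volume and mask I/O, grid mapping and feature-table serialisation.

Volumes are stored as NIfTI-1; in memory they are :class:`ScalarVolume`
(real-valued grid) or :class:`VoiMask` (binary grid), both carrying voxel
spacing and origin.  The coordinate convention is deliberately simple:
voxel indices are 0-based and the physical position of a voxel centre is
``origin + index * spacing`` on each axis (axis-aligned grids only; oblique
orientation matrices are out of scope).

Tumour masks are drawn on CT and must be mapped onto the PET grid before
feature extraction; :func:`map_mask_to_grid` does this by nearest-neighbour
lookup at target voxel centres, assuming the two grids share one physical
frame (perfect co-registration).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .catalog import ALL_FEATURES
from .errors import ValidationError, VolumeIOError


class VolumeUnits(str, Enum):
    ACTIVITY_BQ_ML = "activity_bq_ml"
    SUV = "suv"
    ARBITRARY = "arbitrary"


def _check_grid(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValidationError(f"grid dimensions must be >= 1, got {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise ValidationError(f"spacing must be 3 strictly positive values, got {spacing}")
    origin = np.asarray(origin, dtype=float)
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValidationError(f"origin must be 3 finite values, got {origin}")


@dataclass
class ScalarVolume:
    """A 3D intensity grid with anisotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: VolumeUnits = VolumeUnits.ARBITRARY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _check_grid(self.data, self.spacing, self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains NaN or Inf voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray, units: VolumeUnits | None = None) -> "ScalarVolume":
        return ScalarVolume(data, self.spacing, self.origin, units or self.units)


@dataclass
class VoiMask:
    """Binary tumour mask aligned to a :class:`ScalarVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(np.unique(arr), [0, 1]).all():
            raise ValidationError("mask values must be 0 or 1")
        self.data = arr.astype(bool)
        _check_grid(self.data, self.spacing, self.origin)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class AcquisitionMeta:
    """Injection/scan bookkeeping that drives SUV conversion and decay
    correction.

    ``injected_activity_mbq`` is the activity at injection time; F-18 has a
    half-life of 109.77 min.
    """

    injected_activity_mbq: float
    injection_time: _dt.datetime
    scan_time: _dt.datetime
    body_weight_kg: float
    half_life_min: float = 109.77

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValidationError("injected_activity_mbq must be > 0")
        if self.body_weight_kg <= 0:
            raise ValidationError("body_weight_kg must be > 0")
        if self.half_life_min <= 0:
            raise ValidationError("half_life_min must be > 0")
        if self.scan_time < self.injection_time:
            raise ValidationError("scan_time must not precede injection_time")

    @property
    def uptake_minutes(self) -> float:
        """Minutes elapsed between injection and scan start."""
        return (self.scan_time - self.injection_time).total_seconds() / 60.0

    def to_dict(self) -> dict:
        return {
            "injected_activity_mbq": self.injected_activity_mbq,
            "injection_time": self.injection_time.isoformat(),
            "scan_time": self.scan_time.isoformat(),
            "body_weight_kg": self.body_weight_kg,
            "half_life_min": self.half_life_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            injected_activity_mbq=float(d["injected_activity_mbq"]),
            injection_time=_dt.datetime.fromisoformat(d["injection_time"]),
            scan_time=_dt.datetime.fromisoformat(d["scan_time"]),
            body_weight_kg=float(d["body_weight_kg"]),
            half_life_min=float(d.get("half_life_min", 109.77)),
        )


@dataclass
class TimepointEntry:
    """Paths + metadata for one scan of one patient."""

    pet_path: Path
    mask_path: Path
    meta: AcquisitionMeta


@dataclass
class StudyManifest:
    """One patient with early and late timepoints."""

    patient_id: str
    group: str  # benign | malignant | unknown
    early: TimepointEntry
    late: TimepointEntry

    def __post_init__(self) -> None:
        if self.group not in ("benign", "malignant", "unknown"):
            raise ValidationError(f"unknown group {self.group!r}")


# --------------------------------------------------------------------------
# NIfTI I/O


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, units: VolumeUnits = VolumeUnits.ARBITRARY) -> ScalarVolume:
    """Read a NIfTI-1 volume into a :class:`ScalarVolume`.

    Spacing and origin come from the header affine (axis-aligned part);
    non-finite voxels are rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # noqa: BLE001 - map all loader failures
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: volume contains NaN/Inf voxels")
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return ScalarVolume(data, spacing, origin, units)


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine_from(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VoiMask:
    vol = read_volume(path)
    arr = vol.data
    if not np.isin(np.unique(arr), [0, 1]).all():
        raise ValidationError(f"{path}: mask voxels must be 0 or 1")
    return VoiMask(arr.astype(bool), vol.spacing, vol.origin)


def write_mask(mask: VoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine_from(mask.spacing, mask.origin))
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Grid mapping


def map_mask_to_grid(mask: VoiMask, target: ScalarVolume) -> VoiMask:
    """Resample a mask onto ``target``'s grid by nearest neighbour.

    Each target voxel centre is located in the mask's physical frame and the
    nearest mask voxel decides fore/background, so binarity is preserved and
    a mask already living on the target grid maps to itself bit for bit.
    Raises if the tumour falls entirely outside the target field of view.
    """
    same_grid = (
        mask.data.shape == target.data.shape
        and np.allclose(mask.spacing, target.spacing)
        and np.allclose(mask.origin, target.origin)
    )
    if same_grid:
        return VoiMask(mask.data.copy(), target.spacing, target.origin)

    out = np.zeros(target.data.shape, dtype=bool)
    sp_t = np.asarray(target.spacing)
    sp_m = np.asarray(mask.spacing)
    org_t = np.asarray(target.origin)
    org_m = np.asarray(mask.origin)
    idx = [np.arange(n) for n in target.data.shape]
    # physical centre of each target voxel, per axis
    centres = [org_t[a] + idx[a] * sp_t[a] for a in range(3)]
    # nearest mask index per axis
    near = [np.rint((centres[a] - org_m[a]) / sp_m[a]).astype(int) for a in range(3)]
    valid = [(near[a] >= 0) & (near[a] < mask.data.shape[a]) for a in range(3)]
    ix, iy, iz = np.meshgrid(near[0], near[1], near[2], indexing="ij")
    vx, vy, vz = np.meshgrid(valid[0], valid[1], valid[2], indexing="ij")
    inside = vx & vy & vz
    out[inside] = mask.data[ix[inside], iy[inside], iz[inside]]
    if not out.any():
        raise ValidationError("tumour outside PET field of view: mapped mask is empty")
    return VoiMask(out, target.spacing, target.origin)


# --------------------------------------------------------------------------
# Manifests


def write_manifest(manifests: Sequence[StudyManifest], path: str | Path) -> None:
    records = []
    for m in manifests:
        records.append(
            {
                "patient_id": m.patient_id,
                "group": m.group,
                "early": {
                    "pet": str(m.early.pet_path),
                    "mask": str(m.early.mask_path),
                    "meta": m.early.meta.to_dict(),
                },
                "late": {
                    "pet": str(m.late.pet_path),
                    "mask": str(m.late.mask_path),
                    "meta": m.late.meta.to_dict(),
                },
            }
        )
    Path(path).write_text(json.dumps(records, indent=2))


def read_manifest(path: str | Path) -> list[StudyManifest]:
    base = Path(path).parent
    records = json.loads(Path(path).read_text())
    out = []
    for rec in records:
        entries = {}
        for tp in ("early", "late"):
            d = rec[tp]
            pet = Path(d["pet"])
            msk = Path(d["mask"])
            entries[tp] = TimepointEntry(
                pet_path=pet if pet.is_absolute() else base / pet,
                mask_path=msk if msk.is_absolute() else base / msk,
                meta=AcquisitionMeta.from_dict(d["meta"]),
            )
        out.append(
            StudyManifest(
                patient_id=str(rec["patient_id"]),
                group=rec.get("group", "unknown"),
                early=entries["early"],
                late=entries["late"],
            )
        )
    return out


# --------------------------------------------------------------------------
# Feature tables


ID_COLUMNS = ("patient_id", "timepoint", "group")


def feature_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-scan feature dicts into a table with the canonical
    99-feature column order.

    Every row must carry the identity keys and the same complete feature
    key set; a missing or extra feature name is a contract violation.
    """
    rows = list(rows)
    expected = set(ALL_FEATURES)
    for r in rows:
        keys = set(r) - set(ID_COLUMNS)
        if keys != expected:
            missing = sorted(expected - keys)[:5]
            extra = sorted(keys - expected)[:5]
            raise ValidationError(
                f"inconsistent feature key set (missing={missing}, extra={extra})"
            )
    cols = list(ID_COLUMNS) + list(ALL_FEATURES)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(rows: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = feature_frame(rows)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
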