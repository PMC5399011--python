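"""Paired early/late synthetic patient studies.

The generator emulates the data the dual-timepoint analysis expects: for
each synthetic patient an ellipsoidal tumour with spatially correlated
heterogeneous uptake is placed on a PET-like grid (4.7 x 4.7 x 3.27 mm
voxels), imaged at an early (~100 min post-injection) and a late
(~250 min) timepoint, with one of two kinetic behaviours:

* benign  -- multiplicative washout: late tumour uptake = w x early, w < 1;
* malignant -- focal intensification: the hottest decile of tumour voxels
  is multiplied by g > 1, leaving the rest unchanged, which raises the
  maximum and the skewness of the late histogram but not its bulk.

Uptake fields are expressed on an SUV-like scale and converted to activity
concentration at scan time using the physical decay of F-18, so SUV
conversion downstream recovers the uptake field exactly.  Heteroscedastic
Gaussian noise with variance proportional to local activity and to the
decay factor of the scan delay mimics the count loss of later scans, and
both volumes are smoothed with the reconstruction-like 6 mm FWHM Gaussian.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AcquisitionMeta,
    ScalarVolume,
    StudyManifest,
    TimepointEntry,
    VoiMask,
    VolumeUnits,
    write_manifest,
    write_mask,
    write_volume,
)
from .errors import ValidationError
from .preprocess import F18_HALF_LIFE_MIN, decay_factor, gaussian_fwhm_filter

_INJECTION_TIME = _dt.datetime(2016, 1, 1, 9, 0, 0)


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic paired cohort.

    Defaults mirror the clinical acquisition being emulated: a 54-patient
    cohort split 30 benign / 24 malignant, scans at 101.5 and 251.7 min
    post-injection of 350 MBq in a 70 kg patient, PET voxels of
    4.7 x 4.7 x 3.27 mm and 6 mm FWHM post-smoothing.
    """

    n_patients: int = 54
    benign_fraction: float = 30 / 54
    grid_shape: tuple[int, int, int] = (48, 48, 56)
    spacing: tuple[float, float, float] = (4.7, 4.7, 3.27)
    semi_axes_mm: tuple[float, float] = (10.0, 30.0)   # uniform range per axis
    base_uptake_suv: float = 2.0
    lognormal_sigma: float = 0.4
    background_suv: float = 0.2
    correlation_length_mm: float = 12.0
    washout_w: float = 0.8
    focal_gain_g: float = 1.5
    focal_fraction: float = 0.1
    noise_kappa: float = 20.0
    early_minutes: float = 101.5
    late_minutes: float = 251.7
    smoothing_fwhm_mm: float = 6.0
    injected_activity_mbq: float = 350.0
    body_weight_kg: float = 70.0
    half_life_min: float = F18_HALF_LIFE_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.benign_fraction < 1:
            raise ValidationError("benign_fraction must be in (0, 1)")
        if not 0 < self.washout_w <= 1:
            raise ValidationError("washout_w must be in (0, 1]")
        if self.focal_gain_g < 1:
            raise ValidationError("focal_gain_g must be >= 1")
        if self.early_minutes <= 0 or self.late_minutes <= 0:
            raise ValidationError("scan times must be positive")


@dataclass
class PatientPhantom:
    """In-memory paired study for one synthetic patient."""

    patient_id: str
    group: str
    early_volume: ScalarVolume        # activity concentration, Bq/ml
    late_volume: ScalarVolume
    mask: VoiMask
    early_meta: AcquisitionMeta
    late_meta: AcquisitionMeta


@dataclass
class GroundTruth:
    """True (pre-noise, pre-smoothing) cohort parameters."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_correlated_field(
    shape: tuple[int, int, int],
    correlation_length_mm: float,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field.

    White noise is smoothed by a Gaussian kernel whose sigma (in mm) is the
    requested correlation length, then renormalised by the theoretical
    post-smoothing standard deviation (the L2 norm of the kernel) so the
    marginal variance is 1 regardless of the correlation length.
    """
    if correlation_length_mm <= 0:
        raise ValidationError("correlation_length_mm must be > 0")
    from scipy import ndimage

    sigma_vox = tuple(correlation_length_mm / s for s in spacing)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    # L2 norm of the smoothing kernel = post-smoothing SD of unit white noise
    impulse = np.zeros(tuple(min(n, int(8 * sv) * 2 + 1) for n, sv in zip(shape, sigma_vox)))
    impulse[tuple(n // 2 for n in impulse.shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="constant")
    norm = np.sqrt((kernel**2).sum())
    return smooth / norm


def _ellipsoid_mask(
    shape, spacing, semi_axes_mm: tuple[float, float, float]
) -> np.ndarray:
    centre = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    ax = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, centre)]
    r2 = (
        (ax[0][:, None, None] / semi_axes_mm[0]) ** 2
        + (ax[1][None, :, None] / semi_axes_mm[1]) ** 2
        + (ax[2][None, None, :] / semi_axes_mm[2]) ** 2
    )
    return r2 <= 1.0


def _suv_to_activity_factor(minutes: float, spec: PhantomSpec) -> float:
    """Bq/ml per SUV unit at `minutes` post-injection."""
    a_decayed = spec.injected_activity_mbq * 1e6 / decay_factor(minutes, spec.half_life_min)
    return a_decayed / (spec.body_weight_kg * 1000.0)


def generate_patient(
    spec: PhantomSpec, group: str, patient_id: str, rng: np.random.Generator
) -> PatientPhantom:
    """Generate one paired early/late study."""
    axes = tuple(rng.uniform(*spec.semi_axes_mm) for _ in range(3))
    extent = [2 * a for a in axes]
    fov = [n * s for n, s in zip(spec.grid_shape, spec.spacing)]
    if any(e > f for e, f in zip(extent, fov)):
        raise ValidationError(f"tumour extent {extent} exceeds grid field of view {fov}")
    mask_arr = _ellipsoid_mask(spec.grid_shape, spec.spacing, axes)
    if not mask_arr.any():
        raise ValidationError("tumour smaller than one voxel")

    texture = generate_correlated_field(
        spec.grid_shape, spec.correlation_length_mm, spec.spacing, rng
    )
    uptake_early = np.full(spec.grid_shape, spec.background_suv)
    tumour_early = spec.base_uptake_suv * np.exp(spec.lognormal_sigma * texture[mask_arr])
    uptake_early[mask_arr] = tumour_early

    uptake_late = uptake_early.copy()
    if group == "benign":
        uptake_late[mask_arr] = tumour_early * spec.washout_w
        applied = spec.washout_w
    elif group == "malignant":
        tumour_late = tumour_early.copy()
        cutoff = np.quantile(tumour_early, 1.0 - spec.focal_fraction)
        hot = tumour_early >= cutoff
        tumour_late[hot] = tumour_early[hot] * spec.focal_gain_g
        uptake_late[mask_arr] = tumour_late
        applied = spec.focal_gain_g
    else:
        raise ValidationError(f"unknown group {group!r}")

    volumes = {}
    for tp, minutes, uptake in (
        ("early", spec.early_minutes, uptake_early),
        ("late", spec.late_minutes, uptake_late),
    ):
        factor = _suv_to_activity_factor(minutes, spec)
        activity = uptake * factor
        if spec.noise_kappa > 0:
            var = spec.noise_kappa * np.maximum(activity, 0.0) * decay_factor(
                minutes, spec.half_life_min
            )
            activity = activity + rng.standard_normal(spec.grid_shape) * np.sqrt(var)
        vol = ScalarVolume(activity, spec.spacing, units=VolumeUnits.ACTIVITY_BQ_ML)
        if spec.smoothing_fwhm_mm > 0:
            vol = gaussian_fwhm_filter(vol, spec.smoothing_fwhm_mm)
            vol.units = VolumeUnits.ACTIVITY_BQ_ML
        volumes[tp] = vol

    def _meta(minutes: float) -> AcquisitionMeta:
        return AcquisitionMeta(
            injected_activity_mbq=spec.injected_activity_mbq,
            injection_time=_INJECTION_TIME,
            scan_time=_INJECTION_TIME + _dt.timedelta(minutes=minutes),
            body_weight_kg=spec.body_weight_kg,
            half_life_min=spec.half_life_min,
        )

    return PatientPhantom(
        patient_id=patient_id,
        group=group,
        early_volume=volumes["early"],
        late_volume=volumes["late"],
        mask=VoiMask(mask_arr, spec.spacing),
        early_meta=_meta(spec.early_minutes),
        late_meta=_meta(spec.late_minutes),
    )


def simulate_cohort(spec: PhantomSpec) -> tuple[list[PatientPhantom], GroundTruth]:
    """Generate the full paired cohort in memory.

    Group sizes follow ``round(n_patients * benign_fraction)`` exactly
    (30 benign / 24 malignant at the defaults); per-patient randomness is
    drawn from independent child streams of the master seed.
    """
    n_benign = round(spec.n_patients * spec.benign_fraction)
    groups = ["benign"] * n_benign + ["malignant"] * (spec.n_patients - n_benign)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    patients = []
    truth_rows = []
    for i, (group, ss) in enumerate(zip(groups, seeds)):
        rng = np.random.default_rng(ss)
        pid = f"P{i + 1:03d}"
        p = generate_patient(spec, group, pid, rng)
        truth_rows.append(
            {
                "patient_id": pid,
                "group": group,
                "washout_or_gain": spec.washout_w if group == "benign" else spec.focal_gain_g,
                "tumour_voxels": p.mask.n_foreground,
            }
        )
        patients.append(p)
    return patients, GroundTruth(pd.DataFrame(truth_rows))


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> tuple[list[StudyManifest], GroundTruth]:
    """Generate the cohort and write NIfTI volumes + masks, a JSON manifest
    (``manifest.json``) and the ground-truth CSV to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients, truth = simulate_cohort(spec)
    manifests = []
    for p in patients:
        pdir = out_dir / p.patient_id
        pdir.mkdir(exist_ok=True)
        paths = {}
        for tp, vol in (("early", p.early_volume), ("late", p.late_volume)):
            vp = pdir / f"pet_{tp}.nii"
            write_volume(vol, vp)
            mp = pdir / f"mask_{tp}.nii"
            write_mask(p.mask, mp)
            paths[tp] = (vp, mp)
        manifests.append(
            StudyManifest(
                patient_id=p.patient_id,
                group=p.group,
                early=TimepointEntry(paths["early"][0], paths["early"][1], p.early_meta),
                late=TimepointEntry(paths["late"][0], paths["late"][1], p.late_meta),
            )
        )
    write_manifest(manifests, out_dir / "manifest.json")
    truth.table.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifests, truth
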