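"""Orchestration: manifest -> preprocessing -> 99 features -> statistics.

The pipeline turns a cohort of paired studies into the per-scan feature
table and the early-vs-late comparison report.  Degenerate feature values
are carried as flagged NaN, never silently dropped, so one pathological
lesion cannot abort a cohort run; scans that fail I/O are skipped with a
logged reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import ALL_FEATURES
from .core_io import (
    AcquisitionMeta,
    ScalarVolume,
    StudyManifest,
    VoiMask,
    VolumeUnits,
    feature_frame,
    map_mask_to_grid,
    read_manifest,
    read_mask,
    read_volume,
    write_feature_table,
)
from .errors import PetexError, ValidationError
from .firstorder import FeatureVector, roi_features, suv_features
from .fractal import fractal_features
from .phantom import PatientPhantom
from .preprocess import decay_corrected, quantize_voi, to_suv
from .stats import (
    build_comparison_table,
    comparison_frame,
    comparison_markdown,
    summarize_families,
    summary_frame,
)
from .texture import DEFAULT_DIRECTIONS, DEFAULT_DISTANCES, matrix_features

logger = logging.getLogger("petex")

ALL_FAMILIES = ("first", "second", "high", "fractal")


@dataclass
class PipelineConfig:
    """Resolved analysis settings; the defaults are the protocol settings
    the package implements (64 bins, LoG sigmas 1.5/2.0/2.5 mm, 7
    directions x 2 distances)."""

    n_bins: int = 64
    log_sigmas_mm: tuple[float, float, float] = (1.5, 2.0, 2.5)
    directions: tuple[tuple[int, int, int], ...] = DEFAULT_DIRECTIONS
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    connectivity: int = 26
    fractal_window_vox: int = 8
    fractal_box_sizes: tuple[int, ...] = (2, 4, 8)
    blanket_dilations: int = 5
    hurst_lags: int = 4
    half_life_min: float = 109.77
    alpha: float = 0.05
    zero_method: str = "wilcox"
    families: tuple[str, ...] = ALL_FAMILIES

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("log_sigmas_mm", "distances", "fractal_box_sizes", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "directions" in raw:
            raw["directions"] = tuple(tuple(d) for d in raw["directions"])
        return cls(**raw)


def extract_scan_features(
    volume: ScalarVolume,
    mask: VoiMask,
    meta: AcquisitionMeta,
    config: PipelineConfig | None = None,
    patient_id: str = "",
    timepoint: str = "",
) -> FeatureVector:
    """All 99 features (or the configured family subset) for one scan.

    ``volume`` must be in activity-concentration units on the PET grid;
    the mask is mapped onto that grid if needed.  Features of families not
    requested come back as NaN so every vector has the full key set.
    """
    config = config or PipelineConfig()
    mask = map_mask_to_grid(mask, volume)
    if mask.n_foreground == 0:
        raise ValidationError("mapped mask has no foreground voxels")

    fv = FeatureVector(patient_id=patient_id, timepoint=timepoint)
    fv.values = {name: float("nan") for name in ALL_FEATURES}

    dc = decay_corrected(volume, meta)
    suv = to_suv(volume, meta)

    if "first" in config.families:
        q_roi = quantize_voi(dc, mask, config.n_bins)
        vals, flags = roi_features(dc, mask, q_roi, config.log_sigmas_mm, config.n_bins)
        fv.values.update(vals)
        fv.flags.update(flags)
        q_suv = quantize_voi(suv, mask, config.n_bins)
        vals, flags = suv_features(suv, mask, q_suv)
        fv.values.update(vals)
        fv.flags.update(flags)

    if "second" in config.families or "high" in config.families:
        q = quantize_voi(dc, mask, config.n_bins)
        vals, flags = matrix_features(
            q, config.directions, config.distances, config.connectivity
        )
        wanted = set()
        if "second" in config.families:
            wanted.update(k for k in vals if k.startswith(("glcm_", "gldm_")))
        if "high" in config.families:
            wanted.update(k for k in vals if k.startswith(("glrl_", "glszm_", "ngtdm_")))
        fv.values.update({k: v for k, v in vals.items() if k in wanted})
        fv.flags.update({k: v for k, v in flags.items() if k in wanted or "_offset_" in k or "_direction_" in k})

    if "fractal" in config.families:
        vals, flags = fractal_features(
            dc,
            mask,
            config.fractal_window_vox,
            config.fractal_box_sizes,
            config.blanket_dilations,
            config.hurst_lags,
        )
        fv.values.update(vals)
        fv.flags.update(flags)

    return fv


def _iter_scans(study: StudyManifest | PatientPhantom):
    if isinstance(study, PatientPhantom):
        yield "early", study.early_volume, study.mask, study.early_meta
        yield "late", study.late_volume, study.mask, study.late_meta
    else:
        for tp in ("early", "late"):
            entry = getattr(study, tp)
            volume = read_volume(entry.pet_path, units=VolumeUnits.ACTIVITY_BQ_ML)
            mask = read_mask(entry.mask_path)
            yield tp, volume, mask, entry.meta


def extract_all_features(
    studies: Sequence[StudyManifest | PatientPhantom],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-scan feature table for a cohort (one row per patient and
    timepoint, 99 feature columns in catalogue order).

    A scan failing I/O or validation skips the whole patient with a logged
    reason; the pipeline continues with the remaining cohort.
    """
    config = config or PipelineConfig()
    rows = []
    for study in studies:
        patient_rows = []
        try:
            for tp, volume, mask, meta in _iter_scans(study):
                fv = extract_scan_features(
                    volume, mask, meta, config, patient_id=study.patient_id, timepoint=tp
                )
                row = {
                    "patient_id": study.patient_id,
                    "timepoint": tp,
                    "group": study.group,
                }
                row.update(fv.values)
                patient_rows.append(row)
                logger.debug("extracted %s/%s: %d features", study.patient_id, tp, len(fv.values))
        except PetexError as exc:
            logger.warning("skipping patient %s: %s", study.patient_id, exc)
            continue
        rows.extend(patient_rows)
    return feature_frame(rows)


def run_study(
    studies: Sequence[StudyManifest | PatientPhantom],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Full analysis: features, comparison table, family summary, markdown
    report and the resolved config, all written under ``out_dir``."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features = extract_all_features(studies, config)
    if features.empty:
        raise ValidationError("empty cohort: no scan produced features")
    table = build_comparison_table(
        features, alpha=config.alpha, zero_method=config.zero_method
    )
    summaries = summarize_families(table)

    paths = {
        "features": out_dir / "features.csv",
        "comparison": out_dir / "comparison.csv",
        "summary": out_dir / "family_summary.csv",
        "report": out_dir / "report.md",
        "config": out_dir / "config.yaml",
    }
    write_feature_table(features, paths["features"])
    comparison_frame(table).to_csv(paths["comparison"], index=False)
    summary_frame(summaries).to_csv(paths["summary"], index=False)
    paths["report"].write_text(comparison_markdown(table))
    paths["config"].write_text(yaml.safe_dump(config.to_dict()))
    return paths


def run_from_manifest(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    return run_study(read_manifest(manifest_path), out_dir, config)
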