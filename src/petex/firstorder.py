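"""First-order (histogram) features: 37 per scan.

Twenty "roi_*" statistics are computed on decay-corrected
activity-concentration values, the metabolic-volume pair on the mask
geometry, and seventeen "suv_*" statistics on SUV-converted values.
Moments use the population convention (divisor N) and kurtosis is
non-excess (a Gaussian scores 3).  Entropy/energy are taken over the
64-bin VOI histogram, in bits.

Degenerate inputs never raise: a zero-variance VOI yields skewness and
kurtosis 0, cv 0, and the affected names are recorded in the returned
flag map so downstream layers can carry them as flagged values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import ALL_FEATURES, FAMILY_OF
from .core_io import ScalarVolume, VoiMask
from .errors import ValidationError
from .preprocess import QuantizedVoi, extract_voi, log_filter, quantize

from scipy import ndimage


@dataclass
class FeatureVector:
    """Named feature values for one scan of one tumour."""

    patient_id: str
    timepoint: str
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def family(self, name: str) -> str:
        return FAMILY_OF[name]

    @property
    def complete(self) -> bool:
        return set(self.values) == set(ALL_FEATURES)


_STAT_KEYS = (
    "mean", "max", "min", "range", "sd", "skewness", "kurtosis", "cv",
    "median", "p10", "p25", "p75", "p90",
)


def firstorder_stats(values: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    """The thirteen moment/percentile statistics of a value list.

    Returns ``(stats, flags)``; flags mark degenerate definitions (zero
    variance, zero mean) rather than raising.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("firstorder_stats requires a non-empty value list")
    flags: dict[str, str] = {}
    vmax = float(values.max())
    vmin = float(values.min())
    # exact constancy check: the computed mean of a constant array can be
    # off by an ulp, which would leak a spurious tiny variance
    mean = vmin if vmin == vmax else float(values.mean())
    m2 = 0.0 if vmin == vmax else float(((values - mean) ** 2).mean())
    sd = math.sqrt(m2)
    if m2 == 0.0:
        skew = 0.0
        kurt = 0.0
        flags["skewness"] = flags["kurtosis"] = "zero_variance"
    else:
        m3 = float(((values - mean) ** 3).mean())
        m4 = float(((values - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    if sd == 0.0:
        cv = 0.0
        flags.setdefault("cv", "zero_variance")
    elif mean == 0.0:
        cv = float("nan")
        flags["cv"] = "zero_mean"
    else:
        cv = sd / mean
    p10, p25, p50, p75, p90 = np.percentile(values, [10, 25, 50, 75, 90])
    stats = {
        "mean": mean,
        "max": vmax,
        "min": vmin,
        "range": vmax - vmin,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "cv": cv,
        "median": float(p50),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
    }
    return stats, flags


def histogram_entropy_energy(q: QuantizedVoi) -> dict[str, float]:
    """Shannon entropy (bits) and energy of the binned VOI histogram."""
    p = q.occupancy()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    energy = float((p**2).sum())
    return {"entropy": entropy, "energy": energy}


def log_entropies(
    volume: ScalarVolume,
    mask: VoiMask,
    sigmas_mm: tuple[float, ...] = (1.5, 2.0, 2.5),
    n_bins: int = 64,
) -> dict[str, float]:
    """VOI entropy of the LoG response at each requested scale.

    The filter runs on the full volume (masked filtering would create edge
    artefacts), then the VOI response values are re-quantized to ``n_bins``
    and their histogram entropy taken.  Keys are e.g. ``log_entropy_1_5``.
    """
    out = {}
    for sigma in sigmas_mm:
        filtered = log_filter(volume, sigma)
        values, _ = extract_voi(filtered, mask)
        q = quantize(values, n_bins=n_bins)
        out[f"log_entropy_{str(sigma).replace('.', '_')}"] = histogram_entropy_energy(q)["entropy"]
    return out


def effective_diameter_cm(mav_cm3: float) -> float:
    """Diameter (cm) of the sphere whose volume equals ``mav_cm3``."""
    if mav_cm3 < 0:
        raise ValidationError("volume must be non-negative")
    return float((6.0 * mav_cm3 / math.pi) ** (1.0 / 3.0))


def volume_features(mask: VoiMask) -> dict[str, float]:
    """Metabolic active volume (cm^3) and effective diameter (cm)."""
    if mask.n_foreground == 0:
        raise ValidationError("empty mask has no metabolic volume")
    sx, sy, sz = mask.spacing
    mav = mask.n_foreground * sx * sy * sz / 1000.0
    return {"mav_cm3": mav, "effective_diameter_cm": effective_diameter_cm(mav)}


def suv_peak(suv_volume: ScalarVolume, mask: VoiMask, sphere_radius_mm: float = 6.2) -> float:
    """SUVpeak: highest sphere-averaged SUV over VOI voxels.

    The averaging sphere has a 1 cm^3 volume (radius 6.2 mm), is built in
    physical units on the anisotropic grid, and is clipped to the VOI.
    """
    if mask.n_foreground == 0:
        raise ValidationError("empty mask")
    sx, sy, sz = suv_volume.spacing
    rx = int(math.floor(sphere_radius_mm / sx))
    ry = int(math.floor(sphere_radius_mm / sy))
    rz = int(math.floor(sphere_radius_mm / sz))
    ax = np.arange(-rx, rx + 1) * sx
    ay = np.arange(-ry, ry + 1) * sy
    az = np.arange(-rz, rz + 1) * sz
    dist2 = ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
    kernel = (dist2 <= sphere_radius_mm**2).astype(float)
    fg = mask.data.astype(float)
    num = ndimage.convolve(suv_volume.data * fg, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(fg, kernel, mode="constant", cval=0.0)
    means = np.where(den > 0, num / np.maximum(den, 1e-300), -np.inf)
    return float(means[mask.data].max())


def roi_features(
    decay_corrected_volume: ScalarVolume,
    mask: VoiMask,
    q: QuantizedVoi,
    log_sigmas_mm: tuple[float, ...] = (1.5, 2.0, 2.5),
    n_bins: int = 64,
) -> tuple[dict[str, float], dict[str, str]]:
    """The 20 'roi_*' + metabolic-volume first-order features."""
    values, _ = extract_voi(decay_corrected_volume, mask)
    stats, st_flags = firstorder_stats(values)
    ee = histogram_entropy_energy(q)
    logs = log_entropies(decay_corrected_volume, mask, log_sigmas_mm, n_bins=n_bins)
    vol = volume_features(mask)
    out = {
        "roi_mean": stats["mean"],
        "roi_maximum": stats["max"],
        "roi_minimum": stats["min"],
        "roi_range": stats["range"],
        "roi_standard_deviation": stats["sd"],
        "roi_skewness": stats["skewness"],
        "roi_kurtosis": stats["kurtosis"],
        "roi_coefficient_of_variation": stats["cv"],
        "roi_median": stats["median"],
        "roi_10th_percentile": stats["p10"],
        "roi_25th_percentile": stats["p25"],
        "roi_75th_percentile": stats["p75"],
        "roi_90th_percentile": stats["p90"],
        "roi_entropy": ee["entropy"],
        "roi_energy": ee["energy"],
        "roi_log_entropy_1_5": logs[f"log_entropy_{str(log_sigmas_mm[0]).replace('.', '_')}"],
        "roi_log_entropy_2_0": logs[f"log_entropy_{str(log_sigmas_mm[1]).replace('.', '_')}"],
        "roi_log_entropy_2_5": logs[f"log_entropy_{str(log_sigmas_mm[2]).replace('.', '_')}"],
        "metabolic_active_volume_cm3": vol["mav_cm3"],
        "effective_diameter_cm": vol["effective_diameter_cm"],
    }
    flags = {f"roi_{k}": v for k, v in st_flags.items()}
    return out, flags


def suv_features(
    suv_volume: ScalarVolume,
    mask: VoiMask,
    q_suv: QuantizedVoi,
) -> tuple[dict[str, float], dict[str, str]]:
    """The 17 'suv_*' first-order features, including TLG and SUVpeak."""
    values, _ = extract_voi(suv_volume, mask)
    stats, st_flags = firstorder_stats(values)
    ee = histogram_entropy_energy(q_suv)
    vol = volume_features(mask)
    out = {
        "suv_mean": stats["mean"],
        "suv_total_lesion_glycolysis": stats["mean"] * vol["mav_cm3"],
        "suv_peak": suv_peak(suv_volume, mask),
        "suv_maximum": stats["max"],
        "suv_minimum": stats["min"],
        "suv_range": stats["range"],
        "suv_standard_deviation": stats["sd"],
        "suv_skewness": stats["skewness"],
        "suv_kurtosis": stats["kurtosis"],
        "suv_coefficient_of_variation": stats["cv"],
        "suv_median": stats["median"],
        "suv_10th_percentile": stats["p10"],
        "suv_25th_percentile": stats["p25"],
        "suv_75th_percentile": stats["p75"],
        "suv_90th_percentile": stats["p90"],
        "suv_entropy": ee["entropy"],
        "suv_energy": ee["energy"],
    }
    flags = {f"suv_{k}": v for k, v in st_flags.items()}
    return out, flags
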