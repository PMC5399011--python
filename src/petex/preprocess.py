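"""Everything between the raw PET volume and feature computation.

Covers decay correction back to injection time, body-weight SUV conversion,
VOI value extraction, 64-bin equal-width quantization of VOI intensities,
and the Gaussian / Laplacian-of-Gaussian filters used for smoothing and the
multi-scale LoG entropies.

Quantization is per scan and per VOI: bin edges span the VOI intensity
range of that scan, yielding ``n_bins`` equally spaced bins with the top
edge closed.  This makes every binned feature invariant under positive
affine intensity maps of a single scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import AcquisitionMeta, ScalarVolume, VoiMask, VolumeUnits
from .errors import ValidationError

#: 2 * sqrt(2 * ln 2) -- converts a Gaussian FWHM to its standard deviation
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

F18_HALF_LIFE_MIN = 109.77


def decay_factor(delta_t_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Multiplicative factor referring a measurement back to injection time.

    ``2 ** (delta_t / half_life)``: activity measured ``delta_t`` minutes
    after injection, multiplied by this factor, gives the activity the same
    source had at injection time.
    """
    if half_life_min <= 0:
        raise ValidationError("half_life_min must be > 0")
    if delta_t_min < 0:
        raise ValidationError("delta_t_min must be >= 0")
    return float(2.0 ** (delta_t_min / half_life_min))


def to_suv(volume: ScalarVolume, meta: AcquisitionMeta) -> ScalarVolume:
    """Convert an activity-concentration volume (Bq/ml) to body-weight SUV.

    SUV(v) = c(v) / (A_decayed / W) with the injected activity decayed to
    scan time and W the body weight in grams (tissue density 1 g/ml).
    """
    if volume.units != VolumeUnits.ACTIVITY_BQ_ML:
        raise ValidationError(
            f"SUV conversion requires activity concentration input, got units={volume.units}"
        )
    a_inj_bq = meta.injected_activity_mbq * 1e6
    a_decayed = a_inj_bq / decay_factor(meta.uptake_minutes, meta.half_life_min)
    weight_g = meta.body_weight_kg * 1000.0
    return volume.with_data(volume.data / (a_decayed / weight_g), units=VolumeUnits.SUV)


def decay_corrected(volume: ScalarVolume, meta: AcquisitionMeta) -> ScalarVolume:
    """Refer measured activity concentration back to injection time."""
    f = decay_factor(meta.uptake_minutes, meta.half_life_min)
    return volume.with_data(volume.data * f)


def extract_voi(volume: ScalarVolume, mask: VoiMask) -> tuple[np.ndarray, np.ndarray]:
    """Values and (N, 3) voxel indices of mask foreground, in lexicographic
    index order."""
    if volume.data.shape != mask.data.shape:
        raise ValidationError(
            f"volume grid {volume.data.shape} and mask grid {mask.data.shape} differ"
        )
    if mask.n_foreground == 0:
        raise ValidationError("empty mask: no VOI voxels to extract")
    idx = np.argwhere(mask.data)  # argwhere is lexicographic for C-ordered bool arrays
    values = volume.data[mask.data]
    return values, idx


@dataclass
class QuantizedVoi:
    """VOI voxels with intensities resampled to equally spaced bins.

    ``bin_values`` holds 1-based bin indices per VOI voxel (lexicographic
    order, matching ``values``); ``bin_grid`` is the VOI bounding-box
    sub-grid with 0 outside the VOI, used by the texture-matrix builders.
    """

    values: np.ndarray                 # raw values, one per VOI voxel
    bin_values: np.ndarray             # int bins 1..n_bins, same order
    edges: np.ndarray                  # n_bins + 1 edges (degenerate: 2)
    n_bins: int
    bin_grid: np.ndarray | None = None  # bbox grid, 0 = outside VOI
    spacing: tuple[float, float, float] | None = None
    bbox_offset: tuple[int, int, int] | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def occupancy(self) -> np.ndarray:
        """Occupied fraction per bin, length ``n_bins``, summing to 1."""
        counts = np.bincount(self.bin_values, minlength=self.n_bins + 1)[1:]
        return counts / counts.sum()


def quantize_values(values: np.ndarray, n_bins: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Map raw values to 1-based equal-width bins over [min, max].

    ``bin(v) = 1 + floor(n_bins * (v - vmin) / (vmax - vmin))`` with the
    maximum clamped into the top bin; a constant input degenerates to all
    bin 1 with edges [vmin, vmin].
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot quantize an empty value list")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64), np.array([vmin, vmin])
    bins = 1 + np.floor(n_bins * (values - vmin) / (vmax - vmin)).astype(np.int64)
    np.clip(bins, 1, n_bins, out=bins)
    edges = vmin + (vmax - vmin) * np.arange(n_bins + 1) / n_bins
    return bins, edges


def quantize(
    values: np.ndarray,
    n_bins: int = 64,
    indices: np.ndarray | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> QuantizedVoi:
    """Quantize VOI values; when voxel ``indices`` are supplied, also build
    the bounding-box bin grid needed by the matrix-based features."""
    bins, edges = quantize_values(values, n_bins)
    q = QuantizedVoi(
        values=np.asarray(values, dtype=float),
        bin_values=bins,
        edges=edges,
        n_bins=n_bins,
        spacing=spacing,
    )
    if indices is not None:
        indices = np.asarray(indices)
        lo = indices.min(axis=0)
        hi = indices.max(axis=0)
        grid = np.zeros(tuple(hi - lo + 1), dtype=np.int64)
        grid[tuple((indices - lo).T)] = bins
        q.bin_grid = grid
        q.bbox_offset = tuple(int(v) for v in lo)
    return q


def quantize_voi(volume: ScalarVolume, mask: VoiMask, n_bins: int = 64) -> QuantizedVoi:
    """Extract the VOI from ``volume`` and quantize it in one step."""
    values, indices = extract_voi(volume, mask)
    return quantize(values, n_bins=n_bins, indices=indices, spacing=volume.spacing)


def _sigma_voxels(sigma_mm: float, spacing) -> tuple[float, float, float]:
    return tuple(sigma_mm / s for s in spacing)


def gaussian_fwhm_filter(volume: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """3D Gaussian smoothing parameterised by full-width at half maximum.

    Per-axis sigma in voxels is ``(fwhm / 2.3548) / spacing`` so the kernel
    is isotropic in millimetres on anisotropic grids; reflect (zero-flux) boundaries.
    """
    if fwhm_mm <= 0:
        raise ValidationError("fwhm_mm must be > 0")
    sigma = _sigma_voxels(fwhm_mm / FWHM_TO_SIGMA, volume.spacing)
    out = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="reflect")
    return volume.with_data(out)


def log_filter(volume: ScalarVolume, sigma_mm: float) -> ScalarVolume:
    """Laplacian-of-Gaussian response at scale ``sigma_mm`` (mm).

    Anisotropy-aware (per-axis sigma in voxels), reflect (zero-flux) boundaries, so a
    constant volume maps to exactly zero.  Scales below a tenth of a voxel
    on any axis are rejected as numerically unstable.
    """
    if sigma_mm <= 0:
        raise ValidationError("sigma_mm must be > 0")
    sigma = _sigma_voxels(sigma_mm, volume.spacing)
    if min(sigma) < 0.1:
        raise ValidationError(
            f"LoG sigma {sigma_mm} mm is below 0.1 voxel on some axis (sigma_vox={sigma})"
        )
    smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="reflect")
    # discrete Laplacian in physical units (1/mm^2); exactly zero on
    # constants, unlike a sampled second-derivative Gaussian kernel at
    # sub-voxel sigma
    out = np.zeros_like(smoothed)
    for axis, sp in enumerate(volume.spacing):
        out += ndimage.correlate1d(
            smoothed, np.array([1.0, -2.0, 1.0]) / sp**2, axis=axis, mode="reflect"
        )
    return volume.with_data(out, units=VolumeUnits.ARBITRARY)
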