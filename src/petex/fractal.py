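"""Model-based (fractal) features of the tumour intensity field.

Six features are derived from the VOI bounding-box subvolume, treated as a
3D intensity "surface":

* ``fd_mean`` / ``fd_sd`` -- mean and SD of local fractal dimensions
  estimated by differential box counting (DBC) on a grid of windows tiling
  the bounding box; ``fd_inverse`` is the reciprocal of the mean.
* ``fd_lacunarity`` -- gliding-box lacunarity (second-moment ratio of box
  mass minus one), averaged over the box-size ladder.
* ``fd_blanket_mean`` -- Peleg blanket-method dimension, windowed and
  averaged like the DBC map.
* ``fd_hurst_exponent`` -- half the log-log slope of the isotropic
  variogram of the VOI intensities.

For DBC and the blanket method the subvolume intensities are rescaled to
[0, G-1] with G = 64 grey levels, the bounding box is padded by edge
replication to a multiple of the window size, and each window contributes
one local estimate.  A flat (constant) field gives a dimension of exactly
3 -- the topological dimension of the support -- for both estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import ScalarVolume, VoiMask
from .errors import ValidationError

DEFAULT_WINDOW_VOX = 8
DEFAULT_BOX_SIZES = (2, 4, 8)
DEFAULT_GREY_LEVELS = 64
DEFAULT_BLANKET_DILATIONS = 5
DEFAULT_HURST_LAGS = 4


@dataclass
class FdMap:
    """Per-window local fractal-dimension estimates."""

    estimates: np.ndarray       # flat array, one value per window
    window_vox: int
    box_sizes: tuple[int, ...]


def _bbox_subvolume(
    volume: ScalarVolume, mask: VoiMask, fill: str | None = None
) -> np.ndarray:
    """VOI bounding-box subvolume.

    ``fill="mean"`` replaces voxels outside the VOI by the VOI mean (used
    by the surface estimators so the mask boundary itself contributes no
    roughness); ``fill="zero"`` zeroes them (gliding-box mass); ``None``
    keeps the raw intensities.
    """
    if volume.data.shape != mask.data.shape:
        raise ValidationError("volume and mask grids differ")
    if mask.n_foreground == 0:
        raise ValidationError("empty mask")
    idx = np.argwhere(mask.data)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    box = tuple(slice(lo[a], hi[a]) for a in range(3))
    sub = volume.data[box].copy()
    if fill is not None:
        outside = ~mask.data[box]
        sub[outside] = volume.data[mask.data].mean() if fill == "mean" else 0.0
    return sub


def _rescale_grey(sub: np.ndarray, g: int = DEFAULT_GREY_LEVELS) -> np.ndarray:
    vmin = sub.min()
    vmax = sub.max()
    if vmax == vmin:
        return np.zeros_like(sub)
    return (sub - vmin) / (vmax - vmin) * (g - 1)


def _windows(sub: np.ndarray, window_vox: int) -> np.ndarray:
    """Pad to a multiple of the window size (edge replication) and return a
    (n_windows, w, w, w) stack of non-overlapping windows."""
    pads = [(0, (-s) % window_vox) for s in sub.shape]
    padded = np.pad(sub, pads, mode="edge")
    nx, ny, nz = (s // window_vox for s in padded.shape)
    w = window_vox
    stack = (
        padded.reshape(nx, w, ny, w, nz, w)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(nx * ny * nz, w, w, w)
    )
    return stack


def dbc_local_fd(
    volume: ScalarVolume,
    mask: VoiMask,
    window_vox: int = DEFAULT_WINDOW_VOX,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES,
    grey_levels: int = DEFAULT_GREY_LEVELS,
) -> FdMap:
    """Local fractal dimension by differential box counting.

    Per window and box size ``s`` the window is partitioned into s x s x s
    spatial columns; each column spans ``n_r = ceil(max/h) - ceil(min/h) + 1``
    intensity boxes of height ``h = s * G / window_vox``, and
    ``N_s = sum(n_r)``.  The local dimension is the least-squares slope of
    log N_s against log(1/s), which is 3 for a flat field and at most 4 by
    construction.
    """
    box_sizes = tuple(sorted(int(s) for s in box_sizes))
    if len(box_sizes) < 2:
        raise ValidationError("need at least 2 box sizes for the regression")
    if box_sizes[0] < 2 or box_sizes[-1] > window_vox:
        raise ValidationError("box sizes must satisfy 2 <= s <= window_vox")
    for s in box_sizes:
        if window_vox % s:
            raise ValidationError(f"box size {s} does not divide window size {window_vox}")
    sub = _rescale_grey(_bbox_subvolume(volume, mask, fill="mean"), grey_levels)
    stack = _windows(sub, window_vox)
    n_win = stack.shape[0]
    w = window_vox

    log_ns = np.empty((n_win, len(box_sizes)))
    for k, s in enumerate(box_sizes):
        m = w // s
        h = s * grey_levels / w
        blocks = stack.reshape(n_win, m, s, m, s, m, s)
        cmax = blocks.max(axis=(2, 4, 6))
        cmin = blocks.min(axis=(2, 4, 6))
        n_r = np.ceil(cmax / h) - np.ceil(cmin / h) + 1
        log_ns[:, k] = np.log(n_r.reshape(n_win, -1).sum(axis=1))
    x = np.log(1.0 / np.asarray(box_sizes, dtype=float))
    xc = x - x.mean()
    slopes = (log_ns - log_ns.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    if not np.all(np.isfinite(slopes)):
        raise ValidationError("non-finite local fractal dimension estimate")
    return FdMap(estimates=slopes, window_vox=window_vox, box_sizes=box_sizes)


def fd_summary(fd_map: FdMap) -> dict[str, float]:
    """Mean, population SD and reciprocal mean of the local FD estimates."""
    est = fd_map.estimates
    if est.size == 0:
        raise ValidationError("empty fractal-dimension map")
    mean = float(est.mean())
    return {
        "fd_mean": mean,
        "fd_sd": float(est.std()),
        "fd_inverse": 1.0 / mean,
    }


def lacunarity(
    volume: ScalarVolume,
    mask: VoiMask,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES,
) -> float:
    """Gliding-box lacunarity of the masked intensity field.

    For each box size the mass ``S`` (intensity sum) of every fully
    contained gliding box is collected and ``Lambda(s) = M2/M1**2 - 1``
    computed from its first two moments; the returned value is the mean
    over the box-size ladder.  Intensity-scale invariant; 0 for a constant
    field.
    """
    sub = _bbox_subvolume(volume, mask, fill="zero")
    lams = []
    for s in box_sizes:
        if any(dim < s for dim in sub.shape):
            continue
        view = np.lib.stride_tricks.sliding_window_view(sub, (s, s, s))
        masses = view.sum(axis=(3, 4, 5)).ravel()
        m1 = masses.mean()
        if m1 == 0:
            raise ValidationError("zero mean box mass; lacunarity undefined")
        lams.append(float((masses**2).mean() / m1**2 - 1.0))
    if not lams:
        raise ValidationError("VOI bounding box smaller than every box size")
    return float(np.mean(lams))


def blanket_fd(
    volume: ScalarVolume,
    mask: VoiMask,
    n_dilations: int = DEFAULT_BLANKET_DILATIONS,
    window_vox: int = DEFAULT_WINDOW_VOX,
    grey_levels: int = DEFAULT_GREY_LEVELS,
) -> float:
    """Peleg blanket-method fractal dimension, averaged over windows.

    Upper and lower blankets grow by iterated +-1 dilation/erosion with a
    6-neighbour structuring element; the surface area at scale ``e`` is
    ``A(e) = sum(u_e - l_e) / (2 e)`` and the dimension ``3 - slope`` of
    log A against log e.  A flat field keeps A constant, giving exactly 3.
    """
    if n_dilations < 2:
        raise ValidationError("need n_dilations >= 2 for the regression")
    sub = _rescale_grey(_bbox_subvolume(volume, mask, fill="mean"), grey_levels)
    stack = _windows(sub, window_vox)  # (n_win, w, w, w)
    footprint = ndimage.generate_binary_structure(3, 1)[None, :, :, :]
    upper = stack.astype(float)
    lower = stack.astype(float)
    n_win = stack.shape[0]
    areas = np.empty((n_win, n_dilations))
    for e in range(1, n_dilations + 1):
        upper = np.maximum(upper + 1.0, ndimage.grey_dilation(upper, footprint=footprint))
        lower = np.minimum(lower - 1.0, ndimage.grey_erosion(lower, footprint=footprint))
        areas[:, e - 1] = (upper - lower).reshape(n_win, -1).sum(axis=1) / (2.0 * e)
    x = np.log(np.arange(1, n_dilations + 1, dtype=float))
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValidationError("degenerate blanket regression")
    log_a = np.log(areas)
    slopes = (log_a - log_a.mean(axis=1, keepdims=True)) @ xc / denom
    return float(np.mean(3.0 - slopes))


def hurst_exponent(
    volume: ScalarVolume,
    mask: VoiMask,
    max_lag: int = DEFAULT_HURST_LAGS,
) -> tuple[float, str | None]:
    """Hurst exponent from the isotropic variogram of VOI intensities.

    Mean squared increments are pooled per lag over the three axes (lag
    distance in physical mm), and ``H = slope / 2`` of log variogram
    against log distance.  A constant field has zero increments and
    returns ``(0.0, "zero_increments")``.
    """
    if volume.data.shape != mask.data.shape:
        raise ValidationError("volume and mask grids differ")
    data = volume.data
    fg = mask.data
    spacing = np.asarray(volume.spacing)
    gammas: dict[float, list[tuple[float, int]]] = {}
    for axis in range(3):
        for lag in range(1, max_lag + 1):
            if data.shape[axis] <= lag:
                continue
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(0, data.shape[axis] - lag)
            sl_b[axis] = slice(lag, data.shape[axis])
            both = fg[tuple(sl_a)] & fg[tuple(sl_b)]
            if not both.any():
                continue
            d2 = (data[tuple(sl_b)][both] - data[tuple(sl_a)][both]) ** 2
            dist = lag * float(spacing[axis])
            gammas.setdefault(round(dist, 9), []).append((float(d2.sum()), int(d2.size)))
    pts = []
    for dist, chunks in gammas.items():
        total = sum(c[0] for c in chunks)
        count = sum(c[1] for c in chunks)
        gamma = total / count
        if gamma > 0:
            pts.append((np.log(dist), np.log(gamma)))
    if not pts:
        return 0.0, "zero_increments"
    if len(pts) < 2:
        raise ValidationError("fewer than 2 valid variogram lags")
    pts_arr = np.asarray(pts)
    x = pts_arr[:, 0]
    y = pts_arr[:, 1]
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    return slope / 2.0, None


def fractal_features(
    volume: ScalarVolume,
    mask: VoiMask,
    window_vox: int = DEFAULT_WINDOW_VOX,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES,
    blanket_dilations: int = DEFAULT_BLANKET_DILATIONS,
    hurst_lags: int = DEFAULT_HURST_LAGS,
) -> tuple[dict[str, float], dict[str, str]]:
    """All six model-based features of one scan."""
    flags: dict[str, str] = {}
    summary = fd_summary(dbc_local_fd(volume, mask, window_vox, box_sizes))
    out = {
        "fd_mean": summary["fd_mean"],
        "fd_sd": summary["fd_sd"],
        "fd_inverse": summary["fd_inverse"],
        "fd_lacunarity": lacunarity(volume, mask, box_sizes),
        "fd_blanket_mean": blanket_fd(volume, mask, blanket_dilations, window_vox),
    }
    h, flag = hurst_exponent(volume, mask, hurst_lags)
    out["fd_hurst_exponent"] = h
    if flag:
        flags["fd_hurst_exponent"] = flag
    return out, flags
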