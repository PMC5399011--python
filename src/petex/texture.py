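"""Second- and high-order texture features on the quantized VOI.

Five matrix constructs are computed from the binned VOI grid:

* GLCM  -- symmetric grey-level co-occurrence matrix per voxel offset,
  yielding 21 Haralick-style features.
* GLDM  -- grey-level *difference* histogram per offset (|bin - bin| of the
  same voxel pairs), yielding mean/entropy/variance/contrast.  By
  construction GLDM mean equals GLCM dissimilarity, GLDM contrast equals
  GLCM contrast and difference variance, and GLDM entropy equals GLCM
  difference entropy; these identities are regression-tested.
* GLRLM -- grey-level run-length matrix per direction (13 features).
* GLSZM -- grey-level size-zone matrix, 26-connected zones, orientation
  free (13 features).
* NGTDM -- neighbourhood grey-tone difference table, 26-neighbourhoods,
  orientation free (5 features).

Pairwise constructs (GLCM, GLDM) are built for 7 directions x 2 distances
(14 matrices) and the feature values averaged across matrices; GLRLM is
averaged over the 7 directions (runs are contiguous, so distance does not
apply).  Matrices with no valid pair (a VOI too thin for the offset) are
flagged empty and excluded from the average.

All logarithms are base 2 with the 0 log 0 := 0 convention; grey levels are
the 1-based bin indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .preprocess import QuantizedVoi

#: Canonical 7-direction reduction of the 13 unique 3D directions: the 3
#: axes, 3 face diagonals and the main body diagonal.
DEFAULT_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
)

DEFAULT_DISTANCES: tuple[int, ...] = (1, 2)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy_bits(p: np.ndarray) -> float:
    return float(-_xlog2(p).sum())


def _require_grid(q: QuantizedVoi) -> np.ndarray:
    if q.bin_grid is None:
        raise ValidationError("QuantizedVoi carries no spatial grid; quantize with voxel indices")
    return q.bin_grid


def _shifted_views(grid: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a, b) with b displaced from a by ``offset``."""
    sa, sb = [], []
    for n, o in zip(grid.shape, offset):
        if abs(o) >= n:
            empty = grid[tuple(slice(0, 0) for _ in grid.shape)]
            return empty, empty
        if o >= 0:
            sa.append(slice(0, n - o))
            sb.append(slice(o, n))
        else:
            sa.append(slice(-o, n))
            sb.append(slice(0, n + o))
    return grid[tuple(sa)], grid[tuple(sb)]


# --------------------------------------------------------------------------
# GLCM / GLDM


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray          # n_bins x n_bins, symmetric
    probabilities: np.ndarray   # counts / counts.sum()
    n_bins: int
    offset: tuple[int, int, int]
    empty: bool


def build_glcm(q: QuantizedVoi, offset) -> CooccurrenceMatrix:
    """Co-occurrence counts of in-VOI voxel pairs separated by ``offset``.

    Both voxels of a pair must lie inside the VOI; each pair increments the
    cell and its transpose, making the matrix symmetric by construction.
    """
    offset = tuple(int(o) for o in offset)
    if offset == (0, 0, 0):
        raise ValidationError("offset must be non-zero")
    grid = _require_grid(q)
    n = q.n_bins
    a, b = _shifted_views(grid, offset)
    valid = (a > 0) & (b > 0)
    counts = np.zeros((n, n), dtype=np.int64)
    if valid.any():
        ai = a[valid] - 1
        bi = b[valid] - 1
        flat = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
        counts = flat + flat.T
    total = counts.sum()
    empty = total == 0
    probs = counts / total if total else counts.astype(float)
    return CooccurrenceMatrix(counts, probs, n, offset, empty)


_GLCM_CONST_CACHE: dict[int, dict[str, np.ndarray]] = {}


def _glcm_constants(n: int) -> dict[str, np.ndarray]:
    """Index grids shared by every co-occurrence matrix of size n."""
    c = _GLCM_CONST_CACHE.get(n)
    if c is None:
        levels = np.arange(1, n + 1, dtype=float)
        I = levels[:, None]
        J = levels[None, :]
        diff_proj = np.zeros((n * n, n))
        diff_proj[np.arange(n * n), np.abs(I - J).astype(int).ravel()] = 1.0
        sum_proj = np.zeros((n * n, 2 * n - 1))
        sum_proj[np.arange(n * n), (I + J).astype(int).ravel() - 2] = 1.0
        c = {
            "levels": levels,
            "IJ": I * J,
            "diff_proj": diff_proj,
            "sum_proj": sum_proj,
            "d": np.arange(n, dtype=float),
            "k": np.arange(2, 2 * n + 1, dtype=float),
            "inv_moment": 1.0 / (1.0 + (I - J) ** 2),
            "inv_moment_norm": 1.0 / (1.0 + ((I - J) / n) ** 2),
            "inv_diff_norm": 1.0 / (1.0 + np.abs(I - J) / n),
        }
        _GLCM_CONST_CACHE[n] = c
    return c


def _xlog2_sum(p: np.ndarray, axis: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return t.sum(axis=axis)


def _glcm_features_batch(P: np.ndarray, n: int) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """The 21 co-occurrence features for a (m, n, n) stack of normalized
    symmetric matrices; returns per-feature arrays of length m and the
    boolean mask of matrices with a zero-variance marginal (their
    correlation is set to 0)."""
    c = _glcm_constants(n)
    m = P.shape[0]
    flat = P.reshape(m, -1)
    px = P.sum(axis=2)                      # (m, n); symmetric: px == py
    mu = (c["levels"] * px).sum(axis=1)
    sigma2 = ((c["levels"][None, :] - mu[:, None]) ** 2 * px).sum(axis=1)

    p_diff = flat @ c["diff_proj"]
    p_sum = flat @ c["sum_proj"]

    autocorrelation = (c["IJ"].ravel() * flat).sum(axis=1)
    contrast = (c["d"] ** 2 * p_diff).sum(axis=1)
    dissimilarity = (c["d"] * p_diff).sum(axis=1)
    zero_var = sigma2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(zero_var, 0.0, (autocorrelation - mu * mu) / np.where(zero_var, 1.0, sigma2))
    centred = c["k"][None, :] - 2 * mu[:, None]
    cluster_shade = (centred**3 * p_sum).sum(axis=1)
    cluster_prominence = (centred**4 * p_sum).sum(axis=1)
    energy = (flat**2).sum(axis=1)
    entropy = -_xlog2_sum(flat, axis=1)
    homogeneity = (c["inv_moment"].ravel() * flat).sum(axis=1)
    idmn = (c["inv_moment_norm"].ravel() * flat).sum(axis=1)
    idn = (c["inv_diff_norm"].ravel() * flat).sum(axis=1)
    max_probability = flat.max(axis=1)
    sum_average = (c["k"] * p_sum).sum(axis=1)
    sum_entropy = -_xlog2_sum(p_sum, axis=1)
    sum_of_squares = ((c["levels"][None, :] - mu[:, None]) ** 2 * px).sum(axis=1)
    sum_variance = ((c["k"][None, :] - sum_average[:, None]) ** 2 * p_sum).sum(axis=1)
    difference_entropy = -_xlog2_sum(p_diff, axis=1)

    # information measures of correlation, log base 2 throughout
    outer = px[:, :, None] * px[:, None, :]
    outer_flat = outer.reshape(m, -1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_outer = np.where(outer_flat > 0, np.log2(np.where(outer_flat > 0, outer_flat, 1.0)), 0.0)
    hxy1 = -(flat * log_outer).sum(axis=1)
    hxy2 = -(outer_flat * log_outer).sum(axis=1)
    hx = -_xlog2_sum(px, axis=1)
    single_level = hx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        imc1 = np.where(single_level, 0.0, (entropy - hxy1) / np.where(single_level, 1.0, hx))
    imc2 = np.sqrt(np.maximum(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy))))

    values = {
        "glcm_autocorrelation": autocorrelation,
        "glcm_cluster_prominence": cluster_prominence,
        "glcm_cluster_shade": cluster_shade,
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_difference_entropy": difference_entropy,
        "glcm_difference_variance": contrast.copy(),
        "glcm_dissimilarity": dissimilarity,
        "glcm_energy": energy,
        "glcm_entropy": entropy,
        "glcm_homogeneity": homogeneity,
        "glcm_information_measure_correlation_1": imc1,
        "glcm_information_measure_correlation_2": imc2,
        "glcm_inverse_difference_moment": homogeneity.copy(),
        "glcm_inverse_difference_moment_normalised": idmn,
        "glcm_inverse_difference_normalised": idn,
        "glcm_maximum_probability": max_probability,
        "glcm_sum_average": sum_average,
        "glcm_sum_entropy": sum_entropy,
        "glcm_sum_of_squares_variance": sum_of_squares,
        "glcm_sum_variance": sum_variance,
    }
    return values, zero_var


def glcm_features(m: CooccurrenceMatrix) -> tuple[dict[str, float], dict[str, str]]:
    """The 21 co-occurrence features of a normalized symmetric matrix."""
    if m.empty:
        raise ValidationError("cannot compute features of an empty co-occurrence matrix")
    batch, zero_var = _glcm_features_batch(m.probabilities[None, :, :], m.n_bins)
    flags: dict[str, str] = {}
    if zero_var[0]:
        flags["glcm_correlation"] = "zero_variance_marginal"
    return {k: float(v[0]) for k, v in batch.items()}, flags


@dataclass
class DifferenceHistogram:
    counts: np.ndarray   # length n_bins, index = |bin difference|
    probabilities: np.ndarray
    n_bins: int
    offset: tuple[int, int, int]
    empty: bool


def build_gldm(q: QuantizedVoi, offset) -> DifferenceHistogram:
    """Histogram of absolute bin differences of in-VOI pairs at ``offset``."""
    offset = tuple(int(o) for o in offset)
    if offset == (0, 0, 0):
        raise ValidationError("offset must be non-zero")
    grid = _require_grid(q)
    n = q.n_bins
    a, b = _shifted_views(grid, offset)
    valid = (a > 0) & (b > 0)
    counts = np.zeros(n, dtype=np.int64)
    if valid.any():
        counts = np.bincount(np.abs(a[valid] - b[valid]), minlength=n)[:n]
    total = counts.sum()
    empty = total == 0
    probs = counts / total if total else counts.astype(float)
    return DifferenceHistogram(counts, probs, n, offset, empty)


def gldm_features(h: DifferenceHistogram) -> dict[str, float]:
    if h.empty:
        raise ValidationError("cannot compute features of an empty difference histogram")
    p = h.probabilities
    d = np.arange(p.size, dtype=float)
    mean = float((d * p).sum())
    return {
        "gldm_mean": mean,
        "gldm_entropy": _entropy_bits(p),
        "gldm_variance": float(((d - mean) ** 2 * p).sum()),
        "gldm_contrast": float((d**2 * p).sum()),
    }


# --------------------------------------------------------------------------
# GLRLM


@dataclass
class RunLengthMatrix:
    counts: np.ndarray   # n_bins x max_run_length
    n_bins: int
    direction: tuple[int, int, int]
    n_voxels: int        # VOI voxels (run-length weighted column sum equals this)
    empty: bool

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def _shift_fill(arr: np.ndarray, offset, fill) -> np.ndarray:
    """Array whose element at v equals arr[v + offset], ``fill`` outside."""
    out = np.full_like(arr, fill)
    a, b = _shifted_views(arr, offset)
    sa = tuple(
        slice(0, n - o) if o >= 0 else slice(-o, n)
        for n, o in zip(arr.shape, offset)
    )
    if a.size:
        out[sa] = b
    return out


def build_glrlm(q: QuantizedVoi, direction) -> RunLengthMatrix:
    """Run-length counts along ``direction`` (unit steps, VOI-confined).

    A run is a maximal sequence of same-bin voxels along the direction; a
    gap in the VOI terminates a run.
    """
    direction = tuple(int(d) for d in direction)
    if direction == (0, 0, 0):
        raise ValidationError("direction must be non-zero")
    grid = _require_grid(q)
    n = q.n_bins
    fg = grid > 0

    nxt = _shift_fill(grid, direction, 0)
    same_next = fg & (nxt == grid) & (nxt > 0)

    # run length ahead of each voxel: f = 1 + f(v+d) when the next voxel
    # continues the run; computed by a reverse sweep along the primary axis
    axis = next(a for a in range(3) if direction[a] != 0)
    step = direction[axis]
    inplane = list(direction)
    inplane[axis] = 0
    inplane = tuple(inplane)

    f = np.zeros_like(grid)
    order = range(grid.shape[axis] - 1, -1, -1) if step > 0 else range(grid.shape[axis])
    sl = [slice(None)] * 3
    for t in order:
        sl[axis] = t
        t_next = t + step
        plane_fg = fg[tuple(sl)]
        plane_same = same_next[tuple(sl)]
        if 0 <= t_next < grid.shape[axis]:
            sln = list(sl)
            sln[axis] = t_next
            nb = _shift_fill(f[tuple(sln)], tuple(o for a2, o in enumerate(inplane) if a2 != axis), 0)
        else:
            nb = np.zeros_like(plane_fg, dtype=f.dtype)
        f[tuple(sl)] = np.where(plane_fg, np.where(plane_same, nb + 1, 1), 0)

    prev = _shift_fill(grid, tuple(-d for d in direction), 0)
    prev_same = (prev == grid) & (prev > 0)
    starts = fg & ~prev_same
    levels = grid[starts] - 1
    lengths = f[starts]
    n_vox = int(fg.sum())
    if levels.size == 0:
        return RunLengthMatrix(np.zeros((n, 1), dtype=np.int64), n, direction, n_vox, True)
    max_len = int(lengths.max())
    counts = np.bincount(levels * max_len + (lengths - 1), minlength=n * max_len)
    counts = counts.reshape(n, max_len)
    return RunLengthMatrix(counts, n, direction, n_vox, False)


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """The 13 run-length features (Galloway/Chu conventions).

    'Intensity variability' and 'run length variability' are the population
    variances of the grey-level and run-length marginal run counts."""
    if m.empty:
        raise ValidationError("cannot compute features of an empty run-length matrix")
    r = m.counts.astype(float)
    nr = r.sum()
    i = np.arange(1, m.n_bins + 1, dtype=float)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    g_marg = r.sum(axis=1)
    l_marg = r.sum(axis=0)
    return {
        "glrl_short_run_emphasis": float((r / j**2).sum() / nr),
        "glrl_long_run_emphasis": float((r * j**2).sum() / nr),
        "glrl_grey_level_nonuniformity": float((g_marg**2).sum() / nr),
        "glrl_run_length_nonuniformity": float((l_marg**2).sum() / nr),
        "glrl_run_percentage": float(nr / m.n_voxels),
        "glrl_low_grey_level_run_emphasis": float((r / i**2).sum() / nr),
        "glrl_high_grey_level_run_emphasis": float((r * i**2).sum() / nr),
        "glrl_short_run_low_grey_level_emphasis": float((r / (i**2 * j**2)).sum() / nr),
        "glrl_short_run_high_grey_level_emphasis": float((r * i**2 / j**2).sum() / nr),
        "glrl_long_run_low_grey_level_emphasis": float((r * j**2 / i**2).sum() / nr),
        "glrl_long_run_high_grey_level_emphasis": float((r * i**2 * j**2).sum() / nr),
        "glrl_intensity_variability": float(g_marg.var()),
        "glrl_run_length_variability": float(l_marg.var()),
    }


# --------------------------------------------------------------------------
# GLSZM


@dataclass
class SizeZoneMatrix:
    counts: np.ndarray   # n_bins x max_zone_size
    n_bins: int
    n_voxels: int

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())


def build_glszm(q: QuantizedVoi, connectivity: int = 26) -> SizeZoneMatrix:
    """Size-zone counts: connected components of equal-bin VOI voxels."""
    grid = _require_grid(q)
    n = q.n_bins
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")
    n_vox = int((grid > 0).sum())
    if n_vox == 0:
        raise ValidationError("empty VOI")
    records: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for level in np.unique(grid[grid > 0]):
        labeled, n_zones = ndimage.label(grid == level, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        records.append((int(level) - 1, sizes))
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((n, max_size), dtype=np.int64)
    for lev, sizes in records:
        counts[lev] += np.bincount(sizes - 1, minlength=max_size)
    return SizeZoneMatrix(counts, n, n_vox)


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    """The 13 size-zone features (Thibault conventions); the two
    'variability' features are population variances of the marginal zone
    counts."""
    z = m.counts.astype(float)
    nz = z.sum()
    i = np.arange(1, m.n_bins + 1, dtype=float)[:, None]
    s = np.arange(1, z.shape[1] + 1, dtype=float)[None, :]
    g_marg = z.sum(axis=1)
    s_marg = z.sum(axis=0)
    return {
        "glszm_short_zone_emphasis": float((z / s**2).sum() / nz),
        "glszm_long_zone_emphasis": float((z * s**2).sum() / nz),
        "glszm_intensity_nonuniformity": float((g_marg**2).sum() / nz),
        "glszm_zone_length_nonuniformity": float((s_marg**2).sum() / nz),
        "glszm_zone_percentage": float(nz / m.n_voxels),
        "glszm_low_intensity_zone_emphasis": float((z / i**2).sum() / nz),
        "glszm_high_intensity_zone_emphasis": float((z * i**2).sum() / nz),
        "glszm_short_zone_low_intensity_emphasis": float((z / (i**2 * s**2)).sum() / nz),
        "glszm_short_zone_high_intensity_emphasis": float((z * i**2 / s**2).sum() / nz),
        "glszm_long_zone_low_intensity_emphasis": float((z * s**2 / i**2).sum() / nz),
        "glszm_long_zone_high_intensity_emphasis": float((z * i**2 * s**2).sum() / nz),
        "glszm_intensity_variability": float(g_marg.var()),
        "glszm_size_zone_variability": float(s_marg.var()),
    }


# --------------------------------------------------------------------------
# NGTDM


@dataclass
class NgtdmTable:
    p: np.ndarray        # occupancy fraction per grey level (length n_bins)
    s: np.ndarray        # summed |level - neighbourhood mean| per level
    n_valid: int         # voxels with at least one VOI neighbour
    n_bins: int
    empty: bool


def build_ngtdm(q: QuantizedVoi, connectivity: int = 26) -> NgtdmTable:
    """Per-level occupancy and summed deviation from the neighbourhood
    mean (neighbourhood = 26-neighbours intersected with the VOI)."""
    grid = _require_grid(q)
    n = q.n_bins
    if connectivity == 26:
        kernel = np.ones((3, 3, 3))
    elif connectivity == 6:
        kernel = ndimage.generate_binary_structure(3, 1).astype(float)
    else:
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")
    kernel[1, 1, 1] = 0.0
    fg = (grid > 0).astype(float)
    nb_sum = ndimage.correlate(grid.astype(float) * fg, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(fg, kernel, mode="constant", cval=0.0)
    valid = (grid > 0) & (nb_cnt > 0.5)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return NgtdmTable(np.zeros(n), np.zeros(n), 0, n, True)
    levels = grid[valid]
    dev = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    counts = np.bincount(levels - 1, minlength=n)[:n]
    s = np.bincount(levels - 1, weights=dev, minlength=n)[:n]
    return NgtdmTable(counts / n_valid, s, n_valid, n, False)


def ngtdm_features(t: NgtdmTable, eps: float = 1e-12) -> dict[str, float]:
    """Amadasun-King coarseness, contrast, busyness, complexity, strength."""
    if t.empty:
        raise ValidationError("cannot compute features of an empty NGTDM table")
    occupied = t.p > 0
    p = t.p[occupied]
    s = t.s[occupied]
    levels = np.arange(1, t.n_bins + 1, dtype=float)[occupied]
    ngp = int(occupied.sum())
    n_valid = t.n_valid

    coarseness = min(1.0 / (eps + float((p * s).sum())), 1e12)

    if ngp > 1:
        pi = p[:, None]
        pj = p[None, :]
        li = levels[:, None]
        lj = levels[None, :]
        contrast = float((pi * pj * (li - lj) ** 2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / n_valid
        busy_den = float(np.abs(li * pi - lj * pj).sum())
        busy_num = float((p * s).sum())
        busyness = busy_num / busy_den if busy_den > 0 else 0.0
        ps = p * s
        complexity = float(
            (np.abs(li - lj) * (ps[:, None] + ps[None, :]) / (pi + pj)).sum()
        ) / n_valid
        strength = float(((pi + pj) * (li - lj) ** 2).sum()) / (eps + float(s.sum()))
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_texture_strength": strength,
    }


# --------------------------------------------------------------------------
# Directional averaging and the combined feature set


def average_directional(
    q: QuantizedVoi,
    directions: tuple[tuple[int, int, int], ...] = DEFAULT_DIRECTIONS,
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
) -> tuple[dict[str, float], dict[str, str]]:
    """GLCM + GLDM features averaged over directions x distances, and
    GLRLM features averaged over directions (unit step).

    Empty matrices (no valid pair along an offset) are excluded from the
    mean; a family whose matrices are all empty comes back as NaN with a
    flag.
    """
    flags: dict[str, str] = {}
    glcm_acc: dict[str, list[float]] = {}
    stacks = []
    for direction in directions:
        for dist in distances:
            offset = tuple(dist * c for c in direction)
            m = build_glcm(q, offset)
            if m.empty:
                flags[f"glcm_offset_{offset}"] = "empty_matrix_excluded"
                continue
            stacks.append(m.probabilities)
            for k, v in gldm_features(build_gldm(q, offset)).items():
                glcm_acc.setdefault(k, []).append(v)
    if stacks:
        batch, zero_var = _glcm_features_batch(np.stack(stacks), q.n_bins)
        if zero_var.any():
            flags["glcm_correlation"] = "zero_variance_marginal"
        for k, v in batch.items():
            glcm_acc[k] = list(v)

    glrl_acc: dict[str, list[float]] = {}
    for direction in directions:
        m = build_glrlm(q, direction)
        if m.empty:
            flags[f"glrl_direction_{direction}"] = "empty_matrix_excluded"
            continue
        for k, v in glrlm_features(m).items():
            glrl_acc.setdefault(k, []).append(v)

    out: dict[str, float] = {}
    from .catalog import GLCM_FEATURES, GLDM_FEATURES, GLRL_FEATURES

    for name in GLCM_FEATURES + GLDM_FEATURES:
        if name in glcm_acc:
            out[name] = float(np.mean(glcm_acc[name]))
        else:
            out[name] = float("nan")
            flags[name] = "all_matrices_empty"
    for name in GLRL_FEATURES:
        if name in glrl_acc:
            out[name] = float(np.mean(glrl_acc[name]))
        else:
            out[name] = float("nan")
            flags[name] = "all_matrices_empty"
    return out, flags


def matrix_features(
    q: QuantizedVoi,
    directions: tuple[tuple[int, int, int], ...] = DEFAULT_DIRECTIONS,
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
    connectivity: int = 26,
) -> tuple[dict[str, float], dict[str, str]]:
    """All 56 second- and high-order features of one quantized VOI."""
    out, flags = average_directional(q, directions, distances)
    out.update(glszm_features(build_glszm(q, connectivity)))
    ngt = build_ngtdm(q, connectivity)
    if ngt.empty:
        from .catalog import NGTDM_FEATURES

        for name in NGTDM_FEATURES:
            out[name] = float("nan")
            flags[name] = "no_voxel_with_neighbours"
    else:
        out.update(ngtdm_features(ngt))
    return out, flags
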