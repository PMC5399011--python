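"""Naive reference implementations used as independent oracles.

Everything here is written as plain triple loops / flood fills straight
from the textbook definitions, with no shared code with the package's
optimized builders.
"""

from __future__ import annotations

import numpy as np


def naive_glcm(bin_grid: np.ndarray, offset, n_bins: int) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    nx, ny, nz = bin_grid.shape
    ox, oy, oz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = bin_grid[x, y, z]
                if a == 0:
                    continue
                x2, y2, z2 = x + ox, y + oy, z + oz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                b = bin_grid[x2, y2, z2]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def naive_gldm(bin_grid: np.ndarray, offset, n_bins: int) -> np.ndarray:
    """Histogram of |bin difference| over in-VOI pairs."""
    counts = np.zeros(n_bins, dtype=np.int64)
    nx, ny, nz = bin_grid.shape
    ox, oy, oz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = bin_grid[x, y, z]
                if a == 0:
                    continue
                x2, y2, z2 = x + ox, y + oy, z + oz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                b = bin_grid[x2, y2, z2]
                if b == 0:
                    continue
                counts[abs(a - b)] += 1
    return counts


def naive_glrlm(bin_grid: np.ndarray, direction, n_bins: int) -> np.ndarray:
    """Run-length counts by walking every line in the given direction."""
    nx, ny, nz = bin_grid.shape
    d = tuple(direction)
    runs: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                # start of a run: previous voxel along -d missing or different
                px, py, pz = x - d[0], y - d[1], z - d[2]
                a = bin_grid[x, y, z]
                if a == 0:
                    continue
                if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz and bin_grid[px, py, pz] == a:
                    continue
                length = 1
                cx, cy, cz = x + d[0], y + d[1], z + d[2]
                while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz and bin_grid[cx, cy, cz] == a:
                    length += 1
                    cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                runs.append((a, length))
    if not runs:
        return np.zeros((n_bins, 1), dtype=np.int64)
    max_len = max(l for _, l in runs)
    counts = np.zeros((n_bins, max_len), dtype=np.int64)
    for level, length in runs:
        counts[level - 1, length - 1] += 1
    return counts


def naive_glszm(bin_grid: np.ndarray, n_bins: int, connectivity: int = 26) -> np.ndarray:
    """Size-zone counts by breadth-first flood fill."""
    nx, ny, nz = bin_grid.shape
    if connectivity == 26:
        neigh = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(bin_grid, dtype=bool)
    zones: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if bin_grid[x, y, z] == 0 or seen[x, y, z]:
                    continue
                level = bin_grid[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        wx, wy, wz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= wx < nx and 0 <= wy < ny and 0 <= wz < nz
                            and not seen[wx, wy, wz]
                            and bin_grid[wx, wy, wz] == level
                        ):
                            seen[wx, wy, wz] = True
                            stack.append((wx, wy, wz))
                zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((n_bins, max_size), dtype=np.int64)
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


def naive_ngtdm(bin_grid: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occupancy fraction and summed deviation from the
    26-neighbourhood mean; returns (p, s, n_valid)."""
    nx, ny, nz = bin_grid.shape
    counts = np.zeros(n_bins)
    s = np.zeros(n_bins)
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = bin_grid[x, y, z]
                if a == 0:
                    continue
                vals = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            wx, wy, wz = x + dx, y + dy, z + dz
                            if 0 <= wx < nx and 0 <= wy < ny and 0 <= wz < nz and bin_grid[wx, wy, wz] > 0:
                                vals.append(bin_grid[wx, wy, wz])
                if not vals:
                    continue
                n_valid += 1
                counts[a - 1] += 1
                s[a - 1] += abs(a - sum(vals) / len(vals))
    p = counts / n_valid if n_valid else counts
    return p, s, n_valid


def naive_mask_mapping(mask_data, mask_spacing, mask_origin, target_shape, target_spacing, target_origin):
    """Per-voxel nearest-neighbour containment check for mask resampling."""
    out = np.zeros(target_shape, dtype=bool)
    for x in range(target_shape[0]):
        for y in range(target_shape[1]):
            for z in range(target_shape[2]):
                pos = [
                    target_origin[a] + (x, y, z)[a] * target_spacing[a]
                    for a in range(3)
                ]
                near = [round((pos[a] - mask_origin[a]) / mask_spacing[a]) for a in range(3)]
                if all(0 <= near[a] < mask_data.shape[a] for a in range(3)):
                    out[x, y, z] = mask_data[near[0], near[1], near[2]]
    return out
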