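"""Independent brute-force oracles for the matrix-based texture metrics.

Deliberately naive (python loops, explicit pair/zone enumeration) so they
share no code path with the package implementations they check.
"""

from __future__ import annotations

import math
from collections import Counter, deque

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def brute_glcm(bin_grid: np.ndarray, mask: np.ndarray):
    """Symmetric co-occurrence probabilities by explicit pair enumeration."""
    counts: Counter = Counter()
    nx, ny, nz = bin_grid.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in OFFSETS_13:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        a, b = int(bin_grid[x, y, z]), int(bin_grid[u, v, w])
                        counts[(a, b)] += 1
                        counts[(b, a)] += 1
    total = sum(counts.values())
    return {pair: c / total for pair, c in counts.items()} if total else {}


def brute_glcm_features(bin_grid, mask):
    p = brute_glcm(bin_grid, mask)
    homog = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    ent = -sum(v * math.log2(v) for v in p.values() if v > 0)
    dis = sum(v * abs(i - j) for (i, j), v in p.items())
    return {"glcm_homogeneity": homog, "glcm_entropy": ent, "glcm_dissimilarity": dis}


def brute_coarseness(bin_grid, mask, eps=1e-6):
    """NGTDM coarseness by per-voxel neighbourhood averaging."""
    nx, ny, nz = bin_grid.shape
    diffs = {}  # bin level -> summed |i - neighbourhood mean|
    counts: Counter = Counter()
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nb = []
                for dx, dy, dz in OFFSETS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        nb.append(int(bin_grid[u, v, w]))
                if not nb:
                    continue
                n_valid += 1
                lvl = int(bin_grid[x, y, z])
                counts[lvl] += 1
                diffs[lvl] = diffs.get(lvl, 0.0) + abs(lvl - sum(nb) / len(nb))
    if n_valid == 0:
        return None
    total = sum((counts[lvl] / n_valid) * diffs[lvl] for lvl in counts)
    return 1.0 / (eps + total)


def brute_zones(bin_grid, mask):
    """26-connected equal-bin zones via breadth-first flood fill."""
    nx, ny, nz = bin_grid.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lvl = int(bin_grid[x, y, z])
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in OFFSETS_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                            and mask[u, v, w] and not seen[u, v, w]
                            and int(bin_grid[u, v, w]) == lvl
                        ):
                            seen[u, v, w] = True
                            queue.append((u, v, w))
                zones.append((lvl, size))
    return zones


def brute_glszm_features(bin_grid, mask):
    zones = brute_zones(bin_grid, mask)
    n_z = len(zones)
    n = int(mask.sum())
    per_level: Counter = Counter(lvl for lvl, _ in zones)
    iv = sum(c * c for c in per_level.values()) / n_z
    lae = sum(s * s for _, s in zones) / n_z
    return {
        "glszm_intensity_variability": iv,
        "glszm_large_area_emphasis": lae,
        "glszm_zone_percentage": n_z / n,
    }
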