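"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (BFS flood fill, pairwise counting)
and shares no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS = {
    6: [(dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1],
    26: [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_components(grid: np.ndarray, connectivity: int) -> list[set]:
    """All connected components of a boolean grid, as sets of index triples."""
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    comps = []
    for start in zip(*np.nonzero(grid)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            comp.add(p)
            for d in NEIGHBORS[connectivity]:
                nb = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if all(0 <= nb[i] < grid.shape[i] for i in range(3)) \
                        and grid[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        comps.append(comp)
    return comps


def volume_filtered_voxels(grid: np.ndarray, connectivity: int,
                           voxel_volume_mm3: float, min_mm3: float) -> set:
    """Voxels surviving the strict component-volume filter (> min_mm3)."""
    kept = set()
    for comp in flood_fill_components(grid, connectivity):
        if len(comp) * voxel_volume_mm3 > min_mm3:
            kept |= comp
    return kept


def pairwise_auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC by counting all positive-negative pairs
    (ties count 0.5)."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))


def percentile_linear(values, p: float) -> float:
    """Sort-and-interpolate percentile with the closest-ranks rule."""
    v = sorted(float(x) for x in values)
    n = len(v)
    r = 1.0 + (p / 100.0) * (n - 1)
    k = int(np.floor(r))
    if k >= n:
        return v[-1]
    return v[k - 1] + (r - k) * (v[k] - v[k - 1])
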