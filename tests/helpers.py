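"""Independent oracles and small utilities shared across tests.

The flood-fill labeller here is deliberately naive (pure-Python BFS over
explicit neighbour offsets) so it is an independent check of the package's
connected-component labelling, and the recovery metrics are defined once so
acceptance and unit tests agree on them.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manh = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manh > 1:
                    continue
                if connectivity == 18 and manh > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(mask_3d: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force BFS connected components; returns a list of sets of
    (i, j, k) tuples."""
    mask_3d = np.asarray(mask_3d, dtype=bool)
    dims = mask_3d.shape
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(dims, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask_3d)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            x, y, z = q.popleft()
            comp.add((x, y, z))
            for dx, dy, dz in offs:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < dims[0]
                    and 0 <= ny < dims[1]
                    and 0 <= nz < dims[2]
                    and mask_3d[nx, ny, nz]
                    and not seen[nx, ny, nz]
                ):
                    seen[nx, ny, nz] = True
                    q.append((nx, ny, nz))
        comps.append(comp)
    return comps


def jaccard(voxels_a, voxels_b) -> float:
    a, b = set(voxels_a), set(voxels_b)
    return len(a & b) / len(a | b) if a | b else 0.0


def best_recovery_jaccard(reports, truth_masks, windows) -> float:
    """Best Jaccard between any significant positive cluster and the truth
    region, over the given 1-based windows."""
    best = 0.0
    for w in windows:
        truth = np.flatnonzero(truth_masks[w - 1])
        for c in reports[w - 1]["positive"].significant_clusters:
            best = max(best, jaccard(c.voxel_ids.tolist(), truth.tolist()))
    return best


def truth_region_flagged(reports, truth_masks, windows, coverage: float = 0.5) -> bool:
    """True if, in some given window, a significant positive cluster covers
    at least ``coverage`` of the truth region."""
    for w in windows:
        truth = set(np.flatnonzero(truth_masks[w - 1]).tolist())
        if not truth:
            continue
        for c in reports[w - 1]["positive"].significant_clusters:
            if len(truth & set(c.voxel_ids.tolist())) >= coverage * len(truth):
                return True
    return False


def peak_window(reports) -> int:
    """1-based window holding the largest significant positive cluster,
    or 0 if none."""
    best_k, best_w = 0, 0
    for w, rep in enumerate(reports, start=1):
        for c in rep["positive"].significant_clusters:
            if c.size > best_k:
                best_k, best_w = c.size, w
    return best_w


def any_significant(reports) -> bool:
    return any(
        bool(rep[s].significant_clusters)
        for rep in reports
        for s in ("positive", "negative")
    )
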