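"""Cluster-based Monte Carlo spatial-permutation correction (MCS).

Mass-univariate maps are binarized at a voxel-level alpha (two-sided p,
split into positive and negative families, corrected independently).
Connected components of each binary mask are formed under the grid's
connectivity (default 26). The null distribution of the maximum cluster
size is built by relocating the observed number of suprathreshold voxels
uniformly at random (without replacement) over the in-brain grid, 1000
times by default, recording each permutation's maximum connected-cluster
size. An observed cluster is significant only if its size is *strictly
greater* than the 95th percentile (nearest-rank) of that null distribution.

This corrects the voxel-level tests for multiple comparisons while staying
agnostic about the statistic's distribution beyond the voxel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .grid import SourceGrid
from .window_stats import StatMap

DEFAULT_N_PERMUTATIONS = 1000
PERCENTILE = 0.95


@dataclass
class BinaryMask:
    """Suprathreshold voxels of one signed family.

    ``values`` is boolean over the grid's source ordering.
    """

    values: np.ndarray
    alpha: float
    sign: str  # "positive" | "negative"
    statmap: Optional[StatMap] = None

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise InvalidInputError("sign must be 'positive' or 'negative'")
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class Cluster:
    voxel_ids: np.ndarray  # indices into the grid's source ordering
    size: int
    peak_stat: float = np.nan
    peak_voxel: int = -1
    significant: bool = False


@dataclass
class ClusterReport:
    """Observed clusters with their permutation null and decisions.

    ``threshold_size`` is the nearest-rank 95th percentile of
    ``null_max_sizes``; a cluster is significant iff size > threshold_size.
    Clusters are sorted by size, descending.
    """

    clusters: list[Cluster]
    null_max_sizes: np.ndarray
    threshold_size: int
    alpha: float
    sign: str
    n_permutations: int
    mask_count: int = 0

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def threshold_map(statmap: StatMap, alpha: float) -> tuple[BinaryMask, BinaryMask]:
    """Binarize a statistic map at two-sided voxel-level ``alpha``,
    split by statistic sign."""
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    if statmap.df is None or statmap.df <= 0:
        raise InvalidInputError("statmap degrees of freedom missing")
    p = statmap.p_values()
    sig = p < alpha
    pos = BinaryMask(sig & (statmap.values > 0), alpha, "positive", statmap)
    neg = BinaryMask(sig & (statmap.values < 0), alpha, "negative", statmap)
    return pos, neg


def find_clusters(
    mask: BinaryMask | np.ndarray,
    grid: SourceGrid,
    statmap: Optional[StatMap] = None,
) -> list[Cluster]:
    """Connected components of a source-space binary mask under the grid's
    connectivity. Every suprathreshold voxel belongs to exactly one cluster."""
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if values.shape != (grid.n_sources,):
        raise InvalidInputError("mask must be defined over the grid's sources")
    if statmap is None and isinstance(mask, BinaryMask):
        statmap = mask.statmap
    vol = grid.embed(values)
    labels, n_labels = ndimage.label(vol, structure=grid.structure())
    lab_src = labels.ravel()[grid.source_flat]
    clusters: list[Cluster] = []
    for lab in range(1, n_labels + 1):
        vox = np.flatnonzero(lab_src == lab)
        peak_stat, peak_voxel = np.nan, -1
        if statmap is not None:
            k = np.argmax(np.abs(statmap.values[vox]))
            peak_stat = float(statmap.values[vox[k]])
            peak_voxel = int(vox[k])
        clusters.append(
            Cluster(voxel_ids=vox, size=int(vox.size), peak_stat=peak_stat, peak_voxel=peak_voxel)
        )
    clusters.sort(key=lambda c: (-c.size, c.voxel_ids[0]))
    return clusters


def _max_cluster_size(vol: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(vol, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def spatial_shuffle_null(
    mask: BinaryMask | int,
    grid: SourceGrid,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Null distribution of the maximum cluster size under spatial shuffling.

    Each permutation relocates the observed number of suprathreshold voxels
    uniformly at random, without replacement, over all in-mask grid voxels,
    and records the maximum connected-cluster size.
    """
    m = mask.count if isinstance(mask, BinaryMask) else int(mask)
    n_grid = grid.n_sources
    if m < 0 or m > n_grid:
        raise InvalidInputError(f"mask count {m} outside 0..{n_grid}")
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    if m == 0:
        return np.zeros(n_permutations, dtype=int)
    if m == n_grid:
        # the full in-brain mask is one cluster only if it is connected;
        # label it once, it is the same for every permutation
        size = _max_cluster_size(grid.embed(np.ones(n_grid, bool)), grid.structure())
        return np.full(n_permutations, size, dtype=int)
    rng = np.random.default_rng(seed)
    if m == 1:
        return np.ones(n_permutations, dtype=int)
    structure = grid.structure()
    picks = _uniform_placements(rng, n_permutations, n_grid, m)
    if m <= 3:
        return _small_mask_maxima(picks, grid)
    maxima = np.empty(n_permutations, dtype=int)
    flat = np.zeros(int(np.prod(grid.dims)), dtype=bool)
    for i in range(n_permutations):
        src = grid.source_flat[picks[i]]
        flat[src] = True
        maxima[i] = _max_cluster_size(flat.reshape(grid.dims), structure)
        flat[src] = False
    return maxima


def _uniform_placements(
    rng: np.random.Generator, n_perm: int, n_grid: int, m: int
) -> np.ndarray:
    """Uniform without-replacement placements, shape (n_perm, m)."""
    if m <= 16 and m < n_grid // 4:
        # with-replacement draws, rejecting rows with duplicates, is uniform
        # over distinct m-sets and far cheaper than argpartition for small m
        picks = rng.integers(0, n_grid, (n_perm, m))
        while True:
            s = np.sort(picks, axis=1)
            bad = np.flatnonzero((s[:, 1:] == s[:, :-1]).any(axis=1))
            if bad.size == 0:
                return picks
            picks[bad] = rng.integers(0, n_grid, (bad.size, m))
    return np.argpartition(rng.random((n_perm, n_grid)), m - 1, axis=1)[:, :m]


def _adjacent(d_ijk: np.ndarray, connectivity: int) -> np.ndarray:
    """Adjacency predicate for absolute coordinate differences (..., 3)."""
    cheb = d_ijk.max(axis=-1)
    manh = d_ijk.sum(axis=-1)
    if connectivity == 6:
        return manh == 1
    if connectivity == 18:
        return (cheb == 1) & (manh <= 2)
    return cheb == 1


def _small_mask_maxima(picks: np.ndarray, grid: SourceGrid) -> np.ndarray:
    """Closed-form maximum component size for 2- or 3-voxel placements."""
    ijk = grid.source_ijk[picks]  # (n_perm, m, 3)
    m = picks.shape[1]
    if m == 2:
        adj = _adjacent(np.abs(ijk[:, 0] - ijk[:, 1]), grid.connectivity)
        return 1 + adj.astype(int)
    # m == 3: max component of a 3-node graph from its edge count
    e = np.zeros(picks.shape[0], dtype=int)
    for a, b in ((0, 1), (0, 2), (1, 2)):
        e += _adjacent(np.abs(ijk[:, a] - ijk[:, b]), grid.connectivity).astype(int)
    return np.array([1, 2, 3, 3])[e]


def nearest_rank_percentile(values: np.ndarray, q: float = PERCENTILE) -> int:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise InvalidInputError("empty null distribution")
    rank = int(np.ceil(q * v.size))
    return int(v[max(rank - 1, 0)])


def significant_clusters(
    clusters: list[Cluster],
    null_max_sizes: np.ndarray,
    alpha: float = np.nan,
    sign: str = "positive",
    mask_count: Optional[int] = None,
) -> ClusterReport:
    """Apply the strict 95th-percentile decision rule.

    A cluster is significant iff its size is strictly greater than the
    nearest-rank 95th percentile of the null maximum cluster sizes; a
    cluster whose size *equals* the threshold is not significant.
    """
    null_max_sizes = np.asarray(null_max_sizes, dtype=int)
    threshold = nearest_rank_percentile(null_max_sizes, PERCENTILE)
    out = []
    for c in clusters:
        out.append(
            Cluster(
                voxel_ids=c.voxel_ids,
                size=c.size,
                peak_stat=c.peak_stat,
                peak_voxel=c.peak_voxel,
                significant=bool(c.size > threshold),
            )
        )
    return ClusterReport(
        clusters=out,
        null_max_sizes=null_max_sizes,
        threshold_size=threshold,
        alpha=alpha,
        sign=sign,
        n_permutations=int(null_max_sizes.size),
        mask_count=mask_count if mask_count is not None else sum(c.size for c in out),
    )


def run_mcs(
    statmap: StatMap,
    grid: SourceGrid,
    alpha: float,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> dict[str, ClusterReport]:
    """Full cluster correction of one statistic map: binarize, label,
    build the spatial-shuffle null, decide. Positive and negative families
    are corrected independently (each with its own permutation stream
    derived from ``seed``)."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
        if not isinstance(seed, np.random.Generator)
        else None
    )
    if ss is None:
        streams = [seed, seed]  # caller-supplied generator: shared stream
    else:
        streams = list(ss.spawn(2))
    pos, neg = threshold_map(statmap, alpha)
    out: dict[str, ClusterReport] = {}
    for mask, stream in zip((pos, neg), streams):
        clusters = find_clusters(mask, grid, statmap)
        null = spatial_shuffle_null(mask, grid, n_permutations, stream)
        out[mask.sign] = significant_clusters(
            clusters, null, alpha=alpha, sign=mask.sign, mask_count=mask.count
        )
    return out
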