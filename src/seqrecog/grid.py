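"""Regular source grids for volumetric source reconstruction.

The reconstruction volume is a regular lattice of candidate dipole locations
(8-mm spacing by default, mirroring the common whole-brain beamforming setup)
together with an in-brain mask, an affine mapping voxel indices to
millimetres, and a neighbourhood rule (6, 18 or 26 connectivity) used for
cluster formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidConfigError

VALID_CONNECTIVITY = (6, 18, 26)

#: scipy.ndimage.generate_binary_structure rank for each connectivity level
_STRUCTURE_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SourceGrid:
    """A 3-D voxel lattice of candidate sources.

    Attributes
    ----------
    dims : tuple of int
        Voxels along each axis.
    spacing_mm : float
        Distance between adjacent voxel centres, millimetres.
    mask : ndarray of bool, shape ``dims``
        In-brain mask; statistics and cluster permutations are restricted to
        the ``True`` voxels.
    affine : ndarray, shape (4, 4)
        Voxel-index -> millimetre map. Voxel (0, 0, 0) maps to the affine's
        translation column.
    connectivity : int
        Neighbourhood rule for cluster formation: 6 (faces), 18 (faces+edges)
        or 26 (faces+edges+vertices).
    """

    dims: tuple[int, int, int]
    spacing_mm: float
    mask: np.ndarray
    affine: np.ndarray
    connectivity: int = 26
    # flat indices (into mask.ravel()) of in-mask voxels, fixed ordering
    source_flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.connectivity not in VALID_CONNECTIVITY:
            raise InvalidConfigError(
                f"connectivity must be one of {VALID_CONNECTIVITY}, got {self.connectivity}"
            )
        if self.spacing_mm <= 0:
            raise InvalidConfigError("spacing_mm must be positive")
        if self.mask.shape != tuple(self.dims):
            raise InvalidConfigError("mask shape does not match dims")
        if not self.mask.any():
            raise InvalidConfigError("mask must contain at least one voxel")
        object.__setattr__(
            self, "source_flat", np.flatnonzero(self.mask.ravel())
        )

    @property
    def n_sources(self) -> int:
        return int(self.source_flat.size)

    @property
    def source_ijk(self) -> np.ndarray:
        """Integer voxel coordinates of in-mask sources, shape (n_sources, 3)."""
        return np.column_stack(np.unravel_index(self.source_flat, self.dims))

    @property
    def source_mm(self) -> np.ndarray:
        """Millimetre coordinates of in-mask sources, shape (n_sources, 3)."""
        ijk1 = np.column_stack([self.source_ijk, np.ones(self.n_sources)])
        return (ijk1 @ self.affine.T)[:, :3]

    def structure(self) -> np.ndarray:
        """Binary 3x3x3 structuring element for this connectivity."""
        return ndimage.generate_binary_structure(3, _STRUCTURE_RANK[self.connectivity])

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-source values into a full 3-D volume."""
        values = np.asarray(values)
        vol = np.full(int(np.prod(self.dims)), fill, dtype=values.dtype)
        vol[self.source_flat] = values
        return vol.reshape(self.dims)

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Gather in-mask voxels of a full volume into a per-source vector."""
        return np.asarray(volume).ravel()[self.source_flat]

    def neighbor_pairs(self) -> np.ndarray:
        """All unordered in-mask neighbour pairs (i, j) with i < j, as
        indices into the source ordering. Symmetric and irreflexive by
        construction."""
        index_vol = np.full(int(np.prod(self.dims)), -1, dtype=np.int64)
        index_vol[self.source_flat] = np.arange(self.n_sources)
        index_vol = index_vol.reshape(self.dims)
        offsets = np.argwhere(self.structure()) - 1
        pairs = []
        for off in offsets:
            if tuple(off) <= (0, 0, 0):
                continue  # keep one direction of each pair
            a = index_vol
            b = np.roll(index_vol, shift=tuple(-off), axis=(0, 1, 2))
            # roll wraps around; mask off wrapped entries
            valid = np.ones(self.dims, dtype=bool)
            for ax, o in enumerate(off):
                if o > 0:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(self.dims[ax] - o, None)
                    valid[tuple(sl)] = False
                elif o < 0:
                    sl = [slice(None)] * 3
                    sl[ax] = slice(None, -o)
                    valid[tuple(sl)] = False
            ok = valid & (a >= 0) & (b >= 0)
            pairs.append(np.column_stack([a[ok], b[ok]]))
        if not pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.vstack(pairs)


def make_grid(
    dims: tuple[int, int, int],
    spacing_mm: float = 8.0,
    mask_rule: str = "full_box",
    connectivity: int = 26,
) -> SourceGrid:
    """Build a regular source grid.

    Parameters
    ----------
    dims : (nx, ny, nz)
        Voxels per axis; all positive.
    spacing_mm : float
        Lattice spacing in millimetres (default 8, the study's grid).
    mask_rule : {"full_box", "centered_ellipsoid"}
        ``full_box`` keeps every voxel; ``centered_ellipsoid`` keeps the
        ellipsoid inscribed in the box, a crude in-brain mask.
    connectivity : {6, 18, 26}
        Neighbourhood rule for downstream clustering.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise InvalidConfigError(f"dims must be three positive integers, got {dims}")
    if spacing_mm <= 0:
        raise InvalidConfigError("spacing_mm must be positive")
    if mask_rule == "full_box":
        mask = np.ones(dims, dtype=bool)
    elif mask_rule == "centered_ellipsoid":
        idx = np.indices(dims, dtype=float)
        center = (np.asarray(dims, dtype=float) - 1.0) / 2.0
        semi = np.maximum(np.asarray(dims, dtype=float) / 2.0, 0.5)
        r2 = sum(
            ((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)
        )
        mask = r2 <= 1.0
        if not mask.any():  # degenerate tiny boxes: keep the centre voxel
            mask[tuple(int(round(c)) for c in center)] = True
    else:
        raise InvalidConfigError(f"unknown mask_rule {mask_rule!r}")
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing_mm
    # voxel (0,0,0) sits at the origin of the grid's millimetre frame
    return SourceGrid(
        dims=dims,
        spacing_mm=float(spacing_mm),
        mask=mask,
        affine=affine,
        connectivity=int(connectivity),
    )


def contiguous_region(
    grid: SourceGrid, center_ijk: tuple[int, int, int], n_voxels: int
) -> np.ndarray:
    """Deterministically grow a contiguous in-mask region of ``n_voxels``
    around ``center_ijk`` (breadth-first by distance, ties broken by index).

    Returns source indices (positions in the grid's source ordering). Used to
    plant spatially contiguous effects.
    """
    if n_voxels < 1 or n_voxels > grid.n_sources:
        raise InvalidConfigError("n_voxels out of range for this grid")
    ijk = grid.source_ijk
    center = np.asarray(center_ijk, dtype=float)
    d2 = ((ijk - center) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(grid.n_sources), d2))
    return np.sort(order[:n_voxels])
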