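"""Lattice discretization of rigid bodies and the complex-valued score grids.

A protein is mapped onto a cubic N x N x N lattice.  A lattice point is
*inside* the protein when it lies within the van der Waals radius of any
atom (closed ball).  Inside points are then layered with face (6-)
connectivity, treating off-grid neighbors as outside:

* surface       -- inside, with at least one outside face-neighbor;
* near-surface  -- remaining inside, with at least one surface face-neighbor;
* core          -- all remaining inside points.

The surface layer is the spacer between interior and exterior; the
near-surface layer and core are the regions actually occupied by atoms.

Each side of a docking pair is then assigned a complex score field.  With J
the imaginary unit, r the Euclidean distance *in grid-index units* between a
point and a neighbor, and both neighbor sums running over near-surface and
core points only:

receptor side
    surface:       -sum_{|di|,|dj|,|dk| <= 3} exp(-(r-1)^2)  +  J
    near-surface:  -1 + 2J * sum_{|di|,|dj|,|dk| <= 1} exp(-r^2)
    core:          -1 + 10J
    outside:        0

ligand side
    surface:        1 - J
    near-surface:   1 - 2J * sum_{|di|,|dj|,|dk| <= 1} exp(-r^2)
    core:           1 - 10J
    outside:        0

The +-3 box on the surface term gives the score its long range: atoms up to
seven layers away still attract a surface point, with an exponential weight
peaked at the adjacent-layer distance r = 1.  The +-1 sums include the
center point itself when it is near-surface (the r = 0 term); this is
controlled by ``include_self``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .structures import Structure

__all__ = [
    "Layer",
    "GridSpec",
    "LayerGrid",
    "ComplexGrid",
    "GridTooLargeError",
    "choose_grid",
    "classify_layers",
    "receptor_grid",
    "ligand_grid",
]


class GridTooLargeError(ValueError):
    """Requested lattice exceeds the configured size cap."""


class Layer(IntEnum):
    OUTSIDE = 0
    SURFACE = 1
    NEAR_SURFACE = 2
    CORE = 3


@dataclass(frozen=True)
class GridSpec:
    """Cubic lattice geometry: point i sits at ``origin + i * spacing``."""

    spacing: float
    n: int
    origin: np.ndarray  # (3,) position of index (0, 0, 0), Angstrom

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.n < 4:
            raise ValueError("grid must have at least 4 points per axis")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def center(self) -> np.ndarray:
        return self.origin + (self.n - 1) / 2.0 * self.spacing

    @property
    def extent(self) -> float:
        """Physical edge length spanned by the lattice points, Angstrom."""
        return (self.n - 1) * self.spacing

    @classmethod
    def centered(cls, spacing: float, n: int, center=(0.0, 0.0, 0.0)) -> "GridSpec":
        center = np.asarray(center, dtype=float)
        origin = center - (n - 1) / 2.0 * spacing
        return cls(spacing=spacing, n=n, origin=origin)


@dataclass(frozen=True)
class LayerGrid:
    """Layer labels over a lattice (values of :class:`Layer`)."""

    spec: GridSpec
    labels: np.ndarray  # (n, n, n) uint8

    def count(self, layer: Layer) -> int:
        return int(np.count_nonzero(self.labels == layer))


@dataclass(frozen=True)
class ComplexGrid:
    """Complex score field for one docking partner."""

    spec: GridSpec
    values: np.ndarray  # (n, n, n) complex128
    side: str  # "receptor" | "ligand"


def _fft_friendly(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}."""
    while True:
        m = n
        for p in (2, 3, 5):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


def _radius_about_centroid(structure: Structure) -> float:
    pos = structure.positions
    return float(np.linalg.norm(pos - pos.mean(axis=0), axis=1).max())


def choose_grid(
    receptor: Structure,
    ligand: Structure,
    spacing: float = 1.2,
    cap: int = 256,
) -> GridSpec:
    """Pick a lattice large enough for an unambiguous translational search.

    The box must hold receptor and ligand side by side (bounding diameters
    about their centroids) plus a margin of ``2 * max_vdw + 2 * spacing`` on
    each side, so that no atom's sphere nor any +-3 surface neighborhood
    touches the boundary and circular FFT wraparound cannot alias a contact
    pose.  N is rounded up to a 2/3/5-smooth FFT size and centered on the
    origin; callers translate both centroids there before gridding.
    """
    for st, name in ((receptor, "receptor"), (ligand, "ligand")):
        if len(st) == 0:
            raise ValueError(f"{name} structure is empty")
        if not st.has_radii():
            raise ValueError(f"{name} structure has unassigned VDW radii")
    rec_extent = 2.0 * _radius_about_centroid(receptor)
    lig_extent = 2.0 * _radius_about_centroid(ligand)
    max_vdw = float(max(receptor.radii.max(), ligand.radii.max()))
    margin = 2.0 * max_vdw + 2.0 * spacing
    need = rec_extent + lig_extent + 2.0 * margin
    n = _fft_friendly(max(4, math.ceil(need / spacing)))
    if n > cap:
        raise GridTooLargeError(
            f"required grid size {n} exceeds cap {cap} (box {need:.1f} A at {spacing} A spacing)"
        )
    return GridSpec.centered(spacing=spacing, n=n)


# ---------------------------------------------------------------------------
# Layer classification
# ---------------------------------------------------------------------------

def _face_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    if connectivity == 6:
        return [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    if connectivity == 26:
        return [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    raise ValueError("connectivity must be 6 or 26")


def _any_neighbor(mask: np.ndarray, offsets, pad_value: bool) -> np.ndarray:
    """True where at least one offset-neighbor of the point satisfies mask."""
    padded = np.pad(mask, 1, constant_values=pad_value)
    out = np.zeros_like(mask, dtype=bool)
    n = mask.shape[0]
    for di, dj, dk in offsets:
        out |= padded[1 + di : 1 + di + n, 1 + dj : 1 + dj + n, 1 + dk : 1 + dk + n]
    return out


def inside_mask(positions: np.ndarray, radii: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Boolean lattice mask: within the VDW sphere of any atom (closed ball)."""
    n, h, origin = spec.n, spec.spacing, spec.origin
    inside = np.zeros((n, n, n), dtype=bool)
    axes = np.arange(n) * h
    for idx, (pos, r) in enumerate(zip(positions, radii)):
        rel = pos - origin
        if np.any(pos < origin) or np.any(pos > origin + (n - 1) * h):
            raise ValueError(f"atom {idx} at {pos} lies outside the grid bounds")
        lo = np.maximum(np.ceil((rel - r) / h).astype(int), 0)
        hi = np.minimum(np.floor((rel + r) / h).astype(int), n - 1)
        if np.any(lo > hi):
            continue
        dx = axes[lo[0] : hi[0] + 1] - rel[0]
        dy = axes[lo[1] : hi[1] + 1] - rel[1]
        dz = axes[lo[2] : hi[2] + 1] - rel[2]
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        inside[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= r * r
    return inside


def classify_layers(
    structure: Structure, spec: GridSpec, connectivity: int = 6
) -> LayerGrid:
    """Label every lattice point as outside / surface / near-surface / core."""
    if not structure.has_radii():
        raise ValueError("structure has unassigned VDW radii; run assign_radii first")
    return _classify_arrays(structure.positions, structure.radii, spec, connectivity)


def _classify_arrays(
    positions: np.ndarray, radii: np.ndarray, spec: GridSpec, connectivity: int = 6
) -> LayerGrid:
    inside = inside_mask(positions, radii, spec)
    offsets = _face_offsets(connectivity)
    # off-grid neighbors count as outside -> pad the outside mask with True
    surface = inside & _any_neighbor(~inside, offsets, pad_value=True)
    near = inside & ~surface & _any_neighbor(surface, offsets, pad_value=False)
    labels = np.zeros(inside.shape, dtype=np.uint8)
    labels[surface] = Layer.SURFACE
    labels[near] = Layer.NEAR_SURFACE
    labels[inside & ~surface & ~near] = Layer.CORE
    return LayerGrid(spec=spec, labels=labels)


# ---------------------------------------------------------------------------
# Complex score grids
# ---------------------------------------------------------------------------

def _distance_kernel(reach: int, fn) -> np.ndarray:
    ax = np.arange(-reach, reach + 1, dtype=float)
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    return fn(r)


_KERNEL_SURFACE = _distance_kernel(3, lambda r: np.exp(-((r - 1.0) ** 2)))
_KERNEL_NEAR = _distance_kernel(1, lambda r: np.exp(-(r**2)))


def _neighbor_sums(layers: LayerGrid, need_surface_sum: bool, include_self: bool):
    occupied = ((layers.labels == Layer.NEAR_SURFACE) | (layers.labels == Layer.CORE)).astype(float)
    s1 = ndimage.convolve(occupied, _KERNEL_NEAR, mode="constant", cval=0.0)
    if not include_self:
        s1 = s1 - occupied  # remove the r = 0 self term where the point is occupied
    s3 = None
    if need_surface_sum:
        s3 = ndimage.convolve(occupied, _KERNEL_SURFACE, mode="constant", cval=0.0)
    return s1, s3


def receptor_grid(layers: LayerGrid, include_self: bool = True) -> ComplexGrid:
    """Receptor-side complex score field (see module docstring)."""
    s1, s3 = _neighbor_sums(layers, need_surface_sum=True, include_self=include_self)
    lab = layers.labels
    values = np.zeros(lab.shape, dtype=np.complex128)
    surf = lab == Layer.SURFACE
    near = lab == Layer.NEAR_SURFACE
    core = lab == Layer.CORE
    values[surf] = -s3[surf] + 1j
    values[near] = -1.0 + 2j * s1[near]
    values[core] = -1.0 + 10j
    return ComplexGrid(spec=layers.spec, values=values, side="receptor")


def ligand_grid(layers: LayerGrid, include_self: bool = True) -> ComplexGrid:
    """Ligand-side complex score field (see module docstring)."""
    s1, _ = _neighbor_sums(layers, need_surface_sum=False, include_self=include_self)
    lab = layers.labels
    values = np.zeros(lab.shape, dtype=np.complex128)
    surf = lab == Layer.SURFACE
    near = lab == Layer.NEAR_SURFACE
    core = lab == Layer.CORE
    values[surf] = 1.0 - 1j
    values[near] = 1.0 - 2j * s1[near]
    values[core] = 1.0 - 10j
    return ComplexGrid(spec=layers.spec, values=values, side="ligand")


def dump_grid_table(grid: LayerGrid | ComplexGrid) -> str:
    """Small-grid debug dump: one line per non-outside point."""
    lines = []
    if isinstance(grid, LayerGrid):
        lines.append("i\tj\tk\tlabel")
        for i, j, k in zip(*np.nonzero(grid.labels)):
            lines.append(f"{i}\t{j}\t{k}\t{Layer(grid.labels[i, j, k]).name.lower()}")
    else:
        lines.append("i\tj\tk\treal\timag")
        for i, j, k in zip(*np.nonzero(grid.values)):
            v = grid.values[i, j, k]
            lines.append(f"{i}\t{j}\t{k}\t{v.real:.6f}\t{v.imag:.6f}")
    return "\n".join(lines) + "\n"
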