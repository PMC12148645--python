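"""Streamline geometry and bundle-level tractometry.

Short association fibers (SAFs, "U-fibers") are short streamlines (5-40 mm)
running directly beneath the cortex.  This module implements the desk-scale
classification computation: length filtering, proximity-based assignment of
SAF streamlines to long-range (LR) bundle masks, voxel occupancy of a bundle,
and averaging of a scalar microstructure map over a bundle's voxels.

Conventions
-----------
* A streamline is an ``(n, 3)`` float array of ordered world-space points
  in millimetres.
* A :class:`VolumeGrid` pairs integer dimensions with a 4x4 NIfTI-style
  voxel-to-world affine.  Voxel centers sit at integer indices (0-based);
  voxel ``i`` owns the half-open cube ``[i - 0.5, i + 0.5)`` in voxel
  coordinates.
* Voxel membership of a streamline is decided by exact traversal of each
  polyline segment through those cubes (Amanatides-Woo grid marching), so a
  segment that clips the corner of a voxel still counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with a voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> world (mm)

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.inverse_affine
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
        return voxels @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def voxel_edges(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class Mask:
    """Binary voxel mask on a grid."""

    grid: VolumeGrid
    voxels: np.ndarray  # bool array, shape == grid.shape

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Tractogram:
    """A list of streamlines sharing one reference grid."""

    streamlines: list[np.ndarray]
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.streamlines = [_validate_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class SAFBundle:
    """Streamline indices assigned to one LR pathway, before/after filtering."""

    pathway: str
    streamline_indices: set[int] = field(default_factory=set)
    post_filter_indices: set[int] | None = None

    def __post_init__(self) -> None:
        if self.post_filter_indices is not None and not (
            set(self.post_filter_indices) <= set(self.streamline_indices)
        ):
            raise ValueError("post_filter_indices must be a subset of streamline_indices")


def _validate_streamline(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError(f"streamline must have shape (n, 3), got {s.shape}")
    if s.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(s)):
        raise ValueError("streamline contains non-finite coordinates")
    return s


# ---------------------------------------------------------------------------
# lengths and resampling
# ---------------------------------------------------------------------------


def streamline_length(streamline: np.ndarray) -> float:
    """Arc length in mm: sum of consecutive Euclidean segment lengths."""
    s = _validate_streamline(streamline)
    return float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())


def filter_by_length(
    tractogram: Tractogram | list[np.ndarray],
    min_mm: float = 5.0,
    max_mm: float = 40.0,
) -> set[int]:
    """Indices of streamlines with ``min_mm <= length <= max_mm`` (inclusive).

    The 5-40 mm band is the operational definition of a short association
    fiber; both bounds are inclusive.
    """
    if min_mm > max_mm:
        raise ValueError(f"min_mm ({min_mm}) > max_mm ({max_mm})")
    return {
        i for i, s in enumerate(tractogram) if min_mm <= streamline_length(s) <= max_mm
    }


def resample_streamline(streamline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample to ``n_points`` equidistant points along the arc."""
    s = _validate_streamline(streamline)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0.0:
        return np.repeat(s[:1], n_points, axis=0)
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, s[:, d])
    return out


def resample_to_spacing(streamline: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Resample so consecutive points are at most ``spacing_mm`` apart."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    length = streamline_length(streamline)
    n = max(2, int(np.ceil(length / spacing_mm)) + 1)
    return resample_streamline(streamline, n)


# ---------------------------------------------------------------------------
# exact voxel traversal
# ---------------------------------------------------------------------------


def _segment_cells(p0: np.ndarray, p1: np.ndarray) -> list[tuple[int, int, int]]:
    """All voxel cells a segment passes through, in voxel coordinates.

    Cell ``i`` spans ``[i - 0.5, i + 0.5)``; boundaries are crossed with the
    standard Amanatides-Woo march.  Exact up to floating point: a segment
    that cuts the corner of a cell for an arbitrarily short length is still
    reported.
    """
    # shift so cell boundaries sit at integers
    a = np.asarray(p0, float) + 0.5
    b = np.asarray(p1, float) + 0.5
    d = b - a
    cell = np.floor(a).astype(int)
    end_cell = np.floor(b).astype(int)
    cells = [tuple(cell)]
    step = np.sign(d).astype(int)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] != 0.0:
            next_boundary = cell[ax] + (1 if step[ax] > 0 else 0)
            t_max[ax] = (next_boundary - a[ax]) / d[ax]
            t_delta[ax] = abs(1.0 / d[ax])
    # bounded number of crossings
    max_steps = int(np.abs(end_cell - cell).sum()) + 6
    for _ in range(max_steps):
        if np.all(cell == end_cell):
            break
        ax = int(np.argmin(t_max))
        if t_max[ax] > 1.0:
            break
        cell = cell.copy()
        cell[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        cells.append(tuple(cell))
    return cells


def streamline_voxels(streamline: np.ndarray, grid: VolumeGrid) -> set[tuple[int, int, int]]:
    """In-grid voxels traversed by the polyline (exact segment marching)."""
    s = _validate_streamline(streamline)
    vox = grid.world_to_voxel(s)
    visited: set[tuple[int, int, int]] = set()
    for i in range(len(vox) - 1):
        visited.update(_segment_cells(vox[i], vox[i + 1]))
    shape = grid.shape
    return {
        c
        for c in visited
        if 0 <= c[0] < shape[0] and 0 <= c[1] < shape[1] and 0 <= c[2] < shape[2]
    }


# ---------------------------------------------------------------------------
# assignment, occupancy, averaging
# ---------------------------------------------------------------------------


def assign_streamlines(
    tractogram: Tractogram,
    lr_masks: dict[str, Mask],
) -> dict[str, SAFBundle]:
    """Assign each streamline to every LR bundle whose mask it traverses.

    A streamline joins pathway ``P`` iff its exact voxel traversal hits a
    nonzero voxel of ``P``'s mask.  Streamlines may join multiple bundles
    (LR masks overlap in real anatomy); streamlines hitting no mask are left
    unassigned.
    """
    for name, mask in lr_masks.items():
        if mask.grid != tractogram.grid:
            raise ValueError(f"mask '{name}' grid does not match tractogram grid")
    bundles = {name: SAFBundle(pathway=name) for name in lr_masks}
    for i, s in enumerate(tractogram):
        cells = streamline_voxels(s, tractogram.grid)
        if not cells:
            continue
        idx = tuple(np.array(sorted(cells)).T)
        for name, mask in lr_masks.items():
            if mask.voxels[idx].any():
                bundles[name].streamline_indices.add(i)
    return bundles


def bundle_occupancy(
    streamlines: list[np.ndarray],
    grid: VolumeGrid,
) -> Mask:
    """Binary mask of voxels visited by at least one member streamline."""
    voxels = np.zeros(grid.shape, dtype=bool)
    for s in streamlines:
        for c in streamline_voxels(s, grid):
            voxels[c] = True
    return Mask(grid=grid, voxels=voxels)


def bundle_mean_feature(mask: Mask, scalar_map: np.ndarray) -> tuple[float, int]:
    """Mean of a voxelwise scalar map over the mask.

    NaN voxels are excluded; the count of excluded voxels is returned so the
    caller can log it.  Raises on an empty mask or a fully-NaN selection.
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    if scalar_map.shape != tuple(mask.grid.shape):
        raise ValueError("scalar map shape does not match mask grid")
    if mask.n_voxels == 0:
        raise ValueError("cannot average over an empty mask")
    values = scalar_map[mask.voxels]
    nan_count = int(np.isnan(values).sum())
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("all voxels in mask are NaN")
    return float(values.mean()), nan_count
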