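"""Data model and I/O for labeled voxel volumes.

Annotated CT slice stacks assign every root cross-section an arbitrary flat
RGB color, one color per individual seedling. This module reads such stacks
into an integer :class:`LabelVolume`, concatenates sequentially scanned
stacks along depth, and extracts per-individual binary occupancy grids.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with z increasing downward (depth).
Indexing is 0-based. The depth of voxel layer ``k`` is
``z_origin + (k + 0.5) * resolution_mm`` (voxel-center convention; voxel
``k`` spans the half-open interval ``[k*h, (k+1)*h)`` below ``z_origin``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "LabelVolume",
    "VoxelGrid",
    "load_label_stack",
    "write_label_stack",
    "write_label_volume",
    "load_label_volume",
    "concatenate_stacks",
    "extract_individual",
]


class AnnotationError(ValueError):
    """A slice pixel carries a color absent from the color map."""


class DimensionError(ValueError):
    """Slice shapes or stack geometries are incompatible."""


@dataclass
class LabelVolume:
    """3D integer-labeled voxel grid; each voxel belongs to one individual.

    Parameters
    ----------
    labels
        Non-negative integer array indexed ``(x, y, z)``; 0 is background,
        positive values identify individual root systems.
    resolution_mm
        Isotropic voxel edge length in mm.
    z_origin
        Depth (mm) of the top face of slice ``z=0``, measured from the
        medium surface. Default 0.
    color_map
        Optional ``individual id -> (r, g, b)`` mapping used when the
        volume round-trips through annotated RGB stacks.
    """

    labels: np.ndarray
    resolution_mm: float
    z_origin: float = 0.0
    color_map: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionError(
                f"labels must be 3D (x, y, z); got ndim={self.labels.ndim}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if self.resolution_mm <= 0:
            raise ValueError("resolution_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def individual_ids(self) -> list[int]:
        """Sorted positive label values present in the volume."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def depth_of_slice(self, k: int) -> float:
        """Center depth (mm) of z-slice ``k``."""
        return self.z_origin + (k + 0.5) * self.resolution_mm


@dataclass
class VoxelGrid:
    """Binary occupancy grid for a single individual.

    Entries are exactly 0 or 1; shape matches the parent
    :class:`LabelVolume`.
    """

    occupancy: np.ndarray
    resolution_mm: float
    z_origin: float = 0.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise DimensionError("occupancy must be 3D (x, y, z)")
        if occ.dtype != np.uint8:
            vals = np.unique(occ)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("occupancy entries must be 0 or 1")
            occ = occ.astype(np.uint8)
        self.occupancy = occ
        if self.resolution_mm <= 0:
            raise ValueError("resolution_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def voxel_depths_mm(self) -> np.ndarray:
        """Center depths (mm) of all occupied voxels."""
        zs = np.nonzero(self.occupancy)[2]
        return self.z_origin + (zs + 0.5) * self.resolution_mm


def _slice_to_labels(
    rgb: np.ndarray,
    color_map: Mapping[int, tuple[int, int, int]],
    where: str,
) -> np.ndarray:
    """Map an (H, W, 3) RGB slice to integer labels; exact color match."""
    if rgb.ndim == 2:  # grayscale: treat nonzero as annotation error bait
        rgb = np.stack([rgb] * 3, axis=-1)
    h, w = rgb.shape[:2]
    out = np.zeros((h, w), dtype=np.int32)
    claimed = np.zeros((h, w), dtype=bool)
    background = np.all(rgb == 0, axis=-1)
    claimed |= background
    for ind_id, color in color_map.items():
        mask = np.all(rgb == np.asarray(color, dtype=rgb.dtype), axis=-1)
        out[mask] = ind_id
        claimed |= mask
    if not claimed.all():
        ys, xs = np.nonzero(~claimed)
        bad = tuple(int(v) for v in rgb[ys[0], xs[0]][:3])
        raise AnnotationError(
            f"unknown non-background color {bad} in {where} "
            f"at pixel (row={ys[0]}, col={xs[0]})"
        )
    return out


def load_label_stack(
    paths: Sequence[str | Path],
    color_map: Mapping[int, tuple[int, int, int]],
    resolution_mm: float,
    z_origin: float = 0.0,
) -> LabelVolume:
    """Read an ordered sequence of RGB slice images into a LabelVolume.

    Each file holds one x-y slice (or a multi-page TIFF holding several);
    file order defines increasing depth. Non-background pixels must match a
    ``color_map`` entry exactly; black ``(0, 0, 0)`` is background.

    Raises
    ------
    DimensionError
        If slices disagree in 2D shape.
    AnnotationError
        If a pixel color is neither background nor in ``color_map``,
        naming the offending slice and color.
    """
    slices: list[np.ndarray] = []
    shape2d: tuple[int, int] | None = None
    for path in paths:
        pages = tifffile.imread(str(path))
        if pages.ndim == 3 and pages.shape[-1] not in (3, 4):
            page_list = list(pages)  # multi-page grayscale (unexpected)
        elif pages.ndim == 4:
            page_list = list(pages)  # multi-page RGB
        else:
            page_list = [pages]
        for page in page_list:
            if page.ndim == 3 and page.shape[-1] == 4:
                page = page[..., :3]
            if shape2d is None:
                shape2d = page.shape[:2]
            elif page.shape[:2] != shape2d:
                raise DimensionError(
                    f"slice {path} has shape {page.shape[:2]}, "
                    f"expected {shape2d}"
                )
            slices.append(_slice_to_labels(page, color_map, str(path)))
    if not slices:
        raise ValueError("no slices given")
    # slices are (row=y, col=x); volume is (x, y, z)
    labels = np.stack([s.T for s in slices], axis=-1)
    return LabelVolume(
        labels=labels,
        resolution_mm=resolution_mm,
        z_origin=z_origin,
        color_map={k: tuple(v) for k, v in color_map.items()},
    )


def write_label_stack(
    volume: LabelVolume,
    path: str | Path,
    color_map: Mapping[int, tuple[int, int, int]] | None = None,
) -> Path:
    """Write a LabelVolume as a multi-page 8-bit RGB TIFF (one page per z).

    Colors come from ``color_map`` or the volume's own; every positive
    label must have a color.
    """
    cmap = dict(color_map) if color_map is not None else dict(volume.color_map)
    missing = [i for i in volume.individual_ids if i not in cmap]
    if missing:
        raise AnnotationError(f"no color assigned to individuals {missing}")
    nx, ny, nz = volume.shape
    rgb = np.zeros((nz, ny, nx, 3), dtype=np.uint8)
    for ind_id, color in cmap.items():
        mask = (volume.labels == ind_id).transpose(2, 1, 0)
        rgb[mask] = np.asarray(color, dtype=np.uint8)
    path = Path(path)
    tifffile.imwrite(str(path), rgb, photometric="rgb")
    return path


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Lossless interchange export: one 16-bit grayscale page per slice."""
    if volume.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed 16-bit range")
    pages = volume.labels.astype(np.uint16).transpose(2, 1, 0)
    path = Path(path)
    tifffile.imwrite(str(path), pages, photometric="minisblack")
    return path


def load_label_volume(
    path: str | Path, resolution_mm: float, z_origin: float = 0.0
) -> LabelVolume:
    """Read a 16-bit grayscale label export back into a LabelVolume."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    labels = pages.transpose(2, 1, 0).astype(np.int32)
    return LabelVolume(labels=labels, resolution_mm=resolution_mm, z_origin=z_origin)


def concatenate_stacks(stacks: Sequence[LabelVolume]) -> LabelVolume:
    """Concatenate sequential stacks along depth.

    z-extents sum; stack ``i`` starts at the cumulative depth of its
    predecessors. All stacks must share x-y shape and resolution. The first
    stack's ``z_origin`` and the union of color maps carry over.
    """
    if not stacks:
        raise ValueError("no stacks to concatenate")
    first = stacks[0]
    for s in stacks[1:]:
        if s.shape[:2] != first.shape[:2]:
            raise DimensionError(
                f"x-y shape mismatch: {s.shape[:2]} vs {first.shape[:2]}"
            )
        if s.resolution_mm != first.resolution_mm:
            raise DimensionError(
                f"resolution mismatch: {s.resolution_mm} vs {first.resolution_mm}"
            )
    labels = np.concatenate([s.labels for s in stacks], axis=2)
    cmap: dict[int, tuple[int, int, int]] = {}
    for s in stacks:
        cmap.update(s.color_map)
    return LabelVolume(
        labels=labels,
        resolution_mm=first.resolution_mm,
        z_origin=first.z_origin,
        color_map=cmap,
    )


def extract_individual(
    volume: LabelVolume, individual_id: int, allow_absent: bool = True
) -> VoxelGrid:
    """Isolate one individual's binary occupancy grid.

    ``occupancy == 1`` exactly where ``labels == individual_id``;
    resolution and depth origin carry over. Extracting an id absent from
    the volume returns an empty grid with a warning.
    """
    if individual_id <= 0:
        raise ValueError(f"individual_id must be positive, got {individual_id}")
    occ = (volume.labels == individual_id).astype(np.uint8)
    if occ.sum() == 0:
        if not allow_absent:
            raise ValueError(f"individual {individual_id} not present in volume")
        warnings.warn(
            f"individual {individual_id} not present; returning empty grid",
            stacklevel=2,
        )
    return VoxelGrid(
        occupancy=occ,
        resolution_mm=volume.resolution_mm,
        z_origin=volume.z_origin,
    )
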