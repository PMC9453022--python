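"""Toy brain geometries and parcellation atlases.

Desk-scale stand-ins for a whole-brain gray-matter template and a
labelled parcellation (AAL-style).  A :class:`ToyGeometry` is a 3-D
grid with voxel size in mm and a binary gray-matter mask; a
:class:`ToyAtlas` partitions the in-mask voxels into labelled regions.
Real NIfTI masks/atlases can be loaded into the same types via
:mod:`neurodc.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ToyGeometry", "ToyAtlas", "generate_toy_geometry", "generate_toy_atlas"]


@dataclass
class ToyGeometry:
    """A 3-D voxel grid with physical voxel size and a binary mask."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.mask.shape != self.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} disagrees with grid shape {self.shape}"
            )
        if int(self.mask.sum()) < 2:
            raise ValueError("mask must contain at least 2 voxels")

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def mask_coordinates(self) -> np.ndarray:
        """(n_mask_voxels, 3) integer coordinates in C order."""
        return np.argwhere(self.mask)


@dataclass
class ToyAtlas:
    """Integer-labelled parcellation (0 = background) over a geometry."""

    labels: np.ndarray
    region_ids: list[int]
    region_names: list[str]
    geometry: ToyGeometry | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.region_ids = [int(r) for r in self.region_ids]
        if len(self.region_ids) != len(self.region_names):
            raise ValueError("one name per region id required")
        if any(r <= 0 for r in self.region_ids):
            raise ValueError("region ids must be positive")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.region_ids)
        if unknown:
            raise ValueError(f"label values {sorted(unknown)} missing from region_ids")
        if self.geometry is not None:
            if self.labels.shape != self.geometry.shape:
                raise ValueError("atlas and geometry shapes disagree")
            in_mask = self.labels[self.geometry.mask]
            for rid in self.region_ids:
                if not np.any(in_mask == rid):
                    raise ValueError(f"region {rid} has no in-mask voxels")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def generate_toy_geometry(
    shape: tuple[int, int, int] = (16, 16, 16),
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    mask_rule: str = "sphere",
    radius: float | None = None,
) -> ToyGeometry:
    """Build a deterministic toy geometry.

    ``mask_rule="full"`` marks every voxel as gray matter;
    ``mask_rule="sphere"`` keeps voxels whose center lies within
    ``radius`` voxels (default: 0.45 * min(shape)) of the volume center.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 4 for s in shape):
        raise ValueError(f"each axis must have >= 4 voxels, got {shape}")
    if mask_rule == "full":
        mask = np.ones(shape, dtype=bool)
    elif mask_rule == "sphere":
        if radius is None:
            radius = 0.45 * min(shape)
        center = (np.asarray(shape) - 1) / 2.0
        grid = np.indices(shape).reshape(3, -1).T
        dist = np.linalg.norm(grid - center, axis=1)
        mask = (dist <= radius).reshape(shape)
    else:
        raise ValueError(f"unknown mask rule {mask_rule!r}")
    if int(mask.sum()) < 2:
        raise ValueError(f"mask rule {mask_rule!r} produced an (almost) empty mask")
    return ToyGeometry(shape=shape, voxel_size_mm=voxel_size_mm, mask=mask)


def generate_toy_atlas(geometry: ToyGeometry, n_regions: int, seed: int = 0) -> ToyAtlas:
    """Partition the in-mask voxels into ``n_regions`` contiguous-ish regions.

    ``n_regions`` seed voxels are drawn at random and every in-mask
    voxel is assigned to its nearest seed (a Voronoi parcellation), so
    each region is nonempty and spatially compact.  Deterministic for a
    given seed.
    """
    if n_regions < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    coords = geometry.mask_coordinates()
    if n_regions > len(coords):
        raise ValueError(
            f"cannot split {len(coords)} in-mask voxels into {n_regions} regions"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xA71A5,)))
    seed_idx = rng.choice(len(coords), size=n_regions, replace=False)
    centers = coords[seed_idx]
    dists = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    assignment = np.argmin(dists, axis=1) + 1
    labels = np.zeros(geometry.shape, dtype=int)
    labels[tuple(coords.T)] = assignment
    region_ids = list(range(1, n_regions + 1))
    region_names = [f"region_{r:03d}" for r in region_ids]
    return ToyAtlas(
        labels=labels,
        region_ids=region_ids,
        region_names=region_names,
        geometry=geometry,
    )
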