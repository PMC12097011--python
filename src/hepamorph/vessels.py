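"""Vein and sinusoid segmentation.

Vein trees are segmented by seeded region growing (intensity-window flood
fill); sinusoids by global thresholding with vessel subtraction and
minimum-size filtering; vein branches are classified central vs portal by
companion-structure proximity — portal veins run alongside the hepatic
artery and bile duct, central veins have no such companions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .morphometry import SkeletonGraph

__all__ = [
    "SeedPoint",
    "region_grow",
    "segment_sinusoids",
    "classify_vein_branches",
    "split_by_seed",
]


@dataclass
class SeedPoint:
    """A physical-µm seed for region growing.

    Physical coordinates keep seed files valid across resampling.
    """

    position: tuple[float, float, float]  # µm
    claimed_type: str = "unknown"  # central | portal | unknown


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def region_grow(
    gray: VoxelGrid,
    seeds: list[SeedPoint],
    low: float,
    high: float,
    connectivity: int = 26,
) -> VoxelGrid:
    """Seeded region growing within an intensity window.

    Each output label is the maximal connected set of voxels with
    intensity in [low, high] reachable from its seed — identical to a
    breadth-first flood fill.  A voxel reachable from several seeds takes
    the label of the *first* such seed in list order (documented
    tie-break); labels are 1-based in seed order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    data = np.asarray(gray.data)
    within = (data >= low) & (data <= high)
    comp, _ = ndimage.label(within, structure=_STRUCTURES[connectivity])
    out = np.zeros(gray.shape, dtype=np.int32)
    claimed: dict[int, int] = {}
    for i, seed in enumerate(seeds):
        idx = gray.world_to_index(seed.position)
        if not all(0 <= v < n for v, n in zip(idx, gray.shape)):
            raise ValueError(f"seed {i} at {seed.position} µm lies outside the volume")
        val = data[idx]
        if not (low <= val <= high):
            raise ValueError(
                f"seed {i} at {seed.position} µm has intensity {val}, "
                f"outside the growing window [{low}, {high}]"
            )
        c = int(comp[idx])
        if c not in claimed:  # first seed in list order wins contested components
            claimed[c] = i + 1
            out[comp == c] = i + 1
    return gray.with_data(out, kind="labels")


def segment_sinusoids(
    gray: VoxelGrid,
    low: float,
    high: float,
    vessel_mask: VoxelGrid,
    min_volume_um3: float = 0.0,
) -> VoxelGrid:
    """Threshold the sinusoid+vessel lumens, subtract vessels, size-filter.

    mask = (low ≤ gray ≤ high) − vessel_mask, with connected components
    smaller than ``min_volume_um3`` removed (26-connectivity).
    """
    gray.require_same_grid(vessel_mask, "vessel_mask")
    data = np.asarray(gray.data)
    mask = (data >= low) & (data <= high)
    mask &= ~(np.asarray(vessel_mask.data) > 0)
    if min_volume_um3 > 0 and mask.any():
        comp, n = ndimage.label(mask, structure=_STRUCTURES[26])
        counts = np.bincount(comp.ravel())
        min_voxels = min_volume_um3 / gray.voxel_volume
        small = np.flatnonzero(counts < min_voxels)
        mask &= ~np.isin(comp, small[small > 0])
    return gray.with_data(mask.astype(np.int8), kind="labels")


def classify_vein_branches(
    vein_graph: SkeletonGraph,
    companion_mask: VoxelGrid,
    search_radius_um: float = 40.0,
    companion_fraction_threshold: float = 0.5,
) -> list[str]:
    """Classify each vein branch as central or portal by companion proximity.

    A branch is portal iff the fraction of its centreline points that
    have companion (artery / bile-duct) voxels within ``search_radius_um``
    *exceeds* ``companion_fraction_threshold``; otherwise central.  An
    empty companion mask classifies everything central.
    """
    if not vein_graph.edges:
        raise ValueError("vein_graph has no branches")
    if search_radius_um <= 0:
        raise ValueError("search_radius must be positive")
    comp = np.asarray(companion_mask.data) > 0
    if not comp.any():
        return ["central"] * len(vein_graph.edges)
    # distance from every voxel to the nearest companion voxel
    dist = ndimage.distance_transform_edt(~comp, sampling=companion_mask.spacing)
    spacing = np.asarray(companion_mask.spacing)
    origin = np.asarray(companion_mask.origin)
    shape = np.asarray(comp.shape)
    classes = []
    for e in vein_graph.edges:
        idx = np.round((e.polyline - origin) / spacing).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        near = dist[idx[:, 0], idx[:, 1], idx[:, 2]] <= search_radius_um
        frac = float(near.mean())
        classes.append("portal" if frac > companion_fraction_threshold else "central")
    return classes


def split_by_seed(
    label_grid: VoxelGrid, seeds: list[SeedPoint], connectivity: int = 26
) -> dict[str, VoxelGrid]:
    """Split a labelled vessel volume into central/portal masks by seed type.

    Each connected component is assigned wholly to the ``claimed_type``
    of the seed(s) it contains; a component containing seeds of
    conflicting types, or no seed at all, is an error.
    """
    mask = np.asarray(label_grid.data) > 0
    comp, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    comp_type: dict[int, str] = {}
    for i, seed in enumerate(seeds):
        idx = label_grid.world_to_index(seed.position)
        if not all(0 <= v < m for v, m in zip(idx, label_grid.shape)):
            raise ValueError(f"seed {i} at {seed.position} µm lies outside the volume")
        c = int(comp[idx])
        if c == 0:
            raise ValueError(f"seed {i} at {seed.position} µm is not inside any component")
        prev = comp_type.get(c)
        if prev is not None and prev != seed.claimed_type:
            raise ValueError(
                f"component {c} contains conflicting seeds ({prev} and {seed.claimed_type})"
            )
        comp_type[c] = seed.claimed_type
    orphans = sorted(set(range(1, n + 1)) - set(comp_type))
    if orphans:
        raise ValueError(f"components without any seed: {orphans}")
    out: dict[str, VoxelGrid] = {}
    for kind in ("central", "portal"):
        comps = [c for c, t in comp_type.items() if t == kind]
        m = np.isin(comp, comps)
        out[kind] = label_grid.with_data(m.astype(np.int8), kind="labels")
    return out
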