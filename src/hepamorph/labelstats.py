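"""Per-connected-component shape analysis and aggregate statistics.

Reproduces the structure of a per-object label analysis: for every
connected component of a binary mask, Volume3d (voxel count × voxel
volume), EqDiameter ((6V/π)^(1/3), the diameter of the equal-volume
sphere), Length3d (maximum Feret diameter over the component's convex
hull), Thickness3d (2 × the maximum inscribed distance-transform value),
Perimeter (per-slice 2D boundary length summed along the slicing axis),
and Shape_VA3d (Area³ / (36π V²), a sphericity index that equals 1 for a
perfect sphere and grows with shape complexity).

Surface area for Shape_VA3d uses exposed-face counting with a 2/3
correction: counting exposed voxel faces overestimates the area of a
smooth surface by a factor of 3/2 on average over orientations, so the
corrected estimate is asymptotically unbiased.  Voxelization still leaves
Shape_VA3d of tiny components below 1 (down to ≈0.2 for a single voxel),
which is documented rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .grid import VoxelGrid

__all__ = [
    "ComponentTable",
    "AggregateTable",
    "connected_components",
    "measure_components",
    "aggregate",
    "eq_diameter",
    "volume_fraction_percent",
]

MEASURE_COLUMNS = ["Length3d", "Thickness3d", "EqDiameter", "Volume3d", "Shape_VA3d", "Perimeter"]

_FACE_AREA_CORRECTION = 2.0 / 3.0


def eq_diameter(volume_um3) -> np.ndarray | float:
    """Diameter of the sphere with the same volume: (6V/π)^(1/3)."""
    return (6.0 * np.asarray(volume_um3, dtype=float) / math.pi) ** (1.0 / 3.0)


def volume_fraction_percent(structure_volume, reference_volume) -> np.ndarray | float:
    """100 × structure / reference — the lobe- and block-level fraction."""
    structure = np.asarray(structure_volume, dtype=float)
    reference = np.asarray(reference_volume, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference volume must be positive")
    return 100.0 * structure / reference


@dataclass
class ComponentTable:
    """Per-component shape measures; one row per connected component."""

    table: pd.DataFrame  # columns MEASURE_COLUMNS, index = component label

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AggregateTable:
    """Summary statistics per measure plus the overall volume fraction."""

    table: pd.DataFrame  # rows Mean..Total, columns MEASURE_COLUMNS
    volume_fraction: float


def connected_components(mask: VoxelGrid, connectivity: int = 26) -> VoxelGrid:
    """Label maximal connected sets 1..n, deterministic by scan order."""
    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    comp, _ = ndimage.label(np.asarray(mask.data) > 0, structure=struct)
    return mask.with_data(comp.astype(np.int32), kind="labels")


def _max_feret(coords_um: np.ndarray, spacing: np.ndarray) -> float:
    """Maximum Feret diameter over the corners of the component's voxels."""
    half = spacing / 2.0
    corners = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                corners.append(coords_um + half * np.array([sx, sy, sz]))
    pts = np.unique(np.vstack(corners), axis=0)
    if len(pts) > 16:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar) components: brute-force below
    if len(pts) > 4000:  # cap the quadratic pairwise search
        sel = np.linspace(0, len(pts) - 1, 4000).astype(int)
        pts = pts[sel]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _slice_perimeter(mask2d: np.ndarray, edge_len: float) -> float:
    """4-connected boundary length of a 2D mask (exposed edge count × length)."""
    m = mask2d
    n = int(m.sum())
    if n == 0:
        return 0.0
    adj_x = int(np.logical_and(m[1:, :], m[:-1, :]).sum())
    adj_y = int(np.logical_and(m[:, 1:], m[:, :-1]).sum())
    return (4 * n - 2 * (adj_x + adj_y)) * edge_len


def _surface_area(mask3d: np.ndarray, face_area: float) -> float:
    """Corrected exposed-face surface area estimate."""
    m = mask3d
    n = int(m.sum())
    adj = 0
    for ax in range(3):
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[ax] = slice(1, None)
        sl2[ax] = slice(None, -1)
        adj += int(np.logical_and(m[tuple(sl1)], m[tuple(sl2)]).sum())
    exposed_faces = 6 * n - 2 * adj
    return exposed_faces * face_area * _FACE_AREA_CORRECTION


def measure_components(labels: VoxelGrid) -> ComponentTable:
    """Shape measures for every labelled component.

    Requires an isotropic grid so that Feret diameters, thicknesses and
    perimeters are direction-independent.
    """
    if not labels.is_isotropic:
        raise ValueError("measure_components requires an isotropic grid; resample first")
    comp = np.asarray(labels.data)
    n = int(comp.max())
    spacing = np.asarray(labels.spacing)
    h = float(spacing[0])
    voxvol = labels.voxel_volume
    objects = ndimage.find_objects(comp)
    rows = []
    for lbl in range(1, n + 1):
        sl = objects[lbl - 1]
        if sl is None:
            continue
        sub = comp[sl] == lbl
        nvox = int(sub.sum())
        volume = nvox * voxvol
        # pad so the distance transform sees background on every side
        padded = np.pad(sub, 1)
        edt = ndimage.distance_transform_edt(padded, sampling=spacing)
        thickness = 2.0 * float(edt.max())
        coords = np.argwhere(sub).astype(float)
        offset = np.array([s.start for s in sl], dtype=float)
        coords_um = (coords + offset) * spacing
        length = _max_feret(coords_um, spacing)
        perimeter = sum(_slice_perimeter(sub[k], h) for k in range(sub.shape[0]))
        area = _surface_area(sub, h * h)
        shape_va = area**3 / (36.0 * math.pi * volume**2)
        rows.append(
            {
                "label": lbl,
                "Length3d": length,
                "Thickness3d": thickness,
                "EqDiameter": float(eq_diameter(volume)),
                "Volume3d": volume,
                "Shape_VA3d": shape_va,
                "Perimeter": perimeter,
            }
        )
    df = pd.DataFrame(rows, columns=["label"] + MEASURE_COLUMNS)
    if len(df):
        df = df.set_index("label")
    else:
        df = df.set_index("label")
    return ComponentTable(df)


def _raw_moment_stats(x: np.ndarray) -> tuple[float, float]:
    """(skewness, raw non-excess kurtosis) from population moments.

    Raw kurtosis is the fourth standardized moment m4/m2²; under a single
    dominant outlier among n values it approaches n.
    """
    x = np.asarray(x, dtype=float)
    m = x.mean()
    d = x - m
    m2 = float(np.mean(d**2))
    if m2 == 0:
        return math.nan, math.nan
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return m3 / m2**1.5, m4 / m2**2


def aggregate(table: ComponentTable, roi_volume_um3: float) -> AggregateTable:
    """Summary statistics over components plus the overall volume fraction.

    Variance is the sample variance (ddof=1); skewness and kurtosis are
    population standardized moments (kurtosis raw, non-excess).  With a
    single component the variance is 0 and skewness/kurtosis are NaN.
    """
    if len(table) == 0:
        raise ValueError("empty component table")
    if roi_volume_um3 <= 0:
        raise ValueError("roi_volume must be positive")
    df = table.table
    stats_rows = {}
    stats_rows["Mean"] = df.mean()
    stats_rows["Min"] = df.min()
    stats_rows["Max"] = df.max()
    stats_rows["Median"] = df.median()
    stats_rows["Variance"] = df.var(ddof=1) if len(df) > 1 else pd.Series(0.0, index=df.columns)
    skew = {}
    kurt = {}
    for col in df.columns:
        s, k = _raw_moment_stats(df[col].to_numpy())
        skew[col], kurt[col] = s, k
    stats_rows["Kurtosis"] = pd.Series(kurt)
    stats_rows["Skewness"] = pd.Series(skew)
    stats_rows["Total"] = df.sum()
    out = pd.DataFrame(stats_rows).T[MEASURE_COLUMNS]
    vf = float(df["Volume3d"].sum() / roi_volume_um3)
    return AggregateTable(out, volume_fraction=vf)
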