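"""Sampling scalar volumes along surface normals and grid resampling.

Each vertex of the GM/WM boundary mesh is probed at four signed offsets along
its outward unit normal — by default +1 mm (cortical GM), 0 mm (boundary),
-1 mm (superficial WM) and -2 mm (superficial/deep WM).  Surface sampling is
trilinear by default (cubic available); points leaving the grid yield missing
values, never extrapolations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import DEPTH_OFFSETS_MM
from .mesh import SurfaceMesh
from .volume import MetricVolume

log = logging.getLogger(__name__)

_ORDERS = {"linear": 1, "cubic": 3}


@dataclass
class ProfileSamples:
    """Per-vertex metric values at signed depth offsets (mm, outward positive).

    ``values`` is (n_vertices, n_offsets); NaN marks missing samples.  The
    default offset order runs outward to inward and must be strictly
    decreasing.
    """

    values: np.ndarray
    depth_offsets: tuple[float, ...] = DEPTH_OFFSETS_MM
    source_metric: str = "scalar"
    participant_id: str | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_offsets = tuple(float(s) for s in self.depth_offsets)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.depth_offsets):
            raise ValueError("values must be (n_vertices, n_offsets)")
        if not all(a > b for a, b in zip(self.depth_offsets, self.depth_offsets[1:])):
            raise ValueError("depth offsets must be strictly decreasing (outward first)")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def to_frame(self, roi_label: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy table (participant_id, hemisphere, vertex, roi, metric, offset_mm, value)."""
        n, k = self.values.shape
        frame = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "hemisphere": self.hemisphere,
                "vertex": np.repeat(np.arange(n), k),
                "roi": -1 if roi_label is None else np.repeat(np.asarray(roi_label), k),
                "metric": self.source_metric,
                "offset_mm": np.tile(self.depth_offsets, n),
                "value": self.values.ravel(),
            }
        )
        return frame


def _interpolate_at_voxels(
    data: np.ndarray, coords: np.ndarray, order: int
) -> np.ndarray:
    """Interpolate at continuous voxel coordinates (n, 3); outside -> NaN."""
    inside = np.all(
        (coords >= 0.0) & (coords <= np.array(data.shape) - 1.0 + 1e-9), axis=1
    )
    out = np.full(len(coords), np.nan)
    if np.any(inside):
        out[inside] = ndimage.map_coordinates(
            data, coords[inside].T, order=order, mode="nearest"
        )
    return out


def sample_profile(
    volume: MetricVolume,
    mesh: SurfaceMesh,
    depth_offsets: tuple[float, ...] = DEPTH_OFFSETS_MM,
    interpolation: str = "linear",
) -> ProfileSamples:
    """Sample the volume at ``vertex + offset * normal`` for every vertex.

    Mesh and volume must share one world coordinate system in mm.  No
    averaging across vertices happens here.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    norms = np.linalg.norm(mesh.normals, axis=1)
    if np.max(np.abs(norms - 1.0)) >= 1e-6:
        raise ValueError("mesh normals must be unit length")
    offsets = np.asarray(depth_offsets, dtype=float)
    points = mesh.vertices[:, None, :] + offsets[None, :, None] * mesh.normals[:, None, :]
    coords = volume.world_to_voxel(points.reshape(-1, 3))
    vals = _interpolate_at_voxels(volume.data, coords, _ORDERS[interpolation])
    return ProfileSamples(
        values=vals.reshape(mesh.n_vertices, len(offsets)),
        depth_offsets=tuple(offsets),
        source_metric=volume.metric,
        participant_id=volume.participant_id,
        hemisphere=mesh.hemisphere,
    )


def resample_volume(
    volume: MetricVolume,
    rigid_transform: np.ndarray,
    interpolation: str = "cubic",
    target_affine: np.ndarray | None = None,
    target_shape: tuple[int, int, int] | None = None,
) -> MetricVolume:
    """Resample through a world-space rigid transform onto a target grid.

    ``rigid_transform`` (4x4) maps source-world to target-world coordinates;
    the target grid defaults to the source grid.  Voxels whose pre-image
    leaves the source field of view are set to NaN (missing), not
    extrapolated.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    t = np.asarray(rigid_transform, dtype=float)
    if t.shape != (4, 4) or abs(np.linalg.det(t)) < 1e-12:
        raise ValueError("rigid_transform must be an invertible 4x4 matrix")
    target_affine = volume.affine if target_affine is None else np.asarray(target_affine)
    target_shape = volume.shape if target_shape is None else tuple(target_shape)

    # target voxel -> target world -> source world -> source voxel
    m = np.linalg.inv(volume.affine) @ np.linalg.inv(t) @ target_affine
    idx = np.indices(target_shape, dtype=float).reshape(3, -1).T
    coords = idx @ m[:3, :3].T + m[:3, 3]
    vals = _interpolate_at_voxels(volume.data, coords, _ORDERS[interpolation])
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        log.info("resample_volume: %d voxels left the field of view", n_missing)
    return MetricVolume(
        vals.reshape(target_shape), target_affine, volume.metric, volume.participant_id
    )
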