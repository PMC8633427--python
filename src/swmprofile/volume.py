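"""Scalar metric volumes with a voxel-to-world affine, backed by NIfTI-1."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: valid value range per metric; None means unbounded on that side.
#: MD is in mm^2/s; the unit-interval metrics are dimensionless fractions.
METRIC_RANGES: dict[str, tuple[float, float | None]] = {
    "FA": (0.0, 1.0),
    "MD": (0.0, None),
    "NDI": (0.0, 1.0),
    "ODI": (0.0, 1.0),
    "TF": (0.0, 1.0),
}

#: representable full scale used for relative tolerances: the unit interval
#: for the bounded metrics, free-water diffusivity (3e-3 mm^2/s) for MD.
METRIC_FULL_SCALE: dict[str, float] = {
    "FA": 1.0,
    "MD": 3.0e-3,
    "NDI": 1.0,
    "ODI": 1.0,
    "TF": 1.0,
}


@dataclass
class MetricVolume:
    """A 3-D scalar grid in a world (mm) coordinate system.

    Attributes
    ----------
    data : 3-D float array; NaN marks undefined voxels.
    affine : 4x4 voxel-to-world transform in mm; must be invertible.
    metric : one of FA, MD, NDI, ODI, TF (or any label for generic fields).
    participant_id : identifier of the scan's participant, if any.
    """

    data: np.ndarray
    affine: np.ndarray
    metric: str = "scalar"
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-space points (n, 3) to continuous voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def validate_range(self) -> None:
        """Raise if defined voxels violate the metric's valid range."""
        lo, hi = METRIC_RANGES.get(self.metric, (None, None))
        vals = self.data[np.isfinite(self.data)]
        if vals.size == 0:
            return
        if lo is not None and vals.min() < lo - 1e-12:
            raise ValueError(f"{self.metric} below {lo}: min={vals.min()}")
        if hi is not None and vals.max() > hi + 1e-12:
            raise ValueError(f"{self.metric} above {hi}: max={vals.max()}")

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header["descrip"] = f"{self.metric}; MD in mm^2/s".encode()[:79]
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def load(
        cls, path: str | Path, metric: str = "scalar", participant_id: str | None = None
    ) -> "MetricVolume":
        img = nib.load(str(path))
        return cls(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            affine=img.affine,
            metric=metric,
            participant_id=participant_id,
        )
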