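"""Triangulated GM/WM boundary surfaces with per-vertex ROI labels.

Real cohorts supply FreeSurfer-derived boundary meshes; the synthetic cohort
uses spherical phantoms (one sphere per hemisphere) so that the signed depth
of any world point from the boundary is known in closed form.  Outward unit
normals point from white matter toward the pial surface; on a sphere they are
exactly radial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull

DEFAULT_RADIUS_MM = 49.0


@dataclass
class SurfaceMesh:
    """Boundary surface in world (mm) coordinates.

    ``roi_label`` holds an integer in ``{0..roi_count-1}`` per vertex, or -1
    for unlabeled vertices.  ``center``/``radius``/``partition`` are present
    only on synthetic spherical meshes and make depth and ROI membership
    analytic functions of position.
    """

    vertices: np.ndarray          # (N, 3) mm
    faces: np.ndarray             # (F, 3) vertex indices
    normals: np.ndarray           # (N, 3) outward unit vectors
    roi_label: np.ndarray         # (N,) int
    hemisphere: str               # "left" | "right"
    center: np.ndarray | None = None
    radius: float | None = None
    partition: dict | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.normals = np.asarray(self.normals, dtype=float)
        self.roi_label = np.asarray(self.roi_label, dtype=int)
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def validate(self) -> None:
        """Check the structural invariants of a boundary mesh."""
        norms = np.linalg.norm(self.normals, axis=1)
        if np.max(np.abs(norms - 1.0)) >= 1e-6:
            raise ValueError("normals are not unit length")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face indices out of range")
        labeled = self.roi_label[self.roi_label >= 0]
        if labeled.size and labeled.max() >= 15 and self.partition is None:
            # real atlases carry 15 regions; synthetic meshes record their own
            raise ValueError("ROI label outside the 15-region atlas")

    # ------------------------------------------------- analytic sphere ops
    def signed_depth(self, points: np.ndarray) -> np.ndarray:
        """Depth into white matter (mm, positive inward) of world points.

        Only defined for spherical phantom meshes, where the boundary is the
        sphere and white matter is its interior.
        """
        if self.center is None or self.radius is None:
            raise ValueError("signed_depth requires a spherical phantom mesh")
        r = np.linalg.norm(np.atleast_2d(points) - self.center, axis=1)
        return self.radius - r

    def roi_of_points(self, points: np.ndarray) -> np.ndarray:
        """ROI label of world points by radial projection onto the sphere."""
        if self.partition is None or self.center is None:
            raise ValueError("roi_of_points requires a spherical phantom mesh")
        rel = np.atleast_2d(points) - self.center
        r = np.linalg.norm(rel, axis=1)
        r = np.where(r == 0, 1.0, r)
        z = rel[:, 2] / r
        lon = np.arctan2(rel[:, 1], rel[:, 0])
        return _labels_from_partition(z, lon, self.partition)

    # ----------------------------------------------------------------- I/O
    def to_json(self, path: str | Path) -> Path:
        """Write the documented JSON mesh format."""
        payload = {
            "format": "swmprofile-mesh-v1",
            "hemisphere": self.hemisphere,
            "vertices": self.vertices.tolist(),
            "faces": self.faces.tolist(),
            "normals": self.normals.tolist(),
            "roi_label": self.roi_label.tolist(),
            "center": None if self.center is None else self.center.tolist(),
            "radius": self.radius,
            "partition": _partition_to_json(self.partition),
        }
        path = Path(path)
        path.write_text(json.dumps(payload) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SurfaceMesh":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "swmprofile-mesh-v1":
            raise ValueError(f"{path}: not a swmprofile JSON mesh")
        return cls(
            vertices=np.array(payload["vertices"], dtype=float),
            faces=np.array(payload["faces"], dtype=int).reshape(-1, 3),
            normals=np.array(payload["normals"], dtype=float),
            roi_label=np.array(payload["roi_label"], dtype=int),
            hemisphere=payload["hemisphere"],
            center=None if payload["center"] is None else np.array(payload["center"]),
            radius=payload["radius"],
            partition=_partition_from_json(payload["partition"]),
        )


def _partition_to_json(partition: dict | None):
    if partition is None:
        return None
    return {
        "z_edges": np.asarray(partition["z_edges"]).tolist(),
        "lon_edges": [np.asarray(e).tolist() for e in partition["lon_edges"]],
        "band_offset": np.asarray(partition["band_offset"]).tolist(),
    }


def _partition_from_json(payload):
    if payload is None:
        return None
    return {
        "z_edges": np.array(payload["z_edges"], dtype=float),
        "lon_edges": [np.array(e, dtype=float) for e in payload["lon_edges"]],
        "band_offset": np.array(payload["band_offset"], dtype=int),
    }


def _labels_from_partition(z: np.ndarray, lon: np.ndarray, partition: dict) -> np.ndarray:
    z_edges = partition["z_edges"]              # interior band boundaries, ascending z
    band = np.searchsorted(z_edges, z, side="right")
    labels = np.empty(z.shape, dtype=int)
    for b, lon_edges in enumerate(partition["lon_edges"]):
        in_band = band == b
        if not np.any(in_band):
            continue
        sector = np.searchsorted(lon_edges, lon[in_band], side="right")
        labels[in_band] = partition["band_offset"][b] + sector
    return labels


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit points by the golden-angle spiral."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _build_partition(units: np.ndarray, roi_count: int) -> tuple[np.ndarray, dict]:
    """Split unit directions into contiguous latitude/longitude patches.

    Bands are equal-count in z; each band is split into equal-count longitude
    sectors.  Edges are midpoints between adjacent sorted values, stored so
    that arbitrary points (e.g. voxel centres) can be labeled by the same
    rule.  Every patch is non-empty whenever ``len(units) >= roi_count``.
    """
    n = len(units)
    n_bands = max(1, int(round(np.sqrt(roi_count))))
    n_bands = min(n_bands, roi_count)
    base, extra = divmod(roi_count, n_bands)
    sectors_per_band = [base + (1 if b < extra else 0) for b in range(n_bands)]

    z = units[:, 2]
    lon = np.arctan2(units[:, 1], units[:, 0])
    order_z = np.argsort(z, kind="stable")

    # band sizes proportional to sector counts, each at least its sector count
    cum = np.cumsum(sectors_per_band)
    splits = [int(round(n * c / roi_count)) for c in cum[:-1]]
    band_indices = np.split(order_z, splits)

    z_sorted = z[order_z]
    z_edges = np.array(
        [0.5 * (z_sorted[s - 1] + z_sorted[s]) for s in splits], dtype=float
    )

    labels = np.empty(n, dtype=int)
    lon_edges_all: list[np.ndarray] = []
    band_offset = np.concatenate([[0], cum[:-1]])
    for b, idx in enumerate(band_indices):
        k = sectors_per_band[b]
        if len(idx) < k:
            raise ValueError("too few vertices for the requested ROI count")
        order_lon = idx[np.argsort(lon[idx], kind="stable")]
        sector_chunks = np.array_split(order_lon, k)
        edges = []
        for s_i in range(1, k):
            lo = lon[sector_chunks[s_i - 1][-1]]
            hi = lon[sector_chunks[s_i][0]]
            edges.append(0.5 * (lo + hi))
        lon_edges_all.append(np.array(edges, dtype=float))
        for s_i, chunk in enumerate(sector_chunks):
            labels[chunk] = band_offset[b] + s_i

    partition = {
        "z_edges": z_edges,
        "lon_edges": lon_edges_all,
        "band_offset": np.asarray(band_offset, dtype=int),
    }
    return labels, partition


def _outward_faces(units: np.ndarray) -> np.ndarray:
    hull = ConvexHull(units)
    faces = hull.simplices.copy()
    # orient each triangle counter-clockwise seen from outside the sphere
    a, b, c = units[faces[:, 0]], units[faces[:, 1]], units[faces[:, 2]]
    fn = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", fn, (a + b + c) / 3.0) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def generate_mesh(
    vertices_per_hemi: int,
    roi_count: int,
    seed: int,
    radius: float = DEFAULT_RADIUS_MM,
    gap: float = 8.0,
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Generate left/right spherical boundary phantoms.

    Each hemisphere is a sphere of the given radius (mm); sphere centres sit
    on the x axis separated so the shells do not touch.  Vertices are a
    seeded random rotation of a golden-angle spiral, so patches move with the
    seed while staying contiguous in latitude/longitude.

    Returns the (left, right) meshes; both carry the analytic partition used
    to label arbitrary world points.
    """
    if vertices_per_hemi <= 0 or roi_count <= 0:
        raise ValueError("vertices_per_hemi and roi_count must be positive")
    if vertices_per_hemi < roi_count:
        raise ValueError("need at least one vertex per ROI")

    offset = radius + gap / 2.0
    centers = {"left": np.array([-offset, 0.0, 0.0]), "right": np.array([offset, 0.0, 0.0])}
    rng = np.random.default_rng(seed)
    meshes = []
    for hemi in ("left", "right"):
        rot = _random_rotation(rng)
        units = _fibonacci_sphere(vertices_per_hemi) @ rot.T
        labels, partition = _build_partition(units, roi_count)
        faces = _outward_faces(units)
        meshes.append(
            SurfaceMesh(
                vertices=centers[hemi] + radius * units,
                faces=faces,
                normals=units,
                roi_label=labels,
                hemisphere=hemi,
                center=centers[hemi],
                radius=radius,
                partition=partition,
            )
        )
    return meshes[0], meshes[1]
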