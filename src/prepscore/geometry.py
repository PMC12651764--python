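"""Mesh input, deterministic point-cloud sampling and pose normalization.

Every training and inference path shares this preprocessing: read a
Wavefront OBJ surface mesh, sample it into a fixed-size point cloud by
area-weighted face selection with uniform barycentric placement, and
normalize the cloud to the unit sphere (centroid at the origin, maximum
radius 1).  Sampling is a pure function of (mesh, config): the random
generator is seeded from the configured seed together with a stable hash
of the mesh's source id, so batches are order-independent and the same
scan always yields the same points — and hence the same scores downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "SamplerConfig",
    "PointCloud",
    "GeometryError",
    "NoFacesError",
    "FaceIndexError",
    "ZeroAreaError",
    "DegenerateCloudError",
    "PointCloudIOError",
    "read_obj",
    "sample_point_cloud",
    "normalize",
    "write_point_cloud",
    "read_point_cloud",
]


class GeometryError(ValueError):
    """Base class for mesh/point-cloud errors."""


class NoFacesError(GeometryError):
    """A mesh has no (non-degenerate) faces."""


class FaceIndexError(GeometryError):
    """A face references a vertex index that does not exist."""


class ZeroAreaError(GeometryError):
    """A mesh has zero total surface area."""


class DegenerateCloudError(GeometryError):
    """All points coincide; the cloud cannot be normalized."""


class PointCloudIOError(GeometryError):
    """A point-cloud file is missing or malformed."""


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    ``vertices``: (V, 3) float array; ``faces``: (F, 3) int array of 0-based
    vertex indices.  Faces with zero area are not retained.
    """

    vertices: np.ndarray
    faces: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) == 0:
            raise NoFacesError(f"mesh {self.source_id!r} has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise FaceIndexError(
                f"mesh {self.source_id!r}: face index out of range "
                f"[0, {len(self.vertices) - 1}]"
            )

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def transformed(self, translation=(0.0, 0.0, 0.0), scale: float = 1.0) -> "TriangleMesh":
        """Rigidly translated and uniformly scaled copy (same source id)."""
        v = self.vertices * float(scale) + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces.copy(), source_id=self.source_id)


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling parameters.  ``n_points`` defaults to the 100,000 points
    used at train and inference time; the seed is fixed per run and recorded
    in the cloud's provenance."""

    n_points: int = 100_000
    seed: int = 0
    normalization: str = "unit_sphere"
    #: Mix the source id into the stream (order-independent batches).  Off,
    #: every mesh shares one stream — used by split hygiene probes.
    derive_from_source: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise GeometryError("n_points must be >= 1")
        if self.normalization != "unit_sphere":
            raise GeometryError(f"unknown normalization {self.normalization!r}")


@dataclass
class PointCloud:
    """Fixed-size surface sample with provenance (source id, seed,
    normalization flag)."""

    points: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def is_normalized(self) -> bool:
        return bool(self.provenance.get("normalized", False))


def _source_hash(source_id: str) -> int:
    digest = hashlib.sha256(source_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


# ---------------------------------------------------------------------------
# OBJ reading


def read_obj(path: str | Path) -> TriangleMesh:
    """Read a Wavefront OBJ surface mesh.

    Supports ``v`` and ``f`` records; ``vn``/``vt``/``mtllib``/``usemtl``/
    ``g``/``o``/``s`` and comments are ignored.  Polygons with more than
    three vertices are fan-triangulated; negative indices resolve relative
    to the vertices read so far (OBJ convention); zero-area faces are
    dropped with a logged count.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"OBJ file not found: {path}")

    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "v":
            if len(parts) < 4:
                raise GeometryError(f"{path}:{lineno}: malformed vertex line {raw!r}")
            vertices.append([float(x) for x in parts[1:4]])
        elif tag == "f":
            idx = []
            for token in parts[1:]:
                # "f v", "f v/vt", "f v/vt/vn", "f v//vn" all start with v
                i = int(token.split("/")[0])
                if i > 0:
                    i -= 1
                elif i < 0:
                    i += len(vertices)
                else:
                    raise FaceIndexError(f"{path}:{lineno}: OBJ index 0 is invalid")
                if i < 0 or i >= len(vertices):
                    raise FaceIndexError(
                        f"{path}:{lineno}: face index {token} out of range"
                    )
                idx.append(i)
            if len(idx) < 3:
                raise GeometryError(f"{path}:{lineno}: face with <3 vertices")
            for k in range(1, len(idx) - 1):  # fan triangulation
                faces.append([idx[0], idx[k], idx[k + 1]])
        # all other records ignored

    if not faces:
        raise NoFacesError(f"{path}: no faces found")
    mesh = TriangleMesh(np.asarray(vertices), np.asarray(faces), source_id=path.stem)
    areas = mesh.face_areas()
    keep = areas > 0.0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_obj(%s): dropped %d zero-area faces", path.name, dropped)
        if not keep.any():
            raise NoFacesError(f"{path}: no faces left after dropping degenerate ones")
        mesh = TriangleMesh(mesh.vertices, mesh.faces[keep], source_id=mesh.source_id)
    return mesh


# ---------------------------------------------------------------------------
# Sampling and normalization


def sample_point_cloud(mesh: TriangleMesh, config: SamplerConfig) -> PointCloud:
    """Sample ``config.n_points`` points uniformly over the mesh surface.

    Faces are chosen with probability proportional to area; points are
    placed by uniform barycentric coordinates (square-folding).  Output is
    bit-identical for identical (mesh, config).
    """
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0.0:
        raise ZeroAreaError(f"mesh {mesh.source_id!r} has zero total area")

    entropy = [int(config.seed)]
    if config.derive_from_source:
        entropy.append(_source_hash(mesh.source_id))
    rng = np.random.default_rng(np.random.SeedSequence(entropy))

    n = config.n_points
    cdf = np.cumsum(areas / total)
    cdf[-1] = 1.0
    face_idx = np.searchsorted(cdf, rng.random(n), side="left")

    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1.0
    u[flip] = 1.0 - u[flip]
    v[flip] = 1.0 - v[flip]

    tri = mesh.vertices[mesh.faces[face_idx]]  # (n, 3, 3)
    pts = tri[:, 0] + u[:, None] * (tri[:, 1] - tri[:, 0]) + v[:, None] * (tri[:, 2] - tri[:, 0])
    return PointCloud(
        pts,
        provenance={
            "source_id": mesh.source_id,
            "seed": int(config.seed),
            "n_points": n,
            "normalized": False,
        },
    )


def normalize(pc: PointCloud) -> PointCloud:
    """Centre the cloud at the origin and rescale so the farthest point
    sits on the unit sphere.  Idempotent up to floating point; invariant to
    rigid translation and positive uniform scaling of the input."""
    pts = pc.points
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    radius = float(np.linalg.norm(centred, axis=1).max())
    if radius <= 0.0:
        raise DegenerateCloudError("all points coincide; zero scale")
    prov = dict(pc.provenance)
    prov["normalized"] = True
    return PointCloud(centred / radius, provenance=prov)


# ---------------------------------------------------------------------------
# ASCII-PLY persistence (provenance carried in header comments)


def write_point_cloud(pc: PointCloud, path: str | Path) -> Path:
    """Write the cloud as ascii PLY; provenance is stored in a header
    comment so a round-trip recovers it."""
    if str(path) in ("", "."):
        raise PointCloudIOError("empty output path")
    path = Path(path)
    header = [
        "ply",
        "format ascii 1.0",
        "comment prepscore_provenance " + json.dumps(pc.provenance, sort_keys=True),
        f"element vertex {pc.n_points}",
        "property double x",
        "property double y",
        "property double z",
        "end_header",
    ]
    body = "\n".join(" ".join(f"{c:.9f}" for c in row) for row in pc.points)
    path.write_text("\n".join(header) + "\n" + body + "\n")
    return path


def read_point_cloud(path: str | Path) -> PointCloud:
    path = Path(path)
    if not path.is_file():
        raise PointCloudIOError(f"point-cloud file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PointCloudIOError(f"{path}: not an ascii PLY file")
    provenance: dict = {}
    n_vertex = None
    try:
        end = lines.index("end_header")
    except ValueError:
        raise PointCloudIOError(f"{path}: missing end_header") from None
    for line in lines[1:end]:
        parts = line.split(maxsplit=2)
        if parts[:2] == ["comment", "prepscore_provenance"] and len(parts) == 3:
            provenance = json.loads(parts[2])
        elif parts[:2] == ["element", "vertex"]:
            n_vertex = int(line.split()[2])
    if n_vertex is None:
        raise PointCloudIOError(f"{path}: no vertex element declared")
    rows = lines[end + 1 : end + 1 + n_vertex]
    if len(rows) != n_vertex:
        raise PointCloudIOError(f"{path}: expected {n_vertex} points, found {len(rows)}")
    pts = np.array([[float(x) for x in r.split()] for r in rows], dtype=np.float64)
    if pts.shape != (n_vertex, 3):
        raise PointCloudIOError(f"{path}: malformed point rows")
    return PointCloud(pts, provenance=provenance)
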