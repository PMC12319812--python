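"""Surface and volume primitives for head-geometry processing.

Conventions used throughout the package:

* World coordinates are RAS millimetres.
* Homogeneous transforms act on column vectors, ``p' = A @ [p; 1]``.
* Voxel indices are 0-based and the voxel *centre* sits at the integer
  index, so ``world = affine @ [i, j, k, 1]`` is the centre of voxel
  ``(i, j, k)``.
* Inside/outside decisions for voxelisation use the voxel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError
from skimage import measure


class EmptySurfaceError(ValueError):
    """No supra-threshold voxels: there is no surface to extract."""


class EmptyResultError(ValueError):
    """An operation removed every point."""


class DegenerateGeometryError(ValueError):
    """Input geometry does not span 3D (coplanar / collinear points)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangulated surface in world millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Each row indexes three distinct vertices.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        if self.faces.size and (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValueError("degenerate face repeats a vertex")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))

    @classmethod
    def load(cls, path) -> "TriangleMesh":
        """Read a PLY / STL / OBJ surface file."""
        tm = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(tm)

    def save(self, path) -> None:
        """Write the surface (format from the file suffix; PLY preferred)."""
        self.to_trimesh().export(str(path))

    def as_point_cloud(self) -> "PointCloud":
        return PointCloud(self.vertices.copy())


@dataclass
class PointCloud:
    """Unstructured 3D points in world millimetres."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def load(cls, path) -> "PointCloud":
        obj = trimesh.load(str(path), process=False)
        return cls(np.asarray(obj.vertices, float))

    def save(self, path) -> None:
        trimesh.PointCloud(self.points).export(str(path))


@dataclass
class VoxelVolume:
    """A scalar 3D grid with a voxel-index -> world-mm affine.

    The carrier type for anatomical volumes, binary head masks, label
    volumes and pseudo-T images alike.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a non-empty 3D array")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("volume affine is singular")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Physical edge length (mm) of a voxel along each index axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centres(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (n_voxels, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx)

    def like(self, data: np.ndarray) -> "VoxelVolume":
        """New volume on this grid with different data."""
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid")
        return VoxelVolume(data, self.affine.copy())

    @classmethod
    def load(cls, path) -> "VoxelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)

    def save(self, path) -> None:
        data = np.asarray(self.data)
        if data.dtype == np.int64:  # NIfTI-1 has no 64-bit integer type
            data = data.astype(np.int32)
        nib.save(nib.Nifti1Image(data, self.affine), str(path))


def as_binary_mask(volume: VoxelVolume) -> VoxelVolume:
    """Validate that a volume is a binary head mask (values in {0, 1})."""
    vals = np.unique(volume.data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be exactly {0, 1}")
    if volume.data.sum() == 0:
        raise ValueError("mask is empty")
    return VoxelVolume(volume.data.astype(np.uint8), volume.affine)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_outer_surface(volume: VoxelVolume, threshold: float) -> TriangleMesh:
    """Extract the scalp-like outer isosurface of a volume.

    The volume is thresholded, restricted to its largest 26-connected
    supra-threshold component (so detached blobs such as noise specks or
    a second object are ignored), and triangulated with marching cubes.
    Vertices are returned in world millimetres.
    """
    above = volume.data > threshold
    if not above.any():
        raise EmptySurfaceError("no voxel above threshold")
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        above = labels == (1 + np.argmax(sizes))
    padded = np.pad(above.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts -= 1.0  # undo padding offset; verts are in voxel-index units
    world = verts @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    return TriangleMesh(world, faces)


def sample_surface_points(mesh: TriangleMesh, n_points: int,
                          rng: np.random.Generator):
    """Area-uniform random samples on a mesh surface.

    Returns ``(points, face_normals_at_points)``; the generator makes
    the draw reproducible.
    """
    tm = mesh.to_trimesh()
    areas = tm.area_faces
    faces = rng.choice(len(areas), size=n_points, p=areas / areas.sum())
    u, v = rng.uniform(size=(2, n_points))
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    tri = tm.triangles[faces]
    pts = tri[:, 0] + u[:, None] * (tri[:, 1] - tri[:, 0]) \
        + v[:, None] * (tri[:, 2] - tri[:, 0])
    normals = np.array(tm.face_normals)[faces]
    # orient outward (relative to the centroid; adequate for star-shaped
    # head surfaces regardless of face winding)
    inward = np.einsum("ij,ij->i", normals, pts - pts.mean(axis=0)) < 0
    normals[inward] *= -1
    return pts, normals


def crop_below_plane(surface, plane_point, plane_normal) -> PointCloud:
    """Keep points on the positive side of a plane.

    A point ``p`` is retained iff ``(p - plane_point) . plane_normal >= 0``.
    Used to trim a structured-light head scan to the coverage of a
    template scalp (e.g. discard neck/shoulders below an axial plane).
    """
    normal = np.asarray(plane_normal, float)
    if np.linalg.norm(normal) == 0:
        raise ValueError("plane normal must be non-zero")
    pts = surface.points if isinstance(surface, PointCloud) else surface.vertices
    keep = (pts - np.asarray(plane_point, float)) @ normal >= 0
    if not keep.any():
        raise EmptyResultError("crop removed every point")
    return PointCloud(pts[keep])


def fill_convex_hull(points: PointCloud, grid: VoxelVolume) -> VoxelVolume:
    """Binarise a point cloud onto a voxel grid via its convex hull.

    A voxel is set to 1 iff its centre (world mm) lies inside or on the
    convex hull of the points. Returns a binary mask on ``grid``'s grid.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
        # tetrahedralise the hull vertices only (a few hundred points even
        # for noisy scans); find_simplex is then a fast walking search
        tri = Delaunay(pts[hull.vertices])
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate point cloud: {err}") from err

    mask = np.zeros(grid.shape, dtype=np.uint8)
    # restrict the centre-in-hull test to the hull's bounding box in index space
    corners_vox = grid.world_to_voxel(pts)
    lo = np.maximum(np.floor(corners_vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(corners_vox.max(axis=0)).astype(int) + 1,
                    np.asarray(grid.shape))
    if (hi <= lo).any():
        return grid.like(mask)
    sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
    centres = grid.voxel_to_world(sub)
    inside = tri.find_simplex(centres) >= 0
    mask[sub[inside, 0], sub[inside, 1], sub[inside, 2]] = 1
    return grid.like(mask)


def dilate_mask(mask: VoxelVolume, radius_mm: float) -> VoxelVolume:
    """Morphological dilation with a sphere of a *physical* radius.

    The spherical structuring element is built in voxel space from the
    per-axis voxel sizes, so anisotropic grids still honour the radius in
    millimetres along every axis.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if radius_mm == 0:
        return VoxelVolume(mask.data.copy(), mask.affine.copy())
    sizes = mask.voxel_sizes
    half = np.floor(radius_mm / sizes).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, sizes)],
                        indexing="ij")
    ball = (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= radius_mm ** 2 + 1e-9
    out = ndimage.binary_dilation(mask.data > 0, structure=ball)
    return mask.like(out.astype(np.uint8))
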