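"""Volume-conductor models and lead fields for triaxial OPM arrays.

Two conductors are provided:

* ``sphere`` — the closed-form field of a current dipole in a
  spherically symmetric conductor (volume currents included). Fast and
  analytic; the standard oracle for the realistic model.
* ``single_shell`` — a realistically shaped single-surface conductor.
  Outside the conductor the quasi-static field is curl-free, so the
  total field is the gradient of a scalar potential, harmonic in the
  exterior. We expand that potential in exterior solid harmonics about
  the shell centroid and fit the coefficients to the magnetic boundary
  condition on the shell surface: the surface-normal field component
  equals that of the primary (infinite-medium) dipole term, the volume
  currents contributing nothing normally (exact on a sphere, the usual
  single-shell approximation otherwise).

Geometry is handled in millimetres at the API, converted to SI metres
internally; dipole moments are in A.m and fields in tesla.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import sph_harm_y

from .geometry import DegenerateGeometryError, PointCloud, TriangleMesh, VoxelVolume
from .sensors import SensorArray

MU0 = 4e-7 * np.pi  # T m / A
_MM = 1e-3


# ---------------------------------------------------------------------------
# conductor and source-space containers
# ---------------------------------------------------------------------------


@dataclass
class ConductorModel:
    kind: str  # "sphere" | "single_shell"
    centre: np.ndarray | None = None  # mm
    radius: float | None = None  # mm
    shell: TriangleMesh | None = None
    order: int = 10

    @classmethod
    def sphere(cls, centre, radius) -> "ConductorModel":
        if radius <= 0:
            raise ValueError("radius must be positive")
        return cls("sphere", np.asarray(centre, float), float(radius))

    @classmethod
    def single_shell(cls, shell: TriangleMesh, order: int = 10) -> "ConductorModel":
        tm = shell.to_trimesh()
        if tm.euler_number != 2:
            raise ValueError("shell mesh must be closed (Euler characteristic 2)")
        c = cls("single_shell", centre=np.asarray(tm.vertices, float).mean(axis=0),
                shell=shell, order=order)
        return c

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_mm)
        if self.kind == "sphere":
            return np.linalg.norm(pts - self.centre, axis=1) < self.radius
        return _points_in_mesh(self.shell, pts)


def _points_in_mesh(mesh: TriangleMesh, pts: np.ndarray,
                    chunk: int = 2048) -> np.ndarray:
    """Point-in-closed-mesh test via the generalized winding number.

    Sums the signed solid angle of every face (Van Oosterom & Strackee)
    seen from each point; ~4pi inside, ~0 outside. Exact for watertight
    meshes regardless of convexity.
    """
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    out = np.empty(len(pts), bool)
    for s in range(0, len(pts), chunk):
        p = pts[s:s + chunk]
        a = tri[None, :, 0] - p[:, None]  # (P, F, 3)
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("pfi,pfi->pf", a, b) * lc
               + np.einsum("pfi,pfi->pf", a, c) * lb
               + np.einsum("pfi,pfi->pf", b, c) * la)
        omega = 2 * np.arctan2(num, den)
        out[s:s + chunk] = np.abs(omega.sum(axis=1)) > 2 * np.pi
    return out


@dataclass
class SourceSpace:
    """Ordered candidate source locations (mm) on an isotropic grid."""

    points: np.ndarray
    spacing: float

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def __len__(self):
        return len(self.points)

    @classmethod
    def from_mask(cls, mask: VoxelVolume, spacing: float) -> "SourceSpace":
        """Axis-aligned world grid at ``spacing`` mm, keeping points whose
        nearest mask voxel is set."""
        on = np.argwhere(np.asarray(mask.data) > 0)
        if len(on) == 0:
            raise ValueError("mask is empty")
        world = mask.voxel_to_world(on)
        lo, hi = world.min(axis=0), world.max(axis=0)
        axes = [np.arange(l, h + spacing / 2, spacing) for l, h in zip(lo, hi)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vox = np.round(mask.world_to_voxel(grid)).astype(int)
        ok = ((vox >= 0) & (vox < np.asarray(mask.shape))).all(axis=1)
        keep = np.zeros(len(grid), bool)
        keep[ok] = np.asarray(mask.data)[tuple(vox[ok].T)] > 0
        return cls(grid[keep], spacing)

    def nearest(self, point_mm) -> int:
        return int(np.argmin(np.linalg.norm(self.points - np.asarray(point_mm), axis=1)))


@dataclass
class LeadField:
    """Per-source channels x 3 gains: tesla per unit dipole moment (A.m)
    along world x, y, z. Channel order follows the sensor array."""

    gains: np.ndarray  # (n_sources, n_channels, 3)
    source_space: SourceSpace
    channel_labels: list

    def __post_init__(self):
        self.gains = np.asarray(self.gains, float)
        if self.gains.ndim != 3 or self.gains.shape[2] != 3:
            raise ValueError("gains must be (n_sources, n_channels, 3)")
        if self.gains.shape[0] != len(self.source_space):
            raise ValueError("gain count must match source space")
        if not np.isfinite(self.gains).all():
            raise ValueError("lead field contains non-finite entries")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("gains", data=self.gains)
            f.create_dataset("source_points", data=self.source_space.points)
            f.attrs["spacing"] = self.source_space.spacing
            f.create_dataset("channel_labels",
                             data=np.array(self.channel_labels, dtype="S"))

    @classmethod
    def load(cls, path) -> "LeadField":
        with h5py.File(path, "r") as f:
            ss = SourceSpace(f["source_points"][()], float(f.attrs["spacing"]))
            labels = [s.decode() for s in f["channel_labels"][()]]
            return cls(f["gains"][()], ss, labels)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------


def fit_sphere(points) -> tuple:
    """Algebraic least-squares sphere fit.

    Returns ``(centre_mm, radius_mm, rms_residual_mm)``. Solves the
    linear system implied by |p|^2 = 2 c.p + (r^2 - |c|^2).
    """
    pts = points.points if isinstance(points, PointCloud) else np.atleast_2d(points)
    if len(pts) < 4:
        raise DegenerateGeometryError("need >= 4 points to fit a sphere")
    A = np.c_[2 * pts, np.ones(len(pts))]
    b = (pts ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("points are coplanar; sphere is ambiguous")
    centre = sol[:3]
    radius = np.sqrt(sol[3] + centre @ centre)
    residual = float(np.sqrt(np.mean(
        (np.linalg.norm(pts - centre, axis=1) - radius) ** 2)))
    return centre, float(radius), residual


# ---------------------------------------------------------------------------
# spherical conductor (Sarvas closed form)
# ---------------------------------------------------------------------------


def _sarvas_field(r0_m: np.ndarray, q: np.ndarray, r_m: np.ndarray) -> np.ndarray:
    """Full field vector (T) of a current dipole in a spherically
    symmetric conductor centred at the origin (SI units)."""
    r = np.atleast_2d(r_m)
    a_vec = r - r0_m
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if (a < 1e-12).any():
        raise ValueError("sensor coincides with the dipole")
    if (rn < 1e-12).any():
        raise ValueError("sensor at the conductor centre is singular")
    r0dr = r @ r0_m
    F = a * (rn * a + rn ** 2 - r0dr)
    if (np.abs(F) < 1e-30).any():
        raise ValueError("singular geometry in the sphere model")
    adr = np.einsum("ij,ij->i", a_vec, r)
    gF = ((a ** 2 / rn + adr / a + 2 * a + 2 * rn)[:, None] * r
          - (a + 2 * rn + adr / a)[:, None] * r0_m)
    qxr0 = np.cross(q, r0_m)
    B = (MU0 / (4 * np.pi * F ** 2))[:, None] * (
        F[:, None] * qxr0 - (r @ qxr0)[:, None] * gF)
    return B


def dipole_field_sphere(r0, q, sensor_pos, sensor_ori, centre) -> np.ndarray:
    """Projected field (T) at sensors for a dipole in a spherical conductor.

    ``r0``/``sensor_pos``/``centre`` in mm, ``q`` in A.m; the returned
    array holds the field component along each sensor orientation.
    """
    c = np.asarray(centre, float)
    pos = np.atleast_2d(sensor_pos) - c
    B = _sarvas_field((np.asarray(r0, float) - c) * _MM, np.asarray(q, float),
                      pos * _MM)
    ori = np.atleast_2d(sensor_ori)
    return np.einsum("ij,ij->i", B, ori)


# ---------------------------------------------------------------------------
# single-shell conductor
# ---------------------------------------------------------------------------


def _real_sph_harm_basis(points: np.ndarray, centre: np.ndarray, order: int,
                         scale: float) -> np.ndarray:
    """Exterior real solid harmonics (scale/r)^(l+1) Y_lm at points.

    Shape (n_points, n_coefficients) with l = 1..order. ``scale`` keeps
    the columns of comparable magnitude near the shell surface.
    """
    d = np.atleast_2d(points) - centre
    r = np.linalg.norm(d, axis=1)
    theta = np.arccos(np.clip(d[:, 2] / np.maximum(r, 1e-30), -1, 1))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols = []
    for l in range(1, order + 1):
        radial = (scale / r) ** (l + 1)
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                cols.append(radial * y.real)
            else:
                f = np.sqrt(2.0) * (-1.0) ** m
                cols.append(radial * f * y.real)
                cols.append(radial * f * y.imag)
    return np.stack(cols, axis=1)


def _basis_gradient(points: np.ndarray, centre: np.ndarray, order: int,
                    scale: float, h: float | None = None) -> np.ndarray:
    """Central-difference gradient of the basis, (n_points, 3, n_coef).

    The basis varies on the scale of the shell radius, so a step of
    1e-3 x scale keeps the O(h^2) truncation error around 1e-6 relative.
    """
    h = h if h is not None else 1e-3 * scale
    grads = []
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = h
        fp = _real_sph_harm_basis(points + e, centre, order, scale)
        fm = _real_sph_harm_basis(points - e, centre, order, scale)
        grads.append((fp - fm) / (2 * h))
    return np.stack(grads, axis=1)


def _primary_field(r0_m: np.ndarray, q: np.ndarray, r_m: np.ndarray) -> np.ndarray:
    """Infinite-medium (primary) dipole field mu0/4pi q x d / |d|^3."""
    d = np.atleast_2d(r_m) - r0_m
    dist = np.linalg.norm(d, axis=1)
    return MU0 / (4 * np.pi) * np.cross(q, d) / dist[:, None] ** 3


class SingleShellModel:
    """Fitted single-shell solver bound to one shell mesh.

    Precomputes the boundary design matrix and its pseudo-inverse once;
    each dipole then costs two small matrix products.
    """

    def __init__(self, conductor: ConductorModel):
        if conductor.kind != "single_shell":
            raise ValueError("conductor must be single_shell")
        self.conductor = conductor
        tm = conductor.shell.to_trimesh()
        self.centre_m = np.asarray(conductor.centre, float) * _MM
        self.faces_m = np.asarray(tm.triangles_center, float) * _MM
        normals = np.array(tm.face_normals, float)
        # orient normals outward
        out = np.einsum("ij,ij->i", normals, self.faces_m - self.centre_m) < 0
        normals[out] *= -1
        self.normals = normals
        self.order = conductor.order
        self.scale = float(np.linalg.norm(self.faces_m - self.centre_m, axis=1).mean())
        areas = np.asarray(tm.area_faces, float)
        w = np.sqrt(areas / areas.mean())
        grad = _basis_gradient(self.faces_m, self.centre_m, self.order, self.scale)
        # design: -n . grad(basis) ; rows weighted by sqrt(face area)
        self.design = -np.einsum("fi,fik->fk", self.normals, grad) * w[:, None]
        self.weights = w
        self.pinv = np.linalg.pinv(self.design, rcond=1e-10)
        self._sensor_cache = {}

    def boundary_residual(self, r0_mm, q) -> float:
        """Relative residual of the Neumann fit for one dipole."""
        g = self._neumann(np.asarray(r0_mm, float) * _MM, np.asarray(q, float))
        coef = self.pinv @ g
        return float(np.linalg.norm(self.design @ coef - g) / np.linalg.norm(g))

    def _neumann(self, r0_m, q) -> np.ndarray:
        bp = _primary_field(r0_m, q, self.faces_m)
        return np.einsum("ij,ij->i", self.normals, bp) * self.weights

    def _sensor_gradient(self, pos_mm: np.ndarray) -> np.ndarray:
        key = (pos_mm.tobytes(), len(pos_mm))
        if key not in self._sensor_cache:
            self._sensor_cache[key] = _basis_gradient(
                np.atleast_2d(pos_mm) * _MM, self.centre_m, self.order, self.scale)
        return self._sensor_cache[key]

    def field(self, r0_mm, q, sensors: SensorArray, _check: bool = True) -> np.ndarray:
        """Projected field (T) per channel for one dipole (mm, A.m)."""
        r0_m = np.asarray(r0_mm, float) * _MM
        if _check and not self.conductor.contains(np.atleast_2d(r0_mm))[0]:
            raise ValueError("source lies outside the shell")
        coef = self.pinv @ self._neumann(r0_m, np.asarray(q, float))
        grad = self._sensor_gradient(sensors.positions)  # (n, 3, k)
        B = -np.einsum("nik,k->ni", grad, coef)
        return np.einsum("ni,ni->n", B, sensors.orientations)


def single_shell_field(r0, q, sensors: SensorArray,
                       conductor: ConductorModel) -> np.ndarray:
    """One-shot single-shell evaluation (see :class:`SingleShellModel`)."""
    return SingleShellModel(conductor).field(r0, q, sensors)


# ---------------------------------------------------------------------------
# lead-field assembly
# ---------------------------------------------------------------------------


def build_leadfield(src: SourceSpace, sensors: SensorArray,
                    conductor: ConductorModel) -> LeadField:
    """Channels x 3 gain matrix per source (unit moments along x, y, z)."""
    inside = conductor.contains(src.points)
    if not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"source {bad} lies outside the conductor")
    n_src, n_ch = len(src), sensors.n_channels
    gains = np.empty((n_src, n_ch, 3))
    eye = np.eye(3)
    if conductor.kind == "sphere":
        gains = _sarvas_gains((src.points - conductor.centre) * _MM,
                              (sensors.positions - conductor.centre) * _MM,
                              sensors.orientations)
    else:
        model = SingleShellModel(conductor)
        for i, p in enumerate(src.points):
            for ax in range(3):
                gains[i, :, ax] = model.field(p, eye[ax], sensors, _check=False)
    return LeadField(gains, src, list(sensors.labels))


def _sarvas_gains(r0s_m: np.ndarray, pos_m: np.ndarray,
                  oris: np.ndarray) -> np.ndarray:
    """Vectorised sphere-model gains (n_src, n_ch, 3) for unit moments
    along x, y, z; conductor centre at the origin (SI units)."""
    r = pos_m  # (C, 3)
    rn = np.linalg.norm(r, axis=1)  # (C,)
    a_vec = r[None, :, :] - r0s_m[:, None, :]  # (S, C, 3)
    a = np.linalg.norm(a_vec, axis=2)
    r0dr = r0s_m @ r.T  # (S, C)
    F = a * (rn[None, :] * a + rn[None, :] ** 2 - r0dr)
    adr = np.einsum("scj,cj->sc", a_vec, r)
    c1 = a ** 2 / rn[None, :] + adr / a + 2 * a + 2 * rn[None, :]
    c2 = a + 2 * rn[None, :] + adr / a
    gF = c1[:, :, None] * r[None, :, :] - c2[:, :, None] * r0s_m[:, None, :]
    pref = MU0 / (4 * np.pi * F ** 2)  # (S, C)
    gains = np.empty((len(r0s_m), len(r), 3))
    for ax, e in enumerate(np.eye(3)):
        qxr0 = np.cross(np.broadcast_to(e, r0s_m.shape), r0s_m)  # (S, 3)
        rdq = qxr0 @ r.T  # (S, C)
        B = pref[:, :, None] * (F[:, :, None] * qxr0[:, None, :]
                                - rdq[:, :, None] * gF)
        gains[:, :, ax] = np.einsum("scj,cj->sc", B, oris)
    return gains
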