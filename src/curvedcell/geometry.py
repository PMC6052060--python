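"""Surface geometry for closed, genus-0 cell meshes.

Coordinates are in micrometres (μm), Gaussian curvature in μm⁻², and
per-face areas in μm².  The discrete curvature estimator is the angle
deficit at each vertex divided by the barycentric vertex area; vertex
values are averaged onto faces.  With barycentric weighting the
face-integrated curvature Σ K_f·A_f telescopes back to the sum of angle
deficits, so Gauss–Bonnet (Σ K·A = 4π for a closed genus-0 surface) holds
to machine precision by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import make_smoothing_spline


class MeshValidationError(ValueError):
    """Raised when a mesh is not a closed, consistently oriented 2-manifold."""


def validate_mesh(mesh: trimesh.Trimesh, repair: bool = True) -> trimesh.Trimesh:
    """Check that ``mesh`` is a closed, oriented 2-manifold with positive areas.

    Meshes failing winding consistency are repaired once (``fix_normals``);
    if they still fail, :class:`MeshValidationError` is raised naming an
    offending edge.
    """
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    bad = unique[counts != 2]
    if len(bad):
        raise MeshValidationError(
            f"mesh is not a closed 2-manifold: edge {tuple(bad[0])} is shared "
            f"by {counts[counts != 2][0]} faces (expected 2)"
        )
    if not mesh.is_winding_consistent or mesh.volume < 0:
        if repair:
            mesh = mesh.copy()
            trimesh.repair.fix_normals(mesh)
        if not mesh.is_winding_consistent:
            raise MeshValidationError("mesh winding is inconsistent after repair")
    if mesh.euler_number != 2:
        raise MeshValidationError(
            f"expected genus-0 surface (Euler characteristic 2), got {mesh.euler_number}"
        )
    areas = mesh.area_faces
    if np.any(areas <= 0):
        j = int(np.argmin(areas))
        raise MeshValidationError(f"degenerate face {j} with area {areas[j]:.3g}")
    return mesh


def face_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-face areas A_j in μm²."""
    areas = np.asarray(mesh.area_faces, dtype=float)
    if np.any(areas <= 0):
        j = int(np.argmin(areas))
        raise MeshValidationError(f"degenerate face {j} with area {areas[j]:.3g}")
    return areas


def vertex_gaussian_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Angle-deficit Gaussian curvature per vertex (μm⁻²).

    K_v = (2π − Σ incident angles) / A_v with A_v the barycentric vertex
    area (one third of the area of the incident faces).
    """
    angles = mesh.face_angles  # (F, 3)
    faces = mesh.faces
    nv = len(mesh.vertices)
    angle_sum = np.zeros(nv)
    np.add.at(angle_sum, faces.ravel(), angles.ravel())
    deficit = 2.0 * np.pi - angle_sum
    barycentric = np.zeros(nv)
    np.add.at(barycentric, faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        k = deficit / barycentric
    if not np.all(np.isfinite(k)):
        raise MeshValidationError("non-finite curvature (isolated vertex?)")
    return k


def gaussian_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-face Gaussian curvature K_j (μm⁻²).

    The face value is the mean of its three vertices' angle-deficit
    curvatures.  Because the vertex normalisation is barycentric,
    Σ_j K_j·A_j equals the total angle deficit 4π exactly.
    """
    mesh = validate_mesh(mesh)
    kv = vertex_gaussian_curvature(mesh)
    return kv[mesh.faces].mean(axis=1)


@dataclass
class RectSurface:
    """Rectangular (u, v) parameterisation of a tube-like surface.

    ``points`` has shape (n_u, n_v, 3): ``u`` runs along the centerline and
    ``v`` is azimuthal and periodic.  The parameterisation degenerates at
    the two poles, which are stored separately; the grid covers the rings
    between them.  ``quad_face_index`` maps grid quad (i, j) to the pair of
    triangles that tile it in the companion mesh.
    """

    points: np.ndarray
    u_arclength: np.ndarray          # (n_u,) cumulative arc length along centerline, μm
    v_circumference: np.ndarray      # (n_u,) local circumference, μm
    quad_face_index: np.ndarray | None = None   # (n_u-1, n_v, 2) face ids

    @property
    def n_u(self) -> int:
        return self.points.shape[0]

    @property
    def n_v(self) -> int:
        return self.points.shape[1]


@dataclass
class CellSurface:
    """A closed triangulated cell surface with per-face measurements.

    Holds the per-face intensity I_j (arbitrary units, interpreted as a
    surface density), per-face area A_j (μm²) and per-face Gaussian
    curvature K_j (μm⁻²).  ``cytoplasmic_total`` is the total intensity of
    any volumetric (non-membrane) signal inside the cell, used for
    membrane-fraction estimates.
    """

    mesh: trimesh.Trimesh
    face_area: np.ndarray = None
    face_curvature: np.ndarray = None
    face_intensity: np.ndarray | None = None
    rect: RectSurface | None = None
    cell_id: str = "cell"
    cytoplasmic_total: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mesh = validate_mesh(self.mesh)
        if self.face_area is None:
            self.face_area = face_areas(self.mesh)
        if self.face_curvature is None:
            self.face_curvature = gaussian_curvature(self.mesh)
        nf = len(self.mesh.faces)
        for name in ("face_area", "face_curvature"):
            arr = getattr(self, name)
            if len(arr) != nf:
                raise ValueError(f"{name} has {len(arr)} entries for {nf} faces")
        if self.face_intensity is not None:
            self.face_intensity = np.asarray(self.face_intensity, dtype=float)
            if len(self.face_intensity) != nf:
                raise ValueError("face_intensity length mismatch")
        if not np.all(np.isfinite(self.face_curvature)):
            raise ValueError("non-finite curvature")

    @property
    def total_area(self) -> float:
        return float(self.face_area.sum())

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))

    def with_intensity(self, intensity: np.ndarray) -> "CellSurface":
        out = CellSurface(
            mesh=self.mesh,
            face_area=self.face_area,
            face_curvature=self.face_curvature,
            face_intensity=np.asarray(intensity, dtype=float),
            rect=self.rect,
            cell_id=self.cell_id,
            cytoplasmic_total=self.cytoplasmic_total,
            meta=dict(self.meta),
        )
        return out


@dataclass
class CenterlineProfile:
    """Diameter along the centerline of an elongated cell.

    ``positions`` are arc-length stations (μm, monotone) along the smoothed
    centerline with the spherical pole caps excluded (stations within one
    mean radius of either end of the body are dropped); ``diameters`` is
    the mean cross-sectional diameter at each station.  ``degenerate`` is
    set for nearly spherical cells (aspect ratio < 1.2), for which the
    profile is still returned but covers only an equatorial band.
    """

    positions: np.ndarray
    diameters: np.ndarray
    centers: np.ndarray
    tangents: np.ndarray
    degenerate: bool = False


def _section_stats(mesh: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray):
    """Length-weighted centroid and mean radius of a planar cross-section."""
    segments = trimesh.intersections.mesh_plane(mesh, normal, origin)
    if len(segments) == 0:
        return None, None
    pts = segments.reshape(-1, 3)
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    w = np.repeat(lengths, 2) / 2.0
    if w.sum() <= 0:
        return None, None
    centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
    rel = pts - centroid
    rel -= np.outer(rel @ normal, normal)  # project into the section plane
    radius = np.average(np.linalg.norm(rel, axis=1), weights=w)
    return centroid, radius


def centerline_profile(
    mesh: trimesh.Trimesh, n_samples: int = 60, exclude_caps: bool = True
) -> CenterlineProfile:
    """Extract the (axial position, diameter) profile of an elongated mesh.

    The centerline is the smoothed locus of cross-section centroids along
    the first principal axis; diameters are then re-measured in planes
    perpendicular to the local centerline tangent, so bent rods report
    their true cross-sectional diameter.
    """
    mesh = validate_mesh(mesh)
    v = np.asarray(mesh.vertices, dtype=float)
    center = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - center, full_matrices=False)
    axis = vt[0]
    t = (v - center) @ axis
    t_lo, t_hi = t.min(), t.max()
    extent = t_hi - t_lo

    # first pass: centroids of sections perpendicular to the principal axis
    margin = 0.02 * extent
    stations = np.linspace(t_lo + margin, t_hi - margin, max(n_samples, 8))
    cents, radii = [], []
    for s in stations:
        c, r = _section_stats(mesh, center + s * axis, axis)
        if c is not None:
            cents.append(c)
            radii.append(r)
    cents = np.asarray(cents)
    radii = np.asarray(radii)
    if len(cents) < 4:
        raise MeshValidationError("too few valid cross-sections for a centerline")
    r_est = float(np.median(radii))

    degenerate = extent < 1.2 * 2.0 * float(radii.max())
    if degenerate:
        warnings.warn(
            f"nearly spherical cell (extent {extent:.2f} μm vs diameter "
            f"{2 * r_est:.2f} μm); profile restricted to an equatorial band",
            stacklevel=2,
        )

    # smooth the centroid locus, take derivatives for local tangents
    s_grid = np.linspace(stations[0], stations[-1], len(cents))
    smoothed = np.empty_like(cents)
    tangent = np.empty_like(cents)
    for k in range(3):
        lam = None if len(cents) >= 10 else 0.0
        spl = make_smoothing_spline(s_grid, cents[:, k], lam=lam)
        smoothed[:, k] = spl(s_grid)
        tangent[:, k] = spl.derivative()(s_grid)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)

    # second pass: cut perpendicular to the local tangent, excluding caps
    if exclude_caps and not degenerate:
        keep = (stations >= t_lo + r_est) & (stations <= t_hi - r_est)
    else:
        band = 0.25 * extent if degenerate else 0.0
        keep = np.abs(stations - 0.5 * (t_lo + t_hi)) <= max(band, 0.5 * extent)
    positions, diameters, centers_out, tangents_out = [], [], [], []
    arc = 0.0
    prev = None
    for i in np.nonzero(keep)[0]:
        c, r = _section_stats(mesh, smoothed[i], tangent[i])
        if c is None:
            continue
        if prev is not None:
            arc += float(np.linalg.norm(c - prev))
        prev = c
        positions.append(arc)
        diameters.append(2.0 * r)
        centers_out.append(c)
        tangents_out.append(tangent[i])
    return CenterlineProfile(
        positions=np.asarray(positions),
        diameters=np.asarray(diameters),
        centers=np.asarray(centers_out),
        tangents=np.asarray(tangents_out),
        degenerate=degenerate,
    )


@dataclass
class UnwrappedImage:
    """2D unwrapped surface image with per-pixel physical metadata.

    ``data`` is indexed (u, v); the azimuthal axis is periodic.
    ``pixel_area`` (μm²) maps each pixel back to the surface patch it
    covers, so ``(data * pixel_area).sum()`` is the total surface-integrated
    intensity.  ``nm_per_px_u``/``nm_per_px_v`` give the physical scale per
    row.
    """

    data: np.ndarray
    pixel_area: np.ndarray
    nm_per_px_u: np.ndarray
    nm_per_px_v: np.ndarray

    @property
    def total_intensity(self) -> float:
        return float((self.data * self.pixel_area).sum())


def unwrap_intensity(
    cell: CellSurface, upsample_u: int = 1, upsample_v: int = 1
) -> UnwrappedImage:
    """Project the per-face intensity onto the rectangular (u, v) frame.

    Each grid quad is tiled by two mesh triangles; the pixel value is the
    area-weighted mean intensity density of its quad, so total intensity is
    preserved exactly over the gridded part of the surface (the degenerate
    pole fans are not part of the rectangular frame).
    """
    if cell.rect is None or cell.rect.quad_face_index is None:
        raise ValueError("cell has no rectangular (u, v) surface")
    if cell.face_intensity is None:
        raise ValueError("cell has no painted intensity")
    rect = cell.rect
    qfi = rect.quad_face_index  # (n_u-1, n_v, 2)
    a = cell.face_area[qfi]     # (n_u-1, n_v, 2)
    i = cell.face_intensity[qfi]
    quad_area = a.sum(axis=2)
    quad_intensity = (a * i).sum(axis=2) / quad_area
    data = np.repeat(np.repeat(quad_intensity, upsample_u, axis=0), upsample_v, axis=1)
    pixel_area = (
        np.repeat(np.repeat(quad_area, upsample_u, axis=0), upsample_v, axis=1)
        / (upsample_u * upsample_v)
    )
    du = np.diff(rect.u_arclength) / upsample_u            # μm per row
    dv = 0.5 * (rect.v_circumference[:-1] + rect.v_circumference[1:]) / (
        rect.n_v * upsample_v
    )
    nm_u = np.repeat(du * 1e3, upsample_u)
    nm_v = np.repeat(dv * 1e3, upsample_u)
    return UnwrappedImage(
        data=data, pixel_area=pixel_area, nm_per_px_u=nm_u, nm_per_px_v=nm_v
    )
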