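"""Geometric morphometrics of cells and nuclei.

Implements the point-cloud shape analysis used on 3D segmentations of
blastomeres and their nuclei:

* the **apical surface** of a cell is the subset of its boundary points
  farther than a cutoff from every neighbouring cell's boundary, and its
  area is summed over boundary facets of a Delaunay tetrahedralization;
* the cell's **oriented bounding box** is aligned with the radial axis
  (embryo centre of mass → apical-surface centre of mass); its extents give
  the aspect ratio ``(Lz − max(Lx, Ly)) / (Lz + max(Lx, Ly))`` and the
  flatness ``Lz_api / Lz``;
* a nucleus's **deformation index** is the mean radial distance from its
  surface points to a least-squares ellipsoid fit, normalized by the
  point's distance to the ellipsoid centre — zero for a perfect ellipsoid,
  growing with surface wrinkling;
* **sphericity** is π^(1/3)(6V)^(2/3)/A on the voxel mask, and per-vertex
  **mean curvature** uses the cotangent-Laplacian estimator on a
  marching-cubes mesh.

All coordinates are physical (µm, ``(z, y, x)`` order as elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from skimage import measure

__all__ = [
    "SurfacePointCloud",
    "OrientedBox",
    "EllipsoidFit",
    "surface_points_from_mask",
    "extract_apical_surface",
    "apical_surface_area",
    "oriented_bounding_box",
    "aspect_ratio",
    "flatness",
    "distance_to_embryo_cm",
    "fit_ellipsoid",
    "nuclear_deformation_index",
    "sphericity",
    "mask_to_mesh",
    "local_mean_curvature",
]


@dataclass
class SurfacePointCloud:
    """Object boundary points in physical µm, ``(n, 3)`` as (z, y, x)."""

    points: np.ndarray
    object_id: int = 0
    source: str = "cell"  # cell | nucleus | apical_subset

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        if len(self.points) == 0:
            raise ValueError("empty point cloud has no centroid")
        return self.points.mean(axis=0)


@dataclass
class OrientedBox:
    """Radially oriented bounding box extents (µm).

    ``frame`` rows are orthonormal axes; row 2 (the local z-axis) points
    along the radial direction used for the orientation.  ``Lz_api`` is the
    z-extent of the apical points in the same frame.
    """

    Lx: float
    Ly: float
    Lz: float
    Lz_api: float
    frame: np.ndarray
    radial_fallback: bool = False  # True when apical surface was empty

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        if not np.allclose(self.frame @ self.frame.T, np.eye(3), atol=1e-9):
            raise ValueError("frame is not orthonormal")


@dataclass
class EllipsoidFit:
    """Least-squares ellipsoid: centre, semi-axes (µm, descending), rotation."""

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray  # rows: principal axes, matching semi_axes order
    residuals: np.ndarray  # per-point normalized radial distances

    def __post_init__(self) -> None:
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")


# ---------------------------------------------------------------------------
# surfaces


def surface_points_from_mask(
    mask: np.ndarray, voxel_spacing: tuple[float, float, float], object_id: int = 0,
    source: str = "cell",
) -> SurfacePointCloud:
    """Boundary-voxel centres (µm) of a binary mask.

    A boundary voxel is a foreground voxel with at least one of its six face
    neighbours in the background (the volume border does not count as
    background; a mask filling the whole volume is an error).
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    if np.all(mask):
        raise ValueError("mask fills the whole volume: no background to define a surface")
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    boundary = mask & ~eroded
    idx = np.argwhere(boundary)
    pts = (idx + 0.5) * np.asarray(voxel_spacing)
    return SurfacePointCloud(points=pts, object_id=object_id, source=source)


def extract_apical_surface(
    cell: SurfacePointCloud,
    neighbors: list[SurfacePointCloud],
    cutoff_um: float = 1.0,
) -> SurfacePointCloud:
    """Contact-free (apical) subset of a cell's surface points.

    Points closer than ``cutoff_um`` to any neighbouring cell's surface are
    deleted; the remainder is the apical surface.  Points at exactly the
    cutoff distance are retained.  An empty result is meaningful: the cell
    is fully internalized (inner cell).
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    keep = np.ones(len(cell), dtype=bool)
    for nb in neighbors:
        if len(nb) == 0:
            continue
        d, _ = cKDTree(nb.points).query(cell.points, k=1)
        keep &= d >= cutoff_um
    return SurfacePointCloud(
        points=cell.points[keep], object_id=cell.object_id, source="apical_subset"
    )


def _polygon_area_3d(tri: np.ndarray) -> float:
    a, b, c = tri
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def apical_surface_area(
    apical: SurfacePointCloud, cell: SurfacePointCloud | None = None
) -> float:
    """Area (µm²) of the apical surface from its point cloud.

    The full cell cloud (default: the apical cloud itself) is Delaunay
    tetrahedralized; the free-boundary facets are its convex-hull triangles,
    and the apical area is the summed area of those whose three vertices are
    all apical points.  Near-coplanar clouds fall back to a planar (2.5D)
    Delaunay triangulation of the projected points.
    """
    if len(apical) == 0:
        return 0.0
    if len(apical) < 3:
        raise ValueError("need at least 3 points for an area")
    base = cell if cell is not None and len(cell) >= 4 else apical
    pts = base.points
    apical_set = {tuple(np.round(p, 9)) for p in apical.points}

    if len(pts) == 3:
        return _polygon_area_3d(pts)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return _planar_fallback_area(apical.points)
    area = 0.0
    matched = 0
    for simplex in hull.simplices:
        verts = pts[simplex]
        if all(tuple(np.round(v, 9)) in apical_set for v in verts):
            area += _polygon_area_3d(verts)
            matched += 1
    if matched == 0 and len(apical) >= 3:
        # apical points may be interior to the hull of the full cloud
        return _planar_fallback_area(apical.points)
    return float(area)


def _planar_fallback_area(points: np.ndarray) -> float:
    """2.5D triangulated area of a near-coplanar cloud (best-fit plane)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    uv = (points - c) @ vt[:2].T
    try:
        tri = Delaunay(uv)
    except QhullError:
        return 0.0
    return float(sum(_polygon_area_3d(points[s]) for s in tri.simplices))


# ---------------------------------------------------------------------------
# oriented bounding box and shape descriptors


def _orthonormal_frame(z_axis: np.ndarray) -> np.ndarray:
    z = z_axis / np.linalg.norm(z_axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def _inplane_extents(xy: np.ndarray, angle: float) -> tuple[float, float]:
    c, s = np.cos(angle), np.sin(angle)
    u = xy @ np.array([c, s])
    v = xy @ np.array([-s, c])
    return float(u.max() - u.min()), float(v.max() - v.min())


def oriented_bounding_box(
    cell: SurfacePointCloud,
    embryo_cm: np.ndarray,
    apical: SurfacePointCloud | None = None,
) -> OrientedBox:
    """Minimal bounding box with its z-axis along the radial direction.

    The z-axis points from the embryo centre of mass to the centre of mass
    of the apical surface (falling back to the cell centroid when the cell
    has no apical surface — recorded in ``radial_fallback``).  The in-plane
    axes are rotated to minimize the box footprint ``Lx·Ly`` by a 0.25° grid
    search with golden-section refinement.
    """
    embryo_cm = np.asarray(embryo_cm, dtype=float)
    fallback = apical is None or len(apical) == 0
    target = cell.centroid if fallback else apical.centroid
    radial = target - embryo_cm
    nrm = np.linalg.norm(radial)
    if nrm == 0:
        raise ValueError("zero-length radial vector: apical CM coincides with embryo CM")
    frame = _orthonormal_frame(radial)
    local = (cell.points - embryo_cm) @ frame.T
    xy = local[:, :2]

    grid = np.deg2rad(np.arange(0.0, 90.0, 0.25))
    areas = [np.prod(_inplane_extents(xy, a)) for a in grid]
    i0 = int(np.argmin(areas))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda a: np.prod(_inplane_extents(xy, a)), bounds=(lo, hi), method="bounded"
    )
    best = float(res.x) if res.fun <= areas[i0] else grid[i0]

    Lx, Ly = _inplane_extents(xy, best)
    Lz = float(local[:, 2].max() - local[:, 2].min())
    if fallback:
        Lz_api = 0.0
    else:
        api_local = (apical.points - embryo_cm) @ frame.T
        Lz_api = float(api_local[:, 2].max() - api_local[:, 2].min())
    # bake the in-plane rotation into the returned frame
    c, s = np.cos(best), np.sin(best)
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    return OrientedBox(
        Lx=Lx, Ly=Ly, Lz=Lz, Lz_api=Lz_api, frame=rot @ frame, radial_fallback=fallback
    )


def aspect_ratio(box: OrientedBox) -> float:
    """Radial elongation: ``(Lz − max(Lx, Ly)) / (Lz + max(Lx, Ly))``.

    In (−1, 1); positive for radially elongated cells, 0 for a cube/sphere.
    """
    m = max(box.Lx, box.Ly)
    denom = box.Lz + m
    if denom == 0:
        raise ValueError("degenerate box with all extents zero")
    return (box.Lz - m) / denom


def flatness(box: OrientedBox) -> float:
    """Apical z-extent over total z-extent, ``Lz_api / Lz`` ∈ [0, 1]."""
    if box.Lz == 0:
        raise ValueError("Lz = 0")
    return box.Lz_api / box.Lz


def distance_to_embryo_cm(object_cm: np.ndarray, embryo_cm: np.ndarray) -> float:
    """Euclidean (2-norm) distance between an object's CM and the embryo CM."""
    return float(np.linalg.norm(np.asarray(object_cm, float) - np.asarray(embryo_cm, float)))


# ---------------------------------------------------------------------------
# ellipsoid fit and deformation index


def fit_ellipsoid(cloud: SurfacePointCloud) -> EllipsoidFit:
    """Least-squares algebraic ellipsoid fit of a surface point cloud.

    Solves the general quadric ``x'Ax + b'x = 1`` in the least-squares sense
    and requires A to be positive definite (a real ellipsoid); degenerate
    quadrics raise with diagnostics.  For points sampled exactly on an
    ellipsoid the semi-axes are recovered to well under 1%.
    """
    pts_raw = np.asarray(cloud.points, dtype=float)
    if len(pts_raw) < 9:
        raise ValueError(f"need >= 9 points for an ellipsoid fit, got {len(pts_raw)}")
    # centre the data first: the algebraic normalization (constant term = 1)
    # is origin-dependent, so fitting in centred coordinates makes the result
    # invariant under rigid motion of the input
    shift = pts_raw.mean(axis=0)
    pts = pts_raw - shift
    z, y, x = pts[:, 0], pts[:, 1], pts[:, 2]
    D = np.column_stack([z * z, y * y, x * x, z * y, z * x, y * x, z, y, x])
    try:
        coef, *_ = np.linalg.lstsq(D, np.ones(len(pts)), rcond=None)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise ValueError(f"ellipsoid fit failed: {e}") from e
    a, b, c, d, e, f, g, h, i = coef
    A = np.array([[a, d / 2, e / 2], [d / 2, b, f / 2], [e / 2, f / 2, c]])
    bvec = np.array([g, h, i])
    if abs(np.linalg.det(A)) < 1e-300:
        raise ValueError("fit degenerated: singular quadratic form")
    center = np.linalg.solve(2 * A, -bvec)
    # x'Ax + b'x = 1  ->  (x-c)' A (x-c) = 1 + c'Ac = k; the quadric is a
    # real ellipsoid iff A/k is positive definite (the lstsq solution may
    # return the (A, k) pair with both signs flipped when the origin lies
    # outside the ellipsoid)
    k = 1.0 + center @ A @ center
    if k == 0:
        raise ValueError("degenerate quadric (zero scale)")
    w, V = np.linalg.eigh(A / k)
    if np.any(w <= 0):
        raise ValueError(
            f"fit degenerated to a non-ellipsoid quadric (normalized eigenvalues {w})"
        )
    semi = 1.0 / np.sqrt(w)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    V = V[:, order]
    fit = EllipsoidFit(
        center=center + shift, semi_axes=semi, orientation=V.T, residuals=np.zeros(len(pts))
    )
    fit.residuals = _radial_residuals(pts_raw, fit)
    return fit


def _radial_residuals(pts: np.ndarray, fit: EllipsoidFit) -> np.ndarray:
    """|1 − 1/‖w‖| per point, w = point in unit-sphere (whitened) frame.

    This equals the radial distance from the point to the ellipsoid surface
    (along the ray from the centre) divided by the point's distance to the
    centre.
    """
    v = (pts - fit.center) @ fit.orientation.T
    w = v / fit.semi_axes
    wn = np.linalg.norm(w, axis=1)
    if np.any(wn == 0):
        raise ValueError("surface point coincides with the ellipsoid centre")
    return np.abs(1.0 - 1.0 / wn)


def nuclear_deformation_index(cloud: SurfacePointCloud, fit: EllipsoidFit | None = None) -> float:
    """Mean normalized radial deviation of a nuclear surface from its ellipsoid fit.

    For each surface point the distance to the fitted ellipsoid is measured
    along the ray from the ellipsoid centre through the point and divided by
    the point's distance to the centre; the index is the mean over points.
    Zero iff all points lie on the ellipsoid; dimensionless.
    """
    if fit is None:
        fit = fit_ellipsoid(cloud)
    return float(_radial_residuals(np.asarray(cloud.points, float), fit).mean())


# ---------------------------------------------------------------------------
# voxel-mask metrics: sphericity, meshes, curvature


def mask_to_mesh(
    mask: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    smooth_sigma_vox: float = 1.0,
) -> trimesh.Trimesh:
    """Marching-cubes triangle mesh (µm) of a binary mask.

    The mask is Gaussian-smoothed (in voxel units) before contouring at 0.5
    to suppress voxelization staircase artefacts that would otherwise
    inflate surface area and curvature.
    """
    mask = np.asarray(mask, dtype=float)
    if not np.any(mask):
        raise ValueError("empty mask")
    vol = np.pad(mask, 2)
    if smooth_sigma_vox > 0:
        vol = ndimage.gaussian_filter(vol, smooth_sigma_vox)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=voxel_spacing)
    verts -= 2.0 * np.asarray(voxel_spacing) - 0.5 * np.asarray(voxel_spacing)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=True)


def sphericity(mask: np.ndarray, voxel_spacing: tuple[float, float, float]) -> float:
    """Ψ = π^(1/3) (6V)^(2/3) / A ∈ (0, 1]; 1 for a perfect sphere.

    V is the voxel-count volume; A is the area of the (smoothed)
    marching-cubes surface mesh.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    V = float(mask.sum()) * float(np.prod(voxel_spacing))
    A = float(mask_to_mesh(mask, voxel_spacing).area)
    if A == 0:
        raise ValueError("zero surface area")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A)


def local_mean_curvature(mesh: trimesh.Trimesh, allow_boundary: bool = False) -> np.ndarray:
    """Per-vertex signed mean curvature (1/µm), cotangent-Laplacian estimator.

    Uses the discrete mean-curvature normal ``H n = L x / (2 A)`` with
    cotangent weights and one-third barycentric vertex areas; the sign is
    positive where the surface bends towards the outward normal (convex),
    as for a sphere, where H = 1/R.  Requires a closed manifold mesh unless
    ``allow_boundary`` is set (open patches give valid values only at
    interior vertices).
    """
    if not mesh.is_watertight and not allow_boundary:
        raise ValueError("mesh must be a closed, manifold surface")
    V = mesh.vertices
    F = mesh.faces
    n = len(V)
    Hvec = np.zeros((n, 3))
    area3 = np.zeros(n)
    tri_pts = V[F]
    tri_area = trimesh.triangles.area(tri_pts)
    for k in range(3):
        np.add.at(area3, F[:, k], tri_area / 3.0)
    # cotangent weights: for each face corner, the opposite edge gets cot(angle)
    for corner in range(3):
        i = F[:, corner]
        j = F[:, (corner + 1) % 3]
        k = F[:, (corner + 2) % 3]
        u = V[j] - V[i]
        v = V[k] - V[i]
        cross = np.cross(u, v)
        denom = np.linalg.norm(cross, axis=1)
        denom = np.where(denom == 0, np.finfo(float).eps, denom)
        cot = np.einsum("ij,ij->i", u, v) / denom
        # edge (j, k) is opposite corner i
        np.add.at(Hvec, j, 0.5 * cot[:, None] * (V[j] - V[k]))
        np.add.at(Hvec, k, 0.5 * cot[:, None] * (V[k] - V[j]))
    area3 = np.where(area3 == 0, np.finfo(float).eps, area3)
    Kn = Hvec / area3[:, None]  # mean-curvature normal, magnitude 2|H|
    H = 0.5 * np.linalg.norm(Kn, axis=1)
    # orient by signed volume so "outward" does not depend on face winding
    orient = 1.0 if mesh.volume >= 0 else -1.0
    sign = np.sign(np.einsum("ij,ij->i", Kn, orient * mesh.vertex_normals))
    return sign * H


def curvature_deformation_score(mesh: trimesh.Trimesh) -> float:
    """SD of per-vertex mean curvature — a surface-irregularity summary."""
    return float(np.std(local_mean_curvature(mesh)))
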