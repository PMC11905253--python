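"""Per-face ESF sampling along perpendicular Bresenham lines.

For every mesh face a 3-D Bresenham (integer-stepping) line is cast
through the face centroid along the inward surface normal, so samples
run air -> tissue.  Pixel values are taken raw at the traversed voxels,
with no interpolation.  Each sample's signed distance to the interface
is the Euclidean distance from its voxel center to the nearest point of
the surface point cloud (kd-tree lookup), negative on the air side of
the body mask and positive inside.

Lines whose direction leaves the axial plane by 10 degrees or more pass
between slices and are discarded up front (the in-plane filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import CurveRejected, SamplingError
from .surface import BinaryMask, SurfaceMesh
from .volume import CTVolume


@dataclass
class ESFCurve:
    """One edge-spread-function sample sequence through the interface."""

    distances: np.ndarray  # signed mm, strictly increasing; negative = air
    values: np.ndarray  # HU
    face_id: int
    direction: np.ndarray  # unit sampling direction (air -> tissue)

    @property
    def N(self) -> int:
        return len(self.values)


def _point_triangle_distance(P, A, B, C):
    """Exact distances from points ``P`` to matched triangles ``(A, B, C)``.

    Interior projections use the plane distance; otherwise the minimum
    over the three edge segments.  All arrays are (n, 3).
    """
    AB, AC, AP = B - A, C - A, P - A
    d00 = np.einsum("ij,ij->i", AB, AB)
    d01 = np.einsum("ij,ij->i", AB, AC)
    d11 = np.einsum("ij,ij->i", AC, AC)
    d20 = np.einsum("ij,ij->i", AP, AB)
    d21 = np.einsum("ij,ij->i", AP, AC)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom == 0, 1e-30, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    closest = A + v[:, None] * AB + w[:, None] * AC
    d_plane = np.linalg.norm(P - closest, axis=1)

    def seg(S0, S1):
        d = S1 - S0
        t = np.einsum("ij,ij->i", P - S0, d)
        t = np.clip(t / np.maximum(np.einsum("ij,ij->i", d, d), 1e-30), 0.0, 1.0)
        return np.linalg.norm(P - (S0 + t[:, None] * d), axis=1)

    d_edge = np.minimum(np.minimum(seg(A, B), seg(B, C)), seg(C, A))
    return np.where(inside, d_plane, d_edge)


class SurfacePointIndex:
    """Nearest-interface distance lookup for a surface mesh.

    A kd-tree over the face centroids shortlists the ``k`` closest faces
    per query point; the reported distance is the exact minimum
    point-to-triangle distance over that shortlist.  A plain
    nearest-vertex lookup folds a tangential offset of up to half the
    vertex spacing into every distance (sqrt(d^2 + u^2)), which blurs
    the pooled ESF measurably at sharp kernels; the exact triangle
    distance removes that floor while keeping the same spatial-index
    mechanism.
    """

    def __init__(self, mesh: SurfaceMesh, k: int = 8):
        self._v = mesh.vertices
        self._f = mesh.faces
        self._k = min(k, len(mesh.faces))
        self._tree = cKDTree(mesh.centroids)

    def distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(points, k=self._k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        P = np.repeat(points, k, axis=0)
        F = self._f[idx.ravel()]
        d = _point_triangle_distance(P, self._v[F[:, 0]], self._v[F[:, 1]], self._v[F[:, 2]])
        return d.reshape(n, k).min(axis=1)


def in_plane_filter(direction: np.ndarray, max_angle_deg: float = 10.0) -> bool:
    """True iff ``direction`` lies within ``max_angle_deg`` of the axial
    (x-y) plane, i.e. the line stays in-slice."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise SamplingError("invalid direction")
    d = d / n
    angle = np.degrees(np.arctan2(abs(d[2]), np.hypot(d[0], d[1])))
    return bool(angle < max_angle_deg)


def bresenham_line(
    centroid_mm: np.ndarray,
    normal: np.ndarray,
    half_length: int,
    vol: CTVolume,
) -> np.ndarray:
    """Voxel indices of the +/-``half_length``-step Bresenham traversal
    through ``centroid_mm`` along ``normal`` (ordered along +normal).

    Stepping is integer along the driving axis (largest index-space
    component); consecutive voxels are unique and 26-connected.  Raises
    ``CurveRejected("out of bounds")`` when the line leaves the volume.
    """
    c = np.rint(vol.mm_to_index(centroid_mm)).astype(int)
    d_idx = np.asarray(normal, dtype=float) / np.asarray(vol.spacing)
    a = int(np.argmax(np.abs(d_idx)))
    if d_idx[a] == 0:
        raise SamplingError("invalid direction")
    m = d_idx / abs(d_idx[a])
    i = np.arange(-half_length, half_length + 1)
    steps = np.floor(np.outer(i, m) + 0.5).astype(int)
    steps[:, a] = i * int(np.sign(d_idx[a]))
    vox = c[None, :] + steps
    dims = np.asarray(vol.dims)
    if np.any(vox < 0) or np.any(vox >= dims):
        raise CurveRejected("out of bounds")
    return vox


def sample_curve(
    vol: CTVolume,
    line: np.ndarray,
    surface: SurfaceMesh | SurfacePointIndex,
    mask: BinaryMask,
    face_id: int = -1,
    direction: np.ndarray | None = None,
    min_side_samples: int = 8,
    max_distance_mm: float | None = None,
) -> ESFCurve:
    """Turn one Bresenham voxel list into an ESF curve.

    Values are the raw HU of the traversed voxels; distances are signed
    nearest-interface distances of the voxel centers, and the samples
    are returned ordered by distance.  Samples beyond
    ``max_distance_mm`` from the interface are dropped so every curve
    has the same physical support regardless of line obliquity.  Curves
    with fewer than ``min_side_samples`` samples on either side of the
    interface are rejected as ``"short curve"``.
    """
    index = surface if isinstance(surface, SurfacePointIndex) else SurfacePointIndex(surface)
    values = vol.voxels[line[:, 0], line[:, 1], line[:, 2]].astype(float)
    pos = vol.index_to_mm(line)
    dist = index.distance(pos)
    inside = mask.voxels[line[:, 0], line[:, 1], line[:, 2]]
    signed = np.where(inside, dist, -dist)
    order = np.argsort(signed, kind="stable")
    signed, values = signed[order], values[order]
    if max_distance_mm is not None:
        keep = np.abs(signed) <= max_distance_mm
        signed, values = signed[keep], values[keep]
    if np.sum(signed < 0) < min_side_samples or np.sum(signed >= 0) < min_side_samples:
        raise CurveRejected("short curve")
    if direction is None:
        direction = np.zeros(3)
    return ESFCurve(distances=signed, values=values, face_id=face_id, direction=np.asarray(direction))


def sample_mesh_curves(
    vol: CTVolume,
    mask: BinaryMask,
    mesh: SurfaceMesh,
    half_length: int,
    max_angle_deg: float = 10.0,
    min_side_samples: int = 8,
    max_distance_mm: float | None = None,
):
    """Vectorized per-face sampling of the whole mesh.

    Returns ``(curves, n_faces, n_in_plane, structural_rejects)`` where
    ``structural_rejects`` maps reason -> count for lines that left the
    volume or produced short curves.  One curve per in-plane face; the
    sampling direction is the inward (negated outward) normal so every
    valid ESF ascends from air to tissue.
    """
    normals_out = mesh.face_normals
    dirs_in = -normals_out
    spacing = np.asarray(vol.spacing)
    dims = np.asarray(vol.dims)

    dz = np.abs(dirs_in[:, 2])
    dxy = np.hypot(dirs_in[:, 0], dirs_in[:, 1])
    in_plane = np.degrees(np.arctan2(dz, dxy)) < max_angle_deg

    face_ids = np.nonzero(in_plane)[0]
    rejects = {"out of bounds": 0, "short curve": 0}
    curves: list[ESFCurve] = []
    if len(face_ids) == 0:
        return curves, mesh.n_faces, 0, rejects

    index = SurfacePointIndex(mesh)
    cents = np.rint(
        ((mesh.centroids[face_ids] - vol.origin) @ vol.axes) / spacing
    ).astype(int)
    d_idx = (dirs_in[face_ids] @ vol.axes) / spacing

    n_samp = 2 * half_length + 1
    steps_i = np.arange(-half_length, half_length + 1)
    axis = np.argmax(np.abs(d_idx), axis=1)

    vox = np.empty((len(face_ids), n_samp, 3), dtype=int)
    for a in range(3):
        sel = axis == a
        if not sel.any():
            continue
        da = d_idx[sel, a]
        m = d_idx[sel] / np.abs(da)[:, None]
        off = np.floor(steps_i[None, :, None] * m[:, None, :] + 0.5).astype(int)
        off[:, :, a] = steps_i[None, :] * np.sign(da).astype(int)[:, None]
        vox[sel] = cents[sel, None, :] + off

    in_bounds = np.all((vox >= 0) & (vox < dims[None, None, :]), axis=(1, 2))
    rejects["out of bounds"] = int(np.sum(~in_bounds))

    ok = np.nonzero(in_bounds)[0]
    if len(ok) == 0:
        return curves, mesh.n_faces, len(face_ids), rejects
    vox = vox[ok]
    kept_faces = face_ids[ok]

    flat = vox.reshape(-1, 3)
    values = vol.voxels[flat[:, 0], flat[:, 1], flat[:, 2]].astype(float).reshape(len(ok), n_samp)
    pos = vol.origin[None, :] + (flat * spacing) @ vol.axes.T
    dist = index.distance(pos).reshape(len(ok), n_samp)
    inside = mask.voxels[flat[:, 0], flat[:, 1], flat[:, 2]].reshape(len(ok), n_samp)
    signed = np.where(inside, dist, -dist)

    n_air = np.sum(signed < 0, axis=1)
    n_tis = n_samp - n_air
    good = (n_air >= min_side_samples) & (n_tis >= min_side_samples)
    rejects["short curve"] = int(np.sum(~good))

    order = np.argsort(signed, axis=1, kind="stable")
    signed = np.take_along_axis(signed, order, axis=1)
    values = np.take_along_axis(values, order, axis=1)
    for row in np.nonzero(good)[0]:
        fid = int(kept_faces[row])
        s, v = signed[row], values[row]
        if max_distance_mm is not None:
            keep = np.abs(s) <= max_distance_mm
            s, v = s[keep], v[keep]
            if np.sum(s < 0) < min_side_samples or np.sum(s >= 0) < min_side_samples:
                rejects["short curve"] += 1
                continue
        curves.append(
            ESFCurve(
                distances=s,
                values=v,
                face_id=fid,
                direction=dirs_in[fid],
            )
        )
    return curves, mesh.n_faces, len(face_ids), rejects
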