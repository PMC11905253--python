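"""Body segmentation and air-skin surface meshing.

The body is separated from air/table by Otsu thresholding, the table is
excluded by the posterior crop plane, and the largest connected
component with cavities filled becomes the binary body mask.  Marching
cubes on that mask yields the skin-air triangle mesh, which is then
Taubin-smoothed (volume-preserving low-pass) to remove voxelization
staircases.  Optional operations: mesh decimation by shortest-edge
collapse (the resampling study) and the head-and-neck slab truncation
with 2x face oversampling.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import SurfaceError
from .volume import CTVolume, table_keep_mask


@dataclass
class BinaryMask:
    """Body segmentation sharing geometry with its source volume."""

    voxels: np.ndarray  # boolean, True = body
    spacing: tuple[float, float, float]
    origin: np.ndarray

    @property
    def dims(self):
        return self.voxels.shape


@dataclass
class SurfaceMesh:
    """Triangulated air-skin interface in patient mm coordinates.

    Faces are wound so that the right-hand-rule normal points outward,
    from body into air.
    """

    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _tri(self):
        return self.vertices[self.faces]

    @property
    def centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self._tri().mean(axis=1)
        return self._cache["centroids"]

    @property
    def face_normals(self) -> np.ndarray:
        """Outward unit normals per face."""
        if "normals" not in self._cache:
            t = self._tri()
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._cache["normals"] = n / norm
        return self._cache["normals"]

    @property
    def areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            t = self._tri()
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            self._cache["areas"] = 0.5 * np.linalg.norm(n, axis=1)
        return self._cache["areas"]

    @property
    def volume(self) -> float:
        """Enclosed volume (divergence theorem); valid for closed meshes."""
        t = self._tri()
        return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2]))) / 6.0

    def flipped(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces[:, ::-1].copy())


def otsu_mask(vol: CTVolume, table_crop: bool = True, table_pixels: int = 50) -> BinaryMask:
    """Segment the body from air by Otsu's threshold on the HU histogram.

    Applies the table-crop exclusion, keeps the largest connected
    component only, and fills internal cavities so marching cubes sees
    the external skin surface alone.
    """
    vox = vol.voxels
    if float(np.ptp(vox)) < 1.0:
        raise SurfaceError("degenerate histogram")
    thr = threshold_otsu(vox)
    mask = vox > thr
    if not mask.any() or mask.all():
        raise SurfaceError("degenerate histogram")
    if table_crop:
        mask &= table_keep_mask(vol, table_pixels)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SurfaceError("degenerate histogram")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(voxels=mask, spacing=vol.spacing, origin=vol.origin.copy())


def extract_surface(mask: BinaryMask) -> SurfaceMesh:
    """Marching-cubes triangulation of the mask iso-surface, in mm.

    The mask is padded by one empty voxel layer laterally (so bodies
    reaching the transverse borders still close) but not longitudinally:
    a body running through the whole stack stays open at the crop
    planes, which keeps artificial end caps out of the nearest-surface
    distance lookups.  Face winding is oriented body -> air.
    """
    if not mask.voxels.any():
        raise SurfaceError("no surface")
    padded = np.pad(mask.voxels, ((1, 1), (1, 1), (0, 0))).astype(np.float32)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    except (ValueError, RuntimeError) as exc:
        raise SurfaceError("no surface") from exc
    verts = verts - np.asarray((mask.spacing[0], mask.spacing[1], 0.0)) + np.asarray(mask.origin)
    mesh = SurfaceMesh(vertices=np.ascontiguousarray(verts), faces=np.ascontiguousarray(faces))
    if _fraction_pointing_inward(mesh, mask) > 0.5:
        mesh = mesh.flipped()
    return mesh


def _fraction_pointing_inward(mesh: SurfaceMesh, mask: BinaryMask) -> float:
    """Fraction of faces whose normal probes into the body mask."""
    step = np.min(mask.spacing)
    probe = mesh.centroids + 0.6 * step * mesh.face_normals
    idx = np.rint((probe - np.asarray(mask.origin)) / np.asarray(mask.spacing)).astype(int)
    dims = np.asarray(mask.dims)
    ok = np.all((idx >= 0) & (idx < dims), axis=1)
    if not ok.any():
        return 0.0
    inside = mask.voxels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return float(np.mean(inside))


def taubin_smooth(mesh: SurfaceMesh, iterations: int = 100, passband: float = 0.05) -> SurfaceMesh:
    """Volume-preserving Taubin low-pass smoothing.

    ``iterations`` counts shrink/dilate pairs; ``passband`` is the
    band-pass coefficient k_pb = 1/lambda - 1/nu.  With lambda = 0.5 the
    dilation weight is nu = 1 / (2 - k_pb).
    """
    if iterations == 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    lamb = 0.5
    nu = 1.0 / (1.0 / lamb - passband)
    tm = trimesh.Trimesh(vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False)
    trimesh.smoothing.filter_taubin(tm, lamb=lamb, nu=nu, iterations=2 * iterations)
    return SurfaceMesh(np.asarray(tm.vertices), mesh.faces.copy())


def decimate_mesh(mesh: SurfaceMesh, keep_fraction: float) -> SurfaceMesh:
    """Reduce face count to ~``keep_fraction`` of the input by repeated
    shortest-edge midpoint collapse.

    Collapsing the shortest edges of a dense marching-cubes mesh keeps
    the enclosed volume nearly unchanged (chordal error is quadratic in
    edge length) while thinning faces uniformly.  Edges whose endpoints
    share more than two neighbours are skipped to preserve manifoldness.
    """
    if keep_fraction <= 0 or keep_fraction > 1:
        raise SurfaceError("invalid fraction")
    if keep_fraction == 1.0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())

    verts = [v for v in mesh.vertices.astype(float)]
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set] = {i: set() for i in range(len(verts))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)

    def neighbors(v):
        out = set()
        for fi in vert_faces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def push_edges_of(v, heap):
        p = verts[v]
        for u in neighbors(v):
            d = p - verts[u]
            heapq.heappush(heap, (float(d @ d), min(u, v), max(u, v)))

    heap: list = []
    f_arr = mesh.faces
    e = np.concatenate([f_arr[:, [0, 1]], f_arr[:, [1, 2]], f_arr[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    d2 = np.einsum("ij,ij->i", mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]],
                   mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]])
    for (a, b), dd in zip(e, d2):
        heap.append((float(dd), int(a), int(b)))
    heapq.heapify(heap)

    target_remove = int(round((1.0 - keep_fraction) * len(faces)))
    removed = 0
    alive = np.ones(len(verts), dtype=bool)
    while removed < target_remove and heap:
        d2_pop, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]):
            continue
        shared = vert_faces[a] & vert_faces[b]
        if not shared:  # stale edge
            continue
        delta = verts[a] - verts[b]
        if float(delta @ delta) > d2_pop * 1.0001:  # length changed since push
            heapq.heappush(heap, (float(delta @ delta), a, b))
            continue
        na, nb = neighbors(a), neighbors(b)
        if len(na & nb) != len(shared):  # link condition: avoid pinching
            continue
        # volume of the affected ring before the collapse
        vol_before = 0.0
        for fi in vert_faces[a] | vert_faces[b]:
            p0, p1, p2 = (verts[v] for v in faces[fi])
            vol_before += p0 @ np.cross(p1, p2)
        # collapse b into a at the midpoint
        verts[a] = 0.5 * (verts[a] + verts[b])
        alive[b] = False
        for fi in list(shared):
            for v in faces[fi]:
                vert_faces[v].discard(fi)
            del faces[fi]
            removed += 1
        for fi in list(vert_faces[b]):
            f = faces[fi]
            faces[fi] = tuple(a if v == b else v for v in f)
            vert_faces[a].add(fi)
        vert_faces[b] = set()
        # volume-preserving placement: shift the merged vertex along the
        # ring's area vector to cancel the chordal volume loss
        vol_after = 0.0
        grad = np.zeros(3)
        for fi in vert_faces[a]:
            f = faces[fi]
            p0, p1, p2 = (verts[v] for v in f)
            vol_after += p0 @ np.cross(p1, p2)
            j = f.index(a)
            grad += np.cross(verts[f[(j + 1) % 3]], verts[f[(j + 2) % 3]])
        g2 = float(grad @ grad)
        if g2 > 1e-12:
            verts[a] = verts[a] - ((vol_after - vol_before) / g2) * grad
        push_edges_of(a, heap)

    keep_faces = np.array([f for f in faces.values() if len(set(f)) == 3], dtype=int)
    used = np.unique(keep_faces)
    remap = -np.ones(len(verts), dtype=int)
    remap[used] = np.arange(len(used))
    new_verts = np.asarray([verts[i] for i in used])
    return SurfaceMesh(vertices=new_verts, faces=remap[keep_faces])


def hn_truncate_and_oversample(
    vol: CTVolume,
    mesh: SurfaceMesh,
    slab_voxels: int = 75,
    factor: int = 2,
) -> SurfaceMesh:
    """Head-and-neck handling: keep only faces inside an anterior-posterior
    slab of ``slab_voxels`` x s_y mm centered on the volume, then raise the
    face count by ~``factor`` via longest-edge midpoint subdivision.

    The slab restricts sampling to the lateral (ear) band where
    thermoplastic masks make the least skin contact; oversampling wins
    back curve statistics lost to the truncation.
    """
    center = vol.index_to_mm((np.asarray(vol.dims) - 1) / 2.0)
    half_width = 0.5 * slab_voxels * vol.spacing[1]
    ap = np.abs(mesh.centroids[:, 1] - center[1])
    keep = ap <= half_width
    if not keep.any():
        raise SurfaceError("no surface in slab")

    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(len(mesh.vertices), dtype=int)
    remap[used] = np.arange(len(used))
    verts = list(mesh.vertices[used])
    faces = [tuple(f) for f in remap[faces]]

    if factor > 1:
        target = factor * len(faces)
        # split the largest faces first until the count target is met
        def area(f):
            a, b, c = (verts[i] for i in f)
            return float(np.linalg.norm(np.cross(b - a, c - a)))

        heap = [(-area(f), i) for i, f in enumerate(faces)]
        heapq.heapify(heap)
        midpoint_cache: dict[tuple[int, int], int] = {}
        live = len(faces)
        while live < target and heap:
            _, fi = heapq.heappop(heap)
            f = faces[fi]
            if f is None:
                continue
            # longest edge of this face
            pts = [verts[i] for i in f]
            lens = [np.linalg.norm(pts[(j + 1) % 3] - pts[j]) for j in range(3)]
            j = int(np.argmax(lens))
            a, b, c = f[j], f[(j + 1) % 3], f[(j + 2) % 3]
            key = (min(a, b), max(a, b))
            if key not in midpoint_cache:
                verts.append(0.5 * (verts[a] + verts[b]))
                midpoint_cache[key] = len(verts) - 1
            m = midpoint_cache[key]
            faces[fi] = None
            live -= 1
            for nf in ((a, m, c), (m, b, c)):
                faces.append(nf)
                live += 1
                heapq.heappush(heap, (-area(nf), len(faces) - 1))

    final = np.asarray([f for f in faces if f is not None], dtype=int)
    return SurfaceMesh(vertices=np.asarray(verts), faces=final)
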