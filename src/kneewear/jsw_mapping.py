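"""Joint-space-width maps, conformal flattening and wear images.

The femorotibial joint space width (JSW) — the distance between the
femoral and tibial articular surfaces — is a CT/radiographic proxy for
cartilage thickness.  Because all femora share template correspondence,
per-vertex JSW values over a fixed articular region of interest (ROI)
are directly comparable across cases.  The ROI patch is flattened onto
the unit square by a discrete harmonic (conformal-type) parameterization
with its boundary pinned to the square's perimeter, and the normalized,
inverted wear values are spline-interpolated onto an isotropic pixel
grid: value 0 = intact joint space, 1 = complete erosion (JSW 0 mm).

Axis convention of the flattened chart: u increases medial → lateral,
v increases anterior → posterior.  Left-right mesh mirroring therefore
corresponds to a horizontal image flip, which is what makes the mirror
augmentation in the encoder stage exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import sparse
from scipy.interpolate import RBFInterpolator
from scipy.sparse.linalg import spsolve

__all__ = [
    "DistanceMap",
    "SquareParam",
    "WearImage",
    "compute_jsw",
    "normalize_invert",
    "conformal_flatten",
    "rasterize",
    "wear_image_pipeline",
    "save_wear_image",
    "load_wear_image",
]

DEFAULT_REFERENCE_MM = 8.0  # cohort-level JSW normalization constant
DEFAULT_IMAGE_SIZE = 128


@dataclass
class DistanceMap:
    """Per-ROI-vertex joint space width (mm) on the femoral template."""

    roi_vertex_ids: np.ndarray
    jsw_mm: np.ndarray

    def __post_init__(self):
        self.roi_vertex_ids = np.asarray(self.roi_vertex_ids)
        self.jsw_mm = np.asarray(self.jsw_mm, dtype=float)
        if self.jsw_mm.shape != self.roi_vertex_ids.shape:
            raise ValueError("jsw_mm length must match roi_vertex_ids")
        if np.any(self.jsw_mm < 0):
            raise ValueError("joint space width must be non-negative")


@dataclass
class SquareParam:
    """Unit-square (u,v) coordinates of the flattened ROI patch."""

    uv: np.ndarray
    faces: np.ndarray | None = None
    max_distortion: float = float("nan")  # max quasi-conformal distortion ratio
    n_flipped: int = 0


@dataclass
class WearImage:
    """S×S normalized wear image; in-mask pixels lie in [0, 1]."""

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.pixels.shape[0] != self.pixels.shape[1] or self.pixels.shape[0] < 8:
            raise ValueError("wear image must be square with side ≥ 8")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


# ---------------------------------------------------------------------------
# Distance maps
# ---------------------------------------------------------------------------


def _point_triangle_closest(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest points on triangles (a,b,c) for query points p, vectorized.

    All arrays are (n, 3); triangle i is paired with point i.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    v = np.where(np.abs(d1 - d3) > 1e-30, d1 / (d1 - d3 + 1e-300), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    w = np.where(np.abs(d2 - d6) > 1e-30, d2 / (d2 - d6 + 1e-300), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(np.abs(denom) > 1e-30, (d4 - d3) / (denom + 1e-300), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    denom = np.where(np.abs(denom) > 1e-30, denom, 1e-300)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_point_on_mesh(
    mesh: trimesh.Trimesh, pts: np.ndarray, n_candidates: int = 16
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest points on a triangle mesh via a centroid KD-tree.

    Returns (closest points, distances, face index).  Candidate faces
    are the ``n_candidates`` nearest by centroid; exact point-triangle
    distances decide among them.
    """
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    tri = np.asarray(mesh.triangles)
    centroids = tri.mean(axis=1)
    k = min(n_candidates, len(tri))
    _, cand = cKDTree(centroids).query(pts, k=k)
    cand = np.atleast_2d(cand)
    n, kk = cand.shape
    flat = cand.ravel()
    P = np.repeat(pts, kk, axis=0)
    cp = _point_triangle_closest(P, tri[flat, 0], tri[flat, 1], tri[flat, 2])
    d = np.linalg.norm(cp - P, axis=1).reshape(n, kk)
    best = np.argmin(d, axis=1)
    rows = np.arange(n)
    closest = cp.reshape(n, kk, 3)[rows, best]
    faces = cand[rows, best]
    return closest, d[rows, best], faces


def compute_jsw(
    femur: trimesh.Trimesh, tibia: trimesh.Trimesh, roi: np.ndarray
) -> DistanceMap:
    """Closest-point distance from femoral ROI vertices to the tibial surface.

    Both meshes must be posed in the same frame.  Interpenetration
    (femoral vertex below the tibial surface, judged by the nearest
    face's outward normal) is clamped to 0 mm with a warning.
    """
    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("ROI must be non-empty")
    pts = np.asarray(femur.vertices)[roi]
    closest, dist, fidx = closest_point_on_mesh(tibia, pts)
    normals = np.asarray(tibia.face_normals)[fidx]
    inside = np.einsum("ij,ij->i", pts - closest, normals) < -1e-9
    if inside.any():
        warnings.warn(
            f"{int(inside.sum())} femoral ROI vertices interpenetrate the tibia; "
            "clamping their JSW to 0"
        )
        dist = dist.copy()
        dist[inside] = 0.0
    return DistanceMap(roi_vertex_ids=roi, jsw_mm=dist)


def normalize_invert(dmap: DistanceMap, reference_mm: float = DEFAULT_REFERENCE_MM) -> np.ndarray:
    """Map JSW to wear: w = clamp(1 − jsw/reference, 0, 1).

    A value of 1 corresponds to complete cartilage erosion (JSW 0 mm),
    0 to a joint space at or beyond the cohort reference width.
    """
    if reference_mm <= 0:
        raise ValueError("reference_mm must be positive")
    return np.clip(1.0 - dmap.jsw_mm / reference_mm, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Conformal (harmonic) flattening
# ---------------------------------------------------------------------------


def _boundary_loop(faces: np.ndarray) -> np.ndarray:
    """Ordered vertex loop of the single boundary of a disk-topology patch."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary_edges = edges[counts[inv] == 1]
    if len(boundary_edges) == 0:
        raise ValueError("patch has no boundary (closed surface, not a disk)")
    nxt = {}
    for a, b in boundary_edges:
        if a in nxt:
            raise ValueError("non-manifold or multi-loop boundary (not a disk)")
        nxt[int(a)] = int(b)
    start = int(boundary_edges[0, 0])
    loop = [start]
    cur = nxt[start]
    while cur != start:
        loop.append(cur)
        if cur not in nxt or len(loop) > len(nxt) + 1:
            raise ValueError("boundary is not a single closed loop (not a disk)")
        cur = nxt[cur]
    if len(loop) != len(nxt):
        raise ValueError("multiple boundary loops found (not a disk)")
    return np.asarray(loop, dtype=int)


def _cotan_laplacian(V: np.ndarray, F: np.ndarray) -> sparse.csr_matrix:
    n = len(V)
    I, J, W = [], [], []
    for k in range(3):
        i = F[:, k]
        j = F[:, (k + 1) % 3]
        o = F[:, (k + 2) % 3]
        e1 = V[i] - V[o]
        e2 = V[j] - V[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-12)
        cot = np.clip(cot, -1e6, 1e6)
        I.extend([i, j])
        J.extend([j, i])
        W.extend([0.5 * cot, 0.5 * cot])
    I = np.concatenate(I)
    J = np.concatenate(J)
    W = np.concatenate(W)
    A = sparse.coo_matrix((W, (I, J)), shape=(n, n)).tocsr()
    L = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return L.tocsr()


def _square_boundary_positions(ts: np.ndarray) -> np.ndarray:
    """Map arc-length parameters in [0,4) onto the unit-square perimeter."""
    uv = np.zeros((len(ts), 2))
    for i, t in enumerate(ts):
        s = t % 4.0
        if s < 1:
            uv[i] = (s, 0.0)
        elif s < 2:
            uv[i] = (1.0, s - 1)
        elif s < 3:
            uv[i] = (3 - s, 1.0)
        else:
            uv[i] = (0.0, 4 - s)
    return uv


def conformal_flatten(
    vertices: np.ndarray, faces: np.ndarray, corners: np.ndarray | None = None
) -> SquareParam:
    """Discrete harmonic map of a disk-topology patch onto the unit square.

    The boundary loop is pinned to the square perimeter by cumulative
    arc length, with four corner vertices (chosen to maximize pairwise
    boundary spread unless given) fixed at the square corners; interior
    vertices solve the cotangent-Laplace equation.  For a planar square
    patch whose corners are the patch corners this reproduces the
    identity map up to solver precision.
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=int)
    areas = 0.5 * np.linalg.norm(
        np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]]), axis=1
    )
    if np.any(areas < 1e-14):
        raise ValueError("degenerate triangles in ROI patch")
    loop = _boundary_loop(F)
    B = V[loop]
    nb = len(loop)

    if corners is None:
        # deterministic corner pick: vertex with max summed distance to the
        # rest of the boundary, then quarter-arc-length companions
        dsum = np.linalg.norm(B[:, None, :] - B[None, :, :], axis=2).sum(axis=1)
        c0 = int(np.argmax(dsum))
        seg = np.linalg.norm(np.roll(B, -1, axis=0) - B, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        arc = (cum[:-1] - cum[c0]) % total
        corner_pos = [int(np.argmin(np.abs(arc - q * total / 4))) for q in range(4)]
    else:
        corner_pos = [int(np.flatnonzero(loop == c)[0]) for c in corners]
        arc = None

    seg = np.linalg.norm(np.roll(B, -1, axis=0) - B, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    order = sorted(range(4), key=lambda q: (cum[corner_pos[q]] - cum[corner_pos[0]]) % cum[-1])
    cpos = [corner_pos[q] for q in order]

    # arc-length parameter in [0,4): each boundary side spans one unit
    t = np.zeros(nb)
    cpos_ext = cpos + [cpos[0]]
    for side in range(4):
        a, b = cpos_ext[side], cpos_ext[side + 1]
        idxs = []
        i = a
        while True:
            idxs.append(i)
            if i == b:
                break
            i = (i + 1) % nb
        side_seg = seg[[j % nb for j in idxs[:-1]]]
        side_len = side_seg.sum()
        if side_len <= 0:
            raise ValueError("zero-length boundary side")
        local = np.concatenate([[0.0], np.cumsum(side_seg)]) / side_len
        for j, li in zip(idxs, local):
            t[j] = side + li
    boundary_uv = _square_boundary_positions(t)

    n = len(V)
    L = _cotan_laplacian(V, F)
    is_b = np.zeros(n, dtype=bool)
    is_b[loop] = True
    interior = np.flatnonzero(~is_b)
    uv = np.zeros((n, 2))
    uv[loop] = boundary_uv
    if len(interior):
        Lii = L[interior][:, interior]
        Lib = L[interior][:, loop]
        rhs = -Lib @ boundary_uv
        sol = spsolve(Lii.tocsc(), rhs)
        uv[interior] = np.atleast_2d(sol).reshape(len(interior), 2)

    # orientation: make signed uv areas positive (flip u if mirrored)
    su = _signed_areas(uv, F)
    if np.sum(su) < 0:
        uv[:, 0] = 1.0 - uv[:, 0]
        su = -su
    n_flipped = int(np.sum(su <= 0))
    if n_flipped:
        warnings.warn(f"{n_flipped} flipped triangles in harmonic parameterization")
    distortion = _max_qc_distortion(V, F, uv)
    return SquareParam(uv=uv, faces=F, max_distortion=distortion, n_flipped=n_flipped)


def _signed_areas(uv: np.ndarray, F: np.ndarray) -> np.ndarray:
    a, b, c = uv[F[:, 0]], uv[F[:, 1]], uv[F[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


def _max_qc_distortion(V: np.ndarray, F: np.ndarray, uv: np.ndarray) -> float:
    """Max ratio of singular values of the per-triangle 3D→2D Jacobian."""
    worst = 1.0
    for f in F:
        p = V[f]
        q = uv[f]
        e1, e2 = p[1] - p[0], p[2] - p[0]
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n)
        if nn < 1e-14:
            continue
        x = e1 / np.linalg.norm(e1)
        y = np.cross(n / nn, x)
        P = np.array([[0, 0], [e1 @ x, e1 @ y], [e2 @ x, e2 @ y]])
        Q = q - q[0]
        M = np.linalg.lstsq(P[1:] - P[0], Q[1:] - Q[0], rcond=None)[0]
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] > 1e-12:
            worst = max(worst, float(s[0] / s[1]))
    return worst


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize(
    param: SquareParam,
    values: np.ndarray,
    size: int = DEFAULT_IMAGE_SIZE,
    smoothing: float = 1e-8,
) -> WearImage:
    """Thin-plate-spline interpolation of scattered (u,v,value) samples
    onto the pixel centres of a size×size isotropic grid, clipped to
    [0, 1].  Deterministic for fixed inputs.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 samples to interpolate")
    if not np.all(np.isfinite(values)):
        raise ValueError("wear values must be finite")
    uv = param.uv
    neighbors = None if len(uv) <= 1500 else 128
    interp = RBFInterpolator(
        uv, values, kernel="thin_plate_spline", smoothing=smoothing, neighbors=neighbors
    )
    g = (np.arange(size) + 0.5) / size
    uu, vv = np.meshgrid(g, g, indexing="xy")
    pix = interp(np.column_stack([uu.ravel(), vv.ravel()])).reshape(size, size)
    mask = np.ones((size, size), dtype=bool)
    return WearImage(pixels=np.clip(pix, 0.0, 1.0), mask=mask)


def sample_image(img: WearImage, uv: np.ndarray) -> np.ndarray:
    """Bilinear sample of the image at (u,v) points (round-trip checks)."""
    from scipy.interpolate import RegularGridInterpolator

    S = img.size
    g = (np.arange(S) + 0.5) / S
    f = RegularGridInterpolator(
        (g, g), img.pixels, bounds_error=False, fill_value=None
    )
    # pixels[row=v, col=u]
    return f(np.column_stack([uv[:, 1], uv[:, 0]]))


# ---------------------------------------------------------------------------
# Convenience pipeline and IO
# ---------------------------------------------------------------------------


def wear_image_pipeline(
    limb,
    param: SquareParam,
    reference_mm: float = DEFAULT_REFERENCE_MM,
    size: int = DEFAULT_IMAGE_SIZE,
) -> WearImage:
    """JSW → normalize/invert → rasterize for one (already flattened) limb.

    ``param`` is the flattened femoral ROI of the shared template, so it
    is computed once per cohort; only the distances vary per case.
    """
    dmap = compute_jsw(limb.femur, limb.tibia, limb.femur_cap_ids)
    wear = normalize_invert(dmap, reference_mm)
    return rasterize(param, wear, size=size)


def save_wear_image(img: WearImage, path_npz, path_png=None) -> None:
    np.savez(path_npz, pixels=img.pixels, mask=img.mask)
    if path_png is not None:
        from PIL import Image

        arr = (np.clip(img.pixels, 0, 1) * 65535).astype(np.uint16)
        Image.fromarray(arr, mode="I;16").save(path_png)


def load_wear_image(path_npz) -> WearImage:
    z = np.load(path_npz)
    return WearImage(pixels=z["pixels"], mask=z["mask"].astype(bool))
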