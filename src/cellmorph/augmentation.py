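"""Morphology-preserving random views for contrastive training.

Mesh views are produced by handle-based surface deformation: a few ball-shaped
handle regions are sampled on the membrane, displaced in a random / normal /
negative-normal direction, and the constraint is propagated to the free
vertices either through a biharmonic displacement field (fourth-order
smoothness) or an as-rigid-as-possible (ARAP) local-global solve, followed by
optional anisotropic scaling, rotation and mirroring.  Texture views combine
axis flips, right-angle rotations and a smooth elastic warp.

Both solvers are built on the cotangent Laplacian of the triangle mesh with a
barycentric lumped mass matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .extraction import SurfaceMesh


class DeformError(RuntimeError):
    pass


@dataclass
class RigidConfig:
    anisotropic_scale_range: tuple[float, float] = (0.9, 1.1)
    rotate: bool = True
    mirror: bool = True


@dataclass
class DeformConfig:
    n_handles: int = 3
    handle_radius: float = 0.10        # fraction of bbox diagonal
    displacement_scale: float = 0.05   # fraction of bbox diagonal
    direction_mode: str = "random"     # random | normal | negative_normal
    method: str = "biharmonic"         # biharmonic | arap
    rigid: RigidConfig = field(default_factory=RigidConfig)
    # biharmonic fields may overshoot the handle displacement; bound used by
    # the displacement-bound property
    displacement_slack: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_handles < 1:
            raise ValueError("n_handles must be >= 1")
        if self.displacement_scale < 0:
            raise ValueError("displacement_scale must be >= 0")
        if self.direction_mode not in ("random", "normal", "negative_normal"):
            raise ValueError(f"bad direction_mode {self.direction_mode!r}")
        if self.method not in ("biharmonic", "arap"):
            raise ValueError(f"bad method {self.method!r}")


# ---------------------------------------------------------------------------
# discrete operators


def cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray) -> sparse.csr_matrix:
    """Symmetric cotangent Laplacian L = D - W (positive semi-definite)."""
    v = vertices
    i0, i1, i2 = faces[:, 0], faces[:, 1], faces[:, 2]
    rows, cols, vals = [], [], []
    for (a, b, c) in ((i0, i1, i2), (i1, i2, i0), (i2, i0, i1)):
        # cotangent at vertex c, opposite edge (a, b)
        e1 = v[a] - v[c]
        e2 = v[b] - v[c]
        cross = np.cross(e1, e2)
        area2 = np.linalg.norm(cross, axis=1)
        cot = (e1 * e2).sum(1) / np.maximum(area2, 1e-12)
        w = 0.5 * cot
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = len(vertices)
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    D = sparse.diags(np.asarray(W.sum(axis=1)).ravel())
    return (D - W).tocsr()


def lumped_mass(vertices: np.ndarray, faces: np.ndarray) -> sparse.dia_matrix:
    v = vertices
    cross = np.cross(v[faces[:, 1]] - v[faces[:, 0]],
                     v[faces[:, 2]] - v[faces[:, 0]])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    m = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(m, faces[:, k], area / 3.0)
    return sparse.diags(np.maximum(m, 1e-12))


def _solve_constrained(A: sparse.spmatrix, n: int, handle_idx: np.ndarray,
                       handle_val: np.ndarray, rhs_full=None) -> np.ndarray:
    """Solve A x = rhs with x fixed on handle vertices; returns full x (n, 3)."""
    free = np.setdiff1d(np.arange(n), handle_idx)
    A = A.tocsr()
    x = np.zeros((n, 3))
    x[handle_idx] = handle_val
    rhs = np.zeros((n, 3)) if rhs_full is None else rhs_full
    b = rhs[free] - A[free][:, handle_idx] @ handle_val
    try:
        sol = spsolve(A[free][:, free].tocsc(), b)
    except Exception as err:  # singular system
        raise DeformError(f"constrained solve failed: {err}") from err
    x[free] = np.atleast_2d(sol).reshape(len(free), 3)
    if not np.isfinite(x).all():
        raise DeformError("solver produced non-finite vertices")
    return x


def biharmonic_deform(vertices: np.ndarray, faces: np.ndarray,
                      handle_idx: np.ndarray,
                      handle_disp: np.ndarray) -> np.ndarray:
    """Propagate handle displacements by a biharmonic field (K d = 0 free)."""
    L = cotangent_laplacian(vertices, faces)
    M_inv = sparse.diags(1.0 / lumped_mass(vertices, faces).diagonal())
    K = (L @ M_inv @ L).tocsr()
    d = _solve_constrained(K, len(vertices), handle_idx, handle_disp)
    return vertices + d


def arap_deform(vertices: np.ndarray, faces: np.ndarray,
                handle_idx: np.ndarray, handle_disp: np.ndarray,
                n_iters: int = 5) -> np.ndarray:
    """Local-global as-rigid-as-possible deformation with cotangent weights."""
    n = len(vertices)
    L = cotangent_laplacian(vertices, faces)
    W = sparse.diags(L.diagonal()) - L  # off-diagonal weights, symmetric
    W = W.tocsr()
    target = vertices[handle_idx] + handle_disp
    # initial guess: biharmonic propagation
    p_new = biharmonic_deform(vertices, faces, handle_idx, handle_disp)
    neighbours = [W.indices[W.indptr[i]:W.indptr[i + 1]] for i in range(n)]
    weights = [W.data[W.indptr[i]:W.indptr[i + 1]] for i in range(n)]
    for _ in range(n_iters):
        # local step: best-fit rotation per vertex cell
        R = np.empty((n, 3, 3))
        for i in range(n):
            j = neighbours[i]
            w = weights[i]
            e = (vertices[i] - vertices[j]) * w[:, None]
            e_new = p_new[i] - p_new[j]
            S = e.T @ e_new
            U, _, Vt = np.linalg.svd(S)
            Ri = Vt.T @ U.T
            if np.linalg.det(Ri) < 0:
                Vt[-1] *= -1
                Ri = Vt.T @ U.T
            R[i] = Ri
        # global step: L p' = b with handles clamped
        b = np.zeros((n, 3))
        for i in range(n):
            j = neighbours[i]
            w = weights[i]
            rot = R[i][None] + R[j]
            d = (vertices[i] - vertices[j])
            b[i] = 0.5 * (w[:, None] * np.einsum("njk,nk->nj", rot, d)).sum(0)
        p_new = _solve_constrained(L, n, handle_idx, target, rhs_full=b)
    return p_new


# ---------------------------------------------------------------------------
# handle sampling and rigid parts


def _handle_sets(mesh: trimesh.Trimesh, cfg: DeformConfig,
                 rng: np.random.Generator):
    diag = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    radius = cfg.handle_radius * diag
    centres = rng.choice(len(mesh.vertices), size=cfg.n_handles, replace=False)
    idx_sets, disps = [], []
    for c in centres:
        d = np.linalg.norm(mesh.vertices - mesh.vertices[c], axis=1)
        members = np.where(d <= radius)[0]
        if len(members) == 0:
            members = np.array([c])
        if cfg.direction_mode == "random":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
        else:
            direction = np.asarray(mesh.vertex_normals[members].mean(axis=0))
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
            if cfg.direction_mode == "negative_normal":
                direction = -direction
        idx_sets.append(members)
        disps.append(direction * cfg.displacement_scale * diag)
    handle_idx = np.concatenate(idx_sets)
    handle_disp = np.concatenate([np.tile(d, (len(s), 1))
                                  for s, d in zip(idx_sets, disps)])
    # deduplicate overlapping handles (first wins)
    _, first = np.unique(handle_idx, return_index=True)
    return handle_idx[first], handle_disp[first]


def mirror_mesh(vertices: np.ndarray, axis: int,
                centre: np.ndarray | None = None) -> np.ndarray:
    """Reflect vertices across the axis-aligned plane through ``centre``.

    Applying the same mirror twice is the identity.
    """
    c = vertices.mean(axis=0) if centre is None else centre
    out = vertices.copy()
    out[:, axis] = 2 * c[axis] - out[:, axis]
    return out


def _apply_rigid(vertices: np.ndarray, rigid: RigidConfig,
                 rng: np.random.Generator) -> np.ndarray:
    centre = vertices.mean(axis=0)
    v = vertices - centre
    lo, hi = rigid.anisotropic_scale_range
    v = v * rng.uniform(lo, hi, size=3)
    if rigid.rotate:
        q = rng.normal(size=(3, 3))
        Q, Rm = np.linalg.qr(q)
        Q *= np.sign(np.diag(Rm))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        v = v @ Q.T
    out = v + centre
    if rigid.mirror and rng.random() < 0.5:
        out = mirror_mesh(out, axis=int(rng.integers(0, 3)))
    return out


# ---------------------------------------------------------------------------
# public ops


def deform_mesh(mesh: SurfaceMesh, cfg: DeformConfig) -> SurfaceMesh:
    """One random morphology-preserving view of a mesh.

    Vertex and face counts are unchanged; with zero displacement and no rigid
    part the output equals the input.
    """
    rng = np.random.default_rng(cfg.seed)
    tm = mesh.to_trimesh()
    verts = np.asarray(tm.vertices, dtype=float)
    if cfg.displacement_scale > 0:
        handle_idx, handle_disp = _handle_sets(tm, cfg, rng)
        if cfg.method == "biharmonic":
            verts = biharmonic_deform(verts, mesh.faces, handle_idx, handle_disp)
        else:
            verts = arap_deform(verts, mesh.faces, handle_idx, handle_disp)
    identity_rigid = (cfg.rigid.anisotropic_scale_range == (1.0, 1.0)
                      and not cfg.rigid.rotate and not cfg.rigid.mirror)
    if not identity_rigid:
        verts = _apply_rigid(verts, cfg.rigid, rng)
    if not np.isfinite(verts).all():
        raise DeformError(f"non-finite vertices deforming object {mesh.object_id}")
    return SurfaceMesh(vertices=verts, faces=mesh.faces.copy(),
                       object_id=mesh.object_id)


def make_mesh_views(mesh: SurfaceMesh, n_views: int, cfg: DeformConfig,
                    cache_dir: str | Path | None = None) -> list[SurfaceMesh]:
    """Precompute ``n_views`` independent deformed views (optionally cached
    as PLY files ``{object_id}_view{k}.ply`` for reuse across epochs)."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    views = []
    for k in range(n_views):
        path = None
        if cache_dir is not None:
            path = Path(cache_dir) / f"{mesh.object_id}_view{k}.ply"
            if path.exists():
                tm = trimesh.load_mesh(path, process=False)
                views.append(SurfaceMesh(np.asarray(tm.vertices),
                                         np.asarray(tm.faces), mesh.object_id))
                continue
        view_cfg = DeformConfig(**{**cfg.__dict__,
                                   "seed": cfg.seed * 1_000_003 + k})
        view = deform_mesh(mesh, view_cfg)
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            view.to_trimesh().export(path)
        views.append(view)
    return views


# ---------------------------------------------------------------------------
# texture augmentation


@dataclass
class ElasticConfig:
    amplitude_voxels: float = 2.0
    grid_points: int = 4
    interpolation_order: int = 1


@dataclass
class TextureAugmentParams:
    flips: tuple[bool, bool, bool]
    rot_axes: tuple[int, int]
    rot_k: int
    elastic_field: np.ndarray | None  # (3, *shape) voxel displacements


def sample_texture_params(shape: tuple, seed: int,
                          cfg: ElasticConfig | None = None) -> TextureAugmentParams:
    cfg = cfg or ElasticConfig()
    rng = np.random.default_rng(seed)
    flips = tuple(bool(b) for b in rng.random(3) < 0.5)
    axes_choices = ((0, 1), (0, 2), (1, 2))
    rot_axes = axes_choices[rng.integers(0, 3)]
    rot_k = int(rng.integers(0, 4))
    field = None
    if cfg.amplitude_voxels > 0:
        g = cfg.grid_points
        coarse = rng.normal(0.0, 1.0, size=(3, g, g, g))
        zoom = [s / g for s in shape]
        field = np.stack([ndi.zoom(coarse[i], zoom, order=3, mode="nearest")
                          for i in range(3)]) * cfg.amplitude_voxels
    return TextureAugmentParams(flips=flips, rot_axes=rot_axes, rot_k=rot_k,
                                elastic_field=field)


def apply_texture_augment(crop: np.ndarray,
                          params: TextureAugmentParams,
                          order: int = 1) -> np.ndarray:
    """Flips + right-angle rotation + elastic warp; shape preserved, clipped
    to [0, 1].  With no elastic field the output is a voxel permutation of
    the input."""
    out = crop
    for ax, f in enumerate(params.flips):
        if f:
            out = np.flip(out, axis=ax)
    if params.rot_k:
        out = np.rot90(out, k=params.rot_k, axes=params.rot_axes)
    out = np.ascontiguousarray(out)
    if params.elastic_field is not None:
        coords = np.mgrid[[slice(s) for s in out.shape]].astype(float)
        coords += params.elastic_field
        out = ndi.map_coordinates(out, coords, order=order, mode="nearest")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def apply_mask_augment(mask: np.ndarray, params: TextureAugmentParams) -> np.ndarray:
    """Carry a boolean compartment mask through the same geometric view."""
    out = mask.astype(np.float32)
    for ax, f in enumerate(params.flips):
        if f:
            out = np.flip(out, axis=ax)
    if params.rot_k:
        out = np.rot90(out, k=params.rot_k, axes=params.rot_axes)
    out = np.ascontiguousarray(out)
    if params.elastic_field is not None:
        coords = np.mgrid[[slice(s) for s in out.shape]].astype(float)
        coords += params.elastic_field
        out = ndi.map_coordinates(out, coords, order=1, mode="nearest")
    return out > 0.5


def augment_texture_with_mask(crop: np.ndarray, mask: np.ndarray, seed: int,
                              elastic_cfg: ElasticConfig | None = None):
    """One texture view plus the matching transformed compartment mask."""
    cfg = elastic_cfg or ElasticConfig()
    params = sample_texture_params(crop.shape, seed, cfg)
    return (apply_texture_augment(crop, params, order=cfg.interpolation_order),
            apply_mask_augment(mask, params))


def augment_texture(crop: np.ndarray, seed: int,
                    elastic_cfg: ElasticConfig | None = None) -> np.ndarray:
    """Random texture view of a [0, 1] crop; deterministic given ``seed``."""
    if crop.min() < 0 or crop.max() > 1:
        raise ValueError("crop values must lie in [0, 1]")
    params = sample_texture_params(crop.shape, seed, elastic_cfg)
    cfg = elastic_cfg or ElasticConfig()
    return apply_texture_augment(crop, params, order=cfg.interpolation_order)
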