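"""Per-cell network inputs from a labelled volume.

Three extraction products feed the encoders:

* **Coarse texture crops** — a cube cut from a downsampled version of the raw
  volume, centred on the nucleus centre of mass, intensity-normalised to
  [0, 1] and masked to the target compartment (cytoplasm or nucleus).
  Training crops are 144^3 (cytoplasm) / 104^3 (nucleus) voxels by default;
  prediction crops grow to 320^3 / 160^3 to fit more context.
* **Fine texture patches** — the compartment bounding box at full (fine)
  resolution is tiled into non-overlapping 32^3 cubes anchored at the box
  minimum corner; only cubes strictly more than half occupied by compartment
  voxels are kept.
* **Surface meshes / point clouds** — marching cubes on the binary mask,
  Laplacian-smoothed (volume-preserving), simplified toward a face budget by
  remeshing at coarser grid resolution, with vertices in nm; point clouds are
  sampled uniformly by surface area together with outward face normals.

Axis order is (z, y, x) in voxel space throughout; meshes live in physical nm
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage as ndi
from skimage.measure import block_reduce, marching_cubes


class ExtractionError(RuntimeError):
    """An extraction stage failed for one cell; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(message)
        self.stage = stage


@dataclass
class ExtractionConfig:
    """Geometry of the extraction stages.

    The cube edge lengths are the reference protocol; desk-scale runs shrink
    them through this config without changing any semantics.  Downsample
    factors map the stored volume onto the coarse / fine working resolutions
    (identity for phantoms, which are generated at coarse resolution).
    """

    coarse_train_cyto: int = 144
    coarse_train_nuc: int = 104
    coarse_predict_cyto: int = 320
    coarse_predict_nuc: int = 160
    coarse_downsample: tuple[int, int, int] = (1, 1, 1)
    fine_downsample: tuple[int, int, int] = (1, 1, 1)
    patch_edge: int = 32
    min_patch_occupancy: float = 0.5  # strictly greater-than retained
    smoothing_iters: int = 10
    target_faces: int = 5000
    n_points: int = 1024
    coarse_mode: str = "train"

    def coarse_shape(self, compartment: str, mode: str) -> tuple[int, int, int]:
        if mode not in ("train", "predict"):
            raise ValueError(f"mode must be train|predict, got {mode!r}")
        if compartment == "cytoplasm":
            edge = self.coarse_train_cyto if mode == "train" else self.coarse_predict_cyto
        elif compartment == "nucleus":
            edge = self.coarse_train_nuc if mode == "train" else self.coarse_predict_nuc
        else:
            raise ValueError(f"compartment must be cytoplasm|nucleus, got {compartment!r}")
        return (edge, edge, edge)


@dataclass
class CoarseCrop:
    values: np.ndarray  # float32 in [0, 1], complement compartment zeroed
    mask: np.ndarray    # bool, compartment support within the crop
    compartment: str
    mode: str
    cell_id: int


@dataclass
class FinePatchSet:
    patches: list[np.ndarray]
    masks: list[np.ndarray]
    occupancy: list[float]
    cell_id: int
    compartment: str


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (n, 3) nm, axis order (z, y, x)
    faces: np.ndarray     # (m, 3) vertex indices
    object_id: int

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class PointCloud:
    points: np.ndarray   # (n, 3)
    normals: np.ndarray  # (n, 3) unit
    n: int


def normalize_intensity(arr: np.ndarray) -> np.ndarray:
    """Map an intensity grid to [0, 1] by dividing by the dtype maximum.

    Float inputs are assumed normalised already (idempotent re-application).
    """
    if np.issubdtype(arr.dtype, np.integer):
        return (arr / np.iinfo(arr.dtype).max).astype(np.float32)
    return arr.astype(np.float32)


def downsample_mean(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    if all(f == 1 for f in factors):
        return arr
    return block_reduce(arr.astype(np.float32), block_size=tuple(factors),
                        func=np.mean)


def downsample_labels(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    if all(f == 1 for f in factors):
        return arr
    fz, fy, fx = factors
    return arr[::fz, ::fy, ::fx]


# ---------------------------------------------------------------------------
# coarse crops


def extract_coarse_crop(volume, cell_id: int, compartment: str,
                        mode: str = "train",
                        config: ExtractionConfig | None = None) -> CoarseCrop:
    """Nucleus-centred, compartment-masked, normalised coarse crop.

    The crop is centred on the nucleus centre of mass; voxels outside the
    target compartment (nucleus masked out of cytoplasm crops and vice versa)
    are zero.  Crops exceeding the volume are zero-padded.
    """
    config = config or ExtractionConfig()
    shape = config.coarse_shape(compartment, mode)
    f = config.coarse_downsample
    raw = normalize_intensity(downsample_mean(volume.raw, f))
    cells = downsample_labels(volume.cell_labels, f)
    nuclei = downsample_labels(volume.nucleus_labels, f)

    nuc_mask_full = nuclei == cell_id
    if not nuc_mask_full.any():
        raise ExtractionError(
            "coarse_crop", f"cell {cell_id}: no nucleus label present")
    centre = np.round(np.array(ndi.center_of_mass(nuc_mask_full))).astype(int)

    if compartment == "cytoplasm":
        comp_full = (cells == cell_id) & ~nuc_mask_full
    else:
        comp_full = nuc_mask_full

    values = np.zeros(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=bool)
    lo = centre - np.array(shape) // 2
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(lo + shape, raw.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    if (src_hi > src_lo).all():
        src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
        m = comp_full[src]
        values[dst] = raw[src] * m
        mask[dst] = m
    return CoarseCrop(values=values, mask=mask, compartment=compartment,
                      mode=mode, cell_id=cell_id)


# ---------------------------------------------------------------------------
# fine patches


def extract_fine_patches(volume, cell_id: int, compartment: str,
                         config: ExtractionConfig | None = None) -> FinePatchSet:
    """Tile the compartment bounding box into 32^3 cubes; keep cubes that are
    strictly more than half occupied by compartment voxels (a cube exactly
    50% empty is dropped)."""
    config = config or ExtractionConfig()
    f = config.fine_downsample
    raw = normalize_intensity(downsample_mean(volume.raw, f))
    cells = downsample_labels(volume.cell_labels, f)
    nuclei = downsample_labels(volume.nucleus_labels, f)
    if compartment == "cytoplasm":
        comp = (cells == cell_id) & (nuclei != cell_id)
    elif compartment == "nucleus":
        comp = nuclei == cell_id
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    if not comp.any():
        return FinePatchSet([], [], [], cell_id, compartment)

    e = config.patch_edge
    idx = np.argwhere(comp)
    lo, hi = idx.min(0), idx.max(0) + 1
    n_tiles = np.maximum(1, np.ceil((hi - lo) / e).astype(int))

    patches, masks, occ = [], [], []
    for tz in range(n_tiles[0]):
        for ty in range(n_tiles[1]):
            for tx in range(n_tiles[2]):
                corner = lo + np.array([tz, ty, tx]) * e
                pm = np.zeros((e, e, e), dtype=bool)
                pv = np.zeros((e, e, e), dtype=np.float32)
                src_lo = corner
                src_hi = np.minimum(corner + e, comp.shape)
                if (src_hi <= src_lo).any():
                    continue
                src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
                dst = tuple(slice(0, b - a) for a, b in zip(src_lo, src_hi))
                pm[dst] = comp[src]
                pv[dst] = raw[src] * comp[src]
                frac = pm.sum() / float(e ** 3)
                if frac > config.min_patch_occupancy:
                    patches.append(pv)
                    masks.append(pm)
                    occ.append(float(frac))
    return FinePatchSet(patches=patches, masks=masks, occupancy=occ,
                        cell_id=cell_id, compartment=compartment)


# ---------------------------------------------------------------------------
# meshes and point clouds


def build_mesh(labels: np.ndarray, object_id: int,
               voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0),
               smoothing_iters: int = 10,
               target_faces: int = 5000) -> SurfaceMesh:
    """Watertight triangular surface of one labelled object, vertices in nm.

    Marching cubes on the binary mask, volume-preserving Laplacian smoothing,
    then (if over budget) remeshing on a 2x-downsampled mask until the face
    count is at most ``target_faces``.
    """
    mask = labels == object_id
    if not mask.any():
        raise ExtractionError("mesh", f"object {object_id} absent from labels")
    idx = np.argwhere(mask)
    extent = idx.max(0) - idx.min(0) + 1
    if (extent < 2).any():
        raise ExtractionError(
            "mesh", f"object {object_id} smaller than 2 voxels in some axis")
    lo, hi = idx.min(0), idx.max(0) + 1
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    spacing = np.asarray(voxel_size_nm, dtype=float)
    scale = 1
    while True:
        verts, faces, _, _ = marching_cubes(
            np.pad(sub, 1).astype(np.float32), level=0.5,
            spacing=tuple(spacing * scale))
        if len(faces) <= target_faces or min(sub.shape) <= 4:
            break
        sub = block_reduce(sub.astype(np.float32), (2, 2, 2), np.mean) >= 0.5
        if not sub.any():
            raise ExtractionError(
                "mesh", f"object {object_id} vanished during simplification")
        scale *= 2

    mesh = trimesh.Trimesh(verts, faces, process=True)
    # keep the largest connected component (stray specks break watertightness)
    if mesh.body_count > 1:
        mesh = max(mesh.split(only_watertight=False), key=lambda m: len(m.faces))
    if smoothing_iters > 0:
        trimesh.smoothing.filter_laplacian(mesh, iterations=smoothing_iters)
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
    if not mesh.is_watertight:
        raise ExtractionError(
            "mesh", f"object {object_id}: mesh not watertight after repair")
    if mesh.volume < 0:
        mesh.invert()
    offset = (lo - 1) * spacing  # undo the 1-voxel pad, restore global coords
    return SurfaceMesh(vertices=np.asarray(mesh.vertices) + offset,
                       faces=np.asarray(mesh.faces), object_id=int(object_id))


def sample_point_cloud(mesh: SurfaceMesh, n: int, seed: int = 0) -> PointCloud:
    """Uniform-by-area surface samples with outward face normals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(mesh.faces) == 0:
        raise ExtractionError("point_cloud", "empty mesh")
    tm = mesh.to_trimesh()
    pts, fidx = trimesh.sample.sample_surface(tm, n, seed=int(seed) % (2 ** 31))
    normals = tm.face_normals[fidx]
    return PointCloud(points=np.asarray(pts, dtype=np.float64),
                      normals=np.asarray(normals, dtype=np.float64), n=n)


def skip_with_warning(fn, *args, stage: str = "extraction", **kwargs):
    """Run an extraction step, returning None (with a warning) on failure."""
    try:
        return fn(*args, **kwargs)
    except ExtractionError as err:
        warnings.warn(f"{stage}: {err}", stacklevel=2)
        return None
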