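"""Synthetic segmented EM-like phantom volumes.

Generates labelled 3D volumes that emulate the structure of a whole-body
serial block-face EM cell atlas at desk scale: each cell contains exactly one
nucleus, cells come in mirrored bilateral pairs across the mediolateral
mid-plane, and cells belong to discrete shape/texture/chromatin classes whose
intensity statistics are separable by construction.  The generator is the
test-bed for the whole pipeline: every downstream module can be exercised on
its output without any external data.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; the mediolateral (mirror) axis is the last
  array axis.  The mirror image of voxel ``x`` is ``X - 1 - x`` where ``X`` is
  the x extent, so mirrored partner centroids agree exactly under ``np.flip``.
* Intensities are 8-bit (0..255), matching SBEM convention; downstream
  normalisation divides by the dtype maximum.
* Cell labels and nucleus labels are paired one-to-one (same positive id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

SHAPE_CLASSES = ("sphere", "ellipsoid", "stellate", "flat")
TEXTURE_CLASSES = ("uniform", "speckle", "vesicular")
CHROMATIN_CLASSES = ("smooth", "granular")

# cytoplasm texture levels chosen so class means differ by >= 30 intensity units
_TEXTURE_LEVELS = {
    "uniform": dict(level=130.0, sd=4.0),
    "speckle": dict(level=190.0, sd=45.0),
    "vesicular": dict(level=70.0, sd=6.0, blob_value=230.0, blob_frac=0.10),
}
_CHROMATIN_LEVELS = {
    "smooth": dict(level=55.0, sd=3.0),
    "granular": dict(level=55.0, sd=3.0, clump_value=185.0, clump_frac=0.30),
}
_BACKGROUND_LEVEL = 40.0
_BACKGROUND_SD = 5.0


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed without overlap."""


@dataclass(frozen=True)
class CellClass:
    shape_class: str
    texture_class: str
    chromatin_class: str

    def __post_init__(self):
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if self.texture_class not in TEXTURE_CLASSES:
            raise ValueError(f"unknown texture class {self.texture_class!r}")
        if self.chromatin_class not in CHROMATIN_CLASSES:
            raise ValueError(f"unknown chromatin class {self.chromatin_class!r}")


def default_class_catalog() -> list[CellClass]:
    """Three shape classes crossed with two cytoplasm textures (6 classes)."""
    out = []
    for i, shape in enumerate(("sphere", "ellipsoid", "stellate")):
        for j, tex in enumerate(("uniform", "speckle")):
            out.append(CellClass(shape, tex, CHROMATIN_CLASSES[(i + j) % 2]))
    return out


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bilateral phantom volume.

    ``grid_shape`` / ``voxel_size_nm`` are (z, y, x).  ``contact_fraction`` is
    the probability that a newly placed cell is attached face-to-face to an
    already placed cell (preferring one of its own class); 0 keeps every pair
    of cells separated by at least one background voxel, 1 grows a single
    connected patch per body side.
    """

    n_cell_pairs: int = 30
    grid_shape: tuple[int, int, int] = (96, 72, 120)
    voxel_size_nm: tuple[float, float, float] = (100.0, 80.0, 80.0)
    class_catalog: Sequence[CellClass] = field(default_factory=default_class_catalog)
    contact_fraction: float = 0.5
    cell_radius_range: tuple[float, float] = (7.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_cell_pairs < 1:
            raise ValueError("n_cell_pairs must be >= 1")
        if len(self.class_catalog) == 0:
            raise ValueError("class_catalog must be non-empty")
        if not (0.0 <= self.contact_fraction <= 1.0):
            raise ValueError("contact_fraction must lie in [0, 1]")
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid too small for any cell with margin")


@dataclass
class PhantomVolume:
    """A generated phantom: raw intensities, paired label grids, and truth."""

    raw: np.ndarray            # uint8, (z, y, x)
    cell_labels: np.ndarray    # int32, 0 = background
    nucleus_labels: np.ndarray # int32, paired ids with cell_labels
    truth: pd.DataFrame        # indexed by cell_id
    voxel_size_nm: tuple[float, float, float]

    @property
    def cell_ids(self) -> np.ndarray:
        return self.truth.index.to_numpy()


# ---------------------------------------------------------------------------
# parametric solids


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _solid_mask(shape_class: str, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Binary voxel mask of one parametric solid in a tight local box."""
    r = float(radius)
    half = int(np.ceil(r)) + 1
    n = 2 * half + 1
    grid = np.stack(np.meshgrid(*([np.arange(n) - half] * 3), indexing="ij"), axis=-1)
    rot = _random_rotation(rng)
    p = grid.astype(float) @ rot.T

    if shape_class == "sphere":
        mask = (p ** 2).sum(-1) <= r ** 2
    elif shape_class == "ellipsoid":
        axes = np.array([r, 0.62 * r, 0.45 * r])
        mask = ((p / axes) ** 2).sum(-1) <= 1.0
    elif shape_class == "flat":
        axes = np.array([r, 0.85 * r, 0.28 * r])
        mask = ((p / axes) ** 2).sum(-1) <= 1.0
    elif shape_class == "stellate":
        # core sphere plus angular lobes: radial threshold modulated by the
        # proximity of each direction to a handful of random spike directions
        n_spikes = rng.integers(4, 7)
        dirs = rng.normal(size=(n_spikes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        norm = np.sqrt((p ** 2).sum(-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            u = p / norm[..., None]
        u[norm == 0] = 0.0
        align = np.max(u @ dirs.T, axis=-1)  # cos of angle to nearest spike
        bump = np.exp((align - 1.0) / 0.08)
        local_r = r * (0.55 + 0.45 * bump)
        mask = norm <= local_r
    else:  # pragma: no cover - guarded by CellClass
        raise ValueError(shape_class)

    # keep only the connected component containing the centre
    lab, _ = ndi.label(mask)
    centre_lab = lab[half, half, half]
    mask = lab == centre_lab if centre_lab > 0 else mask
    # tight bbox
    idx = np.argwhere(mask)
    lo, hi = idx.min(0), idx.max(0) + 1
    return mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _nucleus_mask(cell_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ellipsoidal nucleus strictly inside the (eroded) cell support."""
    interior = ndi.binary_erosion(cell_mask)
    com = np.array(ndi.center_of_mass(cell_mask))
    zz, yy, xx = np.indices(cell_mask.shape)
    p = np.stack([zz, yy, xx], -1).astype(float) - com
    half_extent = (np.array(cell_mask.shape) / 2.0).clip(min=2.0)
    # nuclei occupy a substantial cell fraction, as in differentiated tissue
    axes = np.maximum(0.5 * half_extent, 2.0)
    nuc = (((p / axes) ** 2).sum(-1) <= 1.0) & interior
    if not nuc.any():  # tiny or thin cell: fall back to eroded core voxel(s)
        nuc = interior
    if not nuc.any():
        raise PlacementError("cell too small to hold a nucleus")
    lab, _ = ndi.label(nuc)
    keep = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == keep


# ---------------------------------------------------------------------------
# placement

_FACE_STRUCT = ndi.generate_binary_structure(3, 1)  # 6-connectivity


def _try_place(occ: np.ndarray, mask: np.ndarray, corner: np.ndarray,
               bounds_lo: np.ndarray, bounds_hi: np.ndarray,
               touch_target: np.ndarray | None) -> bool:
    """Check a placement of ``mask`` at ``corner``; True if admissible.

    Non-touching placements require a >=1 voxel background gap to every other
    cell; touching placements require zero overlap plus at least one
    face-adjacent voxel pair with ``touch_target``.
    """
    sz = np.array(mask.shape)
    if (corner < bounds_lo).any() or (corner + sz > bounds_hi).any():
        return False
    sl = tuple(slice(c, c + s) for c, s in zip(corner, sz))
    if (occ[sl] & mask).any():
        return False
    # dilate in a 1-voxel padded frame so adjacency across the bbox is seen
    dil = ndi.binary_dilation(np.pad(mask, 1), _FACE_STRUCT)
    psl = tuple(slice(c - 1, c + s + 1) for c, s in zip(corner, sz))
    if touch_target is None:
        return not (occ[psl] & dil).any()
    return bool((touch_target[psl] & dil).any())


def _touch_place(occ, mask, target, grid_shape, bounds_lo, bounds_hi,
                 rng) -> np.ndarray | None:
    """Find a corner placing ``mask`` face-adjacent to ``target`` (ray march
    outward from the target centre until overlap clears)."""
    sz = np.array(mask.shape)
    tgrid = np.zeros(grid_shape, bool)
    tsl = tuple(slice(c, c + s) for c, s in zip(target["corner"],
                                                target["mask"].shape))
    tgrid[tsl] = target["mask"]
    tc = target["corner"] + np.array(target["mask"].shape) // 2
    max_t = int(np.linalg.norm(sz) + np.linalg.norm(target["mask"].shape))
    for _ in range(60):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for t in range(max_t + 2):
            corner = tc - sz // 2 + np.round(direction * t).astype(int)
            if (corner < bounds_lo).any() or (corner + sz > bounds_hi).any():
                break
            sl = tuple(slice(c, c + s) for c, s in zip(corner, sz))
            if (occ[sl] & mask).any():
                continue
            if _try_place(occ, mask, corner, bounds_lo, bounds_hi, tgrid):
                return corner
            break  # clear of overlap but not touching: next direction
    return None


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate a bilateral phantom volume. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    Z, Y, X = spec.grid_shape
    margin = 2
    half_x = X // 2
    # left cells live in x < half_x - 1 so mirrored pairs never touch
    bounds_lo = np.array([margin, margin, margin])
    bounds_hi = np.array([Z - margin, Y - margin, half_x - margin])

    cell_labels = np.zeros(spec.grid_shape, dtype=np.int32)
    nucleus_labels = np.zeros(spec.grid_shape, dtype=np.int32)
    occ = np.zeros(spec.grid_shape, dtype=bool)

    catalog = list(spec.class_catalog)
    placed: list[dict] = []  # left-side cells: class_id, corner, mask

    for i in range(spec.n_cell_pairs):
        class_id = i % len(catalog)
        cls = catalog[class_id]
        radius = rng.uniform(*spec.cell_radius_range)
        mask = _solid_mask(cls.shape_class, radius, rng)
        sz = np.array(mask.shape)

        touch = rng.random() < spec.contact_fraction and len(placed) > 0
        success = False
        corner = None
        if touch:
            # same-class targets first, then any, in random order
            same = [p for p in placed if p["class_id"] == class_id]
            others = [p for p in placed if p["class_id"] != class_id]
            rng.shuffle(same)
            rng.shuffle(others)
            for target in same + others:
                corner = _touch_place(occ, mask, target, spec.grid_shape,
                                      bounds_lo, bounds_hi, rng)
                if corner is not None:
                    success = True
                    break
            if not success and spec.contact_fraction >= 1.0:
                raise PlacementError(
                    f"could not attach cell pair index {i} to any neighbour")
        if not success:
            for _ in range(400):
                corner = np.array([rng.integers(lo, max(lo + 1, hi - s))
                                   for lo, hi, s in zip(bounds_lo, bounds_hi, sz)])
                if _try_place(occ, mask, corner, bounds_lo, bounds_hi, None):
                    success = True
                    break
        if not success:
            raise PlacementError(
                f"could not place cell pair index {i} after bounded retries")

        sl = tuple(slice(c, c + s) for c, s in zip(corner, sz))
        occ[sl] |= mask
        placed.append(dict(class_id=class_id, corner=corner, mask=mask))

    # assign labels: left ids 1..P, right partner ids P+1..2P (mirror by flip)
    P = spec.n_cell_pairs
    for i, p in enumerate(placed):
        sl = tuple(slice(c, c + s) for c, s in zip(p["corner"], p["mask"].shape))
        cell_labels[sl][p["mask"]] = i + 1
        nuc = _nucleus_mask(p["mask"], rng)
        nucleus_labels[sl][nuc] = i + 1

    left_cells = cell_labels.copy()
    left_nuclei = nucleus_labels.copy()
    flip_c = np.flip(left_cells, axis=2)
    flip_n = np.flip(left_nuclei, axis=2)
    cell_labels[flip_c > 0] = flip_c[flip_c > 0] + P
    nucleus_labels[flip_n > 0] = flip_n[flip_n > 0] + P

    raw = _render_raw(spec, cell_labels, nucleus_labels, placed, rng)
    truth = _build_truth(spec, cell_labels, nucleus_labels, placed)
    return PhantomVolume(raw=raw, cell_labels=cell_labels,
                         nucleus_labels=nucleus_labels, truth=truth,
                         voxel_size_nm=spec.voxel_size_nm)


def _render_raw(spec, cell_labels, nucleus_labels, placed, rng):
    raw = rng.normal(_BACKGROUND_LEVEL, _BACKGROUND_SD, size=spec.grid_shape)
    catalog = list(spec.class_catalog)
    P = spec.n_cell_pairs
    for cid in range(1, 2 * P + 1):
        class_id = placed[(cid - 1) % P]["class_id"]
        cls = catalog[class_id]
        cyto = (cell_labels == cid) & (nucleus_labels != cid)
        nuc = nucleus_labels == cid
        tl = _TEXTURE_LEVELS[cls.texture_class]
        vals = rng.normal(tl["level"], tl["sd"], size=int(cyto.sum()))
        if cls.texture_class == "vesicular":
            # scatter bright 'vesicle' blobs through the cytoplasm
            blob = rng.random(vals.shape) < tl["blob_frac"]
            vals[blob] = rng.normal(tl["blob_value"], 8.0, size=int(blob.sum()))
        raw[cyto] = vals
        cl = _CHROMATIN_LEVELS[cls.chromatin_class]
        nvals = rng.normal(cl["level"], cl["sd"], size=int(nuc.sum()))
        if cls.chromatin_class == "granular":
            clump = rng.random(nvals.shape) < cl["clump_frac"]
            nvals[clump] = rng.normal(cl["clump_value"], 10.0, size=int(clump.sum()))
        raw[nuc] = nvals
    return np.clip(raw, 0, 255).astype(np.uint8)


def _build_truth(spec, cell_labels, nucleus_labels, placed):
    from .features import adjacency_pairs  # local import: avoids cycle at import time

    P = spec.n_cell_pairs
    catalog = list(spec.class_catalog)
    pairs = adjacency_pairs(cell_labels)
    neigh: dict[int, set[int]] = {cid: set() for cid in range(1, 2 * P + 1)}
    for a, b in pairs:
        neigh[a].add(b)
        neigh[b].add(a)

    coms = ndi.center_of_mass(cell_labels > 0, cell_labels,
                              index=list(range(1, 2 * P + 1)))
    rows = []
    for cid in range(1, 2 * P + 1):
        left = cid <= P
        class_id = placed[(cid - 1) % P]["class_id"]
        cls = catalog[class_id]
        rows.append(dict(
            cell_id=cid,
            class_id=class_id,
            shape_class=cls.shape_class,
            texture_class=cls.texture_class,
            chromatin_class=cls.chromatin_class,
            side="left" if left else "right",
            partner_id=cid + P if left else cid - P,
            centroid_z=coms[cid - 1][0],
            centroid_y=coms[cid - 1][1],
            centroid_x=coms[cid - 1][2],
            neighbour_ids=sorted(neigh[cid]),
        ))
    return pd.DataFrame(rows).set_index("cell_id")


# ---------------------------------------------------------------------------
# expression tables


def make_expression_table(truth: pd.DataFrame, markers_per_class: int = 3,
                          noise_sd: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Toy per-cell gene expression table in [0, 1].

    Each class gets ``markers_per_class`` exclusive marker genes valued 1.0 in
    its cells and 0 elsewhere, plus clipped Gaussian noise of sd ``noise_sd``.
    """
    if len(truth) == 0:
        raise ValueError("empty truth table")
    if markers_per_class < 1:
        raise ValueError("markers_per_class must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    class_ids = sorted(truth["class_id"].unique())
    cols = {}
    for cid in class_ids:
        member = (truth["class_id"] == cid).to_numpy(dtype=float)
        for k in range(markers_per_class):
            name = f"gene_c{cid}_m{k}"
            vals = member.copy()
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=len(vals))
            cols[name] = np.clip(vals, 0.0, 1.0)
    table = pd.DataFrame(cols, index=truth.index.copy())
    table.index.name = "cell_id"
    return table


def merge_labels(labels: np.ndarray, id_a: int, id_b: int) -> np.ndarray:
    """Segmentation-error corruption: merge label ``id_b`` into ``id_a``."""
    out = labels.copy()
    out[out == id_b] = id_a
    return out
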