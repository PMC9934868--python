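"""Extraction: crops, patches, meshes, point clouds."""

import numpy as np
import pytest

from cellmorph import extraction as ex
from cellmorph.phantom import PhantomSpec, generate_phantom
from cellmorph.volume import LabeledVolume


@pytest.fixture(scope="module")
def cfg():
    return ex.ExtractionConfig()


# ---------------------------------------------------------------------------
# coarse crops


def test_coarse_crop_reference_shapes(small_volume, cfg):
    c = ex.extract_coarse_crop(small_volume, 1, "cytoplasm", "train", cfg)
    assert c.values.shape == (144, 144, 144)
    n = ex.extract_coarse_crop(small_volume, 1, "nucleus", "train", cfg)
    assert n.values.shape == (104, 104, 104)
    cp = ex.extract_coarse_crop(small_volume, 1, "cytoplasm", "predict", cfg)
    assert cp.values.shape == (320, 320, 320)
    np_ = ex.extract_coarse_crop(small_volume, 1, "nucleus", "predict", cfg)
    assert np_.values.shape == (160, 160, 160)


def test_coarse_crop_masks_out_complement(small_volume, cfg):
    c = ex.extract_coarse_crop(small_volume, 1, "cytoplasm", "train", cfg)
    assert 0.0 <= c.values.min() and c.values.max() <= 1.0
    assert (c.values[~c.mask] == 0).all()
    # nucleus support and cytoplasm support are disjoint (same-size crops
    # share the nucleus-centred frame)
    eq = ex.ExtractionConfig(coarse_train_cyto=64, coarse_train_nuc=64)
    c64 = ex.extract_coarse_crop(small_volume, 1, "cytoplasm", "train", eq)
    n64 = ex.extract_coarse_crop(small_volume, 1, "nucleus", "train", eq)
    assert not (c64.mask & n64.mask).any()
    assert c64.mask.any() and n64.mask.any()


def test_coarse_crop_zero_volume_gives_zero_crop(small_volume, cfg):
    vol = LabeledVolume(raw=np.zeros_like(small_volume.raw),
                        cell_labels=small_volume.cell_labels,
                        nucleus_labels=small_volume.nucleus_labels,
                        voxel_size_nm=small_volume.voxel_size_nm)
    c = ex.extract_coarse_crop(vol, 1, "cytoplasm", "train", cfg)
    assert (c.values == 0).all()


def test_coarse_crop_missing_nucleus_raises(small_volume, cfg):
    with pytest.raises(ex.ExtractionError):
        ex.extract_coarse_crop(small_volume, 9999, "cytoplasm", "train", cfg)


def test_normalisation_idempotent():
    arr = np.random.default_rng(0).random((8, 8, 8)).astype(np.float32)
    assert np.array_equal(ex.normalize_intensity(arr), arr)
    ints = (arr * 255).astype(np.uint8)
    once = ex.normalize_intensity(ints)
    assert np.array_equal(ex.normalize_intensity(once), once)
    assert once.max() <= 1.0


# ---------------------------------------------------------------------------
# fine patches


def _cube_volume(mask_edge, offset=(0, 0, 0)):
    """A volume whose single cell is one axis-aligned cube of given edge."""
    shape = (48, 48, 48)
    cells = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    sl = tuple(slice(o, o + mask_edge) for o in offset)
    cells[sl] = 1
    raw = np.full(shape, 128, dtype=np.uint8)
    return LabeledVolume(raw=raw, cell_labels=cells, nucleus_labels=nuclei,
                         voxel_size_nm=(1, 1, 1))


def test_full_cube_yields_exactly_one_patch(cfg):
    vol = _cube_volume(32, offset=(4, 4, 4))
    ps = ex.extract_fine_patches(vol, 1, "cytoplasm", cfg)
    assert len(ps.patches) == 1
    assert ps.patches[0].shape == (32, 32, 32)
    assert ps.occupancy == [1.0]


def test_exactly_half_occupied_cube_is_excluded(cfg):
    # cell fills exactly half of the single 32^3 tile containing it
    shape = (48, 48, 48)
    cells = np.zeros(shape, dtype=np.int32)
    cells[4:36, 4:36, 4:20] = 1  # 32 x 32 x 16 = half of 32^3
    vol = LabeledVolume(raw=np.full(shape, 100, np.uint8), cell_labels=cells,
                        nucleus_labels=np.zeros(shape, np.int32),
                        voxel_size_nm=(1, 1, 1))
    ps = ex.extract_fine_patches(vol, 1, "cytoplasm", cfg)
    assert ps.patches == []  # 50% empty is not 'less than 50% empty'


def _brute_force_patch_count(comp, edge):
    idx = np.argwhere(comp)
    lo, hi = idx.min(0), idx.max(0) + 1
    count = 0
    import itertools
    nt = np.maximum(1, np.ceil((hi - lo) / edge).astype(int))
    for tz, ty, tx in itertools.product(*(range(n) for n in nt)):
        corner = lo + np.array([tz, ty, tx]) * edge
        total = 0
        for dz, dy, dx in itertools.product(range(edge), repeat=3):
            p = corner + (dz, dy, dx)
            if (p < comp.shape).all() and comp[tuple(p)]:
                total += 1
        if total / edge ** 3 > 0.5:
            count += 1
    return count


def test_patch_filter_matches_exhaustive_scan_on_phantom_cells():
    """Oracle equivalence: retained-patch count equals a voxel-by-voxel scan
    over the same cube grid for 20 random phantom cells."""
    cfg = ex.ExtractionConfig(patch_edge=4)
    checked = 0
    for seed in (0, 1):
        v = generate_phantom(PhantomSpec(n_cell_pairs=5, seed=seed))
        vol = LabeledVolume.from_phantom(v)
        for cid in list(vol.cell_ids)[:10]:
            ps = ex.extract_fine_patches(vol, int(cid), "cytoplasm", cfg)
            comp = (vol.cell_labels == cid) & (vol.nucleus_labels != cid)
            assert len(ps.patches) == _brute_force_patch_count(comp, 4)
            checked += 1
    assert checked >= 20


def test_fine_patches_empty_for_absent_compartment(small_volume, cfg):
    ps = ex.extract_fine_patches(small_volume, 9999, "cytoplasm", cfg)
    assert ps.patches == [] and ps.occupancy == []


# ---------------------------------------------------------------------------
# meshes


def _ball_labels(radius, pad=4):
    n = 2 * (radius + pad) + 1
    c = n // 2
    zz, yy, xx = np.indices((n, n, n))
    lab = np.zeros((n, n, n), dtype=np.int32)
    lab[(zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2] = 1
    return lab


def test_ball_mesh_watertight_genus_zero():
    mesh = ex.build_mesh(_ball_labels(10), 1, (1, 1, 1))
    tm = mesh.to_trimesh()
    assert tm.is_watertight
    assert tm.euler_number == 2


def test_ball_mesh_volume_matches_voxel_count():
    lab = _ball_labels(10)
    mesh = ex.build_mesh(lab, 1, (1, 1, 1))
    vol = mesh.to_trimesh().volume
    assert abs(vol - (lab == 1).sum()) / (lab == 1).sum() < 0.10


def test_mesh_volume_monotone_in_radius():
    vols = []
    for r in (6, 8, 10, 12):
        mesh = ex.build_mesh(_ball_labels(r), 1, (1, 1, 1))
        vols.append(mesh.to_trimesh().volume)
    assert all(b > a for a, b in zip(vols, vols[1:]))


def test_mesh_deterministic():
    a = ex.build_mesh(_ball_labels(8), 1, (1, 1, 1))
    b = ex.build_mesh(_ball_labels(8), 1, (1, 1, 1))
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.faces, b.faces)


def test_mesh_simplification_respects_face_budget():
    mesh = ex.build_mesh(_ball_labels(12), 1, (1, 1, 1), target_faces=400)
    assert len(mesh.faces) <= 400
    assert mesh.to_trimesh().is_watertight


def test_mesh_too_small_object_raises():
    lab = np.zeros((10, 10, 10), dtype=np.int32)
    lab[5, 5, 5] = 1
    with pytest.raises(ex.ExtractionError):
        ex.build_mesh(lab, 1, (1, 1, 1))
    with pytest.raises(ex.ExtractionError):
        ex.build_mesh(lab, 2, (1, 1, 1))  # absent object


def test_mesh_vertices_scaled_to_nm():
    iso = ex.build_mesh(_ball_labels(8), 1, (1.0, 1.0, 1.0))
    aniso = ex.build_mesh(_ball_labels(8), 1, (2.0, 1.0, 1.0))
    ez = aniso.vertices[:, 0].max() - aniso.vertices[:, 0].min()
    ez0 = iso.vertices[:, 0].max() - iso.vertices[:, 0].min()
    assert ez == pytest.approx(2 * ez0, rel=0.05)


# ---------------------------------------------------------------------------
# point clouds


def test_point_cloud_counts_and_unit_normals():
    mesh = ex.build_mesh(_ball_labels(8), 1, (1, 1, 1))
    pc = ex.sample_point_cloud(mesh, 1024, seed=3)
    assert pc.points.shape == (1024, 3)
    assert pc.normals.shape == (1024, 3)
    assert np.abs(np.linalg.norm(pc.normals, axis=1) - 1).max() < 1e-6


def _point_triangle_distance(p, tri):
    """Exact distance from one point to one triangle (brute force)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    n = np.cross(ab, ac)
    n_norm = np.linalg.norm(n)
    # barycentric of the projection
    d00, d01, d11 = ab @ ab, ab @ ac, ac @ ac
    d20, d21 = ap @ ab, ap @ ac
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    if v >= 0 and w >= 0 and v + w <= 1:
        return abs(ap @ (n / n_norm))
    # otherwise distance to the nearest edge
    best = np.inf
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        t = np.clip(((p - e0) @ d) / (d @ d), 0, 1)
        best = min(best, np.linalg.norm(p - (e0 + t * d)))
    return best


def test_point_cloud_samples_lie_on_surface():
    mesh = ex.build_mesh(_ball_labels(6), 1, (1, 1, 1), target_faces=400)
    tm = mesh.to_trimesh()
    pc = ex.sample_point_cloud(mesh, 60, seed=1)
    tris = tm.triangles
    diag = np.linalg.norm(tm.bounds[1] - tm.bounds[0])
    for p in pc.points:
        d = min(_point_triangle_distance(p, t) for t in tris)
        assert d < 1e-6 * diag


def test_point_cloud_deterministic():
    mesh = ex.build_mesh(_ball_labels(8), 1, (1, 1, 1))
    a = ex.sample_point_cloud(mesh, 256, seed=5)
    b = ex.sample_point_cloud(mesh, 256, seed=5)
    assert np.array_equal(a.points, b.points)
    assert np.array_equal(a.normals, b.normals)


def test_point_cloud_area_proportional_sampling():
    """Two-triangle mesh, area ratio 3:1 -> sample share within binomial CI."""
    verts = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0],   # area 3
                      [10, 0, 0], [11, 0, 0], [10, 2, 0]])  # area 1
    faces = np.array([[0, 1, 2], [3, 4, 5]])
    mesh = ex.SurfaceMesh(vertices=verts.astype(float), faces=faces,
                          object_id=1)
    import trimesh
    pts, fidx = trimesh.sample.sample_surface(mesh.to_trimesh(), 10000, seed=0)
    share = (fidx == 0).mean()
    p = 0.75
    ci = 2.58 * np.sqrt(p * (1 - p) / 10000)  # 99% CI
    assert abs(share - p) < ci
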