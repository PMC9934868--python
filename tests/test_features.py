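"""Descriptor assembly, region adjacency graph, context features."""

import numpy as np
import pandas as pd
import pytest

from cellmorph.features import (COMPONENTS, RegionAdjacencyGraph,
                                adjacency_pairs, build_rag, context_features,
                                embed_all, feature_columns,
                                standardize_features)
from cellmorph.phantom import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# region adjacency graph


def _two_cubes(gap):
    lab = np.zeros((12, 12, 12), np.int32)
    lab[2:6, 2:6, 2:6] = 1
    lab[2:6, 2:6, 6 + gap:10 + gap if 10 + gap <= 12 else 12] = 2
    return lab


def test_touching_cubes_give_one_edge():
    rag = build_rag(_two_cubes(0))
    assert rag.nodes == [1, 2]
    assert rag.edges == [(1, 2)]
    assert rag.contact_area[(1, 2)] == 16


def test_separated_cubes_give_no_edge():
    rag = build_rag(_two_cubes(1))
    assert rag.nodes == [1, 2]
    assert rag.edges == []


def _brute_force_edges(labels):
    edges = set()
    Z, Y, X = labels.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                a = labels[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if z2 < Z and y2 < Y and x2 < X:
                        b = labels[z2, y2, x2]
                        if b != 0 and b != a:
                            edges.add((min(a, b), max(a, b)))
    return sorted(edges)


@pytest.mark.parametrize("seed", range(10))
def test_rag_matches_exhaustive_scan_on_phantoms(seed):
    """Oracle equivalence: RAG edges equal a 6-neighbour voxel scan."""
    v = generate_phantom(PhantomSpec(n_cell_pairs=3, seed=seed,
                                     grid_shape=(48, 48, 64),
                                     contact_fraction=0.7))
    sub = v.cell_labels[::1, ::1, ::1]
    rag = build_rag(sub)
    assert rag.edges == _brute_force_edges(sub)
    assert adjacency_pairs(sub) == rag.edges


# ---------------------------------------------------------------------------
# context features


def _feature_table(rows):
    return pd.DataFrame(rows).T if isinstance(rows, dict) else rows


def test_isolated_node_context_equals_own_features():
    table = pd.DataFrame(np.arange(6, dtype=float).reshape(2, 3),
                         index=[1, 2], columns=["a", "b", "c"])
    rag = RegionAdjacencyGraph(nodes=[1, 2], edges=[])
    ctx = context_features(table, rag)
    assert ctx.shape == (2, 6)
    assert np.allclose(ctx[["ctx_a", "ctx_b", "ctx_c"]].values,
                       table.values)


def test_uniform_neighbourhood_context_is_that_vector():
    v = np.array([1.0, 2.0])
    table = pd.DataFrame([v, v, v], index=[1, 2, 3], columns=["a", "b"])
    rag = RegionAdjacencyGraph(nodes=[1, 2, 3], edges=[(1, 2), (2, 3)])
    ctx = context_features(table, rag)
    assert np.allclose(ctx[["ctx_a", "ctx_b"]].values, np.tile(v, (3, 1)))


def test_context_matches_naive_loop_and_scales_linearly(rng):
    n = 12
    table = pd.DataFrame(rng.normal(size=(n, 5)), index=range(1, n + 1))
    table.columns = [f"f{i}" for i in range(5)]
    edges = [(i, i + 1) for i in range(1, n)] + [(1, 5), (3, 9)]
    rag = RegionAdjacencyGraph(nodes=list(range(1, n + 1)), edges=edges)
    ctx = context_features(table, rag)
    neigh = {i: [] for i in range(1, n + 1)}
    for a, b in edges:
        neigh[a].append(b)
        neigh[b].append(a)
    for cid in table.index:
        members = [cid] + neigh[cid]
        ref = table.loc[members].mean(axis=0).to_numpy()
        assert np.allclose(ctx.loc[cid].to_numpy()[5:], ref)
    # linearity in the feature rows
    ctx2 = context_features(table * 3.0, rag)
    assert np.allclose(ctx2.to_numpy(), 3.0 * ctx.to_numpy())


def test_context_missing_neighbour_row_raises():
    table = pd.DataFrame(np.zeros((1, 2)), index=[1], columns=["a", "b"])
    rag = RegionAdjacencyGraph(nodes=[1], edges=[(1, 2)])
    with pytest.raises(KeyError):
        context_features(table, rag)


# ---------------------------------------------------------------------------
# standardisation


def test_standardize_two_point_column():
    t = pd.DataFrame({"a": [1.0, 3.0]})
    z, _ = standardize_features(t)
    assert np.allclose(z["a"].to_numpy(), [-1.0, 1.0])


def test_standardize_constant_column_maps_to_zero():
    t = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [0.0, 1.0, 2.0]})
    z, _ = standardize_features(t)
    assert (z["a"] == 0).all()
    assert z["b"].std(ddof=0) == pytest.approx(1.0)


def test_standardize_transform_reusable():
    t = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                     columns=["a", "b", "c"])
    z, tf = standardize_features(t)
    assert np.allclose(tf.apply(t).to_numpy(), z.to_numpy())


def test_standardize_single_row_rejected():
    with pytest.raises(ValueError):
        standardize_features(pd.DataFrame({"a": [1.0]}))


# ---------------------------------------------------------------------------
# descriptor assembly


@pytest.fixture(scope="module")
def embedded_small():
    from cellmorph.pipeline import DeskScaleConfig, _component_encoders
    from cellmorph.volume import LabeledVolume

    cfg = DeskScaleConfig()
    phantom = generate_phantom(PhantomSpec(n_cell_pairs=3, seed=4))
    vol = LabeledVolume.from_phantom(phantom)
    encs = _component_encoders(cfg, seed=9)
    feats, excl = embed_all(vol, encs, cfg.extraction, seed=0)
    return feats, excl


def test_descriptor_rows_have_480_named_dims(embedded_small):
    feats, excl = embedded_small
    assert feats.shape[1] == 480
    assert list(feats.columns) == feature_columns()
    assert np.isfinite(feats.to_numpy()).all()
    assert len(feats) + len(excl) == 6


def test_descriptor_layout_order_fixed():
    cols = feature_columns()
    assert cols[0] == "cell_shape_00"
    assert cols[80] == "cell_coarse_00"
    assert cols[-1] == "nuc_fine_79"
    assert [c for c in COMPONENTS] == ["cell_shape", "cell_coarse",
                                       "cell_fine", "nuc_shape", "nuc_coarse",
                                       "nuc_fine"]


def test_missing_checkpoint_rejected(small_volume):
    with pytest.raises(KeyError):
        embed_all(small_volume, {"cell_shape": None}, None, seed=0)


def test_fine_component_is_mean_of_patch_embeddings(small_volume):
    """A cell's fine component equals the average of its per-patch
    embeddings (and is order-independent)."""
    from cellmorph import extraction as ex
    from cellmorph.encoders import TextureEncoder, TextureEncoderConfig

    cfg = ex.ExtractionConfig(patch_edge=4)
    enc = TextureEncoder(TextureEncoderConfig(base_channels=2, n_blocks=2),
                         seed=0)
    ps = ex.extract_fine_patches(small_volume, 1, "nucleus", cfg)
    assert len(ps.patches) >= 1
    embs = [enc.encode(p, m)[0] for p, m in zip(ps.patches, ps.masks)]
    mean1 = np.mean(embs, axis=0)
    order = np.random.default_rng(0).permutation(len(embs))
    mean2 = np.mean([embs[i] for i in order], axis=0)
    assert np.allclose(mean1, mean2)
    if len(embs) == 1:
        assert np.allclose(mean1, embs[0])
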