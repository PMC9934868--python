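"""Evaluation protocols: classification, bilateral ranking, clustering,
specificity, representative/extreme selection."""

import numpy as np
import pandas as pd
import pytest

from cellmorph.analysis import (_specificity_c, bilateral_distance,
                                classify_morphotypes, cluster_cells,
                                feature_extremes, feature_specificity,
                                gene_specificity, reflection_candidates,
                                representative_cell, select_dotplot_genes,
                                subcluster)


# ---------------------------------------------------------------------------
# classification


def _blobs(n_per=20, n_classes=4, sep=10.0, dim=8, seed=0):
    r = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        centre = np.zeros(dim)
        centre[c % dim] = sep * (1 + c)
        X.append(r.normal(size=(n_per, dim)) + centre)
        y += [c] * n_per
    X = np.concatenate(X)
    idx = pd.RangeIndex(len(X))
    return pd.DataFrame(X, index=idx), pd.Series(y, index=idx)


def test_separable_classes_classified_perfectly():
    X, y = _blobs()
    accs, conf = classify_morphotypes(X, y, seed=0)
    assert np.mean(accs) == 1.0
    assert np.trace(conf.to_numpy()) == len(X)


def test_confusion_matrix_rows_are_labels():
    X, y = _blobs(n_per=10, n_classes=3)
    _, conf = classify_morphotypes(X, y, seed=1)
    assert conf.to_numpy().sum(axis=1).tolist() == [10, 10, 10]


def test_shuffled_labels_give_chance_accuracy():
    X, y = _blobs(n_per=30, n_classes=4)
    r = np.random.default_rng(7)
    y_shuffled = pd.Series(r.permutation(y.to_numpy()), index=y.index)
    accs, _ = classify_morphotypes(X, y_shuffled, seed=0)
    n = len(X)
    p = 0.25
    ci = 3.29 * np.sqrt(p * (1 - p) / n)  # ~99.9% binomial CI
    assert abs(np.mean(accs) - p) < ci


def test_small_class_rejected_with_name():
    X, y = _blobs(n_per=10, n_classes=2)
    y.iloc[:7] = 2  # class 2 has 7, class 0 only 3
    with pytest.raises(ValueError, match="0"):
        classify_morphotypes(X, y, seed=0)


def test_feature_agglomeration_applied_above_100_columns():
    r = np.random.default_rng(0)
    X = pd.DataFrame(r.normal(size=(60, 150)))
    X.iloc[:30, :] += 6.0  # class signal in every (merged) feature
    y = pd.Series([0] * 30 + [1] * 30)
    accs, _ = classify_morphotypes(X, y, seed=0)
    assert np.mean(accs) == 1.0


# ---------------------------------------------------------------------------
# bilateral ranking


def test_identical_partner_ranks_first(rng):
    X = rng.normal(size=(10, 6)) * 10
    X[5] = X[0]  # exact duplicate
    feats = pd.DataFrame(X, index=range(10))
    br = bilateral_distance(feats, {0: [5, 6, 7]})
    assert br.per_cell["rank"].tolist() == [1]
    assert br.median_rank == 1.0


def _brute_force_rank(X, ids, c, cand):
    import math
    i = ids.index(c)
    d = {o: math.dist(X[i], X[ids.index(o)]) for o in ids if o != c}
    chosen = min(cand, key=lambda p: (d[p], p))
    order = sorted((dist, o) for o, dist in d.items())
    return chosen, 1 + order.index((d[chosen], chosen))


def test_bilateral_matches_quadratic_oracle():
    """20 random trials at n=50: summary equals a naive sort-and-rank."""
    r = np.random.default_rng(42)
    for _ in range(20):
        X = r.normal(size=(50, 5))
        ids = list(range(50))
        feats = pd.DataFrame(X, index=ids)
        cands = {c: list(r.choice([o for o in ids if o != c],
                                  size=r.integers(1, 8), replace=False))
                 for c in r.choice(ids, size=20, replace=False)}
        br = bilateral_distance(feats, {int(k): [int(x) for x in v]
                                        for k, v in cands.items()})
        ranks = []
        for c, cand in cands.items():
            chosen, rank = _brute_force_rank(X, ids, int(c),
                                             [int(x) for x in cand])
            row = br.per_cell[br.per_cell.cell_id == c].iloc[0]
            assert row["chosen_partner"] == chosen
            assert row["rank"] == rank
            ranks.append(rank)
        assert br.median_rank == float(np.median(ranks))


def test_cell_without_candidates_excluded_from_median(rng):
    feats = pd.DataFrame(rng.normal(size=(6, 3)), index=range(6))
    feats.iloc[3] = feats.iloc[1]
    br = bilateral_distance(feats, {0: [], 1: [3]})
    assert br.excluded == [0]
    assert br.median_rank == 1.0


def test_bilateral_invariant_under_rigid_feature_motion(rng):
    X = rng.normal(size=(30, 4))
    ids = list(range(30))
    cands = {c: [int(x) for x in rng.choice([o for o in ids if o != c], 5,
                                            replace=False)] for c in ids[:10]}
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    moved = X @ q + np.array([5.0, -3.0, 2.0, 1.0])
    a = bilateral_distance(pd.DataFrame(X, index=ids), cands)
    b = bilateral_distance(pd.DataFrame(moved, index=ids), cands)
    assert a.per_cell["rank"].tolist() == b.per_cell["rank"].tolist()


def test_reflection_candidates_find_true_partner(small_phantom):
    X = small_phantom.cell_labels.shape[2]
    cands = reflection_candidates(small_phantom.truth, X, n_candidates=3)
    for cid, lst in cands.items():
        assert small_phantom.truth.loc[cid, "partner_id"] in lst


def test_missing_candidate_row_raises(rng):
    feats = pd.DataFrame(rng.normal(size=(4, 2)), index=range(4))
    with pytest.raises(KeyError):
        bilateral_distance(feats, {0: [99]})


# ---------------------------------------------------------------------------
# clustering


@pytest.fixture(scope="module")
def blob_features():
    r = np.random.default_rng(3)
    X = np.concatenate([r.normal(0, 1, size=(60, 10)),
                        r.normal(12, 1, size=(60, 10))])
    return pd.DataFrame(X, index=range(120)), np.array([0] * 60 + [1] * 60)


def test_resolution_sweep_recovers_two_blobs(blob_features):
    feats, truth = blob_features
    found = False
    for gamma in (0.001, 0.004, 0.01, 0.05):
        a = cluster_cells(feats, n_neighbours=20, resolution=gamma, seed=1)
        if a.n_clusters == 2:
            lab = a.labels.to_numpy()
            agree = max((lab == truth).mean(), (lab == 1 - truth).mean())
            if agree >= 0.99:
                found = True
                break
    assert found


def test_clustering_deterministic(blob_features):
    feats, _ = blob_features
    a = cluster_cells(feats, 20, 0.01, seed=5)
    b = cluster_cells(feats, 20, 0.01, seed=5)
    assert (a.labels == b.labels).all()


def test_cluster_count_nondecreasing_in_resolution(blob_features):
    feats, _ = blob_features
    counts = [cluster_cells(feats, 20, g, seed=2).n_clusters
              for g in (0.004, 0.1, 0.5)]
    assert counts[0] <= counts[1] <= counts[2]


def test_too_few_rows_rejected(rng):
    feats = pd.DataFrame(rng.normal(size=(10, 4)))
    with pytest.raises(ValueError):
        cluster_cells(feats, n_neighbours=20, resolution=0.01, seed=0)


def test_subcluster_splits_one_cluster(blob_features):
    feats, truth = blob_features
    a = cluster_cells(feats, 20, 0.01, seed=1)
    big = a.labels.value_counts().idxmax()
    sub = subcluster(feats, a, int(big), resolution=1.0, seed=1)
    assert set(sub.labels.index) == set(a.members(int(big)))


# ---------------------------------------------------------------------------
# specificity


def test_exclusive_marker_gene_specificity():
    expr = pd.DataFrame({"g": [1.0, 1.0, 0.0, 0.0]}, index=range(4))
    cl = pd.Series([0, 0, 1, 1], index=range(4))
    rec = gene_specificity(expr, cl)
    row = rec[(rec.cluster == 0)].iloc[0]
    assert (row.A, row.B, row.C) == (1.0, 1.0, 1.0)


def test_specificity_c_formula_values():
    assert _specificity_c(0.5, 0.5) == 0.5          # C = A when A = B
    assert _specificity_c(0.2, 0.8) == pytest.approx(0.32)
    assert _specificity_c(0.0, 0.0) == 0.0          # convention at 0/0


def test_gene_specificity_bounds_with_unit_expression(rng):
    expr = pd.DataFrame(rng.random((20, 5)), index=range(20),
                        columns=list("abcde"))
    cl = pd.Series(rng.integers(0, 3, 20), index=range(20))
    rec = gene_specificity(expr, cl)
    assert ((rec.C >= 0) & (rec.C <= 1)).all()
    near = rec[np.isclose(rec.A, rec.B)]
    assert np.allclose(near.C, near.A)


def test_negative_expression_rejected():
    expr = pd.DataFrame({"g": [-0.1, 0.5]}, index=[0, 1])
    with pytest.raises(ValueError):
        gene_specificity(expr, pd.Series([0, 1], index=[0, 1]))


def test_feature_specificity_cluster_size_normalisation():
    """Hand-evaluated oracle: a binary feature marking a cluster of relative
    size s gives A=1, B=1/s, C=2/(1+s)."""
    for n, k in ((10, 3), (20, 5)):
        vals = [3.0] * k + [-3.0] * (n - k)  # clips to +-2, scales to 1/0
        feats = pd.DataFrame({"f": vals}, index=range(n))
        cl = pd.Series([0] * k + [1] * (n - k), index=range(n))
        rec = feature_specificity(feats, cl)
        row = rec[rec.cluster == 0].iloc[0]
        s = k / n
        assert row.A == pytest.approx(1.0)
        assert row.B == pytest.approx(1.0 / s)
        assert row.C == pytest.approx(2.0 / (1.0 + s))


def test_feature_specificity_constant_feature_uniform():
    feats = pd.DataFrame({"f": [1.0] * 9}, index=range(9))
    cl = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2], index=range(9))
    rec = feature_specificity(feats, cl)
    assert np.allclose(rec.B, 1.0)  # size-normalised share is 1 everywhere
    assert rec.C.nunique() == 1


def test_feature_specificity_clipping():
    # a value of 5 in a standardised table contributes as 2 (the clip bound)
    feats = pd.DataFrame({"f": [5.0, 2.0, -2.0, -5.0]}, index=range(4))
    cl = pd.Series([0, 0, 1, 1], index=range(4))
    rec = feature_specificity(feats, cl)
    row = rec[rec.cluster == 0].iloc[0]
    assert row.A == pytest.approx(1.0)  # both cluster-0 values clip/scale to 1


def test_dotplot_gene_selection_threshold():
    rec = pd.DataFrame([
        dict(cluster=0, variable="g1", A=1, B=1, C=0.5),
        dict(cluster=1, variable="g1", A=1, B=1, C=0.45),
        dict(cluster=0, variable="g2", A=1, B=1, C=0.05),
        dict(cluster=1, variable="g2", A=1, B=1, C=0.1),
    ])
    assert select_dotplot_genes(rec) == ["g1"]
    # two-cluster pairwise filter: both above threshold, difference < 0.4
    assert select_dotplot_genes(rec, pair_delta=0.4) == []


# ---------------------------------------------------------------------------
# representatives and extremes


def test_representative_cell_examples(rng):
    feats = pd.DataFrame({"a": [0.0, 1.0, 2.0, 10.0]}, index=[1, 2, 3, 4])
    assert representative_cell(feats, [3]) == 3            # singleton
    same = pd.DataFrame(np.ones((3, 2)), index=[7, 5, 6])
    assert representative_cell(same, [7, 5, 6]) == 5       # tie -> smaller id
    # brute-force oracle
    X = rng.normal(size=(15, 4))
    feats = pd.DataFrame(X, index=range(15))
    members = list(range(15))
    med = np.median(X, axis=0)
    d = np.linalg.norm(X - med, axis=1)
    assert representative_cell(feats, members) == int(np.argmin(d))


def test_feature_extremes_examples_and_oracle(rng):
    feats = pd.DataFrame({"a": [3.0, 1.0, 2.0]}, index=[10, 11, 12])
    lo, hi = feature_extremes(feats, "a", 1)
    assert (lo, hi) == ([11], [10])
    lo, hi = feature_extremes(feats, "a", 3)
    assert sorted(lo) == sorted(hi) == [10, 11, 12]
    # sort oracle on a random column
    vals = rng.normal(size=20)
    feats = pd.DataFrame({"v": vals}, index=range(20))
    lo, hi = feature_extremes(feats, "v", 5)
    order = np.argsort(vals, kind="stable")
    assert lo == [int(i) for i in order[:5]]
    assert hi == [int(i) for i in order[::-1][:5]]


def test_feature_extremes_respects_exclusions_and_validates():
    feats = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=[1, 2, 3])
    lo, hi = feature_extremes(feats, "a", 1, exclude=[1])
    assert (lo, hi) == ([2], [3])
    with pytest.raises(KeyError):
        feature_extremes(feats, "zzz", 1)
    with pytest.raises(ValueError):
        feature_extremes(feats, "a", 4)
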