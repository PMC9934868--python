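"""Evaluation and exploration statistics on descriptor tables.

This module houses the quantitative protocols used to judge and explore the
learned descriptors:

* **Morphotype classification** — stratified 5-fold cross-validated
  multinomial logistic regression (C = 1, lbfgs) on standardised features,
  with feature agglomeration to 100 merged columns when the table is wider,
  reporting fold accuracies and a summed confusion matrix (rows = labels,
  columns = predictions).
* **Bilateral partner ranking** — for each cell, the nearest of its candidate
  mirror-partners in feature space is ranked against all other cells by
  Euclidean distance (rank 1 = nearest); the summary is the median rank over
  cells.  Low medians mean the features co-locate mirror-image cells.
* **Clustering** — the UMAP fuzzy k-NN graph (the graph, not the layout)
  partitioned by Leiden with the constant Potts model (CPM) objective at a
  resolution parameter gamma; subclustering re-runs on one cluster's rows.
* **Specificity statistics** — per (cluster, variable): A = mean value in the
  cluster, B = in-cluster share of the total (for features additionally
  normalised by relative cluster size), C = 2AB/(A+B), the harmonic mean.
* **Representative / extreme cells** for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# morphotype classification


def classify_morphotypes(features: pd.DataFrame, labels: pd.Series, seed: int = 0,
                         n_folds: int = 5, agglomerate_above: int = 100):
    """Stratified k-fold logistic-regression evaluation of a feature table.

    Returns ``(fold_accuracies, confusion)`` where the confusion matrix sums
    over folds, rows are true labels and columns predictions.
    """
    from sklearn.cluster import FeatureAgglomeration
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler

    labels = labels.loc[features.index]
    counts = labels.value_counts()
    small = counts[counts < n_folds]
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if len(small):
        raise ValueError(
            f"class(es) with fewer than {n_folds} members: "
            f"{sorted(small.index.tolist())}")

    x = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    if x.shape[1] > agglomerate_above:
        x = FeatureAgglomeration(n_clusters=agglomerate_above).fit_transform(x)
    y = labels.to_numpy()
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for tr, te in skf.split(x, y):
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        accs.append(float((pred == y[te]).mean()))
        conf += confusion_matrix(y[te], pred, labels=classes)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    return accs, confusion


# ---------------------------------------------------------------------------
# bilateral partner ranking


@dataclass
class BilateralRanking:
    per_cell: pd.DataFrame      # cell_id, chosen_partner, rank
    median_rank: float
    excluded: list = field(default_factory=list)  # cells without candidates


def bilateral_distance(features: pd.DataFrame,
                       candidates: dict[int, list[int]]) -> BilateralRanking:
    """Rank each cell's nearest candidate partner among all other cells.

    Distances are Euclidean in feature space; rank 1 is the nearest other
    cell.  Distance ties break toward the smaller cell id.  Cells with an
    empty candidate list are excluded from the median and reported.
    """
    if not candidates:
        raise ValueError("candidate map is empty")
    ids = features.index.to_numpy()
    pos = {int(c): i for i, c in enumerate(ids)}
    X = features.to_numpy(dtype=float)
    rows, excluded = [], []
    for c, cand in candidates.items():
        if c not in pos:
            raise KeyError(f"cell {c} missing from feature table")
        if len(cand) == 0:
            excluded.append(c)
            continue
        missing = [p for p in cand if p not in pos]
        if missing:
            raise KeyError(f"candidate(s) {missing} of cell {c} missing from "
                           "feature table")
        i = pos[c]
        d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        # choose nearest candidate, ties toward smaller id
        cand_keys = sorted((d[pos[p]], p) for p in cand)
        chosen_d, chosen = cand_keys[0]
        # rank among all other cells under the same (distance, id) order
        others = [(d[pos[o]], int(o)) for o in ids if o != c]
        rank = 1 + sum(1 for k in others if k < (chosen_d, chosen))
        rows.append(dict(cell_id=int(c), chosen_partner=int(chosen), rank=rank))
    per_cell = pd.DataFrame(rows, columns=["cell_id", "chosen_partner", "rank"])
    median = float(np.median(per_cell["rank"])) if len(per_cell) else float("nan")
    return BilateralRanking(per_cell=per_cell, median_rank=median,
                            excluded=excluded)


def reflection_candidates(truth: pd.DataFrame, x_extent: int,
                          n_candidates: int = 10) -> dict[int, list[int]]:
    """Candidate mirror partners by centroid reflection.

    Each cell's centroid is reflected across the mediolateral mid-plane
    (x -> X-1-x) and the ``n_candidates`` nearest opposite-side cells by
    physical distance are returned.
    """
    cents = truth[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(float)
    sides = truth["side"].to_numpy()
    ids = truth.index.to_numpy()
    out: dict[int, list[int]] = {}
    for i, c in enumerate(ids):
        refl = cents[i].copy()
        refl[2] = (x_extent - 1) - refl[2]
        opp = np.where(sides != sides[i])[0]
        d = np.sqrt(((cents[opp] - refl) ** 2).sum(axis=1))
        order = opp[np.argsort(d, kind="stable")][:n_candidates]
        out[int(c)] = [int(ids[j]) for j in order]
    return out


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterAssignment:
    labels: pd.Series                # cell id -> cluster label (0-based ints)
    params: dict

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster: int) -> list[int]:
        return self.labels.index[self.labels == cluster].tolist()


def knn_graph(features: pd.DataFrame, n_neighbours: int = 20, seed: int = 0):
    """Weighted k-NN graph via the UMAP fuzzy simplicial-set construction."""
    import igraph as ig
    from umap.umap_ import fuzzy_simplicial_set

    X = features.to_numpy(dtype=float)
    if len(X) < n_neighbours + 1:
        raise ValueError(
            f"need more than n_neighbours={n_neighbours} rows, got {len(X)}")
    graph, _, _ = fuzzy_simplicial_set(
        X, n_neighbors=n_neighbours,
        random_state=np.random.RandomState(seed), metric="euclidean")
    coo = graph.tocoo()
    mask = coo.row < coo.col
    edges = list(zip(coo.row[mask].tolist(), coo.col[mask].tolist()))
    weights = coo.data[mask].tolist()
    g = ig.Graph(n=len(X), edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(features: pd.DataFrame, n_neighbours: int = 20,
                  resolution: float = 0.004, seed: int = 0) -> ClusterAssignment:
    """Leiden/CPM partition of the fuzzy k-NN graph; deterministic by seed.

    ``features`` should already be standardised.
    """
    import leidenalg

    g = knn_graph(features, n_neighbours=n_neighbours, seed=seed)
    part = leidenalg.find_partition(
        g, leidenalg.CPMVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    labels = pd.Series(part.membership, index=features.index, name="cluster")
    return ClusterAssignment(labels=labels,
                             params=dict(n_neighbours=n_neighbours,
                                         metric="euclidean",
                                         resolution=resolution, seed=seed))


def subcluster(features: pd.DataFrame, assignment: ClusterAssignment,
               cluster: int, resolution: float, n_neighbours: int | None = None,
               seed: int = 0) -> ClusterAssignment:
    """Re-cluster the rows of one cluster at a finer resolution."""
    members = assignment.members(cluster)
    if not members:
        raise ValueError(f"cluster {cluster} has no members")
    nn = n_neighbours or assignment.params.get("n_neighbours", 20)
    nn = min(nn, len(members) - 1)
    return cluster_cells(features.loc[members], n_neighbours=nn,
                         resolution=resolution, seed=seed)


# ---------------------------------------------------------------------------
# specificity statistics


def _specificity_c(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def gene_specificity(expression: pd.DataFrame, clusters: pd.Series,
                     scope_cells=None) -> pd.DataFrame:
    """Per (cluster, gene): A = mean in-cluster expression, B = in-cluster
    share of total expression within the scope, C = 2AB/(A+B)."""
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    scope = expression.index if scope_cells is None else pd.Index(scope_cells)
    expr = expression.loc[scope]
    clusters = clusters.loc[scope]
    totals = expr.sum(axis=0)
    rows = []
    for cl in sorted(clusters.unique()):
        sub = expr.loc[clusters == cl]
        a = sub.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            b = sub.sum(axis=0) / totals
        b = b.fillna(0.0)
        for gene in expr.columns:
            ai, bi = float(a[gene]), float(b[gene])
            rows.append(dict(cluster=cl, variable=gene, A=ai, B=bi,
                             C=_specificity_c(ai, bi)))
    return pd.DataFrame(rows)


def select_dotplot_genes(records: pd.DataFrame, c_threshold: float = 0.15,
                         pair_delta: float | None = None) -> list[str]:
    """Genes with C above threshold in some cluster; with ``pair_delta`` (two-
    cluster plots) genes specific in both clusters but differing by less than
    ``pair_delta`` are dropped."""
    keep = records.groupby("variable")["C"].max()
    genes = set(keep[keep > c_threshold].index)
    if pair_delta is not None:
        piv = records.pivot(index="variable", columns="cluster", values="C")
        if piv.shape[1] == 2:
            both = (piv > c_threshold).all(axis=1)
            close = (piv.iloc[:, 0] - piv.iloc[:, 1]).abs() < pair_delta
            genes -= set(piv.index[both & close])
    return sorted(genes)


def feature_specificity(features: pd.DataFrame, clusters: pd.Series,
                        clip: float = 2.0) -> pd.DataFrame:
    """Specificity of standardised features per cluster.

    Values are clipped to [-clip, +clip] and affinely rescaled to [0, 1];
    B is additionally divided by the relative cluster size so small clusters
    are not penalised.  Selection threshold for dot plots is C > 1.
    """
    clusters = clusters.loc[features.index]
    sizes = clusters.value_counts()
    if (sizes == 0).any():
        raise ValueError("empty cluster")
    x = features.to_numpy(dtype=float).clip(-clip, clip)
    x01 = (x + clip) / (2.0 * clip)  # fixed affine [-clip, clip] -> [0, 1]
    scaled = pd.DataFrame(x01, index=features.index, columns=features.columns)
    totals = scaled.sum(axis=0)
    n = len(scaled)
    rows = []
    for cl in sorted(clusters.unique()):
        sub = scaled.loc[clusters == cl]
        rel_size = len(sub) / n
        a = sub.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            b = (sub.sum(axis=0) / totals) / rel_size
        b = b.fillna(0.0)
        for feat in scaled.columns:
            ai, bi = float(a[feat]), float(b[feat])
            rows.append(dict(cluster=cl, variable=feat, A=ai, B=bi,
                             C=_specificity_c(ai, bi)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# representative and extreme cells


def representative_cell(features: pd.DataFrame, members: list) -> int:
    """The member whose feature vector is nearest the coordinate-wise median
    of the cluster (the 'average cell'); ties break to the smaller id."""
    if len(members) == 0:
        raise ValueError("cluster is empty")
    sub = features.loc[members]
    med = sub.median(axis=0).to_numpy()
    d = np.sqrt(((sub.to_numpy(float) - med) ** 2).sum(axis=1))
    order = sorted(zip(d, [int(m) for m in members]))
    return order[0][1]


def feature_extremes(features: pd.DataFrame, feature, k: int,
                     exclude: list | None = None):
    """(k lowest, k highest) cell ids for one feature column.

    Lists are sorted by value (ascending / descending); value ties break to
    the smaller id.  ``exclude`` removes cells (e.g. known merge errors).
    """
    if feature not in features.columns:
        raise KeyError(f"unknown feature {feature!r}")
    col = features[feature]
    if exclude:
        col = col.drop(index=exclude, errors="ignore")
    if not (1 <= k <= len(col)):
        raise ValueError(f"k must be in [1, {len(col)}]")
    vals = col.to_numpy(float)
    ids = [int(i) for i in col.index]
    lowest = [i for _, i in sorted(zip(vals, ids))[:k]]
    highest = [i for _, i in sorted(zip(-vals, ids))[:k]]
    return lowest, highest
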