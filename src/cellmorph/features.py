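"""Per-cell morphology descriptors and neighbourhood context features.

The per-cell descriptor is a 480-dimensional vector: six 80-dimensional
components in the fixed order ``cell_shape, cell_coarse, cell_fine,
nuc_shape, nuc_coarse, nuc_fine`` (cell triplet first, then nucleus triplet).
Context features append the mean descriptor of a cell's contact neighbourhood
(including the cell itself) on the region adjacency graph, giving 960 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COMPONENTS = ("cell_shape", "cell_coarse", "cell_fine",
              "nuc_shape", "nuc_coarse", "nuc_fine")
EMBED_DIM = 80


def feature_columns(components=COMPONENTS, dim: int = EMBED_DIM) -> list[str]:
    return [f"{comp}_{i:02d}" for comp in components for i in range(dim)]


# ---------------------------------------------------------------------------
# region adjacency graph


def adjacency_pairs(labels: np.ndarray, return_counts: bool = False):
    """Face-adjacent (6-connectivity) label pairs in a label grid.

    Returns sorted (a, b) pairs with a < b, background (0) excluded; with
    ``return_counts`` also the number of face-adjacent voxel pairs per edge
    (the voxel contact area).
    """
    los, his = [], []
    for ax in range(labels.ndim):
        a = np.moveaxis(labels, ax, 0)[:-1].ravel()
        b = np.moveaxis(labels, ax, 0)[1:].ravel()
        m = (a != b) & (a > 0) & (b > 0)
        los.append(np.minimum(a[m], b[m]))
        his.append(np.maximum(a[m], b[m]))
    lo = np.concatenate(los) if los else np.array([], dtype=labels.dtype)
    hi = np.concatenate(his) if his else np.array([], dtype=labels.dtype)
    if lo.size == 0:
        return ([], []) if return_counts else []
    key = lo.astype(np.int64) * (int(labels.max()) + 1) + hi
    uniq, counts = np.unique(key, return_counts=True)
    base = int(labels.max()) + 1
    pairs = [(int(k // base), int(k % base)) for k in uniq]
    if return_counts:
        return pairs, counts.tolist()
    return pairs


@dataclass
class RegionAdjacencyGraph:
    """Cell-contact graph: nodes are cell ids, edges are physical contacts."""

    nodes: list[int]
    edges: list[tuple[int, int]]
    contact_area: dict[tuple[int, int], int] = field(default_factory=dict)

    def neighbours(self, cell_id: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == cell_id:
                out.append(b)
            elif b == cell_id:
                out.append(a)
        return sorted(out)


def build_rag(cell_labels: np.ndarray) -> RegionAdjacencyGraph:
    """Region adjacency graph of a cell label volume (6-connectivity).

    Uses scikit-image's RAG construction; contact areas (face-adjacent voxel
    pair counts) come from a direct scan.  Background (label 0) is never a
    node.
    """
    from skimage.graph import RAG

    g = RAG(cell_labels.astype(np.int64), connectivity=1)
    if 0 in g.nodes:
        g.remove_node(0)
    nodes = sorted(int(n) for n in g.nodes)
    edges = sorted((min(int(a), int(b)), max(int(a), int(b)))
                   for a, b in g.edges)
    pairs, counts = adjacency_pairs(cell_labels, return_counts=True)
    area = dict(zip(pairs, counts))
    return RegionAdjacencyGraph(nodes=nodes, edges=edges,
                                contact_area={e: area.get(e, 0) for e in edges})


# ---------------------------------------------------------------------------
# context features


def context_features(table: pd.DataFrame, graph: RegionAdjacencyGraph) -> pd.DataFrame:
    """Concatenate each cell's features with its neighbourhood mean.

    The neighbourhood part is the mean over the cell itself and its contact
    neighbours; an isolated node's neighbourhood part equals its own features.
    """
    missing = [n for n in graph.nodes if n not in table.index]
    if missing:
        raise KeyError(f"graph nodes without feature rows: {missing[:5]}")
    neigh_map = {n: [] for n in graph.nodes}
    for a, b in graph.edges:
        neigh_map[a].append(b)
        neigh_map[b].append(a)
    rows = []
    for cid in table.index:
        members = [cid] + neigh_map.get(cid, [])
        absent = [m for m in members if m not in table.index]
        if absent:
            raise KeyError(
                f"cell {cid}: neighbour(s) {absent} have no feature row")
        rows.append(table.loc[members].to_numpy(dtype=float).mean(axis=0))
    neigh = pd.DataFrame(rows, index=table.index,
                         columns=[f"ctx_{c}" for c in table.columns])
    return pd.concat([table, neigh], axis=1)


# ---------------------------------------------------------------------------
# standardisation


@dataclass
class StandardizeTransform:
    mean: np.ndarray
    std: np.ndarray  # zero-variance columns carry std 0 and map to 0
    columns: list[str]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        x = table[self.columns].to_numpy(dtype=float)
        safe = np.where(self.std > 0, self.std, 1.0)
        z = (x - self.mean) / safe
        z[:, self.std == 0] = 0.0
        return pd.DataFrame(z, index=table.index, columns=self.columns)


def standardize_features(table: pd.DataFrame):
    """Per-feature zero mean / unit variance; returns (table, transform)."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardise")
    x = table.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    t = StandardizeTransform(mean=mean, std=std, columns=list(table.columns))
    return t.apply(table), t


# ---------------------------------------------------------------------------
# descriptor assembly


@dataclass
class ExclusionRecord:
    cell_id: int
    stage: str
    reason: str


def embed_all(volume, encoders: dict, config=None, seed: int = 0):
    """Assemble the 480-dim descriptor table for every cell of a volume.

    ``encoders`` maps each component name in :data:`COMPONENTS` to a fitted
    encoder (``ShapeEncoder`` for ``*_shape``, ``TextureEncoder`` otherwise).
    Fine-texture components average the per-patch embeddings of a cell.
    Cells failing any extraction stage get no row and are listed in the
    returned exclusion table.

    Returns ``(features, exclusions)`` data frames.
    """
    from . import extraction as ex

    config = config or ex.ExtractionConfig()
    missing = [c for c in COMPONENTS if c not in encoders]
    if missing:
        raise KeyError(f"missing encoder checkpoints for {missing}")

    rows, index, excluded = [], [], []
    cell_ids = np.unique(volume.cell_labels)
    cell_ids = cell_ids[cell_ids > 0]
    for cell_id in cell_ids:
        cell_id = int(cell_id)
        try:
            vec = _embed_cell(volume, cell_id, encoders, config, seed)
        except ex.ExtractionError as err:
            excluded.append(ExclusionRecord(cell_id, err.stage, str(err)))
            continue
        rows.append(vec)
        index.append(cell_id)

    feats = pd.DataFrame(rows, index=pd.Index(index, name="cell_id"),
                         columns=feature_columns())
    excl = pd.DataFrame([e.__dict__ for e in excluded],
                        columns=["cell_id", "stage", "reason"])
    return feats, excl


def _embed_cell(volume, cell_id, encoders, config, seed):
    from . import extraction as ex

    parts = []
    for compartment, prefix in (("cytoplasm", "cell"), ("nucleus", "nuc")):
        labels = (volume.cell_labels if compartment == "cytoplasm"
                  else volume.nucleus_labels)
        mesh = ex.build_mesh(labels, cell_id, voxel_size_nm=volume.voxel_size_nm,
                             smoothing_iters=config.smoothing_iters,
                             target_faces=config.target_faces)
        cloud = ex.sample_point_cloud(mesh, config.n_points,
                                      seed=seed * 100003 + cell_id)
        shape_emb = encoders[f"{prefix}_shape"].encode(cloud)

        crop = ex.extract_coarse_crop(volume, cell_id, compartment,
                                      mode=config.coarse_mode, config=config)
        coarse_emb, _ = encoders[f"{prefix}_coarse"].encode(crop.values, crop.mask)

        patches = ex.extract_fine_patches(volume, cell_id, compartment,
                                          config=config)
        if len(patches.patches) == 0:
            raise ex.ExtractionError(
                "fine_patches", f"cell {cell_id}: no patch passed the "
                f"occupancy filter for {compartment}")
        fine = [encoders[f"{prefix}_fine"].encode(p, m)[0]
                for p, m in zip(patches.patches, patches.masks)]
        fine_emb = np.mean(fine, axis=0)
        parts.extend([shape_emb, coarse_emb, fine_emb])
    # fixed layout: cell triplet then nucleus triplet
    order = [0, 1, 2, 3, 4, 5]
    return np.concatenate([np.asarray(parts[i], dtype=float) for i in order])


def write_edge_list(graph: RegionAdjacencyGraph, path: str | Path) -> None:
    df = pd.DataFrame(graph.edges, columns=["cell_a", "cell_b"])
    df["contact_area"] = [graph.contact_area.get(e, 0) for e in graph.edges]
    df.to_csv(path, sep="\t", index=False)
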