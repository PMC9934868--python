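"""Shape and texture encoders.

Six encoders produce one 80-dimensional embedding each: shape, coarse
texture and fine texture, separately for cell (cytoplasm) and nucleus.

* The **shape encoder** consumes a surface point cloud with unit normals.
  Per-point features start as (centred unit-bbox coordinates, normals); a
  stack of dynamic k-NN graph convolutions (EdgeConv: max over neighbours of
  an MLP on (centre, neighbour - centre)) aggregates local geometry, a fuse
  layer plus max pooling over points condenses the cloud into one latent
  vector, and an MLP head maps it to the embedding.  Max pooling makes the
  output invariant to point order.
* The **texture encoder** is the contracting half of a 3D U-Net: blocks of
  3x3x3 convolutions with ELU activations separated by 2x max pooling,
  channel count doubling per block, a 1x1x1 convolution reducing to the
  embedding dimension, then *masked* global average pooling over only the
  spatial positions whose receptive window touches the compartment, so empty
  voxels never dilute the embedding.  The pre-pool feature maps feed the
  reconstruction decoder during training.

Checkpoints are .npz archives with a JSON sidecar recording the config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, Conv3d, Linear, MaxPool3d, Module, Tensor, Upsample2x, concat, gather

EMBED_DIM = 80


@dataclass
class ShapeEncoderConfig:
    k_neighbours: int = 16
    n_graph_layers: int = 3
    hidden_width: int = 64
    out_dim: int = EMBED_DIM

    def __post_init__(self):
        if self.k_neighbours < 1 or self.out_dim < 1:
            raise ValueError("k_neighbours and out_dim must be >= 1")


@dataclass
class TextureEncoderConfig:
    base_channels: int = 64
    n_blocks: int = 3
    out_dim: int = EMBED_DIM
    kernel: int = 3


# ---------------------------------------------------------------------------
# helpers


def knn_indices(x: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbours (self excluded) by brute-force distances."""
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    x = np.asarray(x, dtype=np.float64)
    sq = (x ** 2).sum(-1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, np.inf)
    idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
    # sort the k for determinism
    order = np.take_along_axis(d2, idx, axis=1).argsort(axis=1, kind="stable")
    return np.take_along_axis(idx, order, axis=1)


def normalize_cloud(points: np.ndarray) -> np.ndarray:
    """Centre points and scale the longest bounding-box edge to 1."""
    p = points - points.mean(axis=0)
    extent = p.max(axis=0) - p.min(axis=0)
    scale = max(float(extent.max()), 1e-12)
    return p / scale


def masked_global_pool(feature_maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-channel mean of (C, d, h, w) maps over informative positions."""
    if feature_maps.shape[1:] != mask.shape:
        raise ValueError("mask must match feature-map spatial shape")
    m = mask.astype(bool)
    count = int(m.sum())
    if count == 0:
        raise ValueError("mask has zero informative positions")
    return feature_maps[:, m].sum(axis=1) / count


def downsample_mask_any(mask: np.ndarray, times: int) -> np.ndarray:
    """Mask pyramid rule: a coarse voxel is informative if any voxel in its
    2^times window is informative."""
    m = mask.astype(bool)
    for _ in range(times):
        d, h, w = m.shape
        m = m.reshape(d // 2, 2, h // 2, 2, w // 2, 2).any(axis=(1, 3, 5))
    return m


# ---------------------------------------------------------------------------
# shape encoder


class ShapeEncoder(Module):
    def __init__(self, config: ShapeEncoderConfig | None = None, seed: int = 0):
        self.config = config or ShapeEncoderConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        f_in = 6  # coords + normals
        self.edge_layers = []
        for _ in range(c.n_graph_layers):
            self.edge_layers.append(Linear(2 * f_in, c.hidden_width, rng))
            f_in = c.hidden_width
        latent = 2 * c.hidden_width
        self.fuse = Linear(c.hidden_width, latent, rng)
        self.head1 = Linear(latent, latent, rng)
        self.head2 = Linear(latent, c.out_dim, rng)

    def forward_batch(self, points_list, normals_list) -> Tensor:
        """Embed B equally sized clouds at once; returns (B, out_dim).

        Clouds are concatenated into one node set; k-NN graphs stay within
        each cloud (block structure), so per-cloud results equal the
        single-cloud path."""
        c = self.config
        n_pts = {len(p) for p in points_list}
        if len(n_pts) != 1:
            raise ValueError("all clouds in a batch must share a point count")
        n = n_pts.pop()
        B = len(points_list)
        feats_np = np.concatenate([
            np.concatenate([normalize_cloud(np.asarray(p, dtype=np.float64)),
                            np.asarray(nm)], axis=1)
            for p, nm in zip(points_list, normals_list)]).astype(np.float32)
        x = Tensor(feats_np)
        total = B * n
        k = c.k_neighbours
        centre_rows = np.repeat(np.arange(total), k).reshape(total, k)
        for layer in self.edge_layers:
            # dynamic graph: neighbours in the current feature space,
            # restricted to each cloud's own points
            nbr_rows = np.concatenate([
                knn_indices(x.data[i * n:(i + 1) * n], k) + i * n
                for i in range(B)])
            f = x.shape[1]
            col = np.arange(f)
            gi = centre_rows[..., None] * f + col      # (total, k, f)
            gj = nbr_rows[..., None] * f + col
            xi = gather(x, gi)
            xj = gather(x, gj)
            edge = concat([xi, xj - xi], axis=2)       # (total, k, 2f)
            h = layer(edge.reshape(total * k, 2 * f)).elu()
            x = h.reshape(total, k, c.hidden_width).max(axis=1)
        latent = self.fuse(x).elu()                    # (total, 2*hidden)
        latent = latent.reshape(B, n, 2 * c.hidden_width).max(axis=1)
        return self.head2(self.head1(latent).elu())    # (B, out_dim)

    def forward(self, points: np.ndarray, normals: np.ndarray) -> Tensor:
        return self.forward_batch([points], [normals]).reshape(-1)

    def encode(self, cloud) -> np.ndarray:
        """Inference: embedding of a PointCloud as a plain array."""
        return self.forward(cloud.points, cloud.normals).data.copy()

    def first_layer_knn(self, points: np.ndarray, normals: np.ndarray) -> np.ndarray:
        """The k-NN edge set the first graph layer would use (for inspection)."""
        coords = normalize_cloud(np.asarray(points, dtype=np.float64))
        feats = np.concatenate([coords, np.asarray(normals)], axis=1)
        return knn_indices(feats.astype(np.float32), self.config.k_neighbours)


# ---------------------------------------------------------------------------
# texture encoder / decoder


class TextureEncoder(Module):
    def __init__(self, config: TextureEncoderConfig | None = None, seed: int = 0):
        self.config = config or TextureEncoderConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        self.convs = []
        c_prev = 1
        for b in range(c.n_blocks):
            c_out = c.base_channels * (2 ** b)
            self.convs.append(Conv3d(c_prev, c_out, c.kernel, rng))
            c_prev = c_out
        self.reduce = Conv3d(c_prev, c.out_dim, 1, rng)
        self.pool = MaxPool3d()

    def forward(self, x: Tensor, mask: np.ndarray):
        """``x`` is (N, 1, D, H, W) in [0, 1]; ``mask`` is (N, D, H, W) bool.

        Returns (embeddings (N, out_dim), pre-pool maps (N, out_dim, d, h, w)).
        """
        n = x.shape[0]
        for conv in self.convs:
            x = self.pool(conv(x).elu())
        maps = self.reduce(x).elu()                     # (N, C, d, h, w)
        _, C, d, h, w = maps.shape
        small = np.stack([downsample_mask_any(mask[i], self.config.n_blocks)
                          for i in range(n)])
        counts = small.reshape(n, -1).sum(axis=1).astype(np.float64)
        if (counts == 0).any():
            raise ValueError("all-empty compartment mask reached the encoder")
        m = Tensor(small[:, None].astype(np.float32))
        pooled = (maps * m).reshape(n, C, d * h * w).sum(axis=2)
        emb = pooled * Tensor((1.0 / counts)[:, None].astype(np.float32))
        return emb, maps

    def encode(self, crop: np.ndarray, mask: np.ndarray):
        x = Tensor(np.asarray(crop, dtype=np.float32)[None, None])
        emb, maps = self.forward(x, np.asarray(mask, dtype=bool)[None])
        return emb.data[0].copy(), maps.data[0].copy()


class TextureDecoder(Module):
    """One upsampling block mirroring the last encoder block.

    Three pooling stages shrink the input 8x while only one decoder block
    upsamples 2x, so the reconstruction lives at 1/4 of the input resolution;
    the training target is the input downsampled by local mean to match.
    """

    def __init__(self, config: TextureEncoderConfig | None = None, seed: int = 1):
        self.config = config or TextureEncoderConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        self.up = Upsample2x()
        self.conv1 = Conv3d(c.out_dim, c.base_channels, c.kernel, rng)
        self.conv2 = Conv3d(c.base_channels, 1, 1, rng)

    def forward(self, maps: Tensor) -> Tensor:
        return self.conv2(self.conv1(self.up(maps)).elu())

    def decode(self, maps: np.ndarray) -> np.ndarray:
        if maps.ndim == 4:
            maps = maps[None]
        return self.forward(Tensor(np.asarray(maps, dtype=np.float32))).data


def reconstruction_target(x: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Local-mean downsample of input crops to the decoder output shape."""
    n = x.shape[0]
    D, H, W = x.shape[-3:]
    d, h, w = out_shape
    f = (D // d, H // h, W // w)
    v = x.reshape(n, 1, d, f[0], h, f[1], w, f[2])
    return v.mean(axis=(3, 5, 7))


# ---------------------------------------------------------------------------
# checkpoints

_KINDS = {"shape": (ShapeEncoder, ShapeEncoderConfig),
          "texture": (TextureEncoder, TextureEncoderConfig),
          "texture_decoder": (TextureDecoder, TextureEncoderConfig)}


def save_checkpoint(path: str | Path, module: Module, kind: str,
                    extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, **module.state_dict())
    sidecar = {"kind": kind, "config": asdict(module.config),
               "format_version": 1}
    if extra:
        sidecar.update(extra)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> Module:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cls, cfg_cls = _KINDS[sidecar["kind"]]
    module = cls(cfg_cls(**sidecar["config"]))
    if not str(path).endswith(".npz"):
        path = Path(str(path) + ".npz")
    with np.load(path) as data:
        module.load_state_dict(dict(data))
    return module
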