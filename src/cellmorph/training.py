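"""Self-supervised optimisation of the shape and texture encoders.

Shape encoders train purely contrastively: each iteration samples B source
objects, draws two augmented mesh views per object (from a precomputed view
cache, with independent rigid parts), samples point clouds, and scores the 2B
embeddings with the NT-Xent loss — normalised-temperature cross entropy over
cosine similarities where the positives are the two views of one object.

Texture encoders add an autoencoder objective: a one-block decoder
reconstructs a local-mean-downsampled version of the input crop from the
pre-pool feature maps, scored by MSE, plus an L2 penalty on the bottleneck
embedding.  The total is a weighted sum of the three parts.

Both loops use Adam, evaluate on a held-out validation split every
``eval_every`` iterations, keep the best checkpoint, and decay the learning
rate geometrically whenever validation fails the relative-improvement
criterion (new < improvement_factor * best).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .augmentation import (DeformConfig, ElasticConfig, _apply_rigid,
                           augment_texture_with_mask)
from .encoders import (ShapeEncoder, ShapeEncoderConfig, TextureDecoder,
                       TextureEncoder, TextureEncoderConfig,
                       reconstruction_target)
from .extraction import SurfaceMesh, sample_point_cloud
from .nn import Adam, Tensor, concat


@dataclass
class ContrastiveBatch:
    """2B items ordered so items i and i+B are the two views of source i."""

    items: list
    source_ids: list

    def __post_init__(self):
        if len(self.items) % 2 != 0:
            raise ValueError("contrastive batch size must be even")

    @property
    def n_sources(self) -> int:
        return len(self.items) // 2

    def positive_pairs(self) -> list[tuple[int, int]]:
        B = self.n_sources
        return [(i, i + B) for i in range(B)]


@dataclass
class TrainConfig:
    temperature: float = 0.5
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1e-4)  # ntxent, mse, l2
    lr: float = 2e-4
    weight_decay: float = 4e-4
    iterations: int = 200
    batch_sources: int = 48
    eval_every: int = 100
    lr_decay: float = 0.98
    improvement_factor: float = 0.95
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


def make_contrastive_batch(samples: list, augmenter, seed: int) -> ContrastiveBatch:
    """Two independent augmentations per source, ordered (view1s ++ view2s).

    ``augmenter(sample, seed)`` must return one augmented item.
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(seed)
    first, second = [], []
    for s in samples:
        s1, s2 = rng.integers(0, 2 ** 31, size=2)
        first.append(augmenter(s, int(s1)))
        second.append(augmenter(s, int(s2)))
    ids = list(range(len(samples)))
    return ContrastiveBatch(items=first + second, source_ids=ids + ids)


# ---------------------------------------------------------------------------
# losses


def nt_xent_loss(embeddings: Tensor | np.ndarray, temperature: float = 0.5) -> Tensor:
    """NT-Xent over cosine similarities, averaged over all 2B anchors.

    Positives are the (i, i+B) pairs; self-similarity is excluded from the
    denominator.  For B = 1 there are no negatives and the loss is 0 by
    convention (with a warning).
    """
    if not isinstance(embeddings, Tensor):
        embeddings = Tensor(np.asarray(embeddings, dtype=np.float32))
    n = embeddings.shape[0]
    if n % 2 != 0:
        raise ValueError("embeddings must hold 2B rows")
    B = n // 2
    norms_sq = (embeddings * embeddings).sum(axis=1, keepdims=True)
    if (norms_sq.data <= 0).any():
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    if B == 1:
        warnings.warn("contrastive batch with a single source: loss is 0",
                      stacklevel=2)
        return Tensor(np.zeros(()))
    unit = embeddings * norms_sq.pow(-0.5)
    sim = (unit @ unit.transpose((1, 0))) * (1.0 / temperature)   # (2B, 2B)
    # exclude self-similarity from the softmax by masking with -inf surrogate
    mask = Tensor(np.eye(n, dtype=np.float32) * 1e9)
    logits = sim - mask
    logsum = logits.exp().sum(axis=1).log()                       # (2B,)
    pos_idx = np.concatenate([np.arange(B) + B, np.arange(B)])
    pick = np.zeros((n, n), dtype=np.float32)
    pick[np.arange(n), pos_idx] = 1.0
    pos = (sim * Tensor(pick)).sum(axis=1)
    return (logsum - pos).mean()


def combined_texture_loss(embeddings: Tensor, reconstruction: Tensor,
                          target: np.ndarray, bottleneck: Tensor,
                          cfg: TrainConfig):
    """Weighted sum of NT-Xent + reconstruction MSE + bottleneck L2 penalty."""
    w_nt, w_mse, w_l2 = cfg.loss_weights
    nt = nt_xent_loss(embeddings, cfg.temperature)
    diff = reconstruction - Tensor(np.asarray(target, dtype=np.float32))
    mse = (diff * diff).mean()
    l2 = (bottleneck * bottleneck).mean()
    total = nt * w_nt + mse * w_mse + l2 * w_l2
    parts = {"ntxent": float(nt.data), "mse": float(mse.data),
             "l2": float(l2.data), "total": float(total.data)}
    if not np.isfinite(list(parts.values())).all():
        raise FloatingPointError(f"non-finite loss parts: {parts}")
    return total, parts


# ---------------------------------------------------------------------------
# training loops


@dataclass
class TrainResult:
    model: object
    decoder: object | None
    losses: list[float]
    val_losses: list[float]
    lr_trace: list[float]
    best_state: dict = field(default_factory=dict)


def _split_validation(n: int, fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(fraction * n))) if n > 2 else 0
    return idx[n_val:], idx[:n_val]


class ShapeViewSampler:
    """Draw two cached deformed views of an object and apply independent
    rigid parts, then sample point clouds."""

    def __init__(self, view_sets: list[list[SurfaceMesh]], n_points: int,
                 deform_cfg: DeformConfig):
        self.view_sets = view_sets
        self.n_points = n_points
        self.deform_cfg = deform_cfg

    def sample_pair(self, obj_index: int, rng: np.random.Generator):
        views = self.view_sets[obj_index]
        if len(views) >= 2:
            a, b = rng.choice(len(views), size=2, replace=False)
        else:
            a = b = 0
        out = []
        for v in (int(a), int(b)):
            mesh = self.view_sets[obj_index][v]
            verts = _apply_rigid(mesh.vertices, self.deform_cfg.rigid, rng)
            m = SurfaceMesh(verts, mesh.faces, mesh.object_id)
            out.append(sample_point_cloud(m, self.n_points,
                                          seed=int(rng.integers(0, 2 ** 31))))
        return out


def train_shape(view_sets: list[list[SurfaceMesh]], cfg: TrainConfig,
                encoder_config: ShapeEncoderConfig | None = None,
                n_points: int = 1024,
                deform_cfg: DeformConfig | None = None) -> TrainResult:
    """Contrastive training of one shape encoder (one compartment).

    ``view_sets[i]`` holds the precomputed deformed views of object i.
    """
    rng = np.random.default_rng(cfg.seed)
    encoder = ShapeEncoder(encoder_config or ShapeEncoderConfig(),
                           seed=cfg.seed + 1)
    sampler = ShapeViewSampler(view_sets, n_points,
                               deform_cfg or DeformConfig())
    opt = Adam(encoder.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    train_idx, val_idx = _split_validation(len(view_sets),
                                           cfg.validation_fraction, rng)
    if len(train_idx) == 0:
        raise ValueError("no training objects after validation split")

    def encode_batch(obj_indices, batch_rng):
        firsts, seconds = [], []
        for oi in obj_indices:
            c1, c2 = sampler.sample_pair(int(oi), batch_rng)
            firsts.append(c1)
            seconds.append(c2)
        clouds = firsts + seconds
        return encoder.forward_batch([c.points for c in clouds],
                                     [c.normals for c in clouds])

    losses, val_losses, lr_trace = [], [], []
    best = np.inf
    best_state = encoder.state_dict()
    for it in range(cfg.iterations):
        pick = rng.choice(train_idx, size=min(cfg.batch_sources, len(train_idx)),
                          replace=False)
        emb = encode_batch(pick, rng)
        loss = nt_xent_loss(emb, cfg.temperature)
        if not np.isfinite(loss.data):
            warnings.warn("NaN loss: aborting with last good checkpoint")
            break
        encoder.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        lr_trace.append(opt.lr)
        if len(val_idx) and (it + 1) % cfg.eval_every == 0:
            vrng = np.random.default_rng(cfg.seed + 777)
            vemb = encode_batch(val_idx, vrng)
            vloss = float(nt_xent_loss(vemb, cfg.temperature).data)
            val_losses.append(vloss)
            if vloss < cfg.improvement_factor * best:
                best = vloss
                best_state = encoder.state_dict()
            else:
                opt.lr *= cfg.lr_decay
    if not val_losses:
        best_state = encoder.state_dict()
    return TrainResult(model=encoder, decoder=None, losses=losses,
                       val_losses=val_losses, lr_trace=lr_trace,
                       best_state=best_state)


def train_texture(crops: list[np.ndarray], masks: list[np.ndarray],
                  cfg: TrainConfig,
                  encoder_config: TextureEncoderConfig | None = None,
                  elastic_cfg: ElasticConfig | None = None) -> TrainResult:
    """Combined contrastive + autoencoder training of one texture encoder.

    ``crops``/``masks`` are the cached compartment-masked [0, 1] cubes of one
    granularity (coarse crops or fine patches).
    """
    rng = np.random.default_rng(cfg.seed)
    enc_cfg = encoder_config or TextureEncoderConfig()
    encoder = TextureEncoder(enc_cfg, seed=cfg.seed + 1)
    decoder = TextureDecoder(enc_cfg, seed=cfg.seed + 2)
    params = {**{f"enc.{k}": v for k, v in encoder.parameters().items()},
              **{f"dec.{k}": v for k, v in decoder.parameters().items()}}
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    train_idx, val_idx = _split_validation(len(crops), cfg.validation_fraction,
                                           rng)
    if len(train_idx) == 0:
        raise ValueError("no training crops after validation split")

    def batch_loss(indices, batch_rng):
        # two augmented views per source, ordered first-views ++ second-views;
        # masks travel through the same geometric transform for pooling
        view_crops = [[], []]
        view_masks = [[], []]
        for v in range(2):
            for i in indices:
                seed = int(batch_rng.integers(0, 2 ** 31))
                c, m = augment_texture_with_mask(crops[int(i)], masks[int(i)],
                                                 seed, elastic_cfg)
                if not m.any():  # degenerate warp: fall back to source mask
                    m = masks[int(i)].copy()
                view_crops[v].append(c)
                view_masks[v].append(m)
        x = np.stack(view_crops[0] + view_crops[1])[:, None]
        mask_arr = np.stack(view_masks[0] + view_masks[1])
        emb, maps = encoder.forward(Tensor(x.astype(np.float32)), mask_arr)
        rec = decoder.forward(maps)
        target = reconstruction_target(x, rec.shape[-3:])
        return combined_texture_loss(emb, rec, target, emb, cfg)

    losses, val_losses, lr_trace = [], [], []
    best = np.inf
    state = lambda: {"enc": encoder.state_dict(), "dec": decoder.state_dict()}
    best_state = state()
    for it in range(cfg.iterations):
        pick = rng.choice(train_idx, size=min(cfg.batch_sources, len(train_idx)),
                          replace=False)
        total, parts = batch_loss(pick, rng)
        encoder.zero_grad()
        decoder.zero_grad()
        total.backward()
        opt.step()
        losses.append(parts["total"])
        lr_trace.append(opt.lr)
        if len(val_idx) and (it + 1) % cfg.eval_every == 0:
            vrng = np.random.default_rng(cfg.seed + 777)
            vtotal, vparts = batch_loss(val_idx, vrng)
            val_losses.append(vparts["total"])
            if vparts["total"] < cfg.improvement_factor * best:
                best = vparts["total"]
                best_state = state()
            else:
                opt.lr *= cfg.lr_decay
    if not val_losses:
        best_state = state()
    return TrainResult(model=encoder, decoder=decoder, losses=losses,
                       val_losses=val_losses, lr_trace=lr_trace,
                       best_state=best_state)
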