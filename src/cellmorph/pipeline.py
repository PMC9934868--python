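"""End-to-end desk-scale study: phantom -> training -> descriptors -> metrics.

This module wires the whole pipeline together at a problem size a single CPU
handles in minutes: a bilateral phantom with 3 shape x 2 texture classes,
reduced-width encoders, and a few hundred optimisation steps.  It is used by
the test suite and the reproduction script; the same functions scale up by
passing larger configs.

The desk-scale protocol (chosen once, documented in the methods note):
30 cell pairs on a 96x72x120 grid; shape encoders on 256-point clouds with
k = 10, hidden width 32; texture encoders with 8 base channels on 24^3 (cell)
/ 16^3 (nucleus) coarse crops and 8^3 fine patches; 6 cached views per mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import extraction as ex
from .analysis import bilateral_distance, reflection_candidates
from .augmentation import DeformConfig, ElasticConfig, RigidConfig, make_mesh_views
from .encoders import (ShapeEncoder, ShapeEncoderConfig, TextureEncoder,
                       TextureEncoderConfig)
from .features import embed_all, standardize_features
from .phantom import PhantomSpec, generate_phantom
from .training import TrainConfig, train_shape, train_texture
from .volume import LabeledVolume


@dataclass
class DeskScaleConfig:
    n_cell_pairs: int = 30
    seed: int = 0
    shape_encoder: ShapeEncoderConfig = field(default_factory=lambda: ShapeEncoderConfig(
        k_neighbours=10, n_graph_layers=3, hidden_width=32))
    texture_encoder: TextureEncoderConfig = field(default_factory=lambda: TextureEncoderConfig(
        base_channels=8))
    # fine patches are 4^3 at desk scale, so the fine encoder uses 2 blocks
    fine_encoder: TextureEncoderConfig = field(default_factory=lambda: TextureEncoderConfig(
        base_channels=8, n_blocks=2))
    extraction: ex.ExtractionConfig = field(default_factory=lambda: ex.ExtractionConfig(
        coarse_train_cyto=24, coarse_train_nuc=16, patch_edge=4,
        target_faces=1200, n_points=256))
    n_views: int = 6
    shape_iterations: int = 250
    shape_batch: int = 12
    shape_lr: float = 2e-3
    shape_temperature: float = 0.1
    texture_iterations: int = 80
    texture_batch: int = 8
    texture_lr: float = 3e-4
    texture_temperature: float = 0.5
    fine_iterations: int = 100
    fine_batch: int = 16
    max_patches_per_cell: int = 4
    shape_points: int = 256
    deform: DeformConfig = field(default_factory=lambda: DeformConfig(
        n_handles=3, handle_radius=0.10, displacement_scale=0.05,
        rigid=RigidConfig((0.9, 1.1), True, True)))
    elastic: ElasticConfig = field(default_factory=lambda: ElasticConfig(
        amplitude_voxels=1.5))


@dataclass
class DeskScaleResult:
    volume: LabeledVolume
    truth: pd.DataFrame
    encoders: dict
    random_encoders: dict
    loss_traces: dict
    features: pd.DataFrame
    features_random: pd.DataFrame
    excluded: pd.DataFrame


def _component_encoders(cfg: DeskScaleConfig, seed: int) -> dict:
    """Randomly initialised encoder set (the untrained baseline)."""
    out = {}
    for i, comp in enumerate(("cell_shape", "nuc_shape")):
        out[comp] = ShapeEncoder(cfg.shape_encoder, seed=seed + i)
    for i, comp in enumerate(("cell_coarse", "nuc_coarse")):
        out[comp] = TextureEncoder(cfg.texture_encoder, seed=seed + 10 + i)
    for i, comp in enumerate(("cell_fine", "nuc_fine")):
        out[comp] = TextureEncoder(cfg.fine_encoder, seed=seed + 20 + i)
    return out


def build_view_sets(volume: LabeledVolume, cell_ids, labels: np.ndarray,
                    cfg: DeskScaleConfig, seed: int):
    """Meshes and cached deformed views for one compartment's label grid."""
    view_sets, kept = [], []
    for cid in cell_ids:
        try:
            mesh = ex.build_mesh(labels, int(cid), volume.voxel_size_nm,
                                 cfg.extraction.smoothing_iters,
                                 cfg.extraction.target_faces)
        except ex.ExtractionError:
            continue
        dcfg = DeformConfig(**{**cfg.deform.__dict__,
                               "seed": seed * 7919 + int(cid)})
        view_sets.append(make_mesh_views(mesh, cfg.n_views, dcfg))
        kept.append(int(cid))
    return view_sets, kept


def collect_texture_sets(volume, cell_ids, cfg: DeskScaleConfig,
                         compartment: str):
    """(coarse crops+masks, fine patches+masks) for one compartment."""
    crops, cmasks, patches, pmasks = [], [], [], []
    for cid in cell_ids:
        try:
            crop = ex.extract_coarse_crop(volume, int(cid), compartment,
                                          "train", cfg.extraction)
        except ex.ExtractionError:
            continue
        if crop.mask.any():
            crops.append(crop.values)
            cmasks.append(crop.mask)
        pset = ex.extract_fine_patches(volume, int(cid), compartment,
                                       cfg.extraction)
        for p, m in list(zip(pset.patches, pset.masks))[:cfg.max_patches_per_cell]:
            patches.append(p)
            pmasks.append(m)
    return (crops, cmasks), (patches, pmasks)


def train_all_encoders(volume: LabeledVolume, cfg: DeskScaleConfig):
    """Train the six encoders on one phantom volume; returns encoders and
    per-component loss traces."""
    seed = cfg.seed
    cell_ids = [int(c) for c in np.unique(volume.cell_labels) if c > 0]
    encoders, traces = {}, {}

    for comp, labels, comp_seed in (("cell_shape", volume.cell_labels, 11),
                                    ("nuc_shape", volume.nucleus_labels, 23)):
        view_sets, _ = build_view_sets(volume, cell_ids, labels, cfg,
                                       seed + comp_seed)
        tc = TrainConfig(iterations=cfg.shape_iterations,
                         batch_sources=cfg.shape_batch,
                         eval_every=max(10, cfg.shape_iterations // 4),
                         lr=cfg.shape_lr, temperature=cfg.shape_temperature,
                         weight_decay=4e-4, seed=seed + 1)
        res = train_shape(view_sets, tc, cfg.shape_encoder,
                          n_points=cfg.shape_points, deform_cfg=cfg.deform)
        encoders[comp] = res.model
        traces[comp] = res.losses

    for compartment, prefix in (("cytoplasm", "cell"), ("nucleus", "nuc")):
        (crops, cmasks), (patches, pmasks) = collect_texture_sets(
            volume, cell_ids, cfg, compartment)
        tc = TrainConfig(iterations=cfg.texture_iterations,
                         batch_sources=cfg.texture_batch,
                         eval_every=max(10, cfg.texture_iterations // 4),
                         lr=cfg.texture_lr, temperature=cfg.texture_temperature,
                         weight_decay=5e-5, seed=seed + 2)
        res = train_texture(crops, cmasks, tc, cfg.texture_encoder, cfg.elastic)
        encoders[f"{prefix}_coarse"] = res.model
        traces[f"{prefix}_coarse"] = res.losses

        tcf = TrainConfig(iterations=cfg.fine_iterations,
                          batch_sources=cfg.fine_batch,
                          eval_every=max(10, cfg.fine_iterations // 4),
                          lr=cfg.texture_lr, temperature=cfg.texture_temperature,
                          weight_decay=5e-5, seed=seed + 3)
        resf = train_texture(patches, pmasks, tcf, cfg.fine_encoder,
                             cfg.elastic)
        encoders[f"{prefix}_fine"] = resf.model
        traces[f"{prefix}_fine"] = resf.losses
    return encoders, traces


def run_desk_scale_study(cfg: DeskScaleConfig | None = None) -> DeskScaleResult:
    """Generate a phantom, train all encoders, and assemble descriptors for
    trained and randomly initialised encoder sets."""
    cfg = cfg or DeskScaleConfig()
    phantom = generate_phantom(PhantomSpec(n_cell_pairs=cfg.n_cell_pairs,
                                           seed=cfg.seed))
    volume = LabeledVolume.from_phantom(phantom)
    encoders, traces = train_all_encoders(volume, cfg)
    random_encoders = _component_encoders(cfg, seed=cfg.seed + 500)
    feats, excl = embed_all(volume, encoders, cfg.extraction, seed=cfg.seed)
    feats_rand, _ = embed_all(volume, random_encoders, cfg.extraction,
                              seed=cfg.seed)
    return DeskScaleResult(volume=volume, truth=phantom.truth,
                           encoders=encoders, random_encoders=random_encoders,
                           loss_traces=traces, features=feats,
                           features_random=feats_rand, excluded=excl)


# ---------------------------------------------------------------------------
# evaluation helpers on a finished study


def linear_probe_accuracy(features: pd.DataFrame, labels: pd.Series,
                          seed: int = 0, test_fraction: float = 0.5) -> float:
    """Held-out accuracy of a logistic probe on standardised features."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labels = labels.loc[features.index]
    z, _ = standardize_features(features)
    xtr, xte, ytr, yte = train_test_split(
        z.to_numpy(), labels.to_numpy(), test_size=test_fraction,
        random_state=seed, stratify=labels.to_numpy())
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
    clf.fit(xtr, ytr)
    return float((clf.predict(xte) == yte).mean())


def bilateral_median_rank(features: pd.DataFrame, truth: pd.DataFrame,
                          x_extent: int, n_candidates: int = 10) -> float:
    """Median feature-space rank of the nearest candidate mirror partner."""
    common = features.index.intersection(truth.index)
    cands = reflection_candidates(truth.loc[common], x_extent, n_candidates)
    cands = {c: [p for p in v if p in common] for c, v in cands.items()
             if c in common}
    z, _ = standardize_features(features.loc[common])
    return bilateral_distance(z, cands).median_rank


def loss_decreased(trace: list[float], window: int = 20) -> bool:
    """Final-window mean strictly below initial-window mean."""
    w = min(window, max(1, len(trace) // 3))
    return float(np.mean(trace[-w:])) < float(np.mean(trace[:w]))
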