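"""Labelled-volume container and HDF5 / TSV I/O.

A :class:`LabeledVolume` is the universe every pipeline stage reads: one raw
intensity grid plus cell and nucleus label grids, all (z, y, x), with voxel
sizes in nm.  Volumes are stored as three datasets in a single HDF5 container
(``raw``, ``cell_labels``, ``nucleus_labels``) with a ``voxel_size_nm``
attribute; tables travel as TSV with a ``cell_id`` first column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class LabeledVolume:
    raw: np.ndarray
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (100.0, 80.0, 80.0)

    def __post_init__(self):
        if not (self.raw.shape == self.cell_labels.shape == self.nucleus_labels.shape):
            raise ValueError("raw and label grids must share one shape")
        if self.raw.ndim != 3:
            raise ValueError("volumes are 3D (z, y, x)")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]

    @classmethod
    def from_phantom(cls, phantom) -> "LabeledVolume":
        return cls(raw=phantom.raw, cell_labels=phantom.cell_labels,
                   nucleus_labels=phantom.nucleus_labels,
                   voxel_size_nm=phantom.voxel_size_nm)


def save_volume(volume: LabeledVolume, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=volume.raw, compression="gzip")
        f.create_dataset("cell_labels", data=volume.cell_labels, compression="gzip")
        f.create_dataset("nucleus_labels", data=volume.nucleus_labels,
                         compression="gzip")
        f.attrs["voxel_size_nm"] = np.asarray(volume.voxel_size_nm, dtype=float)


def load_volume(path: str | Path) -> LabeledVolume:
    with h5py.File(path, "r") as f:
        return LabeledVolume(
            raw=f["raw"][:],
            cell_labels=f["cell_labels"][:],
            nucleus_labels=f["nucleus_labels"][:],
            voxel_size_nm=tuple(f.attrs["voxel_size_nm"]),
        )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as TSV with ``cell_id`` as the first column."""
    out = table.copy()
    for col in out.columns:  # lists (e.g. neighbour ids) -> ';'-joined text
        if out[col].map(lambda v: isinstance(v, (list, tuple, set))).any():
            out[col] = out[col].map(lambda v: ";".join(map(str, v)))
    out.index.name = out.index.name or "cell_id"
    out.to_csv(path, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
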