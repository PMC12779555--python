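"""Labeled annotation volumes with a region ontology.

An :class:`AtlasVolume` is a 3D integer label grid at fixed isotropic voxel
size (25 µm by convention) plus an ontology table (region id, acronym,
parent id, brain area).  Coordinates are µm in atlas space; a point maps to
voxel index ``floor(coord / voxel_size)``.  Axis convention: x anterior→
posterior, y superior→inferior, z left→right, so the mid-z plane is the
hemispheric midline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

VOXEL_SIZE_UM = 25.0

ONTOLOGY_COLUMNS = ["id", "acronym", "parent_id", "area"]


@dataclass
class AtlasVolume:
    labels: np.ndarray                # 3D uint32 label grid, 0 = background
    ontology: pd.DataFrame            # columns: id, acronym, parent_id, area
    voxel_size: float = VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        self.ontology = self.ontology.reset_index(drop=True)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def voxel_of(self, xyz_um: np.ndarray) -> np.ndarray:
        """Voxel indices (floor) for µm coordinates; may fall outside the grid."""
        return np.floor(np.atleast_2d(xyz_um) / self.voxel_size).astype(int)

    def label_at(self, xyz_um: np.ndarray) -> np.ndarray:
        """Region label at each µm coordinate; 0 outside the grid."""
        idx = self.voxel_of(xyz_um)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    @property
    def midline_um(self) -> float:
        """z coordinate (µm) of the hemispheric midline."""
        return self.shape[2] * self.voxel_size / 2.0

    def hemisphere_of(self, xyz_um: np.ndarray) -> np.ndarray:
        """'left' for z < midline else 'right'."""
        z = np.atleast_2d(xyz_um)[:, 2]
        return np.where(z < self.midline_um, "left", "right")

    def region_volume_mm3(self, region_id: int) -> float:
        n = int((self.labels == region_id).sum())
        return n * (self.voxel_size / 1000.0) ** 3

    # -- I/O -------------------------------------------------------------
    def save(self, volume_path: str | Path, ontology_path: str | Path) -> None:
        affine = np.diag([self.voxel_size, self.voxel_size, self.voxel_size, 1.0])
        img = nib.Nifti1Image(self.labels.astype(np.uint32), affine)
        nib.save(img, str(volume_path))
        records = self.ontology[ONTOLOGY_COLUMNS].to_dict(orient="records")
        Path(ontology_path).write_text(json.dumps(records, indent=1))

    @classmethod
    def load(cls, volume_path: str | Path, ontology_path: str | Path) -> "AtlasVolume":
        img = nib.load(str(volume_path))
        labels = np.asarray(img.dataobj).astype(np.uint32)
        voxel = float(img.header.get_zooms()[0])
        ontology = pd.DataFrame(json.loads(Path(ontology_path).read_text()))
        return cls(labels=labels, ontology=ontology, voxel_size=voxel)
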