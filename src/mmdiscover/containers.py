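"""Core in-memory containers shared by every pipeline stage.

A :class:`FeatureTable` (samples x features, tagged by modality) is the
common currency flowing from radiomics extraction and miRNA preprocessing
into redundancy reduction, univariate screening and model search.
Volumetric data (image + lesion mask) is carried by
:class:`VolumetricImage` / :class:`RoiMask`, read and written as NIfTI.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES = ("miRNA", "T2W", "ADC", "clinical")

#: Gleason patterns counted as clinically significant under each contrast.
#: ``3+3 vs >=4+3`` drops the intermediate 3+4 samples entirely.
CONTRASTS = ("3+3 vs >=3+4", "3+3 vs >=4+3")


@dataclasses.dataclass
class FeatureTable:
    """Samples x features matrix with a modality tag.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id, one column per feature.
    modality:
        One of ``miRNA``, ``T2W``, ``ADC``, ``clinical``.
    """

    data: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select(self, feature_ids: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data[list(feature_ids)], self.modality)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path, modality: str) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        df.index = df.index.astype(str)
        return cls(df, modality)


@dataclasses.dataclass
class CohortLabels:
    """Per-sample Gleason score plus the binary contrast used for modeling.

    ``gleason`` maps sample id -> pattern string (``"3+3"``, ``"3+4"``,
    ``"4+3"``, ``"4+4"`` ...).  The positive (label 1) class is clinically
    significant disease; under the secondary contrast, 3+4 samples are
    excluded from modeling rather than assigned to either class.
    """

    gleason: pd.Series
    contrast: str = "3+3 vs >=3+4"

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        self.gleason = self.gleason.astype(str)

    @staticmethod
    def _grade_sum(pattern: str) -> tuple[int, int]:
        a, b = pattern.split("+")
        return int(a), int(b)

    def binary(self) -> pd.Series:
        """0/1 labels on the modeled samples (1 = clinically significant)."""
        primary = self.gleason.map(lambda g: self._grade_sum(g) != (3, 3))
        if self.contrast == "3+3 vs >=3+4":
            return primary.astype(int)
        keep = self.gleason.map(
            lambda g: self._grade_sum(g) == (3, 3) or self._grade_sum(g) >= (4, 3)
        )
        return primary[keep].astype(int)

    def subset(self, sample_ids: Iterable[str]) -> "CohortLabels":
        return CohortLabels(self.gleason.loc[list(sample_ids)], self.contrast)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, str], contrast: str = "3+3 vs >=3+4"
    ) -> "CohortLabels":
        return cls(pd.Series(dict(mapping)), contrast)


@dataclasses.dataclass
class VolumetricImage:
    """3D intensity grid with per-axis voxel size in mm."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("image must be 3D")
        if not np.isfinite(self.voxels).all():
            raise ValueError("image has non-finite intensities")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumetricImage":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj, dtype=float), spacing)


@dataclasses.dataclass
class RoiMask:
    """Binary lesion mask aligned voxel-for-voxel with its image."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.voxels.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def bounding_box(self) -> tuple[slice, slice, slice]:
        idx = np.nonzero(self.voxels)
        return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)

    def to_nifti(self, path: str | Path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
        affine = np.diag(list(spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "RoiMask":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj) > 0)
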