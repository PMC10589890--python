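"""4D image series container and thin NIfTI I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageSeries", "save_map", "load_map"]


@dataclass
class ImageSeries:
    """Magnitude MRF data of shape (x, y, slices, frames) with optional mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ImageSeries data must be 4D (x, y, slice, frame)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def voxel_signals(self, mask: np.ndarray | None = None) -> np.ndarray:
        """In-mask signals as an (n_voxels, n_frames) matrix."""
        m = self.mask if mask is None else np.asarray(mask, dtype=bool)
        if m is None:
            return self.data.reshape(-1, self.n_frames)
        return self.data[m]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))

    @classmethod
    def load(cls, path) -> "ImageSeries":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


def save_map(volume: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=float), affine), str(path))


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
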