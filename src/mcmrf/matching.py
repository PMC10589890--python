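"""Single-component dictionary matching and brain-mask extraction.

Every voxel signal x is compared with every L2-normalized dictionary atom a_j
by the absolute normalized inner product |<x, a_j>| / ||x||; the best atom
determines the voxel's (T1, T2*, b1) and the equilibrium magnetization is
recovered as M0 = <x, a_j> / nu_j with nu_j the atom's pre-normalization
norm (unit-M0 signal scale).  Ties are broken toward the lowest entry index,
which orders entries by (b1, T1, T2*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageSeries
from .sequence_dictionary import CompressedDictionary, Dictionary

__all__ = ["ParameterMaps", "match_single", "brain_mask"]

_CHUNK_ELEMENTS = 2**25  # ~256 MB of float64 scores per voxel chunk


@dataclass
class ParameterMaps:
    """Per-voxel single-component fit results on the image grid."""

    t1_ms: np.ndarray
    t2star_ms: np.ndarray
    b1_eff: np.ndarray
    m0: np.ndarray
    m0_relative: np.ndarray
    match_correlation: np.ndarray
    entry_index: np.ndarray
    affine: np.ndarray

    def save(self, out_dir) -> None:
        from pathlib import Path

        from .image import save_map

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("t1_ms", "t2star_ms", "b1_eff", "m0", "m0_relative", "match_correlation"):
            save_map(getattr(self, name), self.affine, out / f"{name}.nii.gz")


def _match_block(signals: np.ndarray, atoms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best |inner product| per signal row against atom columns, chunked."""
    n_vox = signals.shape[0]
    n_entries = atoms.shape[1]
    best_idx = np.zeros(n_vox, dtype=np.int64)
    best_val = np.zeros(n_vox)
    chunk = max(1, _CHUNK_ELEMENTS // max(n_entries, 1))
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        scores = np.abs(signals[lo:hi] @ atoms)
        best_idx[lo:hi] = np.argmax(scores, axis=1)
        best_val[lo:hi] = np.take_along_axis(
            scores, best_idx[lo:hi, None], axis=1
        )[:, 0]
    return best_idx, best_val


def match_single(
    series: ImageSeries,
    dictionary: Dictionary | CompressedDictionary,
    m0_percentile: float = 99.0,
) -> ParameterMaps:
    """Match every voxel to its best dictionary atom.

    Accepts either a frame-space ``Dictionary`` or a ``CompressedDictionary``
    (the series is projected into the compressed space first).  Relative M0
    is M0 divided by its ``m0_percentile``-th percentile over the image, a
    robust proxy for the full-magnetization signal level.
    """
    signals = series.data.reshape(-1, series.n_frames)
    if isinstance(dictionary, CompressedDictionary):
        if dictionary.projector.shape[1] != series.n_frames:
            raise ValueError("series frame count does not match the dictionary")
        signals = dictionary.compress_data(signals)
    elif dictionary.n_frames != series.n_frames:
        raise ValueError("series frame count does not match the dictionary")

    best_idx, best_inner = _match_block(signals, dictionary.atoms)
    t1, t2s, b1 = dictionary.entry_params(best_idx)
    m0 = best_inner / dictionary.norms[best_idx]
    # Correlation against the frame-space signal norm; for compressed data
    # the projection is orthonormal so norms are preserved up to truncation.
    signal_norm = np.linalg.norm(series.data.reshape(-1, series.n_frames), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(signal_norm > 0, best_inner / signal_norm, 0.0)
    corr = np.clip(corr, 0.0, 1.0)

    shape = series.spatial_shape
    scale = np.percentile(m0, m0_percentile)
    m0_rel = m0 / scale if scale > 0 else np.zeros_like(m0)
    return ParameterMaps(
        t1_ms=t1.reshape(shape),
        t2star_ms=t2s.reshape(shape),
        b1_eff=b1.reshape(shape),
        m0=m0.reshape(shape),
        m0_relative=m0_rel.reshape(shape),
        match_correlation=corr.reshape(shape),
        entry_index=best_idx.reshape(shape),
        affine=series.affine,
    )


def brain_mask(maps: ParameterMaps, threshold: float = 0.05) -> np.ndarray:
    """Largest 26-connected 3D component of {relative M0 > threshold}."""
    fg = maps.m0_relative > threshold
    if not fg.any():
        raise ValueError(
            f"brain mask is empty: no voxel has relative M0 > {threshold}"
        )
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))
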