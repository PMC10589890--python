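"""Marchenko-Pastur PCA denoising of 4D MRF magnitude series.

Random-matrix denoising exploits that, in a local patch, the noise-free
signals span only a few temporal principal components while thermal noise
spreads over all of them.  For a patch Casorati matrix X (M voxels x N
frames) with i.i.d. Gaussian noise of variance sigma^2, the eigenvalues of
X^T X / M that carry no signal fill the Marchenko-Pastur bulk

    [sigma^2 (1 - sqrt(gamma))^2,  sigma^2 (1 + sqrt(gamma))^2],
    gamma = (number of noise components) / M,

whose mean is sigma^2 and whose width is 4 sigma^2 sqrt(gamma).  The
estimator scans the candidate signal rank r and keeps the smallest r for
which the trailing eigenvalues are consistent with such a bulk; components
inside the bulk are nulled before reconstruction.

Processing is per slice and across timeframes in square spatial patches
(default radius 7, i.e. 15 x 15 voxels); overlapping reconstructions are
averaged uniformly.  Magnitude (Rician) data are treated as Gaussian, which
slightly biases the noise estimate at low SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import ImageSeries

__all__ = ["PatchConfig", "mppca_patch", "mppca_denoise"]


@dataclass(frozen=True)
class PatchConfig:
    """Square-patch sliding-window configuration.

    ``radius_voxels`` r gives (2r+1) x (2r+1) patches; patches are clipped at
    slice borders rather than padded.  ``aggregation`` is either
    ``"weighted-average"`` (uniform averaging over all overlapping patch
    reconstructions) or ``"center-only"``.
    """

    radius_voxels: int = 7
    stride: int = 1
    aggregation: str = "weighted-average"

    def __post_init__(self) -> None:
        if self.radius_voxels < 1:
            raise ValueError("patch radius must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.aggregation not in ("weighted-average", "center-only"):
            raise ValueError("aggregation must be 'weighted-average' or 'center-only'")


def mppca_patch(casorati: np.ndarray, edge_slack: float = 1.05) -> tuple[np.ndarray, float, int]:
    """Denoise one Casorati matrix (voxels x frames).

    Returns (denoised matrix, sigma estimate, retained component count).

    The rank is chosen as the smallest r such that the spread of the trailing
    N - r eigenvalues does not exceed the Marchenko-Pastur bulk width
    4 sigma^2 sqrt(gamma) implied by their own mean.  ``edge_slack`` widens
    that comparison a few percent to absorb the finite-size (Tracy-Widom)
    fluctuation of the bulk edge, which would otherwise misclassify the
    largest noise eigenvalue as signal in a sizeable minority of patches.
    """
    x = np.asarray(casorati, dtype=float)
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("patch must be at least 2 x 2")
    # Economy SVD; eigenvalues of X^T X / m in descending order.
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    lam = s**2 / m
    k = lam.size
    rank = k
    sigma2 = 0.0
    for r in range(k - 1):
        q = k - r  # candidate number of noise components
        bulk = lam[r:]
        mean_lam = bulk.mean()
        gamma = q / m
        # numerically-zero trailing spectra (noiseless low-rank patches)
        # count as noise
        if bulk[0] <= 1e-12 * lam[0] or (
            bulk[0] - bulk[-1] <= edge_slack * 4.0 * np.sqrt(gamma) * mean_lam
        ):
            rank = r
            sigma2 = mean_lam
            break
    denoised = (u[:, :rank] * s[:rank]) @ vt[:rank]
    return denoised, float(np.sqrt(max(sigma2, 0.0))), rank


def mppca_denoise(
    series: ImageSeries, cfg: PatchConfig = PatchConfig()
) -> tuple[ImageSeries, np.ndarray]:
    """MP-PCA denoise a 4D series per slice; returns (denoised, sigma map).

    Voxels outside ``series.mask`` (when set) pass through unchanged and get
    sigma 0.  The sigma map averages the per-patch noise estimates of all
    patches covering each voxel.
    """
    if series.n_frames < 2:
        raise ValueError("denoising needs at least two timeframes")
    nx, ny, nz, nt = series.data.shape
    size = 2 * cfg.radius_voxels + 1
    if size * size <= nt:
        warnings.warn(
            "patch voxel count does not exceed the frame count; "
            "noise estimation will be poorly conditioned",
            stacklevel=2,
        )
    out = series.data.copy()
    accum = np.zeros_like(series.data)
    sigma_accum = np.zeros((nx, ny, nz))
    weight = np.zeros((nx, ny, nz))
    mask = series.mask

    for z in range(nz):
        plane = series.data[:, :, z, :]
        if mask is not None and not mask[:, :, z].any():
            continue
        x_starts = _patch_starts(nx, size, cfg.stride)
        y_starts = _patch_starts(ny, size, cfg.stride)
        for x0 in x_starts:
            for y0 in y_starts:
                xs = slice(x0, min(x0 + size, nx))
                ys = slice(y0, min(y0 + size, ny))
                patch = plane[xs, ys, :]
                pm, pn = patch.shape[0] * patch.shape[1], nt
                if pm < 2:
                    continue
                den, sigma, _ = mppca_patch(patch.reshape(pm, pn))
                den = den.reshape(patch.shape)
                if cfg.aggregation == "center-only":
                    cx = min(x0 + cfg.radius_voxels, nx - 1)
                    cy = min(y0 + cfg.radius_voxels, ny - 1)
                    accum[cx, cy, z, :] += den[cx - x0, cy - y0]
                    sigma_accum[cx, cy, z] += sigma
                    weight[cx, cy, z] += 1.0
                else:
                    accum[xs, ys, z, :] += den
                    sigma_accum[xs, ys, z] += sigma
                    weight[xs, ys, z] += 1.0

    covered = weight > 0
    out[covered] = accum[covered] / weight[covered][:, None]
    sigma_map = np.zeros((nx, ny, nz))
    sigma_map[covered] = sigma_accum[covered] / weight[covered]
    if mask is not None:
        out[~mask] = series.data[~mask]
        sigma_map[~mask] = 0.0
    return ImageSeries(out, series.affine, series.mask), sigma_map


def _patch_starts(extent: int, size: int, stride: int) -> np.ndarray:
    """Start offsets covering [0, extent) with the final patch clipped inward."""
    if extent <= size:
        return np.array([0])
    starts = np.arange(0, extent - size + 1, stride)
    if starts[-1] != extent - size:
        starts = np.append(starts, extent - size)
    return starts
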