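"""Derived measures from multi-component solutions.

Covers grouping of per-subject components across a cohort (k-means on
log-scaled relaxation times), selection and merging of the long-T2*
components (500 < T1 < 2500 ms and 500 < T2* < 2500 ms, open intervals),
white-matter/regional masking with normalized fraction volumes, and overlap
scoring against lesion masks at a 15% fraction threshold.

A regional "normalized volume" is the sum of per-voxel magnetization
fractions over the region divided by the region's voxel count, a number in
[0, 1]; anisotropic voxels cancel in the ratio.  The 15% threshold is used
only for overlap scoring, not for volume computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .spijn_mc import ComponentSolution

__all__ = [
    "RegionMasks",
    "ComponentSummary",
    "cluster_components",
    "select_long_t2star",
    "mask_and_volume",
    "lesion_overlap",
    "LONG_T1_BOUNDS_MS",
    "LONG_T2STAR_BOUNDS_MS",
]

LONG_T1_BOUNDS_MS = (500.0, 2500.0)
LONG_T2STAR_BOUNDS_MS = (500.0, 2500.0)
LESION_PROBABILITY_THRESHOLD = 0.5
OVERLAP_FRACTION_THRESHOLD = 0.15


@dataclass
class RegionMasks:
    """Tissue and regional segmentations consumed by the volume stage.

    ``lobe_labels`` is an integer map whose positive labels partition the
    brain into named regions (``lobe_names`` maps label -> name, e.g.
    "frontal_left"); 0 means unlabeled.  ``lesion_probability`` is in [0, 1].
    """

    white_matter: np.ndarray
    gray_matter: np.ndarray
    csf: np.ndarray
    lobe_labels: np.ndarray
    lobe_names: dict[int, str] = field(default_factory=dict)
    lesion_probability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.white_matter = np.asarray(self.white_matter, dtype=bool)
        self.gray_matter = np.asarray(self.gray_matter, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        overlap = (
            (self.white_matter & self.gray_matter)
            | (self.white_matter & self.csf)
            | (self.gray_matter & self.csf)
        )
        if overlap.any():
            raise ValueError("tissue masks must be disjoint")
        if self.lesion_probability is not None:
            lp = np.asarray(self.lesion_probability, dtype=float)
            if lp.min() < 0 or lp.max() > 1:
                raise ValueError("lesion_probability must lie in [0, 1]")
            self.lesion_probability = lp

    def lesion_mask(self, threshold: float = LESION_PROBABILITY_THRESHOLD) -> np.ndarray:
        if self.lesion_probability is None:
            return np.zeros_like(self.white_matter)
        return self.lesion_probability > threshold

    def region_mask(self, region: str) -> np.ndarray:
        """Binary mask for a named region ('all', a lobe name, or a
        hemisphere prefix such as 'left'/'right' matching lobe-name suffixes)."""
        if region == "all":
            return np.ones_like(self.white_matter)
        hits = np.zeros_like(self.white_matter)
        found = False
        for label, name in self.lobe_names.items():
            if name == region or name.endswith("_" + region) or name.startswith(region + "_"):
                hits |= self.lobe_labels == label
                found = True
        if not found:
            raise KeyError(f"unknown region {region!r}")
        return hits


@dataclass
class ComponentSummary:
    """k-means clustering result over (T1, T2*) component scatter."""

    assignments: np.ndarray
    t1_mean_ms: np.ndarray
    t1_sd_ms: np.ndarray
    t2star_mean_ms: np.ndarray
    t2star_sd_ms: np.ndarray
    members: list[np.ndarray]
    total_volume: np.ndarray


def cluster_components(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ComponentSummary:
    """k-means on log-scaled relaxation times of pooled components.

    ``points`` has rows (t1_ms, t2star_ms, volume).  Clustering runs on
    (log T1, log T2*); reported per-cluster means and SDs are arithmetic, in
    the original millisecond units; ``total_volume`` sums member volumes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3): t1_ms, t2star_ms, volume")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pts.shape[0]:
        raise ValueError("k cannot exceed the number of components")
    logxy = np.log(pts[:, :2])
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(logxy)
    labels = km.labels_
    # order clusters by ascending mean log-T1 for reproducible numbering
    order = np.argsort([logxy[labels == c, 0].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    members = [np.flatnonzero(labels == c) for c in range(k)]
    return ComponentSummary(
        assignments=labels,
        t1_mean_ms=np.array([pts[m, 0].mean() for m in members]),
        t1_sd_ms=np.array([pts[m, 0].std(ddof=1) if m.size > 1 else 0.0 for m in members]),
        t2star_mean_ms=np.array([pts[m, 1].mean() for m in members]),
        t2star_sd_ms=np.array([pts[m, 1].std(ddof=1) if m.size > 1 else 0.0 for m in members]),
        members=members,
        total_volume=np.array([pts[m, 2].sum() for m in members]),
    )


def select_long_t2star(
    solution: ComponentSolution,
    t1_bounds_ms: tuple[float, float] = LONG_T1_BOUNDS_MS,
    t2star_bounds_ms: tuple[float, float] = LONG_T2STAR_BOUNDS_MS,
) -> tuple[np.ndarray, list[int]]:
    """Merge all components strictly inside both open intervals.

    Returns the summed magnetization-fraction map and the indices of the
    merged components (empty selection yields a zero map).
    """
    selected = [
        i
        for i, (t1, t2s) in enumerate(solution.components)
        if t1_bounds_ms[0] < t1 < t1_bounds_ms[1]
        and t2star_bounds_ms[0] < t2s < t2star_bounds_ms[1]
    ]
    merged = solution.fractions[..., selected].sum(axis=-1)
    return merged, selected


def mask_and_volume(
    fraction_map: np.ndarray,
    masks: RegionMasks,
    region: str = "all",
    lesions_excluded: bool = False,
) -> float:
    """Normalized fraction volume of a region of white matter.

    The region mask is white matter intersected with the named region (minus
    suprathreshold lesions when ``lesions_excluded``); the volume is the sum
    of in-region fractions divided by the region voxel count, in [0, 1].
    """
    fraction_map = np.asarray(fraction_map, dtype=float)
    region_mask = masks.white_matter & masks.region_mask(region)
    if lesions_excluded:
        region_mask = region_mask & ~masks.lesion_mask()
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError(f"region {region!r} is empty")
    return float(fraction_map[region_mask].sum() / n)


def region_volume_table(
    fraction_map: np.ndarray, masks: RegionMasks, regions: list[str]
) -> pd.DataFrame:
    """Per-region volumes with and without lesions, as a tidy table."""
    rows = []
    for region in regions:
        rows.append(
            {
                "region": region,
                "volume": mask_and_volume(fraction_map, masks, region, False),
                "volume_no_lesions": mask_and_volume(fraction_map, masks, region, True),
            }
        )
    return pd.DataFrame(rows)


def lesion_overlap(
    fraction_map: np.ndarray,
    lesion_mask: np.ndarray,
    threshold: float = OVERLAP_FRACTION_THRESHOLD,
) -> dict[str, float]:
    """Overlap of the thresholded fraction map with a lesion mask.

    Returns the Dice coefficient, both volumes (voxel counts), and the
    fraction of suprathreshold voxels lying outside the lesion mask - the
    amount of involvement beyond the visible lesions.
    """
    hot = np.asarray(fraction_map, dtype=float) > threshold
    lesion = np.asarray(lesion_mask, dtype=bool)
    inter = float(np.sum(hot & lesion))
    v_mcmrf = float(hot.sum())
    v_lesion = float(lesion.sum())
    dice = 2 * inter / (v_mcmrf + v_lesion) if v_mcmrf + v_lesion > 0 else np.nan
    excess = (v_mcmrf - inter) / v_mcmrf if v_mcmrf > 0 else 0.0
    return {
        "dice": dice,
        "volume_mcmrf": v_mcmrf,
        "volume_lesion": v_lesion,
        "excess_fraction": excess,
    }
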