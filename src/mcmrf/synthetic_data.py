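"""Synthetic digital brain phantoms, MRF-EPI acquisitions and cohorts.

Everything the study design needs is generated with known ground truth:

* a multi-tissue partial-volume brain slice stack with white matter,
  cortical and deep gray matter, CSF ventricles and rim, focal white-matter
  lesions, and a "dirty-appearing" rim whose long-T2* magnetization fraction
  decays with distance from the ventricles and lesions;
* a smooth multiplicative flip-angle-efficiency field, quantized to the
  dictionary's b1 grid;
* magnitude (Rician) noise at a stated SNR;
* a two-group cohort (patients / controls over two sites) whose white-matter
  long-T2* fraction volumes follow configurable group means and SDs, with
  optional links to clinical covariates.

Default component relaxation times follow the tissue taxonomy a
multi-component analysis finds in vivo: a myelin-water-like pool (short T1
and T2*), the main white-matter pool (T1 970 ms), cortical (T1 1197 ms) and
deep (T1 1494 ms) gray matter, a long-T2* component (T1 1489 ms) and CSF
(T2* 2984 ms).  T2* values that are not established observations are
documented package defaults (WM 45 ms, cortical GM 46 ms, long component
1000 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .component_analysis import RegionMasks
from .image import ImageSeries
from .sequence_dictionary import DictionaryGrid, SequenceTrain, simulate_signals

__all__ = [
    "TissueComponent",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "make_phantom",
    "simulate_acquisition",
    "make_cohort",
    "DEFAULT_COMPONENTS",
]


@dataclass(frozen=True)
class TissueComponent:
    """One relaxation component: a (T1, T2*) pool with a display name."""

    name: str
    t1_ms: float
    t2star_ms: float

    def __post_init__(self) -> None:
        if self.t1_ms < self.t2star_ms:
            raise ValueError(f"component {self.name}: t1 must be >= t2*")


# (name, T1 ms, T2* ms); see module docstring for provenance of defaults.
DEFAULT_COMPONENTS = {
    "myelin": TissueComponent("myelin", 400.0, 35.0),
    "wm": TissueComponent("wm", 970.0, 45.0),
    "gm": TissueComponent("gm", 1197.0, 46.0),
    "deep_gm": TissueComponent("deep_gm", 1494.0, 55.0),
    "long": TissueComponent("long", 1489.0, 1000.0),
    "csf": TissueComponent("csf", 3900.0, 2984.0),
}

# Per-tissue component mixtures (fractions sum to 1).
DEFAULT_MIXTURES: dict[str, list[tuple[str, float]]] = {
    "wm": [("myelin", 0.15), ("wm", 0.85)],
    "gm": [("gm", 1.0)],
    "deep_gm": [("deep_gm", 1.0)],
    "csf": [("csf", 1.0)],
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue mixtures and degradation model of a digital phantom."""

    shape: tuple[int, int, int] = (64, 64, 4)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    components: dict[str, TissueComponent] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS)
    )
    mixtures: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MIXTURES.items()}
    )
    wm_long_volume: float = 0.0088  # target normalized long-T2* volume in WM
    rim_relative_fraction: float = 0.4  # rim peak relative to lesion plateaus
    myelin_gradient: float = 0.5  # relative radial modulation of the myelin pool
    n_lesions: int = 3
    lesion_radius_vox: tuple[int, int] = (1, 3)
    rim_decay_vox: float = 3.0
    b1_amplitude: float = 0.1  # peak deviation of the smooth b1 field from 1
    seed: int = 0

    def __post_init__(self) -> None:
        for tissue, mix in self.mixtures.items():
            fracs = np.array([f for _, f in mix])
            if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture for {tissue!r} must be non-negative and sum to 1")
        if not 0 <= self.wm_long_volume < 1:
            raise ValueError("wm_long_volume must lie in [0, 1)")

    def snapped(self, grid: DictionaryGrid) -> "PhantomSpec":
        """Spec with all component (T1, T2*) pairs snapped to grid points."""
        snapped = {}
        for name, comp in self.components.items():
            i = grid.nearest_pair(comp.t1_ms, comp.t2star_ms)
            snapped[name] = TissueComponent(
                name, float(grid.pair_t1_ms[i]), float(grid.pair_t2star_ms[i])
            )
        return replace(self, components=snapped)


@dataclass
class Phantom:
    """Ground truth of one synthetic subject."""

    spec: PhantomSpec
    component_names: list[str]
    components: list[TissueComponent]
    fractions: np.ndarray  # (x, y, z, n_components), sums to 1 in brain
    masks: RegionMasks
    brain: np.ndarray
    b1_field: np.ndarray
    wm_long_volume: float  # realized normalized long-T2* volume in WM

    @property
    def long_fraction_map(self) -> np.ndarray:
        return self.fractions[..., self.component_names.index("long")]


def _ellipse(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def make_phantom(spec: PhantomSpec, b1_values: np.ndarray | None = None) -> Phantom:
    """Build the digital brain phantom; deterministic given ``spec.seed``.

    ``b1_values`` (e.g. a dictionary's b1 grid) quantizes the smooth
    efficiency field so downstream solvers can group voxels by b1; without
    it the field stays continuous.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    if min(nx, ny) < 16 or nz < 1:
        raise ValueError("phantom grid too small for the built-in geometry")
    cx, cy = (nx - 1) / 2, (ny - 1) / 2

    plane = (nx, ny)
    brain2d = _ellipse(plane, (cx, cy), (0.44 * nx, 0.40 * ny))
    csf_rim2d = brain2d & ~_ellipse(plane, (cx, cy), (0.40 * nx, 0.36 * ny))
    gm2d = (
        _ellipse(plane, (cx, cy), (0.40 * nx, 0.36 * ny))
        & ~_ellipse(plane, (cx, cy), (0.33 * nx, 0.29 * ny))
    )
    vent2d = _ellipse(plane, (cx - 0.06 * nx, cy), (0.06 * nx, 0.10 * ny)) | _ellipse(
        plane, (cx + 0.06 * nx, cy), (0.06 * nx, 0.10 * ny)
    )
    deep2d = (
        _ellipse(plane, (cx, cy), (0.16 * nx, 0.20 * ny)) & ~vent2d
    )
    wm2d = (
        _ellipse(plane, (cx, cy), (0.33 * nx, 0.29 * ny)) & ~deep2d & ~vent2d
    )

    brain = np.repeat(brain2d[:, :, None], nz, axis=2)
    csf = np.repeat((csf_rim2d | vent2d)[:, :, None], nz, axis=2)
    gm = np.repeat(gm2d[:, :, None], nz, axis=2)
    deep = np.repeat(deep2d[:, :, None], nz, axis=2)
    wm = np.repeat(wm2d[:, :, None], nz, axis=2)

    # focal lesions inside white matter, away from its in-plane boundary;
    # each carries its own long-T2* plateau with a radial falloff so that the
    # lesion population spans a range of mixing ratios (endmember diversity,
    # as in vivo where lesion severity varies)
    lesions = np.zeros(spec.shape, dtype=bool)
    lesion_shape = np.zeros(spec.shape)
    eroded2d = ndimage.binary_erosion(wm2d, iterations=max(spec.lesion_radius_vox))
    candidates = np.argwhere(eroded2d)
    if spec.n_lesions > 0 and candidates.size == 0:
        raise ValueError("white matter too thin to place lesions of the requested size")
    xg2, yg2 = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for _ in range(spec.n_lesions):
        x0, y0 = candidates[rng.integers(len(candidates))]
        z0 = int(rng.integers(nz))
        r = int(rng.integers(spec.lesion_radius_vox[0], spec.lesion_radius_vox[1] + 1))
        ball2d = _ellipse(plane, (x0, y0), (r + 0.5, r + 0.5))
        sel = ball2d & wm[:, :, z0]
        severity = 0.6 + 0.4 * rng.random()  # relative plateau, 0.6-1.0
        rr = ((xg2 - x0) ** 2 + (yg2 - y0) ** 2) / (r + 0.5) ** 2
        lesion_shape[:, :, z0] = np.maximum(
            lesion_shape[:, :, z0], np.where(sel, severity * (1.0 - 0.4 * rr), 0.0)
        )
        lesions[:, :, z0] |= sel

    # long-T2* fraction field: lesion plateaus plus a rim decaying with
    # distance from ventricles and lesions (dirty-appearing white matter);
    # one global scale is solved so the WM-normalized volume hits the target
    vent3d = np.repeat(vent2d[:, :, None], nz, axis=2)
    sources = vent3d | lesions
    long_frac = np.zeros(spec.shape)
    if spec.wm_long_volume > 0:
        dist = ndimage.distance_transform_edt(~sources)
        rim = np.clip(1.0 - dist / spec.rim_decay_vox, 0.0, 1.0)
        rim *= wm & ~lesions
        raw = lesion_shape + spec.rim_relative_fraction * rim
        total = raw[wm].sum()
        if total == 0:
            raise ValueError("no white-matter voxels near ventricles or lesions")
        scale = spec.wm_long_volume * wm.sum() / total
        long_frac = scale * raw
        peak = long_frac.max()
        if peak > 0.85:
            raise ValueError(
                f"wm_long_volume target unreachable (peak fraction {peak:.2f} > 0.85)"
            )

    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    names = list(spec.components)
    index = {n: i for i, n in enumerate(names)}
    fractions = np.zeros(spec.shape + (len(names),))
    tissue_masks = {"wm": wm, "gm": gm, "deep_gm": deep, "csf": csf}
    for tissue, mask in tissue_masks.items():
        for comp_name, frac in spec.mixtures[tissue]:
            fractions[mask, index[comp_name]] += frac
    # myelin density varies across white matter (higher centrally); the
    # radial modulation keeps the myelin pool spatially identifiable from
    # the main WM pool instead of a fixed, degenerate mixing ratio
    wm_mix = dict(spec.mixtures["wm"])
    if spec.myelin_gradient > 0 and "myelin" in wm_mix and "wm" in wm_mix:
        radius = np.sqrt(((xg - cx) / (0.44 * nx)) ** 2 + ((yg - cy) / (0.40 * ny)) ** 2)
        u = np.clip(np.repeat(radius[:, :, None], nz, axis=2), 0.0, 1.0)
        m = wm_mix["myelin"] * (1.0 + spec.myelin_gradient * (1.0 - 2.0 * u))
        fractions[..., index["myelin"]] = np.where(wm, m, fractions[..., index["myelin"]])
        fractions[..., index["wm"]] = np.where(
            wm, 1.0 - m - sum(f for n_, f in wm_mix.items() if n_ not in ("myelin", "wm")),
            fractions[..., index["wm"]],
        )
    # blend the long component into white matter
    scale = 1.0 - long_frac[..., None]
    fractions *= scale
    fractions[..., index["long"]] += long_frac

    # smooth multiplicative b1 field: a broad off-center Gaussian bump
    bump = np.exp(-(((xg - 0.4 * nx) / (0.6 * nx)) ** 2 + ((yg - 0.55 * ny) / (0.6 * ny)) ** 2))
    b1 = 1.0 + spec.b1_amplitude * (2 * bump[:, :, None] - 1.0) * np.ones((1, 1, nz))
    if b1_values is not None:
        b1_values = np.asarray(b1_values, dtype=float)
        b1 = b1_values[np.argmin(np.abs(b1[..., None] - b1_values), axis=-1)]

    # geometric octant "lobe" labels within the brain (atlas stand-in)
    lobes = np.zeros(spec.shape, dtype=int)
    lobe_names: dict[int, str] = {}
    label = 0
    for xi, xname in ((xg < cx, "frontal"), (xg >= cx, "occipital")):
        for yi, yname in ((yg < cy, "left"), (yg >= cy, "right")):
            label += 1
            lobes[xi[:, :, None] & yi[:, :, None] & brain] = label
            lobe_names[label] = f"{xname}_{yname}"

    lesion_prob = np.where(lesions, 0.95, 0.0)
    masks = RegionMasks(
        white_matter=wm,
        gray_matter=gm | deep,
        csf=csf,
        lobe_labels=lobes,
        lobe_names=lobe_names,
        lesion_probability=lesion_prob,
    )
    realized = float(long_frac[wm].sum() / wm.sum()) if wm.any() else 0.0
    return Phantom(
        spec=spec,
        component_names=names,
        components=[spec.components[n] for n in names],
        fractions=fractions,
        masks=masks,
        brain=brain,
        b1_field=b1,
        wm_long_volume=realized,
    )


def simulate_acquisition(
    phantom: Phantom,
    train: SequenceTrain,
    snr: float | None = None,
    seed: int = 0,
    slice_offset_ms: float | None = None,
    noise_model: str = "rician",
) -> ImageSeries:
    """Simulate the magnitude MRF-EPI series of a phantom.

    Per voxel the noise-free signal is the fraction-weighted sum of the
    component signals at the voxel's b1 efficiency.  Noise is added at the
    stated SNR, defined as (mean in-brain peak signal) / sigma;
    ``snr=None`` gives the noiseless series.  ``noise_model`` is ``"rician"``
    (magnitude of a complex signal with Gaussian noise on both channels, the
    physical model) or ``"gaussian"`` (zero-mean additive, bias-free - for
    oracle tests that must not confound estimator bias with noise).
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noiseless)")
    if noise_model not in ("rician", "gaussian"):
        raise ValueError("noise_model must be 'rician' or 'gaussian'")
    n_frames = train.n_frames
    data = np.zeros(phantom.spec.shape + (n_frames,))
    b1_levels = np.unique(phantom.b1_field[phantom.brain])
    for ci, comp in enumerate(phantom.components):
        frac = phantom.fractions[..., ci]
        if not np.any(frac > 0):
            continue
        sigs = simulate_signals(
            train,
            np.full(b1_levels.size, comp.t1_ms),
            np.full(b1_levels.size, comp.t2star_ms),
            b1_levels,
            slice_offset_ms,
        )  # (n_frames, n_levels)
        for li, level in enumerate(b1_levels):
            sel = (phantom.b1_field == level) & (frac > 0)
            if sel.any():
                data[sel] += frac[sel][:, None] * sigs[:, li][None, :]
    if snr is not None:
        rng = np.random.default_rng(seed)
        peak = data[phantom.brain].max(axis=-1).mean()
        sigma = peak / snr
        if noise_model == "rician":
            data = np.hypot(
                data + rng.normal(0, sigma, data.shape), rng.normal(0, sigma, data.shape)
            )
        else:
            data = data + rng.normal(0, sigma, data.shape)
    voxel = phantom.spec.voxel_size_mm
    affine = np.diag([voxel[0], voxel[1], voxel[2], 1.0])
    return ImageSeries(data, affine, mask=phantom.brain)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a two-group, two-site cohort.

    Volume distributions default to the observed group statistics of the
    white-matter long-T2* normalized volume (controls 0.30% +/- 0.20%,
    patients 0.88% +/- 0.53%); draws are truncated at 0.  When
    ``edss_slope`` is set, patient volumes are generated as
    mean + slope * (EDSS - mean EDSS) + residual noise instead, keeping the
    marginal SD.
    """

    n_patients: int = 48
    n_controls: int = 12
    patients_site_a: int = 18
    patient_volume: tuple[float, float] = (0.0088, 0.0053)  # mean, sd
    control_volume: tuple[float, float] = (0.0030, 0.0020)
    patient_age: tuple[float, float] = (39.0, 10.0)
    control_age: tuple[float, float] = (26.0, 2.5)
    patient_female_frac: float = 31 / 48
    control_female_frac: float = 3 / 12
    edss_slope: float | None = None
    lesion_volume_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls) < 1:
            raise ValueError("need at least one subject per group")
        for mean, sd in (self.patient_volume, self.control_volume):
            if sd < 0:
                raise ValueError("volume SDs must be non-negative")
            if sd > 0 and mean < -5 * sd:
                raise ValueError("volume mean too far below 0 for truncation")


def _truncated_normal(rng, mean, sd, size, low=0.0):
    if sd == 0:
        return np.full(size, mean)
    a = (low - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort table ready for the statistics stage.

    Columns: id, group, site, age_years, sex, edss, disease_duration_years,
    severity_score, wm_long_volume, lesionmap_volume.  Per-subject phantoms
    for full end-to-end runs can be built by passing each row's
    ``wm_long_volume`` as a ``PhantomSpec.wm_long_volume`` target.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    n = spec.n_patients + spec.n_controls
    is_patient = np.r_[np.ones(spec.n_patients, bool), np.zeros(spec.n_controls, bool)]
    for i in range(n):
        patient = bool(is_patient[i])
        if patient:
            site = "A" if i < spec.patients_site_a else "B"
            age = float(np.clip(rng.normal(*spec.patient_age), 18, 80))
            sex = "F" if rng.random() < spec.patient_female_frac else "M"
            edss = float(np.clip(np.round(rng.gamma(2.0, 1.0) * 2) / 2, 0, 9.5))
            duration = float(rng.lognormal(np.log(5.2), 0.8))
        else:
            site = "A"
            age = float(np.clip(rng.normal(*spec.control_age), 18, 80))
            sex = "F" if rng.random() < spec.control_female_frac else "M"
            edss = np.nan
            duration = np.nan
        mean, sd = spec.patient_volume if patient else spec.control_volume
        if patient and spec.edss_slope is not None:
            resid_sd = max(sd**2 - (spec.edss_slope * 2.0) ** 2, (0.2 * sd) ** 2) ** 0.5
            vol = mean + spec.edss_slope * (edss - 2.0) + rng.normal(0, resid_sd)
            vol = float(max(vol, 0.0))
        else:
            vol = float(_truncated_normal(rng, mean, sd, 1)[0])
        lesion_vol = float(max(vol * spec.lesion_volume_ratio + rng.normal(0, 0.0005), 0.0))
        severity = int(np.clip(np.round(vol * 800 + rng.normal(0, 2.5) + 4), 0, 25))
        rows.append(
            {
                "id": f"S{i:03d}",
                "group": "patient" if patient else "control",
                "site": site,
                "age_years": age,
                "sex": sex,
                "edss": edss,
                "disease_duration_years": duration,
                "severity_score": severity,
                "wm_long_volume": vol,
                "lesionmap_volume": lesion_vol,
            }
        )
    return pd.DataFrame(rows)
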