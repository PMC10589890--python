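# Methods

`mcmrf` implements a complete multi-component MR fingerprinting (MC-MRF)
analysis chain for MRF-EPI brain data and validates it end to end on
synthetic digital phantoms with known ground truth. This note records the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Signal model and dictionary

The acquisition is a train of spoiled gradient-echo EPI frames with
frame-varying flip angle α_k, echo time TE_k and repetition time TR_k,
interleaved with global inversion pulses. With perfect transverse spoiling,
the normalized longitudinal magnetization obeys

    between events:   Mz ← 1 + (Mz − 1) · exp(−Δt / T1)
    at an excitation: Mz ← Mz · cos(b1 · α_k)
    at an inversion:  Mz ← −η · Mz

and the magnitude signal at the echo of frame k is

    s_k = M0 · |Mz⁻| · sin(b1 · α_k) · exp(−TE_k / T2*),

where b1 is the flip-angle efficiency and η the inversion efficiency
(default 1). Echo-pathway bookkeeping (EPG), diffusion and magnetization
transfer are deliberately out of model. An inversion coincident with an
excitation is applied first.

The exact per-frame schedule of the MRF-EPI protocol is not public, so
`default_train` provides a documented stand-in with the protocol's printed
envelope: flip angles sweep 34–86° as a half-sinusoid (rescaled so both
extrema are hit exactly), TE ramps linearly over 21–81.5 ms, TR over
3530–6570 ms, and inversion pulses are spaced uniformly so that their count
per minute of cumulative TR is as close as possible to 3 (13 pulses for the
default 50-frame train, which spans ≈4.2 min, in line with the protocol's
stated duration). Any other schedule can be supplied as a plain-text table.

Dictionaries tabulate the L2-normalized signals on a geometric grid: T1 from
30 to 4000 ms and T2* from 5 to 3000 ms in 5% multiplicative steps (every
value ≤ the upper bound is kept, giving 101 × 132 values), crossed with
efficiencies 0.65–1.35 in steps of 0.05. Excluding T1 < T2* leaves 8,772
admissible pairs, hence 131,580 atoms. Pre-normalization norms are stored so
M0 can be recovered from inner products. `compress` provides the usual SVD
subspace truncation; inner products in rank-r space are exact up to the
(r+1)-th dictionary singular value.

## Denoising

`mppca_denoise` applies Marchenko–Pastur PCA per slice and across
timeframes in square patches (default radius 7, i.e. 15×15 voxels, clipped
at slice borders; sliding stride 1 with uniform averaging of overlapping
reconstructions). For a patch Casorati matrix (M voxels × N frames) the
smallest signal rank r is selected for which the trailing eigenvalue bulk is
compatible with the Marchenko–Pastur law: spread ≤ 4·σ̂²·√((N−r)/M) with σ̂²
the bulk mean, widened by a 5% slack that absorbs the finite-size
(Tracy–Widom) fluctuation of the bulk edge. Noise is treated as Gaussian on
the magnitude data; the Rician bias is not corrected and is documented as a
known bias source at low SNR.

## Single-component matching and the brain mask

Every voxel is matched to the atom maximizing the absolute normalized inner
product (ties broken toward the lowest entry index, i.e. lexicographically
in (b1, T1, T2*)). M0 is the inner product divided by the atom's stored
norm; relative M0 divides by the image's 99th M0 percentile (robust to
bright outliers). The brain mask is the largest 26-connected component of
{relative M0 > 5%}.

Matching in rank-10 compressed space selects atoms that are equivalent as
signals to the full-space choice (cosine ≥ 0.999 in all measurements), but
the selected *indices* can differ inside the long-T2* plateau where
neighbouring atoms differ by less than the truncation error; parameter maps
in that region should be read with that degeneracy in mind.

## Joint-sparse multi-component decomposition

With per-voxel b1 fixed, all voxels share one (T1, T2*) pair index and the
multi-component problem is row-sparse: find weights C ≥ 0 with

    min_C Σ_j ‖D_j c_j − x_j‖² + λ_abs Σ_i log(1 + ‖C_i·‖² / ε²),

whose log penalty charges each globally active component a near-constant
λ_abs — an ℓ0-flavoured count. It is solved by iteratively reweighted NNLS:
each sweep solves per voxel the Tikhonov-weighted NNLS with weights
w_i = r_i² + ε_k² (r_i the previous row norms, initialized at 1), the
standard majorize–minimize surrogate of the log penalty. The smoothing ε_k
anneals from the largest row norm down to 10⁻⁴ of it (halving per sweep),
which stabilizes support selection on this strongly coherent dictionary;
with annealing disabled the monitored objective is provably non-increasing
under exact inner solves, and the tests verify this. Rows that collapse are
pruned; convergence is declared when the support is unchanged and row norms
move by less than 10⁻⁴ relative.

λ is normalized as λ_abs = λ_norm · (mean in-mask per-voxel signal energy) /
n_pairs, making λ_norm invariant to image scaling; the default λ_norm = 11
refers to the native 5%-step grid, and `equivalent_lambda_norm` rescales it
so the per-component charge is unchanged on coarser desk-scale grids.

Two inner solvers share the contract: exact Lawson–Hanson NNLS on the
augmented system for small grids, and a batched strongly convex FISTA
(momentum (1−√(μ/L))/(1+√(μ/L)), warm-started across sweeps) vectorized
over voxels for full grids. Support discovery runs on a deterministic
shape-stratified voxel subsample (signals binned on their leading normalized
compressed coordinates with a per-bin cap, so rare tissues such as small
lesions survive the thinning); the per-component charge is scaled by the
subsample fraction to keep the trade-off unchanged.

Because adjacent atoms are nearly collinear, the annealed iterations can
settle a few grid steps from the best support. A final polish therefore
refines the support at fixed size by best-improvement swaps against (a) the
radius-2 grid neighbourhood of each component and (b) matched-filter
"teleport" candidates scored in the orthogonal complement of the kept
components — accepting a swap only when the exact joint NNLS residual (in a
rank-30 subspace, where the fine shape distinctions survive) decreases. The
surviving support is re-fit per voxel by unregularized NNLS over all voxels,
weights are divided by atom norms (M0 scale) and normalized per voxel to
magnetization fractions; all-zero voxels are flagged and excluded.

### Alternating b1 refinement

Single-component matching biases b1 wherever voxels mix tissues (the
compromise atom trades T1 against b1); on phantoms this bias alone prevents
the true component set from fitting the data. `reestimate_b1` therefore
re-estimates each voxel's efficiency as the grid value minimizing its NNLS
residual over the found support, and `run_pipeline` runs the joint solve in
two such alternating passes by default. On noiseless phantoms this recovers
the exact b1 field and, subsequently, the exact component set.

## Derived measures

Long-T2* components are those with 500 < T1 < 2500 ms and
500 < T2* < 2500 ms (open intervals); their fraction maps are summed into a
single map. Regional volumes are fraction sums over (white matter ∩ region)
divided by the region's voxel count — a number in [0, 1] in which voxel
anisotropy cancels; the 15% threshold is used only for lesion-overlap
scoring (Dice, both volumes, and the fraction of suprathreshold voxels
outside the lesion mask). Lesion masks are probability maps thresholded at
0.5. Component scatter across subjects is grouped by k-means on
(log T1, log T2*) with a fixed seed and multiple restarts; reported
per-cluster means and SDs are arithmetic, in milliseconds.

## Cohort statistics

Group comparisons use OLS (Gaussian family, identity link) of
volume ~ group + age + sex with group coded control = 0 / patient = 1, so a
positive coefficient means a larger volume in patients; Wald 95% CIs.
Constant covariates drop out, so the model degenerates gracefully to a
two-sample t-test. Severity associations use partial Spearman correlation
(rank-transform, residualize on covariate ranks, Fisher-z CI; average ranks
for ties; a single-level covariate reduces exactly to ordinary Spearman).
Method agreement uses a paired t-test; identically zero differences return
NaN by convention, constant non-zero differences raise. Secondary
regressions fit each predictor one at a time. No multiple-testing
correction is applied (each test reported at α = 0.05), matching common
practice for a primary-plus-secondary analysis plan.

## Synthetic data

The digital phantom is a stack of elliptical brain slices (default 64×64×4,
1×1×2 mm voxels): a CSF rim, a cortical gray-matter band, white matter,
deep gray matter around two CSF ventricles, focal white-matter lesions, and
octant "lobe" labels standing in for an atlas parcellation. Tissue
mixtures reference a component table defaulting to a myelin-water-like pool
(T1 400 / T2* 35 ms), white matter (970 / 45 ms), cortical gray matter
(1197 / 46 ms), deep gray matter (1494 / 55 ms), a long-T2* component
(1489 / 1000 ms) and CSF (3900 / 2984 ms). Only the component T1s and the
CSF T2* are established observations; the remaining T2* values are package
defaults. The myelin fraction of white matter carries a radial density
gradient (0.5 relative modulation around 15%), because a spatially constant
mixing ratio would make the myelin and white-matter pools a single
effective atom — unidentifiable in principle.

The long-T2* fraction field combines per-lesion plateaus (relative severity
0.6–1.0 with an internal radial falloff) and a rim decaying with distance
from ventricles and lesions (dirty-appearing white matter); a single global
scale is solved so the white-matter-normalized volume hits the requested
target exactly. This concentrates the component at fractions above the 15%
overlap threshold inside lesions, consistent with its observed strong
correspondence to visible lesions; spreading the same volume thinly makes
the component mathematically unidentifiable (a support without it then fits
the data better than the truth).

Acquisitions are simulated as fraction-weighted sums of component signals
at the voxel's efficiency (a smooth b1 bump quantized to the dictionary
grid), with Rician noise at a stated SNR (mean in-brain peak signal over
sigma). A zero-mean Gaussian noise mode exists for oracle tests that must
not confound the Rician magnitude bias with noise sensitivity: the bias
(~σ²/2s on weak frames) is orders of magnitude larger than the shape
margins separating adjacent long-T2* atoms, so it dominates localization
error under the physical noise model.

Cohorts sample 48 patients (18 site A, 30 site B) and 12 controls (site A)
with ages, sex ratios, EDSS and disease-duration distributions mirroring
the study demographics, and white-matter long-T2* volumes drawn from
truncated normals with group means/SDs 0.88%/0.53% (patients) and
0.30%/0.20% (controls); an optional EDSS slope (e.g. 0.00117 per EDSS
point) can generate the volumes instead. A companion "lesion-map volume"
column (a noisy fraction of the MC-MRF volume) feeds the paired comparison.

## Validation scales and what passes means

All heavy validations run at desk scale on one CPU: 10%-step dictionaries
(2,311 pairs; λ rescaled by `equivalent_lambda_norm`), 48×48×2 phantoms for
the end-to-end round trip and noise-recovery studies, 32×32×1 for the
regularization sweep; the full 131,580-entry protocol dictionary is used
where cheap (cardinality, noiseless matching). The noiseless end-to-end
round trip recovers the ground-truth white-matter long-T2* volume to
~10⁻¹⁰ with the two-pass pipeline — machine-precision agreement, not just
the 0.002 tolerance asserted.

Known information limits, measured on these phantoms and documented rather
than hidden:

* the protocol's signal shapes for T2* ≥ ~300 ms differ by well under 1%
  (0.38% between 150 ms and 1 s at T1 = 1 s), so the long component's T2*
  coordinate is localized only to within a few grid steps under noise,
  although reliably inside the (500, 2500) ms selection box;
* the myelin-water-like pool contributes only a few percent of voxel signal
  energy at these echo times, so its T1 cannot be pinned to one grid step
  at SNR 50 — its fraction map, however, is recovered to ~0.02 mean
  absolute error;
* single-component matches under noise move along (T1, T2*, b1) trade-off
  manifolds on which the signal shape is invariant (chosen atoms stay
  signal-equivalent to truth at cosine ≥ 0.999).

The phantoms are piecewise-elliptical, share one slice timing, and contain
no motion, distortion, B0 effects or physiological noise; passing tests
demonstrate the correctness and calibration of the algorithms under the
stated signal model, not performance on scanner data.

## Limitations

* The sequence schedule is a documented stand-in; absolute signal shapes
  (and hence dictionary-specific degeneracy structure) will differ from any
  specific scanner protocol.
* The joint-sparse solver is a log-penalty IRLS with annealing and discrete
  polish; it inherits the usual caveats of non-convex sparse recovery on
  coherent dictionaries (support positions are exact only when the data
  identify them).
* Rician bias is neither corrected nor modelled in the fit.
* Per-slice timing offsets are supported by the simulator and dictionary
  builder but the phantom studies use a single slice timing.
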