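# mcmrf

Multi-component MR fingerprinting (MC-MRF) relaxometry for MRF-EPI brain
data, built to quantify diffuse white-matter changes — such as those seen in
multiple sclerosis — that extend beyond the lesions visible on conventional
images.

Standard MR fingerprinting matches each voxel's transient-state signal
evolution to a dictionary of simulated signals, assigning a single (T1, T2*)
per voxel. That single-compartment view breaks down in partial-volume and
microstructurally damaged tissue. `mcmrf` instead models each voxel as a
non-negative mixture of a *small, globally shared* set of components,

    x_j ≈ Σ_i c_ij · d(T1_i, T2*_i, b1_j),      c_ij ≥ 0,

found by a joint-sparsity solve over all brain voxels (an iteratively
reweighted NNLS with an ℓ0-like log penalty on component row norms, plus a
discrete support-polish step). The components with long relaxation times
(500 < T1 < 2500 ms, 500 < T2* < 2500 ms) form a free-water-like map whose
white-matter-normalized volume is the marker of interest; a statistics layer
compares it between groups adjusted for age and sex, correlates it with
clinical scores across sites, and checks agreement with lesion-map volumes.

The package covers the full chain:

* `sequence_dictionary` — transient-state Bloch simulation of MRF-EPI
  trains; logarithmic (T1, T2*) × linear b1 dictionary grids (the protocol
  grid has 131,580 atoms); SVD compression.
* `denoise` — Marchenko–Pastur PCA denoising in sliding spatial patches,
  with noise-level maps.
* `matching` — single-component matching (T1, T2*, b1, M0 maps) and the
  relative-M0 brain mask.
* `spijn_mc` — the joint-sparse multi-component solver, with alternating
  per-voxel b1 refinement.
* `component_analysis` — long-T2* selection and merging, k-means component
  grouping, regional fraction volumes, lesion-overlap scores.
* `cohort_stats` — group GLMs, site-adjusted partial Spearman correlations,
  paired volume tests, secondary regressions.
* `synthetic_data` — digital brain phantoms with known ground truth
  (tissue mixtures, lesions, a dirty-appearing rim, smooth b1 fields,
  Rician noise) and synthetic two-site cohorts; these stand in for the
  in-vivo data, which are not public.

## Worked example

Simulate a patient-like phantom, run the pipeline, and quantify the
long-T2* component (about two minutes on one CPU):

```python
from mcmrf import (PhantomSpec, SpijnConfig, build_dictionary, build_grid,
                   default_train, equivalent_lambda_norm, make_phantom,
                   mask_and_volume, run_pipeline, simulate_acquisition)

train = default_train(50)
grid = build_grid((30, 4000), (5, 3000), 0.10, (0.9, 1.1), 0.05)  # desk scale
dictionary = build_dictionary(train, grid)

spec = PhantomSpec(shape=(48, 48, 2), seed=1, lesion_radius_vox=(1, 1)).snapped(grid)
phantom = make_phantom(spec, b1_values=grid.b1_values)
series = simulate_acquisition(phantom, train, snr=None)

cfg = SpijnConfig(lambda_norm=equivalent_lambda_norm(grid))
result = run_pipeline(series, dictionary, spijn_cfg=cfg)

print("components (T1 ms, T2* ms):")
for t1, t2s in result.solution.components:
    print(f"  ({t1:7.0f}, {t2s:6.0f})")
vol = mask_and_volume(result.long_fraction_map, phantom.masks, "all")
print(f"white-matter long-T2* volume: {vol:.5f} (truth {phantom.wm_long_volume:.5f})")
```

prints

```
components (T1 ms, T2* ms):
  (    576,     41)
  (   1020,     45)
  (   1234,     45)
  (   1494,   1384)
  (   1494,     54)
  (   3874,   2967)
white-matter long-T2* volume: 0.00892 (truth 0.00880)
```

The six recovered components are the phantom's ground-truth pools
(myelin-water-like, white matter, cortical and deep gray matter, the
long-T2* component, CSF), each within a few grid steps of its true
relaxation times — the residual offsets sit along the protocol's
near-degenerate shape directions — and the normalized white-matter volume
of the merged long-T2* map, the quantity compared between patients and
controls, is reproduced to 1.2·10⁻⁴, far inside the 0.002 tolerance the
round-trip test asserts. `docs/methods.md` describes the models, the
solver, and the measured information limits under noise.

For cohort-level questions, `make_cohort` draws a two-site patient/control
table whose volumes follow configurable group distributions, and
`glm_group`, `partial_spearman`, `paired_volumes_test` and
`secondary_regressions` provide the statistics stage:

```python
from mcmrf import CohortSpec, glm_group, make_cohort
table = make_cohort(CohortSpec(seed=0))
print(glm_group(table, "wm_long_volume"))
# {'b': 0.00577, 'ci95': (0.00212, 0.00941), 'p': 0.00249, 'n': 60}
```

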