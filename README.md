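# wallfibril3d

Quantitative analysis of fibrillar plant cell-wall architecture in
electron tomograms.

Growing (primary) plant cell walls are built from layered lamellae of
cellulose microfibrils — long, near-parallel filaments a few nanometres
thick — tethered by short hemicellulose/pectin cross-links. Electron
tomography resolves this network in 3D, but turning a noisy, missing-wedge
reconstruction into numbers requires a chain of image analysis: denoise,
segment, skeletonize, classify, measure. `wallfibril3d` implements that
chain as a tested, reproducible pipeline for wall biologists and electron
microscopists, and ships a synthetic phantom generator so every stage can
be validated by parameter recovery on volumes with known geometry.

## What it computes

For each analysis region the pipeline reports, in nm:

* **d** — microfibril cross-sectional diameter (local half-amplitude
  width at sampled cross-sectional planes);
* **g_c**, **g_e** — centre-to-centre distance and edge-to-edge gap of
  neighbouring microfibrils within a lamella (satisfying
  g_c = g_e + (d_i + d_j)/2);
* **ℓ** — surface-to-surface length of cross-links bridging adjacent
  lamellae.

Group comparisons use notched boxplots: the notch is
median ± 1.57·IQR/√n (≈ a 95% confidence interval of the median), and two
groups are called significantly different exactly when their notches do
not overlap.

The stages behind the measurements: nonlinear anisotropic diffusion
denoising (structure-tensor-driven, intensity-conserving), normalised
thresholding (semi-automated with a sensitivity sweep, or automated via
the contour spectrum), topology-preserving 3D thinning to a curve
skeleton, graph classification into fibrils and cross-links, and seeded
cross-sectional plane sampling. See `docs/methods.md` for the model,
parameters and calibrations.

## Worked example

Generate a synthetic frozen-hydrated ("cryo") wall volume, analyse it,
and print the recovered statistics:

```python
from wallfibril3d import (make_preset, generate_wall_phantom,
                          apply_imaging_model, analyze_roi)
from wallfibril3d.metrology import AnalysisROI, AnalysisConfig

spec = make_preset("cryo", shape_voxels=(160, 160, 48), seed=7,
                   snr=3.0, psf_sigma=1.0, missing_wedge_halfangle_deg=60.0)
clean, truth = generate_wall_phantom(spec)       # geometry + ground truth
vol = apply_imaging_model(clean, spec, truth)    # PSF, wedge, noise

table, prov = analyze_roi(vol, AnalysisROI(group="cryo", seed=0),
                          AnalysisConfig(polarity="dense_dark", seed=1,
                                         n_planes=3))
print(table.groupby("type")["value_nm"].agg(["mean", "count"]).round(2))
print("generated:", round(truth.diameters().mean(), 2), "nm diameter,",
      round(truth.drawn_gaps.mean(), 2), "nm gaps,",
      round(truth.crosslink_lengths().mean(), 2), "nm cross-links")
```

```
                mean  count
type
center_dist    12.45     25
crosslink_len   3.91     15
diameter        5.53     58
edge_gap        6.75     25
generated: 5.16 nm diameter, 6.43 nm gaps, 5.11 nm cross-links
```

Despite SNR 3, a 1 nm point-spread blur and a ±60° missing wedge, the
recovered diameter (5.53 vs 5.16 nm generated) and in-lamella gap (6.75
vs 6.43 nm) sit within half a voxel of the generated values; the
cross-link mean (3.91 vs 5.11 nm) is noisier at a single ROI's n = 15 and
stabilises when several ROIs are pooled, which is how the validation
experiments run. `prov` carries the full provenance (threshold used,
component/skeleton/classification counts, plane ids).

The same workflows are available from the shell:

```bash
wallfibril3d phantom --preset cryo --seed 7 --shape 160 160 48 --out demo/
wallfibril3d run --preset cryo --seed 7 --rois 3 --shape 160 160 48 --out run/
wallfibril3d sweep --preset cryo --seed 7 --out sweep/     # threshold sensitivity
wallfibril3d compare --group-a wt/measurements.csv \
                     --group-b mutant/measurements.csv --out cmp/
wallfibril3d recover --run-dir run/                        # vs ground truth
```

Real volumes are read from MRC/CCP4 maps (voxel size from the header) or
TIFF stacks (`--voxel-size` in nm required).

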