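# Methods

`wallfibril3d` quantifies the fibrillar architecture of growing plant cell
walls in electron tomograms: it denoises a reconstructed density volume,
segments the wall material, reduces it to a curve skeleton, classifies the
skeleton into cellulose microfibrils and short hemicellulose/pectin
cross-links, and measures four geometric quantities in nm — fibril
cross-sectional diameter *d*, centre-to-centre spacing *g_c* and
edge-to-edge gap *g_e* of neighbouring fibrils within a lamella, and
cross-link length *ℓ*. Group differences are judged with notched
boxplots. Because no tomograms of this kind are publicly deposited, the
package ships a synthetic phantom generator whose parameters are the
printed measurements of the study conditions; every stage is validated by
recovering those parameters from rendered, degraded volumes.

## The phantom generator

A phantom is a layered network of near-parallel cylinders:

* **Fibrils** are straight soft-edged cylinders (density ramps from the
  feature level to background over one voxel) running along the y axis,
  with per-fibril angular jitter of 1.5° rms — the walls' "nearly
  parallel" texture. Diameters are truncated-normal draws (floor 2.2 nm);
  within a lamella, surface-to-surface gaps are truncated-normal draws
  (floor 2.0 nm) anchored at the ROI mid-plane. Rigid rods cannot
  interpenetrate: placement enforces ≥ 0.8 nm clearance against the
  previous fibril and the lamella below, lifting the anchor if redraws
  fail.
* **Lamellae** stack along the beam (z) axis. Their spacing is derived
  from the cross-link length distribution
  (`layer_spacing_mean = max(2.2, ℓ_mean − ℓ_sd) + d_mean`, sd 0.5 nm):
  cross-links tether fibrils across the narrow inter-lamellar clearance,
  which in every study condition is smaller than the in-lamella spacing
  (e.g. chemically-prepared walls: 17 nm lateral gaps but 5.6 nm
  cross-links). Treating the printed cross-link lengths as realized
  bridge lengths therefore forces bridges to join *adjacent lamellae*;
  this is the one place where the generator interprets, rather than
  copies, the printed numbers.
* **Cross-links** are short cylinders (2.5 nm diameter) between
  adjacent-lamella fibril surfaces. Each link's surface-to-surface
  length is drawn *first* from the preset distribution and an attachment
  site is then sought whose local clearance supports a bridge of that
  length at bounded obliquity (chord ≤ 2 × clearance, i.e. ≤ 60° from
  the lamella normal); drawing first keeps the realized lengths an honest
  sample of the preset distribution (residual truncation ≲ 5%).
  The expected count is `crosslink_density` per fibril per 100 nm
  (default 1.0 — chosen so a study-scale volume carries on the order of
  the study's n = 90 measured links).
* **Imaging**: isotropic Gaussian PSF (default σ = 1 nm); the single-axis
  missing wedge (tilt axis y, beam z) zeroes spatial frequencies with
  `|k_z| > tan(halfangle)·|k_x|`, producing the familiar axial
  elongation; i.i.d. Gaussian noise with σ = contrast/SNR (the rasterizer
  contrast is 1); stained mode plants bright artifact blobs and images
  dense material bright, cryo mode images it dark (the volume is negated)
  at lower SNR.

The ground truth records every primitive (axes, radii, attachment points,
neighbour-pair distances with the exact identity
`centre = edge + r_i + r_j`) so tests can score recovery exhaustively.

What the phantoms deliberately omit: membranes and organelles, section
compression, knife marks, crevasses, fibril kinking or branching, radius
variation along a fibril, and tilt-series/reconstruction artifacts other
than the missing wedge. Passing recovery tests therefore demonstrates the
measurement chain is unbiased under controlled degradation — not that
segmentation of arbitrary real tomograms is solved.

## Filtering

`nad_filter` is divergence-form nonlinear anisotropic diffusion
`∂u/∂t = div(D ∇u)` with `D = I + (g₁−1) v₁v₁ᵀ` built per voxel from the
structure tensor `J = G_{σw} * (∇u_{σd} ∇u_{σd}ᵀ)` (σ_d = 1 voxel,
σ_w = 3 voxels — the feature scale of 3–5 nm fibrils at 0.87 nm/voxel).
The edge-stopping function is the exponent-8 form
`g(s) = 1 − exp(−3.315/(s/K)⁸)`; K is expressed in units of the volume's
own background gradient level (median smoothed-gradient magnitude,
measured at the first iteration and frozen), default 1.0. A hybrid mode
switches voxels whose planar coherence `λ₂−λ₃` exceeds the edge contrast
to coherence-enhancing diffusion; the pipeline default is pure
edge-enhancing mode — in testing, coherence enhancement manufactured
coherent noise ridges that were later misread as cross-links. The
explicit scheme uses antisymmetric face fluxes with zero boundary flux,
so total intensity is conserved to float accuracy (asserted each run);
time step 0.15 (the 3D stability bound), default 10 iterations.

`orientation_smooth` (the automated route) is a normalised anisotropic
Gaussian average elongated along the local minor eigenvector v₃
(σ_along = 3 nm, σ_across = 0.9 nm), implemented by quantising v₃ onto 13
hemisphere directions and convolving once per direction.

## Segmentation

Volumes are standardised (zero mean, unit SD, dense material positive —
cryo volumes are negated first) and thresholded; components below 27
voxels (a ~2.6 nm cube) are dropped. The default operating threshold is
0.65 SD — the level at which, across all presets, the visible wall
density separates from background the way the study describes its
visually chosen level; a sensitivity offset δ sweeps around it. The
automated route instead picks the isovalue from the contour spectrum
(the sampled isovalue whose isosurface carries the largest mean gradient
magnitude, restricted to isovalues enclosing 2–60% of the volume — the
restriction keeps the criterion from chasing the high-gradient residual
core of a feature).

## Skeletonization and classification

Thinning is directional-border simple-point deletion: six fixed border
directions × eight voxel-parity classes per pass (equal-parity voxels are
never 26-adjacent, so batch deletion is provably equivalent to sequential
deletion — the result is deterministic), with the Malandain–Bertrand
simple-point characterisation (one 26-connected foreground component in
N26 and one 6-connected background component in N18 touching a face
neighbour) and line-end protection. Component count and loop count are
preserved exactly (verified against an Euler-characteristic
voxel-counting oracle).

The skeleton becomes a multigraph (junction voxels clustered, since
one-voxel corners otherwise spawn spurious triangle nodes); leaf edges
shorter than 5 nm are pruned with the longest edge per component
protected. Long edges are pre-split where they climb steeply (|dz/ds| >
0.35) between lamellae — a tether and a faint fibril stretch often merge
into one edge. Fibrils are maximal chains of mutually-continuing edges
(junction stubs < 4 nm chain freely) within 45° of the dominant
orientation, ≥ 20 nm long, straight to ≤ 0.9 nm rms about their line fit
(wavier ridges are noise or stain blobs); nearly-collinear fragments
separated by ≤ 14 nm tracing gaps are stitched back together, with the
gap interpolated. Lamella indices come from a histogram split of fibril
heights (gap > 3.5 nm starts a new lamella; isolated heights cannot
bridge a split).

Cross-links are recovered from everything the chains did not consume:
each remaining path is scanned geometrically for the places where it dips
within attachment distance of two different fibril axes (endpoint nodes
count as attachments too); the sub-path between consecutive
distinct-fibril attachments is a bridge candidate, gated by height offset
2.5–13 nm (adjacent lamellae), tortuosity ≤ 1.25, tilt ≤ 60° from the
lamella normal, and surface-to-surface length ≤ 15 nm. The
surface-to-surface length is the chord between the two points where the
path pierces the fibril surfaces (sub-step interpolated); the pierce
radius comes from a local half-amplitude EDT — the fibril's neighbourhood
re-thresholded at its own half level — which tracks the surface the
bridge actually meets, uniformly across contrast modes. At most three links per fibril pair are
kept, chosen by axial position so the cap cannot bias the lengths.

At ~2 nm effective resolution with a ±60° wedge, a noise bridge across
the 2.5–3.5 nm inter-lamellar clearance is locally indistinguishable from
a genuine tether: link-level precision is therefore limited (~0.5–0.6 at
SNR 3) even though the *population statistics* of detected links recover
the generated distribution — which is the quantity the study reports.
The extraction-control preset (no tethers at 17 nm spacings) still yields
zero detections because there the lamellae are far apart.

## Measurements

Cross-sectional planes (default 2 per ROI; the validation experiments use
3) are drawn uniformly over the central 80% of the extent along the
dominant fibril orientation; crossings whose tangent lies within 20° of
the plane are skipped (oblique sections inflate every measure).

* **Diameter**: the half-level width of the density profile along the
  lateral axis through the crossing — the level midway between the local
  peak and the profile background, sub-step interpolated. Measuring on
  the feature's own amplitude removes the bias a single global threshold
  puts on faint (blurred or wedge-attenuated) fibrils; the lateral
  direction is immune to the wedge's axial elongation; and the
  continuous read-out keeps group medians stable (a distance-transform
  read-out snaps to discrete values). The sensitivity offset δ shifts
  the level too, so an operator's threshold variation propagates into
  the measurement as in a manual workflow (|δ| ≤ 0.05 SD moves
  diameters < 0.5 voxel; ±0.15 SD ~1–2 voxels, monotonically).
  Per-crossing bias +0.2–0.5 ± 0.9 nm at SNR 3 (PSF broadening);
  a mask-EDT fallback, calibrated on rasterized-cylinder oracles,
  serves binary fixtures.
* **Spacing**: within each lamella, each crossing pairs with its next
  lateral neighbour (direction within 20° of the lateral axis — robust
  against phantom chains at intermediate heights). Detected-but-untraced
  objects block pairing three ways: a mask corridor check, "virtual"
  crossings extrapolated from chains that stop short of the plane, and
  crossings of short (< 40 nm) untrusted chains. g_c is the distance
  between skeleton crossings (bias +0.14 ± 0.5 nm); g_e is measured
  independently on the density profile along the centre-connecting line
  at local half-amplitude levels (+0.05 ± 0.45 nm) — for convex
  cross-sections the shortest gap lies on this line. A robust screen
  drops pairs whose g_c is beyond ±2.5 MAD of the per-ROI population
  (a missed fibril doubles a spacing; an intruding object halves it).
* **Cross-link length**: from the classified bridge set, as above.
* The cylinder-pair identity `g_c = g_e + (d_i+d_j)/2` is exact in the
  ground truth and holds on noiseless phantoms to about one voxel; at
  SNR 3 per-pair measurement noise exceeds one voxel, so the identity is
  a noiseless contract, not a noisy-data filter (as a filter it would
  preferentially drop close pairs and bias the gap upward).

## Statistics

`boxplot_stats` uses quartiles by linear interpolation of order statistics
(positions 1 + (n−1)p), Tukey whiskers (extreme data within 1.5 IQR), and
the notch `median ± 1.57·IQR/√n`; two groups differ significantly exactly
when their notches are disjoint — the study's stated inference rule, with
no additional hypothesis test. `threshold_sensitivity` re-runs the whole
per-ROI analysis at threshold offsets δ ∈ {−0.15, −0.05, 0, 0.05, 0.15}
SD and reports mean shifts relative to δ = 0 (the δ = 0 row is the
reference analysis itself, bit-identical).

## Validation experiment sizes

The study analysed ROIs of 500 × 500 × Z voxels (Z ∈ {50, 75, 100}) at
0.87 nm/voxel. The package's validation experiments run the same design
at 160 × 160 × 48 voxels (224 × 224 × 56 for the sparse
chemically-prepared geometry, whose 17 nm spacings need a wider field to
pool ≥ 60 measurements), four ROIs and three planes per condition, with
SNR 3, 1 nm PSF and a ±60° wedge. Phantom statistics are size-invariant;
only the measurement counts shrink. The two-group comparison draws n = 60
measurements per group per repeat, as in the study's mutant comparison,
pooling two 128 × 128 × 40 phantom ROIs per group — a single small
phantom holds too few independent fibrils for a stable median.

## Determinism and numerics

Every stochastic step takes an explicit integer seed (one generator
stream per phantom; plane sampling and noise are seeded separately).
Reflecting boundaries for all convolutions; eigen-ties in the structure
tensor resolved by raster-order alignment; thinning, graph tracing and
classification are fully deterministic, so identical configs give
bit-identical measurement tables. Degenerate inputs (constant volumes,
empty masks, all-background ROIs) return empty results or raise the
documented errors rather than crashing.

## Known limitations

* Bridge-level precision/recall at SNR 3 is resolution-limited (see
  above); only population statistics of cross-links should be trusted.
* In the repeated two-group comparison at desk scale, each repeat's
  phantom pair carries finite-fibril median variance plus per-phantom
  measurement-median offsets of a few tenths of a nm; the diameter notch
  test consequently flags a spurious difference in roughly 1 repeat in 7
  even though the generated diameter populations barely differ (the
  notch rule applied to ideal draws from those populations almost never
  does).
* The generator's fibrils are straight and of constant radius; diameter
  variation along real microfibrils is not modelled.
* The missing wedge is applied as a hard Fourier mask about one axis;
  dual-axis acquisition and CTF effects are out of scope.
* Chemical identity of the classified structures is not inferred — the
  classes are geometric.
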