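# Methods

## Signal models

**DTI.** The tensor is estimated from the b = 0 and b = 1000 s/mm² shells
only; higher shells are deliberately excluded because the mono-exponential
assumption fails there. The estimator is weighted linear least squares on
the log-signal: one ordinary pass, then one reweighting pass with weights
equal to the squared predicted signal. This is deterministic and removes
most of the heteroscedasticity bias of the log transform. Negative
eigenvalues are clamped to zero and the voxel flagged (`clamped`), not
refitted. FA = √(3/2)·√Σ(λᵢ−λ̄)² / √Σλᵢ² and trace = Σλᵢ; trace is reported
raw (not divided by 3), a convention correlations are invariant to.

**Biexponential.** Two Gaussian tensor compartments share one eigenvector
frame (fast/slow ordered by mean diffusivity, enforced by relabeling after
the fit), plus an isotropic CSF term with D_iso fixed at 3.0·10⁻³ mm²/s by
default (free via config). The fit is box-constrained nonlinear least
squares on the **linear** signal (Gaussian objective, not a Rician
likelihood — adequate at SNR ≥ 20 and much simpler; a documented
limitation), multi-start: one DTI-seeded start plus jittered restarts, best
residual kept. Eigenvalues are constrained to [10⁻⁶, 4·10⁻³] mm²/s.

MSD and RTOP come from the Gaussian-mixture propagator of the *tissue*
part only — the point of modeling CSF is to remove it before deriving
measures:

* MSD = 2τ [w tr(D_f) + (1−w) tr(D_s)]   (mm²)
* RTOP = (4πτ)^(−3/2) [w det(D_f)^(−1/2) + (1−w) det(D_s)^(−1/2)]  (mm⁻³)

τ is the effective diffusion time, default 0.030 s (a typical spin-echo
value). It is not identifiable from the data used here and every
correlation result is invariant to it (a monotone common rescaling).

**Identifiability.** With *isotropic* compartments, a 3-shell + b0 protocol
provides only four distinct signal values against five or more unknowns
(S₀, f_iso, w, d_f, d_s), so the noise-free least-squares problem has a
one-dimensional manifold of exact solutions: w and the compartment
diffusivities are not individually recoverable no matter the optimizer.
Two consequences shape the defaults:

1. recovery experiments use a ground truth with an anisotropic fast pool
   and an isotropic slow pool (axial ratio 2.2:0.4 at MD 1.2·10⁻³ for the
   fast pool). This is also the natural gray-matter reading of the model —
   restricted cell-body water is nearly isotropic while the fast pool
   carries the residual tissue anisotropy — and it is the regime where a
   Cramér–Rao analysis shows the fast fraction is identifiable at SNR 40
   (bound ≈ 6% median relative error, vs ≥ 18% for isotropic truth);
2. the reduced-scale pipeline fits an isotropic model with the CSF fraction
   pinned at 0.05 and the fast fraction pinned at 0.6 (the generator
   mid-ranges). Pinning only f_iso leaves four parameters against four
   shell means — an exact interpolation whose voxel-wise MSD amplifies
   noise instead of averaging it — while the three-parameter problem is
   over-determined and stable. One deterministic DTI-seeded start is used:
   restarts merely pick arbitrarily among near-equal-cost solutions.

For that pinned isotropic configuration the fit runs as a batched
Levenberg–Marquardt with analytic Jacobian over all voxels simultaneously
(projection onto the box after each step); it is cross-checked against
per-voxel `scipy.optimize.least_squares` in the test suite and exists
because the replicate experiments fit ~10⁵ voxels per run.

## Segmentation

In printed order: enhanced = I + white-tophat(I) − black-tophat(I) with a
disk structuring element of the expected cell radius; percentile contrast
stretch (1/99); histogram-based global threshold (Otsu; a fixed-quantile
rule is available) with dark-object polarity; hole filling; removal of
components smaller than π(r/4)²; 8-connected component labeling.
Laplacian-of-Gaussian edges are generated only for QC overlays and never
feed back into the mask. One guard beyond the classic recipe: if the two
intensity classes produced by the threshold are separated by fewer than 3
pooled within-class standard deviations, the image is declared cell-free —
without this, a blank noisy section segments into spurious blobs (Otsu
always returns *some* threshold).

## Regional statistics

Two deliberately different heterogeneity definitions coexist:

* dMRI: h = (1/N²) ΣᵢΣⱼ|xᵢ−xⱼ|, the mean absolute pairwise difference with
  the i = j zeros counted in N². The implementation uses the sorted-order
  identity h = (2/N²) Σᵢ (2i−N−1) x₍ᵢ₎ and is verified against the O(N²)
  double loop. Note h is *not* a variance (it scales linearly, not
  quadratically, with the data spread);
* histology: population variance of cell area density across grid squares
  of diffusion-voxel size tiling the ROI (anchored at the ROI bounding box;
  a square qualifies when ≥ 50% of its pixels are inside the ROI). The
  regional *average* CAD is the whole-ROI fraction, not the mean of square
  densities — the two differ at partially covered squares.

Voxels with failed fits are excluded from both average and heterogeneity;
a region with fewer than two usable values gets a missing heterogeneity.

## Correlation design

Pearson r with the exact two-sided t test on n−2 degrees of freedom
(appropriate at n = 12–36; Fisher-z would be an approximation here).
Heterogeneity correlations pool all (subject, region) points and are also
split by class; average correlations run only within cortical and within
subcortical groups, because the two classes can trend oppositely and cancel
when pooled. Benjamini–Hochberg correction is applied within each
(family, group) by default, with a global option. The 36 points are treated
as independent — subjects within a region are not modeled hierarchically; a
known simplification of the design being reproduced. A volume-effect check
correlates region voxel counts with average CAD; on the default generator
the blocks are equal-sized, so this check correctly reports "not testable".

**Sign behavior.** The average–average correlations flip sign with the
coupling κ. The heterogeneity–heterogeneity correlations do *not*: every
heterogeneity statistic is a magnitude (second-moment) measure, so the
dMRI-side spread scales with |κ| and the induced correlation is positive
for either sign of a nonzero κ and zero at κ = 0. The test suite asserts
this actual behavior.

## Synthetic study generator

The generator emulates the study's *shape* — 4 subjects, 9 regions
(ACG, precentral, postcentral, STG, insula, entorhinal cortex; caudate,
putamen, thalamus) — with per-region cytoarchitecture parameters: median
cell radius (8–14 μm), radius coefficient of variation, target area density
(0.20–0.30), and a dimensionless `density_gradient` g controlling spatial
patchiness. Region parameter choices follow the qualitative literature:
entorhinal cortex patchiest, pre/postcentral with large dispersed cells,
putamen and thalamus most homogeneous.

*Histology.* Cells are 2D ellipses (axis ratio uniform in [0.7, 1] at
preserved area) with lognormal radii (median = the spec radius), placed by
random sequential adsorption under a hard-core rule (center distance
≥ 0.8(rᵢ+rⱼ), i.e. up to 20% radial overlap) with acceptance probability
modulated by a smoothed-white-noise field of correlation length one
diffusion grid square; placement stops when the painted area fraction
reaches the target, so the ground-truth density is exact by construction.
Local density has relative standard deviation 0.2·g. Rendering: dark cells
(0.30) on bright background (0.85), Gaussian blur σ = 0.6 px for the
optical PSF, additive Gaussian noise σ = 0.04. The default synthetic pixel
size is 4 μm — coarser than real slide scans — to keep runtimes desk-scale;
the scan resolution is available via config.

*Diffusion.* Each voxel draws a latent density from the same field
statistics; the link MD(d) = MD₀(1 + κ(d − d_ref)) with MD₀ = 0.7·10⁻³
mm²/s, d_ref = 0.26 and default κ = 3 sets the fast-pool MD (slow pool at
ratio 0.25); w ~ U(0.55, 0.65), f_iso ~ U(0.02, 0.08), S₀ = 100. Noise is
Rician, |S + ε₁ + iε₂| with ε ~ N(0, S₀/SNR), default SNR 40. κ = 3 was
chosen so the induced study-level hCAD–hTrace correlation sits in the
strong range reported for real tissue (r ≈ 0.7); the nuisance ranges are
narrow because gray-matter CSF contamination away from CSF borders is
modest. Per-subject jitter (10% relative, truncated at 2σ) on density and
gradient makes subjects cluster by region rather than coincide.

*What the generator does not emulate:* cortical lamination, neuron/glia
classes, vasculature, staining artifacts, 3D partial-volume structure,
registration error between modalities, and any myelin/axonal contribution
to FA or RTOP. Passing tests therefore show the *pipeline* recovers a
planted density–diffusivity coupling under realistic noise — not that FA
or RTOP would behave this way in tissue, where their drivers are largely
outside the model. In particular, synthetic RTOP is a deterministic
transform of the same diffusivity field as trace and MSD, so it inherits
their correlation with density; the weak RTOP association observed in real
gray matter reflects structure the generator deliberately omits.

## Problem sizes

The replicate experiments (power and type-I calibration) and the analysis
scripts use a reduced study: 3×3×3-voxel region blocks, a 6 b0 + 3×20
direction protocol, 240×240 px sections with 3×3 grid squares of 0.32 mm.
The full-scale defaults (6×6×6 blocks, 11 b0 + 3×60 directions, 0.8 mm
squares at 600×600 px) remain the `StudyConfig` defaults. Recovery
experiments use the full 191-measurement protocol. Monte-Carlo oracles:
10⁶ displacement samples per parameter draw for MSD; 1D trapezoid
quadrature (8001 points over ±250 mm⁻¹ per eigen-axis, separable Gaussians)
for RTOP.

## Numerical choices

* b ≤ 50 s/mm² counts as b = 0 for shell grouping.
* bvec files are accepted in both 3×M and M×3 layouts (the length-3 axis
  wins; a 3×3 file is read as FSL 3×M).
* Gradient directions are spherical-Fibonacci points on a hemisphere
  (antipodal directions are redundant for diffusion).
* Eigenvalue clamping at 0, with a per-voxel flag, instead of constrained
  refitting.
* Fast/slow relabeling by mean diffusivity after every biexponential fit;
  w is complemented when the pools swap.
* The synthetic-T2 transform is reversal → log1p → min-max rescale →
  discrete histogram equalization (256 bins); constant images return 0.5
  with a warning.
* Grid squares: ≥ 50% in-ROI coverage to qualify; squares are anchored at
  the ROI bounding-box origin.
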