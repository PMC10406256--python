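# cytodmri

Quantitative comparison of gray-matter cytoarchitecture and in-vivo
diffusion-MRI microstructure measures.

## The problem

Diffusion MRI (dMRI) measures in gray matter are indirect: before they can
be used as biomarkers of cellular structure, they need validation against
histology. This package implements, end to end, a validation pipeline that
compares regional **average** and **heterogeneity** of dMRI measures with
the analogous cytoarchitectural measures from Nissl-stained sections:

* **FA** and **trace** (Tr = λ₁+λ₂+λ₃) from the diffusion tensor model,
  fitted by weighted linear least squares to the b = 0 and b = 1000 s/mm²
  shells;
* **MSD** and **RTOP** from a biexponential model — two Gaussian tensor
  compartments sharing one eigenframe plus an isotropic CSF term,

  S(b,g) = S₀ [ f_iso e^(−b·D_iso) + (1−f_iso)( w e^(−b·gᵀD_f g) + (1−w) e^(−b·gᵀD_s g) ) ],

  with the closed-form propagator measures computed from the tissue part
  only: MSD = 2τ[w·tr D_f + (1−w)·tr D_s] and
  RTOP = (4πτ)^(−3/2)[w·det(D_f)^(−1/2) + (1−w)·det(D_s)^(−1/2)];
* **cell area density** (CAD) — the fraction of ROI area covered by cell
  bodies in a segmented section — with heterogeneity defined as the variance
  of CAD across diffusion-voxel-sized grid squares.

Regional dMRI heterogeneity uses the inter-voxel statistic

  h = (1/N²) Σᵢ Σⱼ |xᵢ − xⱼ|,

the mean absolute pairwise difference over a region's voxels (a Gini-type
mean difference; the i = j zero terms are included in the N² denominator).

Because the original animal data are not public, a first-class synthetic
study generator stands in for them: 4 subjects × 9 gray-matter regions
(6 cortical, 3 subcortical), cell bodies as hard-core-placed dark ellipses
under a smooth density field, and multi-shell diffusion signals (11 b0 +
3×60 directions at b = 1000/2000/3000 s/mm²) from the biexponential forward
model with Rician noise. A single coupling coefficient κ links local cell
density d to compartment diffusivity, MD(d) = MD₀(1 + κ(d − d_ref)), so the
histology–dMRI association the pipeline should recover is a known, tunable
ground truth.

## Worked example

```bash
python analysis/01_generate_study.py --seed 1 --out results/study
python analysis/04_regional_summary.py --seed 1 --out results
python analysis/05_correlations.py --summary results/regional_summary.csv --out results
```

prints (seed 1):

```
heterogeneity correlations over all 36 (subject, region) points:
  hCAD~hFA: r = +0.20, p = 0.23, q = 0.23
  hCAD~hTR: r = +0.74, p = 2.1e-07, q = 6.1e-07 *
  hCAD~hMSD: r = +0.74, p = 3e-07, q = 6.1e-07 *
  hCAD~hRTOP: r = +0.64, p = 2.9e-05, q = 3.8e-05 *
```

Each of the 36 points is one region in one subject. With the default
positive coupling, heterogeneity of trace and MSD track cytoarchitectural
heterogeneity strongly (q < 0.05 after Benjamini–Hochberg correction within
the family). FA correlates weakly: its biological drivers (fiber
orientation, myelin) are not modeled by cell-body density. RTOP correlates
here because in the generator it is a deterministic transform of the same
diffusivity field — in real tissue its unmodeled structural drivers
dominate (see `docs/methods.md`). Segmentation QC against
the generator's exact masks (`analysis/03_segment_histology.py`) reports
Dice ≈ 0.98 and mean cell-area-density error ≈ 0.001 at the default noise
level.

## Layout

```
src/cytodmri/     library: io, synthetic, dti, biexp, segmentation,
                  regional, correlate, study (pipeline driver)
analysis/         numbered narrative drivers writing under results/
scripts/          acceptance.py
docs/methods.md   model assumptions, parameter choices, limitations
tests/            pytest suite (unit, property, and study-level experiments)
```
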