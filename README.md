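# histodti

Voxel-wise validation of diffusion tensor imaging (DTI) against
myelin-stain histology.

High-resolution diffusion MRI promises microstructural information, but
the diffusion tensor is a blunt model: one principal axis and three
eigenvalues per voxel. How well do tensor orientations and the scalar
maps derived from them (FA, MD, RD) reflect the actual fiber
architecture? `histodti` implements the analysis pipeline that answers
this question at the level of individual voxels, by comparing diffusion
tensors fitted to a DWI volume with fiber orientation distributions
(FODs) extracted from co-registered, stained 2D sections of the same
tissue. It is written for researchers validating diffusion models
against histology, and ships a fully synthetic phantom generator so the
entire pipeline is testable end to end without any imaging data.

## Method

**Histology arm.** Per pixel of a stained section, the structure tensor

J = [[f_xx, f_xy], [f_xy, f_yy]]

is built from derivative-of-Gaussian gradients (9-px kernel, σ = 2) with
Gaussian-smoothed products; the fiber axis φ_ST is the axis of the
leading eigenvector rotated by 90° (gradients point across stripes).
Pixels are pooled into voxel-sized tiles (340 μm in the reference
acquisition); each tile yields a staining intensity (1 − mean gray
level) and a 180-bin axial orientation histogram, smoothed with a
23°-FWHM circular Gaussian and fitted greedily with up to three axial
von Mises components f(x; θ, κ) ∝ exp(κ·cos 2(x−θ)). The first
component's center is the voxel's primary orientation Φ_ST; κ maps to a
relative width 1 − κ/κ_max.

**MRI arm.** Diffusion tensors are fitted by ordinary least squares on
the log-signal, ln S = ln S₀ − b·gᵀDg; FA, MD = tr(D)/3 and
RD = (λ₂+λ₃)/2 follow from the eigendecomposition. The principal
eigenvector is projected into the sectioning (xy) plane, giving Φ_DT;
voxels tilted more than 45° out of plane are excluded.

**Comparison.** Per voxel the axis-angle difference
d(Φ_DT, Φ_ST) = min(|Φ_DT−Φ_ST|, 180−|Φ_DT−Φ_ST|) ∈ [0°, 90°] is
summarized per tissue class and per FA bin (1.96·SE confidence
intervals, bins under 100 voxels suppressed), the difference
distribution is fitted with a generalized Pareto distribution, and
correlations/multiple regressions between DTI scalars and histological
covariates are computed per section and pooled with voxel-count weights.

**Phantom.** A polygonal geometry with known fiber axes, densities and
tensor eigenvalues is rendered both as striped "stained sections" and as
a Rician-noise DWI volume (b = 3000 s·mm⁻², 60 directions from
electrostatic repulsion + 6 b=0, SNR 50). The default cortical phantom
includes a unidirectional white-matter pathway, a 60° fiber crossing,
and a gray-matter ribbon whose stained texture is tangential while the
tensor axis is radial — the configuration in which myelin and diffusion
orientations are orthogonal.

## Worked example

```python
from histodti.pipeline import run_phantom_pipeline

res = run_phantom_pipeline(seed=1)
print(res.summary_by_tissue.round(2).to_string(index=False))
print("SNR estimate: %.1f" % res.snr_estimate)
uni = res.region_records("uni")
cross = res.region_records("crossing")
print("unidirectional WM median diff: %.2f deg" % uni["diff"].median())
print("crossing WM mean diff:         %.2f deg" % cross["diff"].mean())
```

prints

```
tissue   n  mean  median   se  ci95  suppressed
    GM 128 82.92   84.55 0.52  1.02       False
    WM 256 16.31    5.81 1.17  2.29       False
SNR estimate: 50.5
unidirectional WM median diff: 3.06 deg
crossing WM mean diff:         29.09 deg
```

Reading: in the unidirectional white-matter pathway the tensor axis
matches the stained fibers to ~3° (measurement noise); in the crossing
region the tensor compromises between the two fiber populations, pushing
the mean difference to ~29°; in the gray-matter ribbon the tensor is
radial while the myelin is tangential, so differences cluster near 90°
— which is why the GM mean is a poor summary and the difference
histogram is better described by its modes. The SNR estimated from the
b=0 background corner reproduces the simulated SNR of 50.
Correlations on the same run show the expected sign structure:
corr(FA, stain) = +0.67, corr(MD, stain) = −0.69.

A command-line interface mirrors the stages:

```sh
histodti simulate --out sim/ --seed 1 --voxel-um 64
histodti hist-orient --in sim/section_000.tif --out orient/
histodti dti --dwi sim/dwi.nii.gz --bval sim/dwi.bval --bvec sim/dwi.bvec \
             --mask sim/tissue.nii.gz --out dti.csv
```

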