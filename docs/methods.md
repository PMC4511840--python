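# Methods

This note documents the models, parameter choices and numerical
decisions behind `histodti`, and what the synthetic phantom does and
does not establish about real data.

## Orientation estimation from section images

Local image orientation is estimated with the classical structure
tensor: the image is convolved with the partial derivatives of a
rotationally symmetric Gaussian (kernel size 9 px, σ = 2 px — the
defaults of the reference analysis), the gradient products f_x², f_x·f_y,
f_y² are smoothed with the *same* Gaussian (an integration scale equal
to the differentiation scale; nothing in the pipeline depends on them
being distinct), and the per-pixel 2×2 tensor is eigendecomposed in
closed form. Boundaries are handled by reflection.

Two conventions are supported. The leading eigenvector of a structure
tensor points along the dominant *gradient*, i.e. across the stained
stripes; its axis is available as `convention="gradient"`. All
downstream comparisons use `convention="fiber"` (the default): the
gradient axis rotated by 90°, which is the stripe/fiber direction. One
shared angle convention is used everywhere: axes in degrees in
[0, 180), measured from the +x (column) axis toward +y (row).

Pixels with an isotropic tensor — including blank areas, where the
gradient energy is below 1e-12 — have no defined orientation and are
excluded from all histograms rather than contributing arctan noise.

Known numerical behavior: sampled derivative-of-Gaussian kernels are
slightly anisotropic for wavelengths approaching the kernel size, which
biases recovered axes toward the nearest coordinate axis (≈2.5° for
8-px stripes, <0.5° for 16-px stripes at the default kernel). Test
gratings and phantom textures are therefore band-limited to stripe
scales ≳ 16 px; on real micrographs the analysis resolution should be
chosen so that fibers span several pixels for the same reason.

## Histological voxel space

Sections are partitioned into square tiles whose side is
`round(voxel_size / pixel_size)` pixels (340 μm against 1.3 μm pixels
in the reference acquisition, i.e. 262 px; the desk-scale phantom uses
64 μm tiles — see below). Per tile:

- **staining intensity** = 1 − mean gray level over valid pixels;
- a **180-bin orientation histogram** (1°/bin) of all defined pixel
  axes, normalized by the number of *contributing* pixels. Normalizing
  by the full tile pixel count would deflate every amplitude wherever
  the damage mask has holes, coupling FOD amplitudes to mask coverage;
  the literal total-pixel divisor remains available as
  `divisor="total"`. The valid-pixel fraction is carried separately and
  used by the damage filter.
- the histogram is denoised by **circular convolution** (wrapping at
  0/180°) with a unit-sum Gaussian of 23° FWHM; mass is conserved to
  1e-12.

### Axial von Mises mixture

The axial density f(x; θ, κ) ∝ exp(κ·cos 2(x−θ)) is normalized so the
180 one-degree bins sum to 1 (hence κ = 0 is exactly uniform and the
maximum sits at θ). Up to three components are fitted greedily:

1. θ ← argmax bin (ties to the lowest index), d ← its height;
2. κ ← argmin of the squared error between the histogram and
   d·f(x;θ,κ)/f(θ;θ,κ) over the circularly wrapped window θ ± 42°,
   by bounded scalar minimization (κ ∈ [0.01, 100], tolerance 1e-6);
3. the component curve is subtracted over all bins — residuals are not
   clipped at zero — and the loop repeats.

Greediness guarantees non-increasing amplitudes; the first component's
center is the voxel's primary orientation Φ_ST. Component widths are
1 − κ/κ_max with κ_max the maximum over all fitted components of the
analysis run (a fixed κ_max can be supplied for cross-run
comparability). A flat histogram drives κ to its lower bound; an
all-zero histogram yields an empty component list and the voxel is
flagged. Voxels are discarded when the valid-pixel fraction is < 0.05
or staining intensity < 0.02 (both configurable): tiles that are mostly
damage or contain no stained material carry no usable orientation.

All three components are always emitted; consumers decide whether to
trust the third (in practice only the first two reliably represent
fiber populations, which is why the default covariate set uses
amplitude/width of components 1–2 most heavily).

## Diffusion tensor fitting

Ordinary least squares on the log-signal with design rows
[−b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz, 1]. OLS (not
weighted, not positivity-constrained) is the deliberate baseline — it
is the plain "linear regression" fit; a WLS refinement would change
noise propagation but not the pipeline's structure. Nonpositive
signals (possible under Rician noise at high b) are clamped to the
voxel's smallest positive signal and the voxel flagged. A design with
fewer than 6 distinct non-collinear directions raises an error.

FA, MD and RD use the standard eigenvalue definitions
(MD = (λ₁+λ₂+λ₃)/3, RD = (λ₂+λ₃)/2,
FA = √(3/2)·‖λ−MD‖/‖λ‖, FA := 0 for the all-zero tensor). Negative
eigenvalues are permitted but flagged; λ₁ ≈ λ₂ flags the principal axis
as degenerate while the voxel is still emitted.

The principal eigenvector is projected into the sectioning plane by
discarding z: Φ_DT = atan2(w_y, w_x) folded to [0, 180) (eigenvector
sign is meaningless), out-of-plane angle = asin(|w_z|), projection
length = √(w_x²+w_y²). The out-of-plane filter retains angles ≤ 45°
*inclusive*. A vector along z has no in-plane axis and is flagged.

### SNR estimation

SNR is estimated from the b=0 volumes as mean tissue signal divided by
the noise level of a signal-free image corner. In magnitude MR images
the corner noise is Rayleigh-distributed with standard deviation
≈0.655σ of the underlying Gaussian channel noise, so the corner SD is
rescaled by default (`rayleigh_correction=True`) — without this the
raw ratio overestimates SNR by ×1.53 and a phantom simulated at SNR 50
would read ≈76. The uncorrected ratio (the literal
signal-over-corner-SD definition) is available via
`rayleigh_correction=False`.

## Alignment

Within-plane alignment is a similarity transform (one rotation, two
translations, one isotropic scale — anisotropic scale and shear are
deliberately outside the model), stored canonically as T·R·S about the
image origin in homogeneous coordinates; any composition of such
operations is representable, so composition order ambiguity is moot.
Landmark-based estimation uses the closed-form least-squares similarity
(Umeyama) fit and reports the RMS residual; two non-coincident pairs
suffice (4 degrees of freedom), and collinear configurations remain
solvable. Sections are assigned to slices by rounding their physical
depth to the nearest slice: with 300 μm section spacing and 340 μm
slices this reproduces the approximately 1:1 pairing in which every
~8–9th section doubles up on a slice. A manual override table can be
substituted for the rounding rule.

## Statistics

- **Axis metric**: d(a,b) = min(|a−b|, 180−|a−b|), a true metric on the
  axis circle (checked exhaustively on the 1° grid).
- **Axial mean**: doubled-angle vector mean; exactly orthogonal axes
  with equal weights cancel and are flagged undefined. The supremum of
  d(mean, member) over all pairs is 45° — the crossing-fiber averaging
  bound, computed by grid enumeration plus extrapolation toward the
  orthogonal limit (d is linear in the gap, so one Richardson step is
  exact).
- **Summaries**: per-group n, mean, median, SE and 1.96·SE; optional
  truncation (default 50°) before averaging; FA bins of width 0.05 with
  groups under 100 voxels flagged suppressed. Bin width and floor are
  configurable.
- **Generalized Pareto fit**: MLE with location pinned to 0; goodness
  of fit as R² between the fitted per-1°-bin probability mass on
  [0, 90] and the empirical histogram. Note that truncating a GPD
  sample at 90° biases the shape MLE downward (≈0.1 for shape 0.3,
  scale 8) — an effect of the truncated model, not the estimator;
  parameter-recovery checks therefore use untruncated draws.
- **Correlations/regression**: Pearson correlations and OLS R²
  (predictors: stain, amplitudes and widths of components 1–3) are
  computed per section and pooled as voxel-count-weighted means,
  because staining intensity varies between sections for technical
  reasons. Sections where a variable is constant (or with too few
  voxels / a rank-deficient design) are skipped per pair and tallied.
  Complete-case handling is per pair.
- **Join and filters**: histology and DTI tables are inner-joined on
  the voxel index; filters apply in the fixed order damage →
  unstained → out-of-plane, and the exclusion ledger reports counts
  and fractions per stage in that order.

## Phantom: what it emulates, and what it does not

The phantom renders striped textures (white noise filtered in the
Fourier domain with an elongated Gaussian, σ_along = 24 px across
σ_across = 3 px, aspect ratio 8) whose darkness scales with fiber
density, plus Gaussian pixel noise (SD 0.02); and a matching DWI volume
from the mono-exponential tensor signal with independent per-measurement
Rician noise (σ = S0/SNR, default SNR 50, S0 = 1000). Gradient
directions come from minimizing the 1/r Coulomb energy of point charges
on the whole sphere (no antipodal symmetrization; the energy exponent
is configurable), via projected gradient descent from seeded restarts —
6 charges recover the octahedron's 90° separations.

The default geometry is desk-scale: 8 sections of 256×256 px at
2 μm/px (512 μm field of view) with four horizontal bands — background,
unidirectional WM (axis 20°, density 0.9, λ = (1.7, 0.3, 0.3)·10⁻³
mm²/s), a 60° WM crossing (axes 30°/90°, equal weights, density 0.8,
λ = (1.0, 0.55, 0.45)·10⁻³) and a GM ribbon (tangential texture at 0°,
radial tensor override +90°, density 0.4, λ = (1.2, 0.9, 0.9)·10⁻³).
Eigenvalues and densities are chosen so that high stain coincides with
high FA and low MD, giving the expected correlation signs. Because the
512 μm field holds only ~1.5 voxels of 340 μm, the end-to-end
comparison uses a 64 μm voxel (8×8 voxels per section, 384 tissue
records over 8 sections); 340 μm remains the library default for
real-scale data. This is the package's scaling choice for a
desk-runnable validation, not a claim about achievable MRI resolution.

What passing the phantom shows: every stage is internally consistent —
orientations survive texture synthesis, tensor fitting, projection and
joining with correct bookkeeping (no 90° convention bugs), noise
calibration is honest, and the qualitative regimes (unidirectional
match, crossing compromise, tangential/radial orthogonality) emerge for
the right reasons. What it does not show: robustness to real
histological artifacts (tears, ripples, vessel holes, staining
gradients within sections), partial-volume mixtures at region
boundaries, non-Gaussian diffusion, imperfect registration, or the
empirical effect sizes of real tissue — the phantom's correlation
magnitudes are consequences of its construction, only their signs are
meaningful checks.

## Degenerate inputs and tie-breaks (summary)

| situation | behavior |
|---|---|
| isotropic structure tensor / blank pixel | orientation undefined (NaN), excluded |
| histogram argmax tie | lowest bin index |
| all-zero histogram | empty component list, voxel flagged |
| κ at optimization bound | returned as-is (flat histograms pin the lower bound) |
| eigenvalue tie λ₁ = λ₂ | voxel emitted, degeneracy flagged |
| principal eigenvector along z | Φ_DT undefined, excluded by the out-of-plane filter |
| orthogonal axes, equal weights | axial mean undefined (NaN) |
| nonpositive DWI signal | clamped to voxel's smallest positive signal, flagged |
| b=0 row with nonzero direction vector | vector zeroed on read, warning |

## Limitations

- 2D only: structure tensors and FODs live in the sectioning plane;
  through-plane fiber curvature appears only via the out-of-plane
  filter on the MRI side.
- The greedy mixture fit is deliberately simple (it is the procedure
  under validation); it can misattribute mass when components are
  closer than the smoothing window, and component 3 mostly absorbs
  residual ripple.
- The exclusion fractions of a phantom run depend on its geometry and
  are not comparable to any particular tissue sample.
- GPD fits on truncated differences inherit the truncation bias
  discussed above; compare fits, not absolute shape values, across
  analyses with different truncation.
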