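# Methods

## DOPU from polarization-diverse OCT

A polarization-diverse OCT records two complex tomograms per acquisition,
`E_H` and `E_V`. Each voxel's measured state is fully polarized; melanin
reveals itself as rapid spatial decorrelation of that state. Per voxel we
form Stokes components

    I = |E_H|² + |E_V|²,  Q = |E_H|² − |E_V|²,
    U = 2 Re(conj(E_H)·E_V),  V = −2 Im(conj(E_H)·E_V)

(the V sign convention maps the right-circular state (1, i)/√2 to V = −1;
DOPU is invariant to it). Additive detector noise inflates I and biases
DOPU downward, so the channel noise energies `n_H`, `n_V` — estimated as
mean |E|² over a signal-free depth band, by construction the top 16 rows of
every phantom B-scan — are subtracted before normalization:

    I_c = I − (n_H + n_V),   Q_c = Q − (n_H − n_V)
    DOPU = ‖⟨(Q_c, U, V) / I_c⟩_kernel‖, clipped to [0, 1]

The kernel is 3 × 3 within a B-scan (depth × A-line; DOPU images are
per-B-scan objects, so the kernel never crosses B-scans). Numerical
choices:

- Voxels enter the kernel mean only where `I_c > ε·(n_H + n_V)` with
  ε = 1 by default (≈3 dB over the noise floor); normalizing nearly
  noise-level intensities is unstable in both directions.
- Kernels are cropped at image borders — padding would fabricate
  polarization data. A voxel whose kernel retains fewer than half the
  nominal members is invalid; invalid voxels are NaN, never zero, and are
  excluded from the melanin mask and all downstream counts.
- The melanin criterion is **strictly** DOPU < 0.8.

## Choroid segmentation and compartments

The upper choroid boundary is found per A-line as the steepest negative
gradient of the axially smoothed intensity within 12 px below the
brightest band (the RPE complex); the lower boundary is the deepest depth
whose smoothed intensity exceeds `max(5 × noise floor, 5% of the A-line
peak)`. Both are median-regularized across A-lines (width 15); A-lines
with no detectable bright band are interpolated from neighbors, whole-B-scan
failures stay flagged and propagate as missing map values. This finder is a
documented functional replacement for the proprietary segmentation of the
reference clinical device; every metric stage also accepts externally
supplied (ground-truth or operator) boundaries so that melanin
quantification is testable independently of segmentation quality.

Vessel/interstitium separation: the log₁₀ intensity inside the choroid is
lightly smoothed (Gaussian σ = 1 px, standing in for the speckle reduction
that repeat-scan composited structural images would provide), quantized to
8 bits between its 1st and 99th percentiles, and thresholded by a local
Otsu filter in a 64 × 64 window (global Otsu fallback when the choroid is
smaller than the window); voxels at or below the local threshold are
hyposcattering vessel lumen, the rest interstitial stroma, followed by a
median filter of radius 2. Window and radius are unconstrained by the
source description and are config keys. The partition
`vessel ∪ interstitium = choroid` is exact by construction and asserted.

## Melanin metrics and regions

ChMeT(A-line) = (# voxels with DOPU < 0.8 ∧ interstitial) × 4.3 μm;
ChMeTratio is the same count as a percentage of the A-line's stromal
voxels (A-lines with empty stroma are missing, never 0% or 100%). The
identity ChMeT = (ChMeTratio/100) × stroma count × 4.3 μm holds exactly.

Transverse scale: a Littman-type linearization
`scale = (AL − 1.82) / (24.39 − 1.82)` (AL = axial length in mm,
reference 24.39 mm emmetropic eye, 1.82 mm anterior nodal offset). The
reference length and linearization are this package's documented choice
within the Littman family. Regional membership uses pixel-center distance
to the fovea with closed outer edges: center disc d ≤ 1 mm, outer ring
1 < d ≤ 2.5 mm, whole disc d ≤ 2.5 mm — deterministic and partition-exact,
so the count-weighted identity between the whole mean and the
center/outer means is exact when no values are missing. Means are
pixel-weighted (not mm²-weighted); missing values propagate, they are
never imputed. The fovea position is an input (phantom truth or operator
supplied); automatic fovea detection is out of scope.

Repeatability: CV = sample SD / mean over ≥ 2 (typically 4) repeated
measurements per subject; the cohort summary is the mean ± SD of subject
CVs.

## Sunset glow index

SGI = L_red / (L_red + L_green + L_blue) over an 800-px square crop of a
1500 × 1500 fundus image, where L_* are raw 8-bit channel means — no
colorimetric weighting, matching measurement of channels on a 256-step
scale. The crop is centered by default; an explicit origin supports
disc-avoiding placement. SGI is brightness-invariant and undefined (NaN)
for an all-black crop.

## Synthetic phantom

The phantom emulates a layered posterior eye: noise-only band (16 rows),
vitreous gap, retina (200 μm), bright RPE (25 μm), choroid (250 μm
default) with elliptical vessel lumina and melanin-bearing stroma, sclera.
Field-amplitude reflectivities (retina 0.6, RPE 3.0, stroma 1.5, vessel
0.15, sclera 0.25) give the contrast ordering the boundary finder and the
Otsu binarization rely on; the dim sclera stands for choroidal shadowing.
Speckle is fully developed — independent circular complex Gaussian per
voxel, no axial PSF correlation — which makes kernel members independent,
the conservative case for DOPU statistics. Polarization-preserving tissue
shares one global Jones state; with probability `p` (the melanin mixing
probability, a scalar or an en-face field for regional gradients) a
stromal voxel's state is replaced by an independent Haar-uniform Poincaré
state, likewise `rpe_mixing` (default 0.9 — RPE melanin is preserved in
the disease being modeled) for the RPE band. Detector noise is additive
complex Gaussian per channel at `snr_db` (default 25 dB) relative to mean
stroma intensity. Sclera is polarization-preserving; scleral birefringence
is irrelevant to choroid-restricted metrics.

This binary state-replacement model is deliberately not scattering
physics: it buys an exact per-voxel melanin ground-truth mask and a
tractable Monte-Carlo mapping from `p` to the expected low-DOPU fraction
(`calibrate_mixing_to_dopu`). The default vessel layout occupies roughly a
tenth to a quarter of the choroid, mirroring real choroidal vascularity;
vessel-free local-Otsu windows would otherwise split pure speckle.

Geometry defaults mirror the reference acquisition (512 A-lines × 256
B-scans over 6 × 6 mm, 4.3 μm axial pixel, 2.8 mm depth range); tests and
the acceptance script use scaled-down rasters (96–128 A-lines, 16–64
B-scans, ~200 depth px) with identical voxel-level statistics, since the
per-voxel physics, not the raster size, carries the scientific content.

What the phantom does **not** emulate — and hence what passing tests do
not show about clinical data: motion and blink artifacts, axial PSF and
speckle correlation, depth-dependent signal roll-off and attenuation
(beyond the static dim sclera), birefringence of sclera or fibrosis,
RPE atrophy, real fundus pigmentation texture. The 4-repeat CVs measured
on phantom repeats (~10⁻³) are therefore far below clinically reported
values, which are dominated by positioning and physiological variability;
the phantom CV checks the analysis chain, not the instrument.

## Statistics

All group tests are rank-based and two-sided, hence invariant under
monotone transforms; exactness thresholds: Mann–Whitney U exact for both
n ≤ 8 without cross-group ties, Wilcoxon signed rank exact for ≤ 15
non-zero tie-free pairs (zeros dropped), otherwise tie-corrected normal
approximations. Dunn's post-hoc z uses pooled-rank means with tie
correction and Bonferroni adjustment over all pairs (the adjustment is a
config key). Friedman requires complete blocks (no imputation); its
post-hoc is pairwise Wilcoxon with Bonferroni factor = number of pairs.
AUC is the pair-counting probability (ties ½), identical to the
trapezoidal ROC integral; its p-value against 0.5 comes from the
Mann–Whitney equivalence; for ChMeT and ChMeTratio the depigmented class
scores lower, and the reported orientation records this. Correlations
default to Spearman (Pearson on request) and are labeled with their
method. Weighted kappa uses linear weights by default (quadratic
available); it is undefined when the raters use a single category.
Significance is reported at 0.05 in summaries but never hard-coded into
computations. Cohort tables are analyzed one row per eye; when both eyes
of a patient enter, no clustering correction is applied — a documented
caveat of the mirrored design.

## Known limitations

- DOPU-based melanin thickness is proportional to, not identical with,
  anatomical melanin thickness: kernel size, packing density and
  wavelength all scale it. The phantom shows the same saturation — at
  mixing p ≥ 0.5 the 3 × 3 kernel flags nearly all stromal voxels, so
  ChMeTratio compresses toward 100% long before p does.
- The boundary finder is a functional replacement for a proprietary
  algorithm; whether its lower boundary matches that device's
  choroid–sclera definition on real data cannot be verified here.
- Incident-polarization management and birefringence compensation are out
  of scope, as is OCT angiography and the acquisition itself.
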