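# chmet — choroidal melanin quantification from polarization-sensitive OCT

In Vogt–Koyanagi–Harada (VKH) disease, autoimmune attack on choroidal
melanocytes can progress to the depigmented "sunset glow fundus". Grading
that appearance from color fundus photographs is subjective and confounded
by choroidal thinning. Polarization-sensitive OCT (PS-OCT) offers an
objective alternative: melanin depolarizes backscattered light, so the
degree of polarization uniformity (DOPU) drops wherever melanin is present,
and the loss of low-DOPU tissue in the choroidal interstitial stroma tracks
depigmentation directly.

This package implements that quantification end to end, for researchers
working with polarization-diverse OCT volumes:

- **DOPU** with additive-noise bias correction over a 3 × 3 kernel:
  per voxel, Stokes components (I, Q, U, V) are formed from the two
  detection channels, the channel noise energies (estimated from a
  signal-free band) are subtracted from I and Q, and
  DOPU = ‖⟨(Q_c, U, V)/I_c⟩_kernel‖, clipped to [0, 1].
- **Choroid segmentation** (intensity/gradient boundary finder) and
  **vessel/interstitium separation** by local Otsu thresholding of the
  log-scaled intensity plus median filtering.
- **ChMeT** (choroidal melanin thickness): per A-line count of voxels with
  DOPU < 0.8 inside the interstitial stroma × 4.3 μm axial pixel;
  **ChMeTratio**: the same count as a percentage of the stromal voxels;
  **choroidal thickness**; all as en-face maps.
- **Regional summaries** over fovea-centered 2 mm / 5 mm discs and the
  2–5 mm outer ring, with Littman-type transverse magnification calibration
  from axial length, plus 4-repeat coefficients of variation.
- **Sunset glow index** of color fundus crops:
  SGI = L_red / (L_red + L_green + L_blue) over an 800-px square.
- A **statistical battery** (Kruskal–Wallis + Dunn, Mann–Whitney U,
  Wilcoxon signed rank, Friedman + Bonferroni, pair-counting ROC/AUC,
  rank correlations, weighted kappa) driving a one-call cohort report.
- A **synthetic phantom** of the layered posterior eye with exact
  per-voxel melanin ground truth, so every stage is testable without
  clinical data.

## Worked example

```python
import numpy as np
from chmet import PhantomSpec, RunConfig, generate_psoct_phantom, run_eye

# a depigmented outer ring (melanin probability 0.2) around a preserved center
n_a, n_b = 128, 64
da = (np.arange(n_a) - n_a // 2) * (6000.0 / n_a)
db = (np.arange(n_b) - n_b // 2) * (6000.0 / n_b)
dist = np.sqrt(da[:, None] ** 2 + db[None, :] ** 2)
p = np.where(dist <= 1000.0, 0.9, 0.2)

spec = PhantomSpec(n_alines=n_a, n_bscans=n_b, n_depth=220,
                   melanin_p=p, vessels=(), seed=61)
vol, truth = generate_psoct_phantom(spec)
res = run_eye(vol, config=RunConfig(boundaries="truth"), truth=truth)
s = res.summaries["chmetratio"]
print(f"center {s.center_mean:.1f}%  outer {s.outer_mean:.1f}%  "
      f"center/outer {s.center_outer_ratio:.2f}")
```

prints

```
center 99.9%  outer 42.9%  center/outer 2.33
```

i.e. the low-DOPU occupancy of the stroma is near-complete where melanin is
preserved, much lower in the depigmented ring, and the center/outer ratio
above 1 localizes the depigmentation to the periphery — the same regional
logic used to characterize VKH eyes.

A command-line interface mirrors the library
(`chmet phantom | dopu | sgi | run | report | fundus-phantom`); volumes and
maps travel as TIFF + JSON sidecars, tables as CSV.

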