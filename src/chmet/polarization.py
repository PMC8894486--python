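"""Stokes parameters and noise-corrected DOPU from polarization-diverse OCT.

A polarization-diverse OCT system records two complex tomograms per
acquisition, one per orthogonal detection channel (``E_H``, ``E_V``).  Each
voxel therefore carries a fully polarized measured state; depolarizing tissue
(melanin) reveals itself as rapid spatial *variation* of that state.  The
degree of polarization uniformity (DOPU) quantifies this as the norm of the
spatial average of normalized Stokes vectors over a small kernel: 1.0 for
polarization-preserving tissue, toward 0 where the state is randomized.

Additive detector noise biases DOPU downward; the correction applied here
subtracts the per-channel noise energies from the intensity-like Stokes
components before normalization, following the noise-bias-corrected DOPU
estimator used with single-measurement kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PSOCTVolume",
    "StokesVolume",
    "NoiseEstimate",
    "DOPUVolume",
    "compute_stokes",
    "estimate_noise",
    "compute_dopu",
    "low_dopu_mask",
]


@dataclass
class PSOCTVolume:
    """Two-channel complex OCT volume, shape ``(depth, A-line, B-scan)``.

    Parameters
    ----------
    e_h, e_v
        Complex amplitude per voxel for the horizontal / vertical detection
        channel.  Shapes must match.
    axial_pixel_um
        Physical axial pixel pitch in micrometres.
    scan_width_mm
        Nominal transverse extent of the raster scan (square scans assumed).
    noise_band
        Half-open depth-row range ``(start, stop)`` known to be signal-free;
        used to estimate the detector noise floor.
    axial_length_mm
        Ocular axial length used for transverse magnification calibration.
    fovea
        ``(A-line, B-scan)`` indices of the fovea, if known.
    """

    e_h: np.ndarray
    e_v: np.ndarray
    axial_pixel_um: float = 4.3
    scan_width_mm: float = 6.0
    noise_band: tuple[int, int] = (0, 16)
    axial_length_mm: float = 24.39
    fovea: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.e_h = np.asarray(self.e_h)
        self.e_v = np.asarray(self.e_v)
        if self.e_h.shape != self.e_v.shape:
            raise ValueError(
                f"channel shapes differ: {self.e_h.shape} vs {self.e_v.shape}"
            )
        if self.e_h.ndim != 3:
            raise ValueError("expected a 3-D (depth, A-line, B-scan) volume")
        lo, hi = self.noise_band
        if not (0 <= lo < hi <= self.n_depth):
            raise ValueError(f"noise band {self.noise_band} outside depth range")

    @property
    def n_depth(self) -> int:
        return self.e_h.shape[0]

    @property
    def n_alines(self) -> int:
        return self.e_h.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.e_h.shape[2]


@dataclass
class StokesVolume:
    """Per-voxel Stokes components I, Q, U, V.

    Convention: I = |E_H|^2 + |E_V|^2, Q = |E_H|^2 - |E_V|^2,
    U = 2 Re(conj(E_H) E_V), V = -2 Im(conj(E_H) E_V), so the
    right-circular state (1, i)/sqrt(2) maps to V = -1.  DOPU is invariant
    to the sign convention of V.
    """

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.i.shape


@dataclass(frozen=True)
class NoiseEstimate:
    """Mean detector noise energy per channel, in |E|^2 units."""

    n_h: float
    n_v: float

    def __post_init__(self) -> None:
        if self.n_h < 0 or self.n_v < 0:
            raise ValueError("noise energies must be non-negative")

    @property
    def total(self) -> float:
        return self.n_h + self.n_v


ZERO_NOISE = NoiseEstimate(0.0, 0.0)


@dataclass
class DOPUVolume:
    """Degree of polarization uniformity in [0, 1] with a validity mask.

    ``valid`` is False where the corrected intensity was too close to the
    noise floor or where fewer than half the kernel members were usable;
    ``dopu`` is NaN there, never silently zero.
    """

    dopu: np.ndarray
    valid: np.ndarray
    kernel: tuple[int, int]
    noise: NoiseEstimate = ZERO_NOISE
    threshold_note: dict = field(default_factory=dict)


def compute_stokes(vol: PSOCTVolume) -> StokesVolume:
    """Compute the Stokes components of each voxel.

    Pure elementwise function of the two channels; raises on non-finite
    input because NaNs would silently poison every downstream kernel mean.
    """
    eh, ev = vol.e_h, vol.e_v
    if not (np.all(np.isfinite(eh.real)) and np.all(np.isfinite(eh.imag))
            and np.all(np.isfinite(ev.real)) and np.all(np.isfinite(ev.imag))):
        raise ValueError("non-finite values in input volume")
    ih = (eh.real ** 2 + eh.imag ** 2).astype(np.float64)
    iv = (ev.real ** 2 + ev.imag ** 2).astype(np.float64)
    cross = np.conj(eh) * ev
    return StokesVolume(
        i=ih + iv,
        q=ih - iv,
        u=2.0 * cross.real.astype(np.float64),
        v=-2.0 * cross.imag.astype(np.float64),
    )


def estimate_noise(vol: PSOCTVolume) -> NoiseEstimate:
    """Estimate per-channel noise energy from the signal-free depth band."""
    lo, hi = vol.noise_band
    if hi <= lo:
        raise ValueError("empty noise band")
    band_h = vol.e_h[lo:hi]
    band_v = vol.e_v[lo:hi]
    return NoiseEstimate(
        n_h=float(np.mean(band_h.real ** 2 + band_h.imag ** 2)),
        n_v=float(np.mean(band_v.real ** 2 + band_v.imag ** 2)),
    )


def _kernel_mean(x: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    # Sum over the (depth, A-line) kernel inside each B-scan; zero-padded
    # borders implement kernel cropping once divided by the member count.
    size = (kernel[0], kernel[1], 1)
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * (
        kernel[0] * kernel[1]
    )


def compute_dopu(
    stokes: StokesVolume,
    noise: NoiseEstimate = ZERO_NOISE,
    kernel: tuple[int, int] = (3, 3),
    intensity_eps: float = 1.0,
    min_valid_frac: float = 0.5,
) -> DOPUVolume:
    """Noise-corrected DOPU over a 2-D kernel within each B-scan.

    Per voxel the noise-bias correction subtracts the summed channel noise
    energies from I and their difference from Q::

        I_c = I - (n_H + n_V),   Q_c = Q - (n_H - n_V)

    Normalized components (q, u, v) = (Q_c, U, V) / I_c are formed only where
    ``I_c > intensity_eps * (n_H + n_V)`` (default: corrected signal must
    exceed the noise floor, i.e. SNR >= ~3 dB), averaged over the kernel's
    valid members, and DOPU is the Euclidean norm of that average, clipped
    to [0, 1].  Kernels are cropped at borders — no polarization data is
    fabricated by padding.  Voxels whose kernel retains fewer than
    ``min_valid_frac`` of the nominal member count are marked invalid.
    """
    kd, ka = kernel
    if kd % 2 == 0 or ka % 2 == 0 or kd < 1 or ka < 1:
        raise ValueError("kernel must be odd-sized in both in-plane dimensions")

    i_c = stokes.i - noise.total
    q_c = stokes.q - (noise.n_h - noise.n_v)
    voxel_valid = i_c > intensity_eps * noise.total

    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(voxel_valid, 1.0 / np.where(voxel_valid, i_c, 1.0), 0.0)
    qn = q_c * inv
    un = stokes.u * inv
    vn = stokes.v * inv

    vf = voxel_valid.astype(np.float64)
    count = _kernel_mean(vf, kernel)
    sq = _kernel_mean(qn * vf, kernel)
    su = _kernel_mean(un * vf, kernel)
    sv = _kernel_mean(vn * vf, kernel)

    min_members = min_valid_frac * kd * ka
    out_valid = count >= min_members
    if not out_valid.any():
        raise ValueError(
            "DOPU undefined everywhere: no voxel has a sufficiently valid "
            f"kernel (noise floor {noise.total:.3g}, eps {intensity_eps})"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.sqrt(sq ** 2 + su ** 2 + sv ** 2) / count
    dopu = np.where(out_valid, np.clip(norm, 0.0, 1.0), np.nan)
    return DOPUVolume(dopu=dopu, valid=out_valid, kernel=(kd, ka), noise=noise)


def low_dopu_mask(dopu: DOPUVolume, threshold: float = 0.8) -> np.ndarray:
    """Binary melanin mask: valid voxels with DOPU strictly below threshold.

    The strict inequality matters: a voxel at exactly the threshold is not
    counted as depolarizing.  Invalid voxels are always False.
    """
    if not (0.0 < threshold < 1.0):
        if threshold == 0.0:
            # Degenerate but well-defined: nothing is strictly below zero.
            return np.zeros_like(dopu.valid, dtype=bool)
        raise ValueError("threshold must lie in (0, 1)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        below = dopu.dopu < threshold
    return below & dopu.valid
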