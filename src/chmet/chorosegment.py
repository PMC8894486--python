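"""Choroid delimitation and vessel/interstitium separation in OCT B-scans.

The choroid lies between the outer edge of the bright RPE/Bruch's complex
and the choroid-sclera interface.  The boundary finder here is an
intensity/gradient method: the upper boundary is the steepest intensity
drop just below the brightest axial band, the lower boundary is the deepest
depth at which the smoothed signal still clearly exceeds a noise- and
peak-referenced floor.  Downstream metric code also accepts ground-truth or
operator-supplied boundaries, so melanin quantification is testable
independently of segmentation quality.

Within the choroid, hyposcattering vessel lumina are separated from the
melanin-bearing interstitial stroma by local Otsu thresholding of the
log-scaled intensity followed by median filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.filters.rank import otsu as rank_otsu
from skimage.morphology import disk

from .melanin_metrics import EnfaceMap

__all__ = [
    "ChoroidBoundaries",
    "TissueMasks",
    "segment_choroid",
    "binarize_vessels",
    "tissue_masks",
    "choroid_mask_from_boundaries",
    "choroidal_thickness",
    "SegmentationError",
]


class SegmentationError(RuntimeError):
    pass


@dataclass
class ChoroidBoundaries:
    """Upper/lower choroid boundary depth indices per (A-line, B-scan).

    ``flagged`` marks A-lines where no boundary could be found (excluded
    from maps as missing values).  ``provenance`` records whether the
    boundaries came from the automatic finder, phantom ground truth, or a
    manual override.
    """

    upper: np.ndarray
    lower: np.ndarray
    flagged: np.ndarray
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper)
        self.lower = np.asarray(self.lower)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if not (self.upper.shape == self.lower.shape == self.flagged.shape):
            raise ValueError("boundary arrays must be congruent")
        ok = ~self.flagged
        if np.any(self.upper[ok] > self.lower[ok]):
            raise ValueError("upper boundary below lower boundary on some A-line")


@dataclass
class TissueMasks:
    """Per-voxel choroid/vessel/interstitial masks.

    Invariant (exact): vessel and interstitial are disjoint and their union
    is the choroid.
    """

    choroid: np.ndarray
    vessel: np.ndarray
    interstitial: np.ndarray

    def __post_init__(self) -> None:
        if (self.vessel & self.interstitial).any():
            raise ValueError("vessel and interstitial masks overlap")
        if not np.array_equal(self.vessel | self.interstitial, self.choroid):
            raise ValueError("vessel + interstitial must partition the choroid")


def segment_choroid(
    intensity: np.ndarray,
    noise_floor: float = 0.0,
    axial_sigma: float = 2.0,
    lateral_sigma: float = 1.0,
    grad_window: int = 12,
    peak_frac: float = 0.05,
    noise_mult: float = 5.0,
    median_width: int = 15,
    min_peak_snr: float = 10.0,
) -> ChoroidBoundaries:
    """Locate the choroid in every A-line of an intensity volume.

    Parameters
    ----------
    intensity
        Linear OCT intensity, shape ``(depth, A-line, B-scan)``.
    noise_floor
        Total noise energy (``n_H + n_V``); the lower-boundary threshold and
        the A-line failure test are referenced to it.
    axial_sigma, lateral_sigma
        Gaussian smoothing (pixels) applied before boundary search.
    grad_window
        Depth window below the brightest band searched for the steepest
        negative gradient (the RPE outer edge).
    peak_frac
        The lower boundary is the deepest depth whose smoothed intensity
        exceeds ``max(noise_mult * noise_floor, peak_frac * peak)``.
    median_width
        Width of the per-B-scan median filter regularizing boundaries
        across A-lines.
    min_peak_snr
        A-lines whose peak smoothed intensity is below
        ``min_peak_snr * noise_floor`` (or non-positive) are flagged and
        interpolated from neighbors where possible.

    Raises ``SegmentationError`` when no A-line in the volume yields a
    detectable bright band.
    """
    if not np.all(np.isfinite(intensity)):
        raise ValueError("non-finite intensity")
    n_depth, n_alines, n_bscans = intensity.shape
    sm = ndimage.gaussian_filter(
        intensity.astype(np.float64), sigma=(axial_sigma, lateral_sigma, 0)
    )

    peak_idx = np.argmax(sm, axis=0)                        # (A, B)
    peak_val = np.take_along_axis(sm, peak_idx[None], axis=0)[0]
    floor = max(noise_floor, 0.0)
    flagged = peak_val <= max(min_peak_snr * floor, 1e-12)
    if flagged.all():
        raise SegmentationError("no detectable bright band anywhere in the volume")

    grad = np.diff(sm, axis=0)                              # grad[d] = sm[d+1]-sm[d]
    depth_idx = np.arange(n_depth - 1)[:, None, None]
    in_window = (depth_idx >= peak_idx[None]) & (
        depth_idx < np.minimum(peak_idx + grad_window, n_depth - 1)[None]
    )
    masked_grad = np.where(in_window, grad, np.inf)
    # steepest descent just below the peak = outer edge of the RPE complex
    upper = np.argmin(masked_grad, axis=0) + 1

    thr = np.maximum(noise_mult * floor, peak_frac * peak_val)
    above = sm > thr[None]
    # deepest depth still above threshold
    lower = (n_depth - 1) - np.argmax(above[::-1], axis=0)
    lower = np.where(above.any(axis=0), lower, 0)

    # regularize across A-lines within each B-scan
    upper = ndimage.median_filter(upper.astype(float), size=(median_width, 1))
    lower = ndimage.median_filter(lower.astype(float), size=(median_width, 1))

    # interpolate flagged A-lines from valid neighbors in the same B-scan
    for b in range(n_bscans):
        bad = flagged[:, b]
        if bad.any() and not bad.all():
            x = np.arange(n_alines)
            upper[bad, b] = np.interp(x[bad], x[~bad], upper[~bad, b])
            lower[bad, b] = np.interp(x[bad], x[~bad], lower[~bad, b])
        elif bad.all():
            warnings.warn(f"B-scan {b}: segmentation failed for every A-line")

    upper = np.clip(np.rint(upper), 0, n_depth - 1).astype(np.int64)
    lower = np.clip(np.rint(lower), 0, n_depth - 1).astype(np.int64)
    lower = np.maximum(lower, upper)
    # interpolated A-lines are recovered; whole-B-scan failures stay flagged
    still_flagged = flagged & flagged.all(axis=0)[None, :]
    return ChoroidBoundaries(
        upper=upper, lower=lower, flagged=still_flagged, provenance="automatic"
    )


def choroid_mask_from_boundaries(
    bounds: ChoroidBoundaries, n_depth: int
) -> np.ndarray:
    """Boolean (depth, A-line, B-scan) mask of voxels within [upper, lower)."""
    depth = np.arange(n_depth)[:, None, None]
    mask = (depth >= bounds.upper[None]) & (depth < bounds.lower[None])
    mask &= ~bounds.flagged[None]
    return mask


def binarize_vessels(
    intensity: np.ndarray,
    choroid: np.ndarray,
    window: int = 64,
    median_radius: int = 2,
    speckle_sigma: float = 1.0,
    log_floor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Split one B-scan's choroid into vessel and interstitial masks.

    The log-scaled intensity restricted to the choroid is quantized to
    8 bits and thresholded with a local Otsu filter over a
    ``window x window`` neighborhood; voxels below the local threshold are
    hyposcattering vessel lumen, voxels above are interstitial stroma.  A
    median filter of the given radius despeckles the binary vessel image
    (radius 0 disables it).  ``speckle_sigma`` applies a light Gaussian
    smoothing to the log image first, emulating the speckle reduction of
    repeat-scan composited structural images (0 disables).  When the
    choroid's bounding box is smaller than the window the threshold falls
    back to global Otsu with a warning.

    Log scaling matters: OCT intensity spans orders of magnitude and
    linear-domain Otsu degenerates on its heavy tail.  Quantization to
    8 bits uses robust (1st-99th percentile) limits so single hot speckle
    voxels do not compress the histogram.
    """
    if intensity.ndim != 2 or intensity.shape != choroid.shape:
        raise ValueError("expected congruent 2-D B-scan arrays")
    if not choroid.any():
        raise ValueError("empty choroid mask for this B-scan")

    logi = np.log10(np.maximum(intensity, log_floor))
    if speckle_sigma > 0:
        logi = ndimage.gaussian_filter(logi, speckle_sigma)
    vals = logi[choroid]
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        # constant choroid: nothing to separate, call it all interstitium
        vessel = np.zeros_like(choroid)
        return vessel, choroid.copy()

    scaled = np.clip((logi - lo) / (hi - lo), 0.0, 1.0)
    img8 = np.rint(scaled * 255).astype(np.uint8)
    # neutral fill outside the choroid so the local histogram is not skewed
    img8[~choroid] = np.uint8(np.rint(np.median((img8[choroid]))))

    rows = np.any(choroid, axis=1).sum()
    cols = np.any(choroid, axis=0).sum()
    if rows < window and cols < window:
        warnings.warn(
            f"choroid bounding box smaller than {window}x{window} window; "
            "falling back to global Otsu"
        )
        thr = threshold_otsu(img8[choroid])
        vessel = (img8 <= thr) & choroid
    else:
        footprint = np.ones((window, window), dtype=np.uint8)
        local_thr = rank_otsu(img8, footprint)
        vessel = (img8 <= local_thr) & choroid

    if median_radius > 0:
        vessel = ndimage.median_filter(
            vessel.astype(np.uint8), footprint=disk(median_radius)
        ).astype(bool)
        vessel &= choroid
    interstitial = choroid & ~vessel
    return vessel, interstitial


def tissue_masks(
    intensity: np.ndarray,
    bounds: ChoroidBoundaries,
    window: int = 64,
    median_radius: int = 2,
) -> TissueMasks:
    """Vessel/interstitium separation for every B-scan of a volume."""
    n_depth = intensity.shape[0]
    choroid = choroid_mask_from_boundaries(bounds, n_depth)
    vessel = np.zeros_like(choroid)
    interstitial = np.zeros_like(choroid)
    for b in range(intensity.shape[2]):
        if not choroid[:, :, b].any():
            continue
        v, s = binarize_vessels(
            intensity[:, :, b], choroid[:, :, b], window=window,
            median_radius=median_radius,
        )
        vessel[:, :, b] = v
        interstitial[:, :, b] = s
    return TissueMasks(choroid=choroid, vessel=vessel, interstitial=interstitial)


def choroidal_thickness(
    bounds: ChoroidBoundaries,
    axial_pixel_um: float = 4.3,
    pitch_um: tuple[float, float] | None = None,
    fovea: tuple[int, int] | None = None,
) -> EnfaceMap:
    """Choroidal thickness map in micrometres; flagged A-lines become NaN."""
    values = (bounds.lower - bounds.upper).astype(np.float64) * axial_pixel_um
    values = np.where(bounds.flagged, np.nan, values)
    na, nb = values.shape
    if pitch_um is None:
        pitch_um = (6000.0 / na, 6000.0 / nb)
    if fovea is None:
        fovea = (na // 2, nb // 2)
    return EnfaceMap(values=values, units="um", pitch_um=pitch_um, fovea=fovea)
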