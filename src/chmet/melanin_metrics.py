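"""Choroidal melanin metrics: ChMeT, ChMeTratio, regional summaries.

ChMeT (choroidal melanin thickness) counts low-DOPU voxels within the
choroidal interstitial stroma along each A-line and converts the count to
micrometres via the axial pixel pitch (4.3 um on the reference device).
ChMeTratio is the percentage occupancy of low-DOPU voxels within the stroma
of each A-line, which decouples melanin content from choroidal thickness.
En-face maps of both, plus choroidal thickness, are summarized over
fovea-centered discs (2 mm center, 5 mm whole) and the 2-5 mm outer ring;
the center/outer ratio localizes depigmentation.

Transverse scale is calibrated from ocular axial length with a linearized
Littman-type magnification model before regional membership is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnfaceMap",
    "MagnificationModel",
    "RegionalSummary",
    "chmet_map",
    "chmetratio_map",
    "calibrate_transverse_scale",
    "regional_summary",
    "repeatability_cv",
]

#: emmetropic reference axial length (mm) for the magnification model
REFERENCE_AXIAL_LENGTH_MM = 24.39
#: nodal-point offset (mm) of the linearized Littman magnification model
LITTMAN_OFFSET_MM = 1.82


@dataclass
class EnfaceMap:
    """Per-A-line scalar map over the raster, shape ``(n_alines, n_bscans)``.

    Missing values (flagged A-lines, zero-stroma A-lines) are NaN; they are
    never imputed and propagate explicitly into the regional means.
    """

    values: np.ndarray
    units: str
    pitch_um: tuple[float, float]       # (per A-line, per B-scan), post-calibration
    fovea: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("en-face map must be 2-D (A-line, B-scan)")
        if min(self.pitch_um) <= 0:
            raise ValueError("transverse pitch must be positive")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass(frozen=True)
class MagnificationModel:
    """Transverse magnification relative to the emmetropic reference eye."""

    axial_length_mm: float
    reference_axial_length_mm: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("magnification scale must be positive")


@dataclass
class RegionalSummary:
    """Whole / center / outer-ring means and the center/outer ratio.

    Regions are fovea-centered: center disc of diameter 2 mm, whole disc of
    5 mm, outer ring between them.  ``*_n`` are counts of non-missing pixels.
    The exact invariant (no missing data) is
    ``whole = (center*center_n + outer*outer_n) / (center_n + outer_n)``.
    """

    units: str
    whole_mean: float
    center_mean: float
    outer_mean: float
    center_outer_ratio: float
    whole_n: int
    center_n: int
    outer_n: int


def _require_congruent(low_mask: np.ndarray, tissue: np.ndarray) -> None:
    if low_mask.shape != tissue.shape:
        raise ValueError(
            f"mask shapes differ: {low_mask.shape} vs {tissue.shape}"
        )


def chmet_map(
    low_mask: np.ndarray,
    interstitial: np.ndarray,
    axial_pixel_um: float = 4.3,
    pitch_um: tuple[float, float] | None = None,
    fovea: tuple[int, int] | None = None,
    flagged: np.ndarray | None = None,
) -> EnfaceMap:
    """Choroidal melanin thickness per A-line, in micrometres.

    ``low_mask`` and ``interstitial`` are congruent boolean volumes
    ``(depth, A-line, B-scan)``; the metric is the per-A-line count of
    voxels in their intersection times the axial pixel pitch.  A-lines
    flagged by segmentation become NaN.
    """
    _require_congruent(low_mask, interstitial)
    counts = (low_mask & interstitial).sum(axis=0).astype(np.float64)
    values = counts * axial_pixel_um
    if flagged is not None:
        values = np.where(flagged, np.nan, values)
    na, nb = values.shape
    if pitch_um is None:
        pitch_um = (6000.0 / na, 6000.0 / nb)
    if fovea is None:
        fovea = (na // 2, nb // 2)
    return EnfaceMap(values=values, units="um", pitch_um=pitch_um, fovea=fovea)


def chmetratio_map(
    low_mask: np.ndarray,
    interstitial: np.ndarray,
    pitch_um: tuple[float, float] | None = None,
    fovea: tuple[int, int] | None = None,
    flagged: np.ndarray | None = None,
) -> EnfaceMap:
    """Low-DOPU occupancy of the interstitial stroma per A-line, in percent.

    A-lines whose stroma is empty have no defined occupancy and are NaN —
    never 0 or 100.
    """
    _require_congruent(low_mask, interstitial)
    stroma_n = interstitial.sum(axis=0).astype(np.float64)
    low_n = (low_mask & interstitial).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(stroma_n > 0, 100.0 * low_n / stroma_n, np.nan)
    if flagged is not None:
        values = np.where(flagged, np.nan, values)
    na, nb = values.shape
    if pitch_um is None:
        pitch_um = (6000.0 / na, 6000.0 / nb)
    if fovea is None:
        fovea = (na // 2, nb // 2)
    return EnfaceMap(values=values, units="%", pitch_um=pitch_um, fovea=fovea)


def calibrate_transverse_scale(
    axial_length_mm: float,
    nominal_width_mm: float = 6.0,
    n_alines: int = 512,
    reference_axial_length_mm: float = REFERENCE_AXIAL_LENGTH_MM,
) -> MagnificationModel:
    """Littman-type transverse magnification from ocular axial length.

    The retinal extent subtended by a fixed scan angle grows roughly
    linearly with the distance from the eye's second nodal point to the
    retina; the linearization used here is

        scale = (AL - 1.82) / (AL_ref - 1.82),   AL_ref = 24.39 mm

    so a longer eye maps the same nominal 6-mm scan onto a proportionally
    larger retinal patch.  The calibrated per-A-line pitch is
    ``scale * nominal_width_mm / n_alines``.
    """
    if not (20.0 <= axial_length_mm <= 32.0):
        raise ValueError(
            f"axial length {axial_length_mm} mm outside plausible 20-32 mm range"
        )
    scale = (axial_length_mm - LITTMAN_OFFSET_MM) / (
        reference_axial_length_mm - LITTMAN_OFFSET_MM
    )
    return MagnificationModel(
        axial_length_mm=axial_length_mm,
        reference_axial_length_mm=reference_axial_length_mm,
        scale=scale,
    )


def regional_summary(
    emap: EnfaceMap,
    center_diameter_mm: float = 2.0,
    whole_diameter_mm: float = 5.0,
) -> RegionalSummary:
    """Fovea-centered regional means with pixel-center membership.

    A pixel belongs to the center disc if its center lies within 1 mm of
    the fovea, to the outer ring if strictly beyond 1 mm and within 2.5 mm
    (closed outer edges), and to the whole disc if within 2.5 mm.  Means
    ignore missing (NaN) pixels; an outer mean of zero leaves the
    center/outer ratio undefined (NaN).
    """
    pa, pb = emap.pitch_um
    na, nb = emap.values.shape
    fa, fb = emap.fovea
    da = (np.arange(na) - fa) * pa
    db = (np.arange(nb) - fb) * pb
    dist = np.sqrt(da[:, None] ** 2 + db[None, :] ** 2)  # um

    r_center = center_diameter_mm * 500.0
    r_whole = whole_diameter_mm * 500.0
    in_center = dist <= r_center
    in_whole = dist <= r_whole
    in_outer = in_whole & ~in_center

    def _mean_n(region: np.ndarray) -> tuple[float, int]:
        vals = emap.values[region]
        good = ~np.isnan(vals)
        n = int(good.sum())
        return (float(vals[good].mean()) if n else float("nan")), n

    whole_mean, whole_n = _mean_n(in_whole)
    center_mean, center_n = _mean_n(in_center)
    outer_mean, outer_n = _mean_n(in_outer)
    if outer_n == 0 or outer_mean == 0 or np.isnan(outer_mean) or np.isnan(center_mean):
        ratio = float("nan")
    else:
        ratio = center_mean / outer_mean
    return RegionalSummary(
        units=emap.units,
        whole_mean=whole_mean,
        center_mean=center_mean,
        outer_mean=outer_mean,
        center_outer_ratio=ratio,
        whole_n=whole_n,
        center_n=center_n,
        outer_n=outer_n,
    )


def repeatability_cv(measurements: np.ndarray) -> dict:
    """Coefficient of variation over repeated measurements per subject.

    ``measurements`` has shape ``(n_subjects, n_repeats)`` with
    ``n_repeats >= 2`` (the reference protocol uses four).  CV is the
    sample standard deviation divided by the mean, per subject; subjects
    with zero mean have no defined CV.  Returns per-subject CVs plus the
    cohort mean and SD of the defined CVs.
    """
    m = np.asarray(measurements, dtype=np.float64)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[1] < 2:
        raise ValueError("need at least two repeats per subject")
    means = m.mean(axis=1)
    sds = m.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvs = np.where(means != 0, sds / means, np.nan)
    good = ~np.isnan(cvs)
    if not good.any():
        warnings.warn("no subject has a defined CV (all means zero)")
    return {
        "cv": cvs,
        "mean_cv": float(cvs[good].mean()) if good.any() else float("nan"),
        "sd_cv": float(cvs[good].std(ddof=1)) if good.sum() > 1 else float("nan"),
    }
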