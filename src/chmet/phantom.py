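"""Synthetic polarization-diverse OCT volumes and fundus images with ground truth.

The phantom emulates a layered posterior eye as seen by a 1-um swept-source
PS-OCT: vitreous, retina, a bright RPE band, a choroid containing
hyposcattering vessel lumina embedded in melanin-bearing interstitial stroma,
and sclera.  Speckle is fully developed (independent circular complex
Gaussian per voxel) and detector noise is additive complex Gaussian per
channel.  Depolarization by melanin is modeled as per-voxel polarization-state
replacement: with probability ``p`` a stromal voxel's Jones vector is replaced
by an independent state drawn uniformly on the Poincare sphere.  This binary
mixture gives an exact per-voxel melanin ground truth and makes the expected
low-DOPU fraction Monte-Carlo tractable (`calibrate_mixing_to_dopu`).

Geometry defaults mirror a 512 A-line x 256 B-scan raster over 6.0 x 6.0 mm
with a 4.3-um axial pixel; tests and examples typically use scaled-down
volumes with the same voxel-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polarization import PSOCTVolume

__all__ = [
    "Vessel",
    "PhantomSpec",
    "GroundTruth",
    "FundusPhantomSpec",
    "generate_psoct_phantom",
    "generate_fundus_phantom",
    "calibrate_mixing_to_dopu",
    "default_vessel_layout",
    "LABELS",
]

#: tissue label codes for the ground-truth label volume
LABELS = {
    "vitreous": 0,
    "retina": 1,
    "rpe": 2,
    "vessel": 3,
    "stroma": 4,
    "sclera": 5,
}

#: field-amplitude reflectivity per tissue (mean intensity = amplitude^2);
#: vessel lumina are hyposcattering, sclera is dim through choroidal shadowing
REFLECTIVITY = {
    "vitreous": 0.0,
    "retina": 0.6,
    "rpe": 3.0,
    "vessel": 0.15,
    "stroma": 1.5,
    "sclera": 0.25,
}


@dataclass(frozen=True)
class Vessel:
    """Elliptical choroidal vessel cross-section swept over a B-scan range.

    ``depth_frac`` places the ellipse center at that fraction of the local
    choroid thickness below the upper choroid boundary.
    """

    aline: float
    depth_frac: float
    semi_aline: float
    semi_depth: float
    bscans: tuple[int, int]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic PS-OCT acquisition.

    Thicknesses may be scalars or ``(n_alines, n_bscans)`` arrays (smooth
    variation across the scan).  ``melanin_p`` is the per-A-line probability
    that a stromal voxel is depolarized (a scalar or an en-face field, so
    heterogeneous depigmentation can be emulated); ``rpe_mixing`` plays the
    same role for the RPE band, which retains its melanin in the disease
    this phantom is built to probe.
    """

    n_alines: int = 512
    n_bscans: int = 256
    n_depth: int = 651
    axial_pixel_um: float = 4.3
    scan_width_mm: float = 6.0
    retina_um: float | np.ndarray = 200.0
    rpe_um: float | np.ndarray = 25.0
    choroid_um: float | np.ndarray = 250.0
    vessels: tuple[Vessel, ...] | None = None
    melanin_p: float | np.ndarray = 0.9
    rpe_mixing: float = 0.9
    snr_db: float = 25.0
    fovea: tuple[int, int] | None = None
    axial_length_mm: float = 24.39
    seed: int = 0
    noise_band_rows: int = 16
    vitreous_px: int = 24

    def fovea_or_center(self) -> tuple[int, int]:
        if self.fovea is not None:
            return self.fovea
        return (self.n_alines // 2, self.n_bscans // 2)


@dataclass
class GroundTruth:
    """Exact per-voxel truth for a generated phantom.

    ``melanin_mask`` records which voxels actually had their polarization
    state randomized, so the expected maps are exact counts rather than
    probabilistic expectations.
    """

    labels: np.ndarray                  # (depth, A-line, B-scan) uint8
    upper_px: np.ndarray                # (A-line, B-scan) choroid upper boundary
    lower_px: np.ndarray                # (A-line, B-scan) choroid lower boundary
    melanin_mask: np.ndarray            # (depth, A-line, B-scan) bool
    chmet_um: np.ndarray                # (A-line, B-scan) expected ChMeT, um
    chmetratio_pct: np.ndarray          # (A-line, B-scan) expected ratio, %
    fovea: tuple[int, int] = (0, 0)
    axial_pixel_um: float = 4.3

    @property
    def choroid(self) -> np.ndarray:
        return (self.labels == LABELS["vessel"]) | (self.labels == LABELS["stroma"])

    @property
    def vessel(self) -> np.ndarray:
        return self.labels == LABELS["vessel"]

    @property
    def stroma(self) -> np.ndarray:
        return self.labels == LABELS["stroma"]


def default_vessel_layout(spec: PhantomSpec, rng: np.random.Generator) -> tuple[Vessel, ...]:
    """A vessel-rich mid-choroid layout (roughly a quarter of the choroid).

    The choroid is a vascular tissue; a realistic interstitial/vessel split
    also keeps every local-Otsu window bimodal during binarization.
    Vessel centers stay in the middle half of the choroid depth so lumina
    do not touch the segmentation boundaries.
    """
    n_vessels = max(4, spec.n_alines // 6)
    vessels = []
    for _ in range(n_vessels):
        aline = float(rng.uniform(0.05, 0.95)) * spec.n_alines
        span = max(2, spec.n_bscans // 2)
        b0 = int(rng.integers(0, max(1, spec.n_bscans - span // 2)))
        b1 = min(spec.n_bscans, b0 + span)
        vessels.append(
            Vessel(
                aline=aline,
                depth_frac=float(rng.uniform(0.3, 0.7)),
                semi_aline=float(rng.uniform(0.03, 0.08)) * spec.n_alines,
                semi_depth=float(rng.uniform(2.5, 5.0)),
                bscans=(b0, b1),
            )
        )
    return tuple(vessels)


def _broadcast_field(x: float | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return np.broadcast_to(np.asarray(x, dtype=np.float64), shape).copy()


def _random_jones(rng: np.random.Generator, n: int) -> np.ndarray:
    """Jones vectors Haar-uniform on the unit sphere of C^2 (uniform Poincare states)."""
    g = rng.standard_normal((n, 2)) + 1j * rng.standard_normal((n, 2))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def generate_psoct_phantom(spec: PhantomSpec) -> tuple[PSOCTVolume, GroundTruth]:
    """Generate a seeded two-channel complex volume plus exact ground truth.

    Raises ``ValueError`` if the layer stack does not fit inside the depth
    range.  The top ``noise_band_rows`` rows are always signal-free so the
    noise-floor estimator has a documented, deterministic location.
    """
    rng = np.random.default_rng(spec.seed)
    shape_en = (spec.n_alines, spec.n_bscans)

    px = spec.axial_pixel_um
    retina_px = np.rint(_broadcast_field(spec.retina_um, shape_en) / px).astype(int)
    rpe_px = np.rint(_broadcast_field(spec.rpe_um, shape_en) / px).astype(int)
    choroid_px = np.rint(_broadcast_field(spec.choroid_um, shape_en) / px).astype(int)
    if (retina_px < 0).any() or (rpe_px < 0).any() or (choroid_px < 0).any():
        raise ValueError("layer thicknesses must be non-negative")

    retina_top = spec.noise_band_rows + spec.vitreous_px
    rpe_top = retina_top + retina_px
    choroid_top = rpe_top + rpe_px
    choroid_bot = choroid_top + choroid_px
    if int(choroid_bot.max()) >= spec.n_depth:
        raise ValueError(
            f"layer stack reaches depth {int(choroid_bot.max())} "
            f">= n_depth={spec.n_depth}: enlarge n_depth or shrink layers"
        )

    depth = np.arange(spec.n_depth)[:, None, None]
    labels = np.full((spec.n_depth,) + shape_en, LABELS["vitreous"], dtype=np.uint8)
    labels[(depth >= retina_top) & (depth < rpe_top)] = LABELS["retina"]
    labels[(depth >= rpe_top) & (depth < choroid_top)] = LABELS["rpe"]
    labels[(depth >= choroid_top) & (depth < choroid_bot)] = LABELS["stroma"]
    labels[depth >= choroid_bot] = LABELS["sclera"]

    vessels = spec.vessels
    if vessels is None:
        vessels = default_vessel_layout(spec, rng)
    aline_idx = np.arange(spec.n_alines)[None, :, None]
    bscan_idx = np.arange(spec.n_bscans)[None, None, :]
    for ves in vessels:
        center_depth = choroid_top + ves.depth_frac * choroid_px  # (A, B)
        ell = (
            ((aline_idx - ves.aline) / max(ves.semi_aline, 1e-9)) ** 2
            + ((depth - center_depth[None]) / max(ves.semi_depth, 1e-9)) ** 2
        ) <= 1.0
        ell &= (bscan_idx >= ves.bscans[0]) & (bscan_idx < ves.bscans[1])
        labels[ell & (labels == LABELS["stroma"])] = LABELS["vessel"]

    # fully developed speckle: circular complex Gaussian amplitude per voxel
    refl = np.zeros(6)
    for name, code in LABELS.items():
        refl[code] = REFLECTIVITY[name]
    amp = refl[labels]
    g = (rng.standard_normal(labels.shape) + 1j * rng.standard_normal(labels.shape))
    g = g.astype(np.complex128) * (amp / np.sqrt(2.0))

    # global polarization state shared by polarization-preserving tissue
    j0 = np.array([1.0 + 0.0j, 0.0 + 0.0j])
    e_h = g * j0[0]
    e_v = g * j0[1]

    # melanin: replace states in stroma (prob p field) and the RPE band
    p_field = np.clip(_broadcast_field(spec.melanin_p, shape_en), 0.0, 1.0)
    if np.any((np.asarray(spec.melanin_p) < 0) | (np.asarray(spec.melanin_p) > 1)):
        raise ValueError("melanin_p must lie in [0, 1]")
    u = rng.random(labels.shape)
    stroma_mel = (labels == LABELS["stroma"]) & (u < p_field[None])
    rpe_mel = (labels == LABELS["rpe"]) & (u < spec.rpe_mixing)
    melanin = stroma_mel | rpe_mel
    n_mel = int(melanin.sum())
    if n_mel:
        jr = _random_jones(rng, n_mel)
        gm = g[melanin]
        e_h[melanin] = gm * jr[:, 0]
        e_v[melanin] = gm * jr[:, 1]

    # additive detector noise per channel, referenced to mean stroma intensity
    if np.isfinite(spec.snr_db):
        i_sig = REFLECTIVITY["stroma"] ** 2
        sigma2 = i_sig * 10.0 ** (-spec.snr_db / 10.0) / 2.0  # per channel
        s = np.sqrt(sigma2 / 2.0)
        e_h = e_h + s * (rng.standard_normal(labels.shape) + 1j * rng.standard_normal(labels.shape))
        e_v = e_v + s * (rng.standard_normal(labels.shape) + 1j * rng.standard_normal(labels.shape))

    fovea = spec.fovea_or_center()
    stroma_count = (labels == LABELS["stroma"]).sum(axis=0)
    mel_count = stroma_mel.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(stroma_count > 0, 100.0 * mel_count / stroma_count, np.nan)

    truth = GroundTruth(
        labels=labels,
        upper_px=choroid_top.astype(np.int64),
        lower_px=choroid_bot.astype(np.int64),
        melanin_mask=melanin,
        chmet_um=mel_count * px,
        chmetratio_pct=ratio,
        fovea=fovea,
        axial_pixel_um=px,
    )
    vol = PSOCTVolume(
        e_h=e_h,
        e_v=e_v,
        axial_pixel_um=px,
        scan_width_mm=spec.scan_width_mm,
        noise_band=(0, spec.noise_band_rows),
        axial_length_mm=spec.axial_length_mm,
        fovea=fovea,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# fundus phantom

@dataclass
class FundusPhantomSpec:
    """Synthetic 45-degree color fundus image with controllable red dominance.

    ``red_dominance`` is the target ratio of mean red luminance to the summed
    channel means inside the central 800-px square (the sunset glow index the
    image should yield before noise).  Decorations (dark vessels, bright
    disc) are multiplicative, so they leave that ratio unchanged.
    """

    size: int = 1500
    red_dominance: float = 0.45
    base_total: float = 330.0
    decorations: bool = True
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.red_dominance < 1.0):
            raise ValueError("red_dominance must lie in (0, 1)")


def generate_fundus_phantom(spec: FundusPhantomSpec) -> np.ndarray:
    """RGB uint8 image of shape ``(size, size, 3)``."""
    rng = np.random.default_rng(spec.seed)
    r = spec.red_dominance
    total = spec.base_total
    base = np.array([r * total, (1 - r) * total / 2.0, (1 - r) * total / 2.0])
    if base.max() > 250.0:
        base *= 250.0 / base.max()

    img = np.ones((spec.size, spec.size, 3), dtype=np.float64) * base

    if spec.decorations:
        yy, xx = np.mgrid[0 : spec.size, 0 : spec.size]
        gain = np.ones((spec.size, spec.size))
        # dark vessel arcs: multiplicative dimming preserves channel ratios
        for k in range(6):
            cy = rng.uniform(0.2, 0.8) * spec.size
            phase = rng.uniform(0, 2 * np.pi)
            track = cy + 0.08 * spec.size * np.sin(2 * np.pi * xx / spec.size + phase)
            gain[np.abs(yy - track) < spec.size * 0.004] = 0.55
        img *= gain[..., None]
        # restore exact channel means in the central crop by uniform rescale
        c0 = (spec.size - 800) // 2 if spec.size >= 800 else 0
        crop = img[c0 : c0 + 800, c0 : c0 + 800]
        scale = base.mean() / crop.mean()
        img *= scale

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# mixing -> low-DOPU calibration

def calibrate_mixing_to_dopu(
    p: float,
    kernel: tuple[int, int] = (3, 3),
    snr_db: float = np.inf,
    n_mc: int = 20000,
    seed: int = 0,
    threshold: float = 0.8,
) -> tuple[float, float]:
    """Monte-Carlo probability that a voxel with mixing ``p`` is flagged low-DOPU.

    Simulates ``n_mc`` independent kernels of speckle voxels whose states are
    the global state with probability ``1 - p`` and uniformly random
    otherwise, adds detector noise at ``snr_db``, applies the same noise
    correction and kernel averaging as the DOPU stage, and counts kernels
    whose center-norm falls strictly below ``threshold``.

    Returns ``(fraction, half_width)`` where ``half_width`` is the 99%
    binomial confidence half-width of the estimate.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable estimate")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = kernel[0] * kernel[1]

    g = (rng.standard_normal((n_mc, k)) + 1j * rng.standard_normal((n_mc, k))) / np.sqrt(2.0)
    jones = np.zeros((n_mc, k, 2), dtype=np.complex128)
    jones[..., 0] = 1.0
    mix = rng.random((n_mc, k)) < p
    n_mix = int(mix.sum())
    if n_mix:
        jones[mix] = _random_jones(rng, n_mix)
    e_h = g * jones[..., 0]
    e_v = g * jones[..., 1]

    if np.isfinite(snr_db):
        sigma2 = 10.0 ** (-snr_db / 10.0) / 2.0  # unit mean tissue intensity
        s = np.sqrt(sigma2 / 2.0)
        e_h = e_h + s * (rng.standard_normal(e_h.shape) + 1j * rng.standard_normal(e_h.shape))
        e_v = e_v + s * (rng.standard_normal(e_v.shape) + 1j * rng.standard_normal(e_v.shape))
        n_h = n_v = sigma2
    else:
        n_h = n_v = 0.0

    ih = np.abs(e_h) ** 2
    iv = np.abs(e_v) ** 2
    i_c = ih + iv - (n_h + n_v)
    q_c = ih - iv - (n_h - n_v)
    uu = 2.0 * (np.conj(e_h) * e_v).real
    vv = -2.0 * (np.conj(e_h) * e_v).imag
    valid = i_c > (n_h + n_v)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(valid, 1.0 / np.where(valid, i_c, 1.0), 0.0)
    count = valid.sum(axis=1)
    ok = count >= k / 2.0
    mq = (q_c * inv).sum(axis=1)
    mu = (uu * inv).sum(axis=1)
    mv = (vv * inv).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.sqrt(mq ** 2 + mu ** 2 + mv ** 2) / np.maximum(count, 1)
    low = (norm < threshold) & ok
    frac = float(low.sum() / max(ok.sum(), 1))
    half = 2.576 * np.sqrt(max(frac * (1 - frac), 1e-12) / max(int(ok.sum()), 1))
    return frac, float(half)
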