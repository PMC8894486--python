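"""Disk formats: TIFF volumes with JSON sidecars, en-face maps, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .chorosegment import ChoroidBoundaries
from .melanin_metrics import EnfaceMap, RegionalSummary
from .polarization import PSOCTVolume


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def save_volume(vol: PSOCTVolume, basepath: str | Path) -> None:
    """Write the two channels as multi-page float32 TIFFs plus a JSON sidecar.

    Each complex channel is stored as interleaved real/imaginary planes
    (page 2k = Re of B-scan k, page 2k+1 = Im).
    """
    base = Path(basepath)
    for name, ch in (("H", vol.e_h), ("V", vol.e_v)):
        pages = np.empty((2 * ch.shape[2],) + ch.shape[:2], dtype=np.float32)
        pages[0::2] = np.moveaxis(ch.real, 2, 0)
        pages[1::2] = np.moveaxis(ch.imag, 2, 0)
        tifffile.imwrite(base.with_suffix(f".ch{name}.tif"), pages)
    save_json(
        {
            "axial_pixel_um": vol.axial_pixel_um,
            "scan_width_mm": vol.scan_width_mm,
            "noise_band": list(vol.noise_band),
            "axial_length_mm": vol.axial_length_mm,
            "fovea": list(vol.fovea) if vol.fovea else None,
            "shape": list(vol.e_h.shape),
        },
        base.with_suffix(".json"),
    )


def load_volume(basepath: str | Path) -> PSOCTVolume:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    channels = {}
    for name in ("H", "V"):
        pages = tifffile.imread(base.with_suffix(f".ch{name}.tif"))
        ch = (pages[0::2] + 1j * pages[1::2]).astype(np.complex128)
        channels[name] = np.moveaxis(ch, 0, 2)
    return PSOCTVolume(
        e_h=channels["H"],
        e_v=channels["V"],
        axial_pixel_um=meta["axial_pixel_um"],
        scan_width_mm=meta["scan_width_mm"],
        noise_band=tuple(meta["noise_band"]),
        axial_length_mm=meta["axial_length_mm"],
        fovea=tuple(meta["fovea"]) if meta.get("fovea") else None,
    )


def save_label_volume(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.moveaxis(labels.astype(np.uint8), 2, 0))


def save_mask_volume(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.moveaxis(mask.astype(np.uint8) * 255, 2, 0))


def save_enface_map(emap: EnfaceMap, path: str | Path) -> None:
    """32-bit float TIFF with a JSON sidecar carrying units and geometry."""
    p = Path(path)
    tifffile.imwrite(p, emap.values.astype(np.float32))
    save_json(
        {
            "units": emap.units,
            "pitch_um": list(emap.pitch_um),
            "fovea": list(emap.fovea),
        },
        p.with_suffix(".json"),
    )


def render_enface_png(emap: EnfaceMap, path: str | Path, vmax: float | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(emap.values.T, origin="lower", cmap="inferno", vmin=0, vmax=vmax)
    fig.colorbar(im, ax=ax, label=emap.units)
    ax.set_xlabel("A-line")
    ax.set_ylabel("B-scan")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_boundaries_csv(bounds: ChoroidBoundaries, path: str | Path) -> None:
    na, nb = bounds.upper.shape
    aa, bb = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    pd.DataFrame(
        {
            "bscan": bb.ravel(),
            "aline": aa.ravel(),
            "upper": bounds.upper.ravel(),
            "lower": bounds.lower.ravel(),
            "flagged": bounds.flagged.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def summary_row(summary: RegionalSummary) -> dict:
    return {
        "units": summary.units,
        "whole_mean": summary.whole_mean,
        "center_mean": summary.center_mean,
        "outer_mean": summary.outer_mean,
        "center_outer_ratio": summary.center_outer_ratio,
        "whole_n": summary.whole_n,
        "center_n": summary.center_n,
        "outer_n": summary.outer_n,
    }
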