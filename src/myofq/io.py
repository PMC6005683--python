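"""Image reading, result tables and QC figures.

Images come in as single-plane grayscale TIFF (8/16-bit) or PNG; the pixel
size is taken from TIFF resolution metadata when present and must otherwise
be supplied explicitly — it is never silently defaulted.  Results go out as
long-format CSV (one row per ROI or per image with a ``metric`` column) plus
optional PNG quality-control figures: the spectrum with its detected peak,
the cross-section image with detected centres, and the template radial
profile with the 26% crossing.

Coordinates are 0-based (row, col) with pixel centres at integer positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .core_signals import Image2D
from .crosswise import CrosswiseResult
from .lengthwise import LengthwiseResult

__all__ = [
    "ImageProvenance",
    "read_image",
    "write_image",
    "lengthwise_table",
    "crosswise_table",
    "write_results_csv",
    "write_config_echo",
    "save_lengthwise_qc",
    "save_crosswise_qc",
]

CSV_COLUMNS = ["file", "stage", "roi", "metric", "value", "units", "qc"]


@dataclass(frozen=True)
class ImageProvenance:
    path: str
    bit_depth: int
    pixel_size_source: str  # "metadata" | "override"


_UNIT_TO_UM = {2: 25400.0, 3: 10000.0}  # inch, cm


def _pixel_size_from_tiff(page) -> Optional[float]:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags.get("ResolutionUnit")
    unit_um = _UNIT_TO_UM.get(getattr(unit, "value", 1), None)
    if unit_um is None:
        # ImageJ-style TIFFs use unit NONE with the resolution in px/µm; a
        # writer default of exactly 1 px/unit means "no information".
        if num == den:
            return None
        unit_um = 1.0
    return float(den) / float(num) * unit_um


def read_image(
    path: str | Path,
    pixel_size_um: Optional[float] = None,
    channel: Optional[int] = None,
    slice_index: Optional[int] = None,
) -> tuple[Image2D, ImageProvenance]:
    """Load a grayscale micrograph with a definite physical pixel size.

    ``pixel_size_um`` overrides any file metadata.  Multi-channel or stacked
    files require ``channel`` / ``slice_index``; anything else is an error —
    the caller must be explicit about what plane is analysed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_px: Optional[float] = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta_px = _pixel_size_from_tiff(tf.pages[0])
            ij = tf.imagej_metadata
            if ij and "spacing" in ij and meta_px is None:
                meta_px = float(ij["spacing"])
    else:
        from PIL import Image as PILImage

        arr = np.asarray(PILImage.open(path))

    if arr.ndim == 3:
        # Stack (planes first) or multichannel (channels last).
        if arr.shape[-1] in (3, 4) and channel is None and slice_index is None:
            raise ValueError(
                f"{path.name} is multi-channel {arr.shape}; select one with "
                "--channel"
            )
        if arr.shape[-1] in (3, 4) and channel is not None:
            arr = arr[..., channel]
        elif slice_index is not None:
            arr = arr[slice_index]
        elif channel is not None:
            arr = arr[channel]
        else:
            raise ValueError(
                f"{path.name} is a stack {arr.shape}; select a plane with "
                "--slice"
            )
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D plane, got shape {arr.shape}")

    if pixel_size_um is not None:
        px, source = float(pixel_size_um), "override"
    elif meta_px is not None:
        px, source = meta_px, "metadata"
    else:
        raise ValueError(
            f"{path.name} carries no pixel-size metadata; pass pixel_size_um "
            "explicitly"
        )
    prov = ImageProvenance(
        path=str(path), bit_depth=arr.dtype.itemsize * 8, pixel_size_source=source
    )
    return Image2D(pixels=arr.astype(float), pixel_size_um=px, label=path.name), prov


def write_image(img: Image2D, path: str | Path) -> None:
    """Write an image as 16-bit TIFF with px/µm resolution tags."""
    path = Path(path)
    arr = np.clip(img.pixels, 0, 65535).astype(np.uint16)
    res = 1.0 / img.pixel_size_um  # pixels per um, ImageJ convention
    tifffile.imwrite(
        path, arr, imagej=True, resolution=(res, res), metadata={"unit": "um"}
    )


def _row(file: str, stage: str, roi, metric: str, value, units: str, qc: str = ""):
    return {
        "file": file, "stage": stage, "roi": roi, "metric": metric,
        "value": value, "units": units, "qc": qc,
    }


def lengthwise_table(
    result: LengthwiseResult, file: str = "", stage: str = ""
) -> pd.DataFrame:
    """Long-format table: one repeat and one width row per ROI, plus summary rows."""
    rows = []
    for m in result.rois:
        if m.ok:
            qc = f"prominence={m.peak_prominence:.3g}" + (
                ";band_edge" if m.peak_on_band_edge else ""
            )
            rows.append(_row(file, stage, m.index, "repeat", m.repeat_um, "um", qc))
            rows.append(
                _row(
                    file, stage, m.index, "thickness",
                    m.width_um if m.minimum_found else np.nan, "um",
                    "" if m.minimum_found else "no_minimum",
                )
            )
        else:
            rows.append(_row(file, stage, m.index, "repeat", np.nan, "um", m.error))
    for key, units in [
        ("repeat_mean_um", "um"), ("repeat_median_um", "um"),
        ("width_mean_um", "um"), ("width_median_um", "um"),
        ("repeat_cv", ""), ("n_valid_rois", ""),
    ]:
        if key in result.summary:
            rows.append(
                _row(file, stage, "summary", key, result.summary[key], units)
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def crosswise_table(
    result: CrosswiseResult, file: str = "", stage: str = ""
) -> pd.DataFrame:
    """Long-format table of the crosswise per-image quantities."""
    rows = [
        _row(file, stage, "image", "diameter", result.diameter_um, "um"),
        _row(
            file, stage, "image", "initial_diameter", result.d0_um, "um",
            "fallback" if result.d0_fallback else "",
        ),
        _row(file, stage, "image", "n_fibrils", result.n_detected, ""),
        _row(file, stage, "image", "density", result.density_per_um2, "per_um2"),
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_results_csv(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a results CSV with exact (round-trip) float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def write_config_echo(config: dict, path: str | Path) -> None:
    """Machine-readable echo of every effective configuration value."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _agg():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def save_lengthwise_qc(result: LengthwiseResult, path: str | Path) -> None:
    """Spectra of all valid ROIs with the detected repeat marked."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(7, 4))
    for spectrum, m in zip(result.qc_spectra, [r for r in result.rois if r.ok]):
        ax.semilogy(spectrum.axis, spectrum.values, lw=0.7, alpha=0.6)
        ax.axvline(1.0 / m.repeat_um, color="crimson", lw=0.6, ls="--")
    ax.set_xlabel("horizontal frequency (cycles/um)")
    ax.set_ylabel("power")
    ax.set_title("per-ROI spectra with detected sarcomere frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_crosswise_qc(
    img: Image2D, result: CrosswiseResult, path: str | Path
) -> None:
    """Detected centres over the image, and the radial profile with its crossing."""
    plt = _agg()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 5))
    ax1.imshow(img.pixels, cmap="gray")
    ax1.plot(
        result.cross_sections.centers[:, 1],
        result.cross_sections.centers[:, 0],
        "r+", ms=4, mew=0.6,
    )
    ax1.set_title(f"{result.n_detected} cross-sections")
    ax1.set_axis_off()
    p = result.radial_profile
    ax2.plot(p.axis, p.values)
    ax2.axhline(result.threshold_value, color="crimson", ls="--", lw=0.8)
    ax2.axvline(result.diameter_um / 2.0, color="crimson", lw=0.8)
    ax2.set_xlabel("radius (um)")
    ax2.set_ylabel("mean intensity")
    ax2.set_title(f"template radial profile; diameter {result.diameter_um:.3f} um")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
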