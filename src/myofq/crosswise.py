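"""Transverse analysis: myofibril diameter, count and density.

On a fiber cross-section every myofibril appears as a bright disk.  The
pipeline is:

1. **Initial scale** — the first minimum of the radial-averaged image
   autocorrelation gives a rough disk scale d0 (a mixture of disk size and
   packing distance; it only calibrates later steps, never the result).
2. **Detection** — local intensity maxima of a lightly smoothed image, with a
   minimum separation and an intensity threshold, both derived from d0.
3. **Template averaging** — equal-size crops around every detected centre are
   recentred on their intensity centroid and averaged into a noise-free
   template of the typical cross-section.
4. **Diameter** — the template's radial intensity profile is measured where it
   falls to 26% of its range (full width at 26%), the operational diameter
   definition used throughout.

Density is the detected count over the border-margin-excluded search area, so
disks that could not have been detected (their crop would leave the frame) do
not deflate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.feature import peak_local_max

from .core_signals import (
    ACFMap,
    Image2D,
    Profile1D,
    autocorrelate_2d,
    first_local_minimum,
    radial_average,
)
from .errors import (
    AnalysisError,
    DegenerateTemplateError,
    EmptySetError,
    NoCrossingError,
    NoMinimumError,
)

__all__ = [
    "CrosswiseConfig",
    "CrossSectionSet",
    "CrosswiseResult",
    "initial_diameter",
    "detect_cross_sections",
    "average_cross_section",
    "radial_intensity_profile",
    "diameter_from_template",
    "analyze_crosswise",
]

MIN_CROP_HALFWIDTH_PX = 8


@dataclass(frozen=True)
class CrosswiseConfig:
    """Tunable knobs of the crosswise pipeline.

    ``crop_factor`` sets the crop side to ``crop_factor * d0``;
    ``threshold_k`` the detection threshold ``median + k * MAD`` (statistics
    of the raw image, applied to the smoothed one); ``range_anchor`` chooses
    whether the 26% diameter threshold is anchored at the profile minimum
    (``"min"``, the range reading) or at zero (``"zero"``, fraction of the
    absolute maximum).
    """

    crop_factor: float = 2.0
    threshold_k: float = 3.0
    min_separation_factor: float = 0.8
    smooth_sigma_factor: float = 0.25
    diameter_fraction: float = 0.26
    range_anchor: str = "min"
    fallback_d0_um: float = 1.0
    recenter: bool = True


@dataclass(frozen=True)
class CrossSectionSet:
    """Detected cross-section centres and the geometry of their crops."""

    centers: np.ndarray  # (n, 2) int array of (row, col)
    crop_halfwidth_px: int
    valid_area_um2: float
    threshold: float
    smooth_sigma_px: float

    @property
    def n_detected(self) -> int:
        return int(self.centers.shape[0])


@dataclass(frozen=True)
class CrosswiseResult:
    """Full crosswise analysis output."""

    n_detected: int
    diameter_um: float
    d0_um: float
    d0_fallback: bool
    density_per_um2: float
    template: Image2D
    radial_profile: Profile1D
    cross_sections: CrossSectionSet
    threshold_value: float  # intensity at the 26% crossing


def initial_diameter(
    img: Image2D, fallback_um: float = 1.0, smooth_halfwidth: int = 1
) -> tuple[float, bool]:
    """Rough disk scale: first minimum of the radial-averaged autocorrelation.

    Returns ``(d0_um, used_fallback)``.  When the radial profile has no
    interior minimum (e.g. a single disk on black), the configured fallback is
    returned flagged — d0 only calibrates the crop geometry downstream.
    """
    acf = autocorrelate_2d(img)
    profile = radial_average(acf)
    try:
        return first_local_minimum(profile, smooth_halfwidth=smooth_halfwidth), False
    except NoMinimumError:
        return fallback_um, True


def detect_cross_sections(
    img: Image2D, d0_um: float, config: CrosswiseConfig = CrosswiseConfig()
) -> CrossSectionSet:
    """Locate cross-section centres as thresholded local intensity maxima.

    The image is smoothed with a Gaussian of σ = ``smooth_sigma_factor * d0``;
    maxima closer than ``min_separation_factor * d0`` keep only the brighter
    one, maxima dimmer than ``median + k * MAD`` of the raw image are dropped,
    and maxima within one crop halfwidth of a border are discarded so every
    retained centre supports a full crop.

    Raises
    ------
    EmptySetError
        If no peak survives; the message carries threshold diagnostics.
    """
    if d0_um <= 0:
        raise ValueError(f"d0_um must be > 0, got {d0_um}")
    px = img.pixel_size_um
    d0_px = d0_um / px
    sigma_px = config.smooth_sigma_factor * d0_px
    smoothed = gaussian_filter(img.pixels, sigma_px, mode="reflect")
    med = float(np.median(img.pixels))
    mad = float(np.median(np.abs(img.pixels - med)))
    threshold = med + config.threshold_k * mad
    halfwidth = max(
        int(round(config.crop_factor * d0_px / 2.0)), MIN_CROP_HALFWIDTH_PX
    )
    min_sep = max(int(round(config.min_separation_factor * d0_px)), 1)
    peaks = peak_local_max(
        smoothed,
        min_distance=min_sep,
        threshold_abs=threshold,
        exclude_border=halfwidth,
    )
    rows, cols = img.shape
    valid_area_um2 = (rows - 2 * halfwidth) * (cols - 2 * halfwidth) * px**2
    if peaks.shape[0] == 0:
        raise EmptySetError(
            f"no cross-section found: threshold {threshold:.3g} "
            f"(median {med:.3g} + {config.threshold_k} * MAD {mad:.3g}), "
            f"smoothed max {smoothed.max():.3g}, border margin {halfwidth} px"
        )
    return CrossSectionSet(
        centers=peaks.astype(int),
        crop_halfwidth_px=halfwidth,
        valid_area_um2=valid_area_um2,
        threshold=threshold,
        smooth_sigma_px=sigma_px,
    )


def _centroid_shift(crop: np.ndarray, radius_px: float) -> tuple[int, int]:
    """Integer offset of the intensity centroid within ``radius_px`` of centre."""
    n = crop.shape[0]
    c = n // 2
    dy = np.arange(n)[:, None] - c
    dx = np.arange(n)[None, :] - c
    mask = np.hypot(dy, dx) <= radius_px
    w = np.clip(crop - np.median(crop), 0.0, None) * mask
    total = w.sum()
    if total <= 0:
        return 0, 0
    return int(round(float((w * dy).sum() / total))), int(
        round(float((w * dx).sum() / total))
    )


def average_cross_section(
    img: Image2D,
    cross_sections: CrossSectionSet,
    d0_um: Optional[float] = None,
    recenter: bool = True,
) -> Image2D:
    """Average equal-size crops around every detected centre into a template.

    Each crop is optionally recentred on its intensity centroid (searched
    within d0/2 of the nominal centre, integer shifts only) before averaging;
    this removes the ±1 px detection jitter that would otherwise blur the
    template edge.  Centres whose recentred crop would leave the frame keep
    their original crop.
    """
    if cross_sections.n_detected < 1:
        raise ValueError("need at least one detected cross-section")
    h = cross_sections.crop_halfwidth_px
    rows, cols = img.shape
    radius_px = (
        (d0_um / img.pixel_size_um) / 2.0 if d0_um is not None else float(h) / 2.0
    )
    acc = np.zeros((2 * h + 1, 2 * h + 1), dtype=float)
    for r, c in cross_sections.centers:
        crop = img.pixels[r - h : r + h + 1, c - h : c + h + 1]
        if recenter:
            dr, dc = _centroid_shift(crop, radius_px)
            r2, c2 = r + dr, c + dc
            if h <= r2 < rows - h and h <= c2 < cols - h:
                crop = img.pixels[r2 - h : r2 + h + 1, c2 - h : c2 + h + 1]
        acc += crop
    acc /= cross_sections.n_detected
    return Image2D(
        pixels=acc, pixel_size_um=img.pixel_size_um, label="cross-section template"
    )


def radial_intensity_profile(
    template: Image2D, step_px: float = 0.25, n_angles: int = 180
) -> Profile1D:
    """Angle-averaged radial intensity about the template centre.

    Sampled by polar resampling (bilinear interpolation on ``n_angles`` rays,
    radial step ``step_px``), which gives a smooth sub-pixel profile; distinct
    from the per-pixel distance binning used for autocorrelation maps.
    """
    n = template.shape[0]
    c = (n - 1) / 2.0
    r_max = n // 2
    radii = np.arange(0.0, r_max + step_px / 2.0, step_px)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    rr = radii[:, None]
    coords_r = c + rr * np.sin(angles)[None, :]
    coords_c = c + rr * np.cos(angles)[None, :]
    samples = map_coordinates(
        template.pixels, [coords_r, coords_c], order=1, mode="nearest"
    )
    return Profile1D(
        axis=radii * template.pixel_size_um,
        values=samples.mean(axis=1),
        kind="radial_acf",
    )


def diameter_from_template(
    template: Image2D,
    fraction: float = 0.26,
    range_anchor: str = "min",
) -> tuple[float, Profile1D, float]:
    """Full width of the template's radial profile at a fraction of its range.

    The threshold is ``min + fraction * (max - min)`` (``range_anchor="min"``)
    or ``fraction * max`` (``range_anchor="zero"``); the diameter is twice the
    smallest radius at which the profile crosses the threshold downward,
    located by linear interpolation between radial samples.

    Returns ``(diameter_um, radial_profile, threshold_value)``.

    Raises
    ------
    DegenerateTemplateError
        If the profile is flat (no measurable range).
    NoCrossingError
        If the profile never crosses the threshold downward.
    """
    profile = radial_intensity_profile(template)
    vals, ax = profile.values, profile.axis
    vmax, vmin = float(vals.max()), float(vals.min())
    if vmax - vmin <= 1e-12 * max(abs(vmax), 1.0):
        raise DegenerateTemplateError("template radial profile is flat")
    if range_anchor == "min":
        threshold = vmin + fraction * (vmax - vmin)
    elif range_anchor == "zero":
        threshold = fraction * vmax
    else:
        raise ValueError(f"range_anchor must be 'min' or 'zero', got {range_anchor!r}")
    for i in range(vals.size - 1):
        if vals[i] >= threshold > vals[i + 1]:
            t = (vals[i] - threshold) / (vals[i] - vals[i + 1])
            r_star = ax[i] + t * (ax[i + 1] - ax[i])
            return 2.0 * float(r_star), profile, float(threshold)
    raise NoCrossingError(
        f"radial profile never crosses the {fraction:.0%} threshold downward"
    )


def analyze_crosswise(
    img: Image2D, config: CrosswiseConfig = CrosswiseConfig()
) -> CrosswiseResult:
    """Full crosswise analysis of one transverse micrograph.

    Runs scale estimation, detection, template averaging and the diameter
    read-out; density is count over the border-excluded search area.  Stage
    failures propagate with the stage named in the message.
    """
    d0_um, d0_fallback = initial_diameter(img, fallback_um=config.fallback_d0_um)
    try:
        cross_sections = detect_cross_sections(img, d0_um, config)
    except EmptySetError as exc:
        raise EmptySetError(f"detection stage: {exc}") from exc
    template = average_cross_section(
        img, cross_sections, d0_um=d0_um, recenter=config.recenter
    )
    try:
        diameter_um, profile, threshold = diameter_from_template(
            template,
            fraction=config.diameter_fraction,
            range_anchor=config.range_anchor,
        )
    except (DegenerateTemplateError, NoCrossingError) as exc:
        raise AnalysisError(f"diameter stage: {exc}") from exc
    return CrosswiseResult(
        n_detected=cross_sections.n_detected,
        diameter_um=diameter_um,
        d0_um=d0_um,
        d0_fallback=d0_fallback,
        density_per_um2=cross_sections.n_detected / cross_sections.valid_area_um2,
        template=template,
        radial_profile=profile,
        cross_sections=cross_sections,
        threshold_value=threshold,
    )
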