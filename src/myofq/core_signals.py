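"""Shared signal-processing primitives for striation and cross-section analysis.

This module owns the numerics that both analysis pipelines build on:

* 2-D circular autocorrelation of a micrograph, normalized to 1 at zero lag
  (:func:`autocorrelate_2d`),
* radial and axial lag profiles of that autocorrelation
  (:func:`radial_average`, :func:`axis_profile`),
* a row-averaged horizontal power spectrum (:func:`horizontal_power_spectrum`),
* sub-sample extremum location (:func:`first_local_minimum`,
  :func:`dominant_peak`).

Conventions
-----------
Images are (row, col) arrays with the pixel centre of sample ``[i, j]`` at
integer coordinates ``(i, j)``; the physical pixel size is isotropic and given
in µm.  Lag maps place zero lag at the central sample ``(rows // 2,
cols // 2)``.  All physical axes are in µm (lags) or cycles/µm (frequencies).

The autocorrelation is the circular (wrap-around) one computed through the
power spectrum after mean subtraction; mean subtraction removes the DC
pedestal that would otherwise mask the first minimum, and the wrap-around
convention keeps the unit normalization at zero lag exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Optional

import numpy as np

from .errors import BandError, DegenerateInputError, NoMinimumError

__all__ = [
    "Image2D",
    "ACFMap",
    "Profile1D",
    "PeakEstimate",
    "autocorrelate_2d",
    "radial_average",
    "axis_profile",
    "horizontal_power_spectrum",
    "first_local_minimum",
    "dominant_peak",
    "parabolic_vertex_offset",
]

MIN_IMAGE_SIDE = 16


@dataclass(frozen=True)
class Image2D:
    """A 2-D fluorescence intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels
        Non-negative intensity samples, shape ``(rows, cols)``, arbitrary
        fluorescence units.
    pixel_size_um
        Physical edge length of one (square) pixel in µm.
    label
        Optional free-text provenance (channel, stage, file of origin).
    """

    pixels: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} px, "
                f"got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0:
            raise ValueError("image contains negative intensities")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the field of view in µm."""
        return (
            self.shape[0] * self.pixel_size_um,
            self.shape[1] * self.pixel_size_um,
        )


@dataclass(frozen=True)
class ACFMap:
    """Normalized 2-D autocorrelation, zero lag at the central sample."""

    values: np.ndarray
    pixel_size_um: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


ProfileKind = Literal["radial_acf", "vertical_acf", "horizontal_acf", "horizontal_spectrum"]


@dataclass(frozen=True)
class Profile1D:
    """A 1-D sampled curve with a physical axis.

    ``axis`` is strictly increasing; units are µm for lag profiles and
    cycles/µm for spectra, recorded in ``kind``.
    """

    axis: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if ax.ndim != 1 or vals.ndim != 1 or ax.size != vals.size:
            raise ValueError("axis and values must be 1-D and of equal length")
        if ax.size < 3:
            raise ValueError("profile needs at least 3 samples")
        if not np.all(np.diff(ax) > 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "axis", ax)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.axis.size)


class PeakEstimate(NamedTuple):
    """A refined spectral peak with its quality-control score."""

    frequency: float          # cycles/µm, sub-bin refined
    prominence: float         # peak power / median in-band power
    on_band_edge: bool        # True when the argmax sat on a band boundary


def autocorrelate_2d(img: Image2D) -> ACFMap:
    """Circular, mean-subtracted 2-D autocorrelation, unit value at zero lag.

    Computed through the power spectrum (Wiener–Khinchin), then recentred so
    the zero-lag sample sits at ``(rows // 2, cols // 2)``.

    Raises
    ------
    DegenerateInputError
        If the image has zero variance (constant frame).
    """
    x = img.pixels - img.pixels.mean()
    if not np.any(x):
        raise DegenerateInputError(
            "autocorrelation undefined for a constant (zero-variance) image"
        )
    f = np.fft.fft2(x)
    acf = np.fft.ifft2(np.abs(f) ** 2).real
    acf /= acf[0, 0]
    acf = np.fft.fftshift(acf)
    return ACFMap(values=acf, pixel_size_um=img.pixel_size_um)


def _radial_bin_indices(shape: tuple[int, int], center: tuple[int, int],
                        bin_width_px: float) -> np.ndarray:
    rows, cols = shape
    dy = np.arange(rows)[:, None] - center[0]
    dx = np.arange(cols)[None, :] - center[1]
    r = np.hypot(dy, dx)
    return np.floor(r / bin_width_px).astype(int)


def radial_average(acf: ACFMap, bin_width_px: float = 1.0) -> Profile1D:
    """Azimuthally averaged lag profile of an autocorrelation map.

    Sample ``k`` is the mean of all map values whose Euclidean lag falls in
    ``[k*b, (k+1)*b)`` pixels; the axis reports bin centres in µm.  Empty bins
    are dropped.
    """
    if bin_width_px < 0.5:
        raise ValueError(f"bin_width_px must be >= 0.5, got {bin_width_px}")
    idx = _radial_bin_indices(acf.shape, acf.center, bin_width_px)
    flat_idx = idx.ravel()
    sums = np.bincount(flat_idx, weights=acf.values.ravel())
    counts = np.bincount(flat_idx)
    occupied = counts > 0
    values = sums[occupied] / counts[occupied]
    centers_px = (np.flatnonzero(occupied) + 0.5) * bin_width_px
    return Profile1D(
        axis=centers_px * acf.pixel_size_um,
        values=values,
        kind="radial_acf",
    )


def axis_profile(acf: ACFMap, axis: Literal["vertical", "horizontal"]) -> Profile1D:
    """1-D slice of the autocorrelation through zero lag, non-negative lags.

    ``vertical`` walks down rows (lag in the row direction); ``horizontal``
    walks along columns.  Returns ``ceil(n/2)`` samples, lag axis in µm.
    """
    r0, c0 = acf.center
    if axis == "vertical":
        vals = acf.values[r0:, c0]
    elif axis == "horizontal":
        vals = acf.values[r0, c0:]
    else:
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
    lags = np.arange(vals.size) * acf.pixel_size_um
    return Profile1D(axis=lags, values=vals.copy(), kind=f"{axis}_acf")


def horizontal_power_spectrum(
    img: Image2D, window: Literal["hann", "none"] = "hann"
) -> Profile1D:
    """Power per horizontal spatial frequency, averaged over vertical frequencies.

    The image is mean-subtracted, each row optionally multiplied by a periodic
    Hann window (reduces leakage when the striation period does not divide the
    row length), 2-D Fourier transformed, and the power is averaged over all
    vertical frequencies.  Positive horizontal frequencies only, DC excluded;
    axis in cycles/µm.

    Raises
    ------
    DegenerateInputError
        If the image has zero variance.
    """
    x = img.pixels - img.pixels.mean()
    if not np.any(x):
        raise DegenerateInputError("spectrum undefined for a constant image")
    rows, cols = x.shape
    if window == "hann":
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(cols) / cols)
        x = x * w[None, :]
    elif window != "none":
        raise ValueError(f"window must be 'hann' or 'none', got {window!r}")
    power = np.abs(np.fft.fft2(x)) ** 2
    keep = np.arange(1, cols // 2 + 1)
    freqs = keep / (cols * img.pixel_size_um)
    values = power[:, keep].mean(axis=0)
    return Profile1D(axis=freqs, values=values, kind="horizontal_spectrum")


def parabolic_vertex_offset(y_minus: float, y0: float, y_plus: float) -> float:
    """Sub-sample vertex offset of the parabola through three equispaced samples.

    Returns the offset (in samples, clipped to [-0.5, 0.5]) of the extremum
    relative to the central sample: ``-(y+ - y-) / (2 (y+ - 2 y0 + y-))``.
    A degenerate (flat) triple returns 0.
    """
    denom = y_plus - 2.0 * y0 + y_minus
    if denom == 0:
        return 0.0
    return float(np.clip(-(y_plus - y_minus) / (2.0 * denom), -0.5, 0.5))


def _moving_average(values: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth <= 0:
        return values
    kernel = np.ones(2 * halfwidth + 1) / (2 * halfwidth + 1)
    padded = np.pad(values, halfwidth, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def first_local_minimum(profile: Profile1D, smooth_halfwidth: int = 0) -> float:
    """Axis position (µm) of the first interior local minimum of a profile.

    After optional moving-average smoothing (window ``2 h + 1``), the smallest
    index ``k > 0`` with ``v[k] <= v[k-1]`` and ``v[k] < v[k+1]`` is taken
    (ties resolved toward smaller lag) and refined to sub-sample precision by
    parabolic interpolation through its three surrounding samples.

    Raises
    ------
    NoMinimumError
        If no interior sample qualifies (e.g. a monotone profile).
    """
    if len(profile) < 5:
        raise ValueError("profile too short for minimum search (need >= 5 samples)")
    v = _moving_average(profile.values, smooth_halfwidth)
    ax = profile.axis
    for k in range(1, v.size - 1):
        if v[k] <= v[k - 1] and v[k] < v[k + 1]:
            offset = parabolic_vertex_offset(v[k - 1], v[k], v[k + 1])
            step = ax[k + 1] - ax[k] if offset >= 0 else ax[k] - ax[k - 1]
            return float(ax[k] + offset * step)
    raise NoMinimumError("profile has no interior local minimum")


def dominant_peak(
    profile: Profile1D,
    band: tuple[float, float],
) -> PeakEstimate:
    """Location of the strongest spectral peak inside a frequency band.

    The argmax of the in-band power (ties toward lower frequency) is refined
    by parabolic interpolation over the log-power of the three bins around it,
    using neighbours from the full profile so peaks adjacent to the band edge
    still refine.  The QC prominence is peak power over median in-band power.

    Raises
    ------
    BandError
        If the band contains no spectral sample or ``f_lo >= f_hi``.
    """
    f_lo, f_hi = band
    if not f_lo < f_hi:
        raise BandError(f"invalid band: [{f_lo}, {f_hi}]")
    ax, vals = profile.axis, profile.values
    in_band = (ax >= f_lo) & (ax <= f_hi)
    if not np.any(in_band):
        raise BandError(
            f"band [{f_lo}, {f_hi}] cycles/um contains no spectral sample "
            f"(axis spans [{ax[0]:.4g}, {ax[-1]:.4g}])"
        )
    band_idx = np.flatnonzero(in_band)
    k = band_idx[int(np.argmax(vals[band_idx]))]
    median_power = float(np.median(vals[band_idx]))
    prominence = float(vals[k] / median_power) if median_power > 0 else float("inf")
    on_edge = k == band_idx[0] or k == band_idx[-1]

    freq = float(ax[k])
    if 0 < k < ax.size - 1 and vals[k - 1] > 0 and vals[k + 1] > 0 and vals[k] > 0:
        logs = np.log(vals[k - 1 : k + 2])
        offset = parabolic_vertex_offset(logs[0], logs[1], logs[2])
        step = ax[k + 1] - ax[k] if offset >= 0 else ax[k] - ax[k - 1]
        freq = float(ax[k] + offset * step)
    return PeakEstimate(frequency=freq, prominence=prominence, on_band_edge=on_edge)
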