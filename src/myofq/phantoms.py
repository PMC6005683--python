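"""Synthetic fluorescence micrographs with known ground truth.

Two phantom classes mirror the two kinds of flight-muscle image the analysis
pipelines consume:

* **Lengthwise phantoms** — parallel myofibrils running horizontally, each a
  bright stripe of width ``fibril_width_um`` repeating every
  ``fibril_spacing_um`` across the image, carrying bright Z-line bands every
  ``repeat_um`` along the fibril axis (emulating a phalloidin + Z-disc
  composite stain).
* **Crosswise phantoms** — transverse fiber sections in which every myofibril
  appears as a bright disk; disks are dart-thrown with a minimum separation.

Both are blurred with an isotropic Gaussian point-spread function and sampled
with Poisson shot noise on top of a constant background, which is an adequate
noise model for photon-limited confocal imaging.  Generation is deterministic
under a fixed seed, and the returned ground-truth record echoes every
parameter needed to re-render the image bit-identically.

Diameter convention
-------------------
A fluorescent cross-section has no sharp geometric edge, so the stated disk
diameter uses the same operational definition the measurement reports: the
full width of the isolated blob's radial intensity profile at 26% of its
range.  Given the PSF width, the generator inverts the analytic forward model
of a blurred disk (its radial profile is a noncentral-χ² CDF in the squared
radius) to find the underlying tophat radius whose rendered blob has the
requested operational diameter.  With no blur the convention coincides with
the geometric tophat diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.stats import ncx2

from .core_signals import Image2D
from .errors import PhantomSpecError, PlacementError

__all__ = [
    "LengthwisePhantomSpec",
    "CrosswisePhantomSpec",
    "make_lengthwise_phantom",
    "make_crosswise_phantom",
    "make_stage_series",
    "blurred_disk_profile",
    "disk_render_radius_px",
    "DEFAULT_STAGE_TABLE",
]

#: Default PSF width: a Gaussian approximation of a high-NA confocal spot at
#: the 50 nm/px sampling the pipelines assume.
DEFAULT_PSF_SIGMA_UM = 0.15

#: Fraction of the radial-profile range defining the operational diameter.
DIAMETER_RANGE_FRACTION = 0.26


@dataclass(frozen=True)
class LengthwisePhantomSpec:
    """Parameters of a longitudinal (striation) phantom.

    ``duty_profile`` selects the transverse fibril profile: ``rect`` is a
    tophat stripe (duty cycle = width / spacing), ``gaussian`` a Gaussian
    ridge whose FWHM equals ``fibril_width_um``.  ``zdisc_contrast`` sets the
    body-to-Z-line intensity ratio: the fibril body renders at
    ``(1 - zdisc_contrast) * photon_peak`` and Z-lines at ``photon_peak``.
    """

    repeat_um: float
    fibril_width_um: float
    shape_px: tuple[int, int] = (512, 1024)
    pixel_size_um: float = 0.05
    fibril_spacing_um: Optional[float] = None  # default 2x width (50% duty)
    duty_profile: Literal["rect", "gaussian"] = "rect"
    zdisc_contrast: float = 0.6
    zline_width_px: float = 2.0
    rotation_deg: float = 0.0
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM
    photon_peak: float = 50.0
    background: float = 5.0
    seed: int = 0

    @property
    def spacing_um(self) -> float:
        return (
            self.fibril_spacing_um
            if self.fibril_spacing_um is not None
            else 2.0 * self.fibril_width_um
        )

    def validate(self) -> None:
        if self.repeat_um <= 2.0 * self.pixel_size_um:
            raise PhantomSpecError(
                f"repeat {self.repeat_um} um is at or below the Nyquist limit "
                f"for {self.pixel_size_um} um pixels"
            )
        if self.fibril_width_um <= 0:
            raise PhantomSpecError("fibril_width_um must be > 0")
        if self.spacing_um < self.fibril_width_um:
            raise PhantomSpecError("fibril spacing must be >= fibril width")
        if not 0.0 <= self.zdisc_contrast <= 1.0:
            raise PhantomSpecError("zdisc_contrast must lie in [0, 1]")
        if self.photon_peak <= 0:
            raise PhantomSpecError("photon_peak must be > 0")


@dataclass(frozen=True)
class CrosswisePhantomSpec:
    """Parameters of a transverse (cross-section) phantom.

    Exactly one of ``n_disks`` or ``density_per_um2`` must be set; density is
    interpreted over the placement region (frame minus border margin).
    ``disk_diameter_um`` follows the operational 26%-of-range convention (see
    module docstring).  ``edge_sigma_um`` applies only to the
    ``gaussian-edged`` profile and softens the disk edge before the PSF.
    """

    disk_diameter_um: float
    shape_px: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = 0.05
    n_disks: Optional[int] = None
    density_per_um2: Optional[float] = None
    min_separation_um: Optional[float] = None  # default 3x diameter
    edge_profile: Literal["tophat", "gaussian-edged"] = "tophat"
    edge_sigma_um: float = 0.05
    psf_sigma_um: float = 0.10
    photon_peak: float = 50.0
    background: float = 5.0
    margin_um: Optional[float] = None  # default min_sep/2 + 2x diameter
    seed: int = 0

    @property
    def separation_um(self) -> float:
        return (
            self.min_separation_um
            if self.min_separation_um is not None
            else 3.0 * self.disk_diameter_um
        )

    @property
    def border_margin_um(self) -> float:
        # Wide enough that the analysis-side crop window of every planted
        # disk lies fully inside the frame.
        if self.margin_um is not None:
            return self.margin_um
        return self.separation_um / 2.0 + 2.0 * self.disk_diameter_um

    def resolve_count(self) -> int:
        rows, cols = self.shape_px
        m = self.border_margin_um / self.pixel_size_um
        area_um2 = (
            max(rows - 2 * m, 0) * max(cols - 2 * m, 0) * self.pixel_size_um**2
        )
        if (self.n_disks is None) == (self.density_per_um2 is None):
            raise PhantomSpecError("set exactly one of n_disks / density_per_um2")
        if self.n_disks is not None:
            return int(self.n_disks)
        return int(round(self.density_per_um2 * area_um2))

    def validate(self) -> None:
        if self.disk_diameter_um <= 2.0 * self.pixel_size_um:
            raise PhantomSpecError("disk diameter must exceed 2 px")
        n = self.resolve_count()
        if n < 1:
            raise PhantomSpecError("phantom must contain at least one disk")
        rows, cols = self.shape_px
        m_px = self.border_margin_um / self.pixel_size_um
        usable = max(rows - 2 * m_px, 0) * max(cols - 2 * m_px, 0)
        sep_px = self.separation_um / self.pixel_size_um
        packing = n * np.pi * (sep_px / 2.0) ** 2 / max(usable, 1e-9)
        if packing >= 0.6:
            raise PhantomSpecError(
                f"requested packing fraction {packing:.2f} (by exclusion disks) "
                "is not feasible; reduce density or separation"
            )
        if self.photon_peak <= 0:
            raise PhantomSpecError("photon_peak must be > 0")


def blurred_disk_profile(r_um, radius_um: float, sigma_um: float):
    """Radial intensity of a unit tophat disk convolved with a Gaussian PSF.

    For blur σ the value at radius r is ``P(|X| <= R)`` with
    ``X ~ N(r, σ² I₂)``, i.e. the noncentral-χ²(2) CDF of ``(R/σ)²`` with
    noncentrality ``(r/σ)²``.  With σ = 0 this degenerates to the indicator
    of ``r <= R``.
    """
    r = np.asarray(r_um, dtype=float)
    if sigma_um <= 0:
        return (r <= radius_um).astype(float)
    return ncx2.cdf((radius_um / sigma_um) ** 2, 2, (r / sigma_um) ** 2)


def disk_render_radius_px(
    diameter_um: float, total_sigma_um: float, pixel_size_um: float,
    fraction: float = DIAMETER_RANGE_FRACTION,
) -> float:
    """Tophat radius (px) whose blurred blob has the requested operational diameter.

    Solves ``I(D/2; R, σ) = fraction * I(0; R, σ)`` for R, where I is the
    blurred-disk radial profile.  With σ = 0 the answer is exactly D/2.

    Raises
    ------
    PhantomSpecError
        If the target diameter is unresolvably small for the given blur.
    """
    target_r_um = diameter_um / 2.0
    if total_sigma_um <= 1e-9:
        return target_r_um / pixel_size_um

    def g(radius_um: float) -> float:
        i0 = blurred_disk_profile(0.0, radius_um, total_sigma_um)
        ir = blurred_disk_profile(target_r_um, radius_um, total_sigma_um)
        return float(ir - fraction * i0)

    lo, hi = 1e-4 * target_r_um, target_r_um
    if g(hi) <= 0:
        raise PhantomSpecError(
            f"diameter {diameter_um} um cannot be realised with blur "
            f"sigma {total_sigma_um} um"
        )
    if g(lo) >= 0:
        raise PhantomSpecError(
            f"diameter {diameter_um} um is unresolvably small for blur "
            f"sigma {total_sigma_um} um"
        )
    r_um = brentq(g, lo, hi, xtol=1e-6)
    return r_um / pixel_size_um


def _apply_noise(
    intensity: np.ndarray, background: float, rng: np.random.Generator,
    poisson: bool,
) -> np.ndarray:
    expected = intensity + background
    if not poisson:
        return expected
    return rng.poisson(expected).astype(float)


def make_lengthwise_phantom(
    spec: LengthwisePhantomSpec, *, poisson: bool = True
) -> tuple[Image2D, dict]:
    """Render a longitudinal striation phantom.

    Returns the image and a ground-truth record (the spec echoed as a dict,
    plus the noise flag) sufficient to re-render the phantom exactly.
    """
    spec.validate()
    rows, cols = spec.shape_px
    px = spec.pixel_size_um
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    if spec.rotation_deg != 0.0:
        theta = np.deg2rad(spec.rotation_deg)
        cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
        dy, dx = yy - cy, xx - cx
        # Rotate the pattern by +theta: sample it on coordinates rotated by -theta.
        xr = np.cos(theta) * dx + np.sin(theta) * dy
        yr = -np.sin(theta) * dx + np.cos(theta) * dy
    else:
        xr, yr = xx, yy

    spacing_px = spec.spacing_um / px
    width_px = spec.fibril_width_um / px
    repeat_px = spec.repeat_um / px

    phase_y = np.mod(yr, spacing_px)
    if spec.duty_profile == "rect":
        transverse = (phase_y < width_px).astype(float)
    else:  # gaussian ridge, FWHM = fibril width
        sigma_f = width_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        d = np.abs(phase_y - width_px / 2.0)
        d = np.minimum(d, spacing_px - d)  # periodic distance to ridge centre
        transverse = np.exp(-(d**2) / (2.0 * sigma_f**2))

    phase_x = np.mod(xr, repeat_px)
    zline = (phase_x < spec.zline_width_px).astype(float)

    body_level = 1.0 - spec.zdisc_contrast
    pattern = transverse * (body_level + (1.0 - body_level) * zline)
    intensity = spec.photon_peak * pattern
    if spec.psf_sigma_um > 0:
        intensity = gaussian_filter(intensity, spec.psf_sigma_um / px, mode="reflect")

    rng = np.random.default_rng(spec.seed)
    pixels = _apply_noise(intensity, spec.background, rng, poisson)
    img = Image2D(pixels=pixels, pixel_size_um=px, label="lengthwise-phantom")
    truth = {**asdict(spec), "poisson": poisson,
             "fibril_spacing_um": spec.spacing_um}
    return img, truth


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    rows: int,
    cols: int,
    margin_px: float,
    sep_px: float,
    max_attempts_per_disk: int = 2000,
) -> np.ndarray:
    """Place n centres with pairwise distance >= sep_px via dart throwing.

    A coarse occupancy grid (cell edge = sep) keeps each rejection test O(1).
    """
    lo_r, hi_r = margin_px, rows - 1 - margin_px
    lo_c, hi_c = margin_px, cols - 1 - margin_px
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError("border margin leaves no placement area")
    cell = sep_px
    grid: dict[tuple[int, int], list[int]] = {}
    centers = np.empty((n, 2), dtype=float)
    placed = 0
    attempts = 0
    budget = max_attempts_per_disk * n
    sep2 = sep_px * sep_px
    while placed < n:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n} disks with separation {sep_px:.1f} px "
                f"after {attempts} attempts ({placed} placed)"
            )
        attempts += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        ci, cj = int(r // cell), int(c // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    dr = centers[k, 0] - r
                    dc = centers[k, 1] - c
                    if dr * dr + dc * dc < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers[placed] = (r, c)
            grid.setdefault((ci, cj), []).append(placed)
            placed += 1
    return centers


def _render_disks(
    rows: int, cols: int, centers: np.ndarray, radius_px: float
) -> np.ndarray:
    """Additively render antialiased unit tophat disks on a zero canvas."""
    canvas = np.zeros((rows, cols), dtype=float)
    pad = int(np.ceil(radius_px)) + 2
    for r0, c0 in centers:
        ri, ci = int(round(r0)), int(round(c0))
        rlo, rhi = max(ri - pad, 0), min(ri + pad + 1, rows)
        clo, chi = max(ci - pad, 0), min(ci + pad + 1, cols)
        dy = np.arange(rlo, rhi)[:, None] - r0
        dx = np.arange(clo, chi)[None, :] - c0
        d = np.hypot(dy, dx)
        # 1-px linear edge ramp approximates pixel-area coverage.
        canvas[rlo:rhi, clo:chi] += np.clip(radius_px + 0.5 - d, 0.0, 1.0)
    return canvas


def make_crosswise_phantom(
    spec: CrosswisePhantomSpec, *, poisson: bool = True
) -> tuple[Image2D, np.ndarray, dict]:
    """Render a transverse cross-section phantom.

    Returns the image, the planted centres (n × 2 array of (row, col), in px,
    sub-pixel), and a ground-truth record including the solved tophat render
    radius and the placement-region area.
    """
    spec.validate()
    rows, cols = spec.shape_px
    px = spec.pixel_size_um
    n = spec.resolve_count()
    margin_px = spec.border_margin_um / px
    sep_px = spec.separation_um / px

    rng = np.random.default_rng(spec.seed)
    centers = _dart_throw(rng, n, rows, cols, margin_px, sep_px)

    if spec.edge_profile == "gaussian-edged":
        total_sigma = float(np.hypot(spec.psf_sigma_um, spec.edge_sigma_um))
    else:
        total_sigma = spec.psf_sigma_um
    radius_px = disk_render_radius_px(spec.disk_diameter_um, total_sigma, px)

    canvas = _render_disks(rows, cols, centers, radius_px)
    if spec.edge_profile == "gaussian-edged" and spec.edge_sigma_um > 0:
        canvas = gaussian_filter(canvas, spec.edge_sigma_um / px, mode="reflect")
    if spec.psf_sigma_um > 0:
        canvas = gaussian_filter(canvas, spec.psf_sigma_um / px, mode="reflect")
    intensity = spec.photon_peak * canvas

    pixels = _apply_noise(intensity, spec.background, rng, poisson)
    img = Image2D(pixels=pixels, pixel_size_um=px, label="crosswise-phantom")
    m = margin_px
    placement_area_um2 = (rows - 2 * m) * (cols - 2 * m) * px**2
    truth = {
        **asdict(spec),
        "poisson": poisson,
        "n_disks": n,
        "min_separation_um": spec.separation_um,
        "margin_um": spec.border_margin_um,
        "render_radius_px": radius_px,
        "placement_area_um2": placement_area_um2,
        "density_per_um2": n / placement_area_um2,
    }
    return img, centers, truth


#: Stage table of published morphology: (stage, sarcomere repeat µm, myofibril
#: width µm, myofibril diameter µm).  Early pupal stages keep short, thin
#: sarcomeres; growth after 48 hr APF triples the diameter by eclosion, and
#: spalt knock-down (salmIR) arrests repeat growth at 2.8 µm.
DEFAULT_STAGE_TABLE: tuple[tuple[str, float, float, float], ...] = (
    ("34h APF", 2.0, 0.5, 0.46),
    ("48h APF", 2.0, 0.5, 0.46),
    ("adult", 3.2, 1.43, 1.43),
    ("salmIR adult", 2.8, 1.43, 1.43),
)


def make_stage_series(
    stage_table=DEFAULT_STAGE_TABLE,
    *,
    lengthwise_shape: tuple[int, int] = (512, 1024),
    crosswise_shape: tuple[int, int] = (1024, 1024),
    n_disks: int = 100,
    base_seed: int = 0,
    poisson: bool = True,
) -> list[dict]:
    """One lengthwise + one crosswise phantom per developmental stage.

    Each row of ``stage_table`` is ``(stage, repeat_um, width_um,
    diameter_um)``; the default table carries the published stage values.
    Returns a list of records with keys ``stage``, ``lengthwise`` (Image2D,
    truth), ``crosswise`` (Image2D, centers, truth).
    """
    series = []
    for i, (stage, repeat_um, width_um, diameter_um) in enumerate(stage_table):
        lw_spec = LengthwisePhantomSpec(
            repeat_um=repeat_um,
            fibril_width_um=width_um,
            shape_px=lengthwise_shape,
            seed=base_seed + 2 * i,
        )
        cw_spec = CrosswisePhantomSpec(
            disk_diameter_um=diameter_um,
            shape_px=crosswise_shape,
            n_disks=n_disks,
            seed=base_seed + 2 * i + 1,
        )
        series.append(
            {
                "stage": stage,
                "lengthwise": make_lengthwise_phantom(lw_spec, poisson=poisson),
                "crosswise": make_crosswise_phantom(cw_spec, poisson=poisson),
            }
        )
    return series
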