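"""Derived whole-fiber quantities and distribution summaries.

These combine the image-level measurements into per-fiber morphometrics:
sarcomeres per myofibril (fiber length over sarcomere length), myofibrils per
fiber (areal density times fiber cross-sectional area) and bead-normalized
fluorescence; plus Tukey box summaries (quartiles by linear interpolation,
whiskers at the most extreme data point within 1.5 IQR of the quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FiberMorphometrics",
    "BoxSummary",
    "sarcomeres_per_fibril",
    "fibrils_per_fiber",
    "bead_normalized_intensity",
    "box_summary",
]


def sarcomeres_per_fibril(fiber_length_um: float, sarcomere_length_um: float) -> float:
    """Number of sarcomeres chained along one myofibril.

    Fiber length divided by sarcomere length; real-valued (rounding is a
    presentation decision).
    """
    if fiber_length_um <= 0 or sarcomere_length_um <= 0:
        raise ValueError(
            "fiber length and sarcomere length must both be positive, got "
            f"{fiber_length_um} and {sarcomere_length_um}"
        )
    return fiber_length_um / sarcomere_length_um


def fibrils_per_fiber(density_per_um2: float, cross_area_um2: float) -> float:
    """Total myofibrils in a fiber: areal density × fiber cross-sectional area."""
    if density_per_um2 < 0 or cross_area_um2 < 0:
        raise ValueError(
            "density and area must be non-negative, got "
            f"{density_per_um2} and {cross_area_um2}"
        )
    return density_per_um2 * cross_area_um2


def bead_normalized_intensity(
    fiber_means: Sequence[float], bead_means: Sequence[float]
) -> float:
    """Fiber-to-bead fluorescence ratio from three ROI means each.

    Mean of the three fiber ROI intensities over the mean of the three bead
    ROI intensities; the beads calibrate out illumination and detector drift.
    """
    if len(fiber_means) != 3 or len(bead_means) != 3:
        raise ValueError("expected exactly three fiber and three bead ROI means")
    bead_mean = float(np.mean(bead_means))
    if bead_mean <= 0:
        raise ValueError(f"bead mean intensity must be positive, got {bead_mean}")
    return float(np.mean(fiber_means)) / bead_mean


@dataclass(frozen=True)
class FiberMorphometrics:
    """Stage-labelled per-fiber morphometrics with their derived quantities."""

    stage: str
    fiber_length_um: float
    sarcomere_length_um: float
    cross_area_um2: float
    density_per_um2: float
    sarcomeres_per_fibril: float
    fibrils_per_fiber: float

    @classmethod
    def from_measurements(
        cls,
        stage: str,
        fiber_length_um: float,
        sarcomere_length_um: float,
        cross_area_um2: float,
        density_per_um2: float,
    ) -> "FiberMorphometrics":
        return cls(
            stage=stage,
            fiber_length_um=fiber_length_um,
            sarcomere_length_um=sarcomere_length_um,
            cross_area_um2=cross_area_um2,
            density_per_um2=density_per_um2,
            sarcomeres_per_fibril=sarcomeres_per_fibril(
                fiber_length_um, sarcomere_length_um
            ),
            fibrils_per_fiber=fibrils_per_fiber(density_per_um2, cross_area_um2),
        )


@dataclass(frozen=True)
class BoxSummary:
    """Tukey five-number summary with fence outliers."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Tukey box-plot summary of a sample.

    Quartiles use linear interpolation between order statistics (the default
    convention of most plotting packages); whiskers reach the most extreme
    data point within 1.5 IQR of the quartiles; points beyond the fences are
    listed as outliers.  A constant sample degenerates to whiskers at the
    median with no outliers.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )
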