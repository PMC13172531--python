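"""Telophase quantification on 3D z-stacks.

Implements the image-analysis rules used to score histone / p63 / Pol II
partitioning between the two sister-chromatid sets of a dividing cell:

* background-subtracted integrated intensity per chromatid set, summed
  over z-slices (the "RawIntDen" workflow: per slice, sum the gray values
  inside the drawn ROI and subtract the mean background gray value times
  the ROI pixel count);
* the max/min asymmetry ratio with a 1.5-fold classification cutoff;
* the division angle between the chromatid axis and the basal membrane
  (60-90 deg perpendicular, 0-30 deg parallel, otherwise intermediate);
* Spearman rank correlation of two channels over a shared ROI as the
  colocalization index.

Masks are inputs (hand-drawn ROIs in practice); no segmentation is done.
All coordinates are 0-based (z, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ZStackROI",
    "QuantResult",
    "DivisionGeometry",
    "SpearmanResult",
    "IntensityResult",
    "integrated_intensity",
    "asymmetry_call",
    "division_angle",
    "spearman_colocalization",
    "quantify_stack",
    "ASYMMETRY_CUTOFF",
]

#: Fold-change cutoff above which sister-chromatid signals are called
#: asymmetric (ratio >= cutoff, boundary inclusive).
ASYMMETRY_CUTOFF = 1.5


@dataclass
class ZStackROI:
    """A 3D image with ROI masks for the two chromatid sets and background.

    image : (z, y, x) array of gray values (16-bit scale, unscaled)
    mask_a, mask_b : boolean masks of sister-chromatid sets A and B
    background_mask : boolean mask of a cell-free region
    channel : optional channel label
    """

    image: np.ndarray
    mask_a: np.ndarray
    mask_b: np.ndarray
    background_mask: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3:
            raise ValueError("image must be a 3-D (z, y, x) array")
        for name in ("mask_a", "mask_b", "background_mask"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != self.image.shape:
                raise ValueError(f"{name} shape {m.shape} != image shape "
                                 f"{self.image.shape}")
            setattr(self, name, m)
        if not self.mask_a.any() or not self.mask_b.any():
            raise ValueError("each signal mask must be nonempty")
        if (self.mask_a & self.mask_b).any() or \
           ((self.mask_a | self.mask_b) & self.background_mask).any():
            raise ValueError("signal and background masks must be disjoint")


@dataclass
class IntensityResult:
    """Background-subtracted integrated intensity of one chromatid set."""

    total: float
    per_slice: np.ndarray
    n_clamped: int  # slices whose subtracted signal was negative -> 0


@dataclass
class QuantResult:
    """Asymmetry call for one cell."""

    total_a: float
    total_b: float
    ratio: float
    label: str  # "asymmetric" | "symmetric"
    cutoff: float = ASYMMETRY_CUTOFF


@dataclass
class DivisionGeometry:
    """Division-axis geometry relative to the basal membrane (2D, in the
    maximum-intensity-projection plane)."""

    basal_line: tuple[tuple[float, float], tuple[float, float]]
    axis_points: tuple[tuple[float, float], tuple[float, float]]
    angle: float | None = None
    label: str | None = None  # "perpendicular" | "parallel" | "intermediate"


@dataclass
class SpearmanResult:
    rho: float
    n: int
    degenerate: bool = False


def integrated_intensity(
    stack: ZStackROI,
    which: str = "a",
    per_slice_background: bool = True,
    clamp_negative: bool = True,
) -> IntensityResult:
    """Integrated signal of one chromatid set, background subtracted.

    For each z-slice containing ROI pixels: signal = sum(gray values in
    ROI) - mean(background gray values) * (ROI pixel count); the totals
    are then summed across slices.  Negative per-slice values (ROI dimmer
    than background) are clamped to zero and counted.  With
    ``per_slice_background=False`` a single stack-wide background mean is
    used instead.
    """
    mask = {"a": stack.mask_a, "b": stack.mask_b}.get(which.lower())
    if mask is None:
        raise ValueError("which must be 'a' or 'b'")
    img = stack.image.astype(float)
    bg = stack.background_mask

    if not per_slice_background:
        if not bg.any():
            raise ValueError("background mask is empty")
        global_bg_mean = img[bg].mean()

    per_slice = []
    n_clamped = 0
    for z in range(img.shape[0]):
        n_sig = int(mask[z].sum())
        if n_sig == 0:
            per_slice.append(0.0)
            continue
        if per_slice_background:
            if not bg[z].any():
                raise ValueError(
                    f"slice {z} has signal pixels but no background pixels")
            bg_mean = img[z][bg[z]].mean()
        else:
            bg_mean = global_bg_mean
        val = float(img[z][mask[z]].sum() - bg_mean * n_sig)
        if val < 0 and clamp_negative:
            val = 0.0
            n_clamped += 1
        per_slice.append(val)
    per_slice = np.asarray(per_slice)
    return IntensityResult(total=float(per_slice.sum()),
                           per_slice=per_slice, n_clamped=n_clamped)


def asymmetry_call(total_a: float, total_b: float,
                   cutoff: float = ASYMMETRY_CUTOFF) -> QuantResult:
    """Classify a pair of integrated intensities by their fold ratio.

    ratio = max/min; a ratio at or above the cutoff (1.5 by default,
    boundary inclusive) is called asymmetric.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be strictly positive for a ratio")
    ratio = max(total_a, total_b) / min(total_a, total_b)
    label = "asymmetric" if ratio >= cutoff else "symmetric"
    return QuantResult(total_a=float(total_a), total_b=float(total_b),
                       ratio=float(ratio), label=label, cutoff=cutoff)


def division_angle(geom: DivisionGeometry) -> DivisionGeometry:
    """Acute angle between the division axis and the basal membrane.

    The basal membrane line and the chromatid-centroid axis are each
    defined by two 2D points; the result is the acute angle in [0, 90]
    degrees, labelled perpendicular (60-90), parallel (0-30) or
    intermediate (30-60, excluded from the two-class tally).
    """
    (b0, b1), (a0, a1) = geom.basal_line, geom.axis_points
    u = np.asarray(b1, float) - np.asarray(b0, float)
    v = np.asarray(a1, float) - np.asarray(a0, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("line-defining points must be distinct")
    cosang = abs(float(np.dot(u, v))) / (nu * nv)
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if 60.0 <= angle <= 90.0:
        label = "perpendicular"
    elif angle <= 30.0:
        label = "parallel"
    else:
        label = "intermediate"
    geom.angle = angle
    geom.label = label
    return geom


def spearman_colocalization(ch1, ch2) -> SpearmanResult:
    """Spearman rank correlation of two channels over the same ROI pixels.

    +1 for perfect correlation, 0 for none, -1 for perfect
    anti-correlation; ties receive average ranks.  A constant channel
    leaves the coefficient undefined (NaN, flagged).
    """
    ch1 = np.asarray(ch1, dtype=float).ravel()
    ch2 = np.asarray(ch2, dtype=float).ravel()
    if ch1.shape != ch2.shape:
        raise ValueError("channels must contain the same pixels")
    if ch1.size < 10:
        raise ValueError("need at least 10 paired pixels")
    if np.ptp(ch1) == 0 or np.ptp(ch2) == 0:
        return SpearmanResult(rho=float("nan"), n=ch1.size, degenerate=True)
    rho = float(_sps.spearmanr(ch1, ch2).statistic)
    return SpearmanResult(rho=rho, n=ch1.size)


def quantify_stack(stack: ZStackROI, cutoff: float = ASYMMETRY_CUTOFF,
                   per_slice_background: bool = True) -> QuantResult:
    """Integrated intensities of both chromatid sets plus the asymmetry call."""
    a = integrated_intensity(stack, "a", per_slice_background)
    b = integrated_intensity(stack, "b", per_slice_background)
    return asymmetry_call(a.total, b.total, cutoff)
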