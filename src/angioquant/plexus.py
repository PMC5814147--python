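"""Vascular plexus morphometry: loops, their regularity, and vessel density.

A capillary plexus viewed as a binary vessel mask encloses "loops" — the
bounded connected components of the non-vessel area.  A regular, honeycomb-
like plexus has loops of similar size and shape; irregular networks show a
wide spread.  Regularity is therefore summarised by the sample standard
deviation of loop area and of loop circularity (4*pi*A/P^2, 1 for a disc).
Vessel density is the fraction of the field of view covered by vessel
pixels.

Loops smaller than ``min_loop_area`` (default 86 um^2) are treated as
segmentation artifacts and excluded, as are lacunae touching the image
border (those are not closed loops).  Perimeters are measured as the arc
length of the marching-squares contour after a light periodic Gaussian
smoothing of the contour coordinates (sigma = 1.5 vertices).  The smoothing
suppresses the rasterization staircase, which would otherwise bias discs
toward circularities near 0.93 and, with a Crofton estimator, bias
axis-aligned rectangles the other way; the smoothed contour keeps a
rasterized disc within 1% of circularity 1 and a 10:1 rectangle within a
few percent of its analytic value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage import filters, measure, morphology

from .io_formats import BinaryMask, CalibratedImage

__all__ = [
    "LoopRecord",
    "RegularityReport",
    "segment_vessels",
    "extract_loops",
    "loop_circularity",
    "regularity_stats",
]

DEFAULT_MIN_LOOP_AREA = 86.0  # um^2
SPECKLE_AREA = 10.0  # um^2; vessel fragments below this are noise


@dataclass
class LoopRecord:
    """One closed loop of the plexus (a bounded lacuna of the vessel mask)."""

    id: int
    area: float  # um^2
    perimeter: float  # um
    circularity: float  # 4*pi*A/P^2, clamped to (0, 1]
    centroid_x: float  # um
    centroid_y: float  # um
    touches_border: bool = False


@dataclass
class RegularityReport:
    """Cohort dispersion statistics of the loops plus vessel density.

    Standard deviations are sample SDs (n-1 denominator) and are ``None``
    when fewer than two loops are available — undefined, never silently 0.
    """

    n_loops: int
    mean_area: float | None
    sd_area: float | None
    mean_circularity: float | None
    sd_circularity: float | None
    vessel_density: float | None
    min_loop_area: float = DEFAULT_MIN_LOOP_AREA


def segment_vessels(
    image: CalibratedImage,
    method: str = "otsu",
    *,
    threshold: float | None = None,
    percentile: float = 50.0,
    closing_radius: int = 1,
) -> BinaryMask:
    """Threshold a vessel-marker image into a binary vessel mask.

    ``method`` is ``"otsu"`` (default), ``"fixed"`` (requires ``threshold``)
    or ``"percentile"``.  The thresholded mask is cleaned by a morphological
    closing (disk of ``closing_radius`` px) and removal of vessel components
    smaller than 10 um^2 (speckle).
    """
    pixels = np.asarray(image.pixels, dtype=float)
    if np.ptp(pixels) == 0:
        if method == "fixed" and threshold is not None:
            return BinaryMask(pixels > threshold, image.pixel_size)
        raise ValueError("cannot auto-threshold a constant image")
    if method == "otsu":
        thr = filters.threshold_otsu(pixels)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        thr = threshold
    elif method == "percentile":
        thr = np.percentile(pixels, percentile)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = pixels > thr
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    min_px = int(np.ceil(SPECKLE_AREA / image.pixel_size**2))
    # max_size removes objects <= the value, hence min_px - 1 keeps min_px.
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    return BinaryMask(mask, image.pixel_size)


CONTOUR_SMOOTH_SIGMA = 1.5  # contour vertices; see module docstring


def region_perimeter(region_image: np.ndarray) -> float:
    """Perimeter (px) of a binary region via smoothed marching squares.

    Contour coordinates are smoothed with a periodic Gaussian before the
    arc length is summed; regions too small to yield a contour fall back to
    the Crofton estimate.
    """
    padded = np.pad(region_image.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return float(measure.perimeter_crofton(region_image))
    total = 0.0
    for c in contours:
        pts = c[:-1] if np.allclose(c[0], c[-1]) else c
        if len(pts) < 4:
            total += np.sum(np.hypot(*np.diff(np.vstack([pts, pts[:1]]),
                                              axis=0).T))
            continue
        sm = np.column_stack([
            gaussian_filter1d(pts[:, 0], CONTOUR_SMOOTH_SIGMA, mode="wrap"),
            gaussian_filter1d(pts[:, 1], CONTOUR_SMOOTH_SIGMA, mode="wrap"),
        ])
        diffs = np.diff(np.vstack([sm, sm[:1]]), axis=0)
        total += np.sum(np.hypot(diffs[:, 0], diffs[:, 1]))
    return float(total)


def loop_circularity(area: float, perimeter: float) -> float:
    """Circularity 4*pi*A/P^2, clamped to [0, 1]; 1 for an ideal disc."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def extract_loops(
    mask: BinaryMask,
    min_loop_area: float = DEFAULT_MIN_LOOP_AREA,
) -> list[LoopRecord]:
    """Extract the closed loops of a binary vessel mask.

    Loops are the connected components of the mask complement that do not
    touch the image border, using 4-connectivity for the background (the
    complementary pairing to 8-connected vessels, avoiding topological
    paradoxes).  Components below ``min_loop_area`` are dropped.
    """
    ps = mask.pixel_size
    background = ~mask.pixels
    labels = measure.label(background, connectivity=1)
    border_labels = set(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ]))
    border_labels.discard(0)
    loops: list[LoopRecord] = []
    next_id = 0
    for region in measure.regionprops(labels):
        if region.label in border_labels:
            continue
        area = region.area * ps**2
        if area < min_loop_area:
            continue
        perimeter = region_perimeter(region.image) * ps
        cy, cx = region.centroid
        loops.append(LoopRecord(
            id=next_id,
            area=area,
            perimeter=perimeter,
            circularity=loop_circularity(area, perimeter),
            centroid_x=cx * ps,
            centroid_y=cy * ps,
            touches_border=False,
        ))
        next_id += 1
    return loops


def regularity_stats(
    loops: list[LoopRecord],
    mask: BinaryMask | None = None,
    *,
    min_loop_area: float = DEFAULT_MIN_LOOP_AREA,
) -> RegularityReport:
    """Summarise a loop cohort: mean/SD of area and circularity, density.

    Vessel density is vessel pixels / field pixels and requires ``mask``.
    With fewer than two loops the SDs are reported as ``None``.
    """
    n = len(loops)
    density = None
    if mask is not None:
        density = float(mask.pixels.mean())
    if n == 0:
        return RegularityReport(0, None, None, None, None, density,
                                min_loop_area)
    areas = np.array([l.area for l in loops])
    circ = np.array([l.circularity for l in loops])
    sd_area = float(np.std(areas, ddof=1)) if n >= 2 else None
    sd_circ = float(np.std(circ, ddof=1)) if n >= 2 else None
    return RegularityReport(
        n_loops=n,
        mean_area=float(areas.mean()),
        sd_area=sd_area,
        mean_circularity=float(circ.mean()),
        sd_circularity=sd_circ,
        vessel_density=density,
        min_loop_area=min_loop_area,
    )
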