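"""Distance-resolved marker intensity profiles from a tissue boundary.

For a marker imaged over a vascular plexus, the quantity of interest is how
its expression falls off with distance from the sprouting front — the leading
edge of the growing network.  The profile is computed as:

1. normalise the marker channel by the mean intensity *outside* the vessel
   mask (so the extravascular level is 1 by construction and the profile is
   invariant to detector gain);
2. compute, for every pixel, the exact Euclidean distance to the nearest
   front pixel (um);
3. average the normalised intensity of intravascular, non-arterial pixels in
   half-open distance bins (default 15 um wide, from 0 to 500 um).

Replicate profiles (e.g. one per retina quarter) are combined unweighted:
mean and SEM across curves, each replicate counting once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import BinaryMask, CalibratedImage

__all__ = [
    "GradientProfile",
    "AggregateProfile",
    "distance_to_front",
    "normalize_marker",
    "profile",
    "aggregate_profiles",
]

DEFAULT_BIN_WIDTH = 15.0  # um
DEFAULT_MAX_DISTANCE = 500.0  # um


@dataclass
class GradientProfile:
    """Distance-binned, extravascular-normalised marker intensity."""

    bin_edges: np.ndarray  # um, half-open [lo, hi)
    mean_normalized_intensity: np.ndarray  # NaN where pixel_count == 0
    pixel_count: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean_normalized_intensity = np.asarray(
            self.mean_normalized_intensity, dtype=float)
        self.pixel_count = np.asarray(self.pixel_count, dtype=np.int64)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class AggregateProfile:
    """Mean and SEM across replicate profiles, each curve weighted once."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray  # NaN where undefined (any replicate empty, or n == 1)
    n_replicates: int


def distance_to_front(shape: tuple[int, int], front: BinaryMask) -> np.ndarray:
    """Exact Euclidean distance (um) of every pixel to the nearest front pixel."""
    if not front.pixels.any():
        raise ValueError("front mask is empty")
    if front.shape != tuple(shape):
        raise ValueError(f"shape {shape} does not match front mask {front.shape}")
    dist_px = ndimage.distance_transform_edt(~front.pixels)
    return dist_px * front.pixel_size


def normalize_marker(
    marker: CalibratedImage, vessel_mask: BinaryMask
) -> CalibratedImage:
    """Divide the marker image by its mean intensity outside the vessel mask.

    The extravascular mean of the result is 1 by construction.  An empty
    vessel mask degenerates to dividing by the image's own mean (warned).
    """
    if not vessel_mask.same_geometry(marker):
        raise ValueError("marker and vessel mask geometry mismatch")
    pixels = np.asarray(marker.pixels, dtype=float)
    outside = ~vessel_mask.pixels
    if not outside.any():
        raise ValueError("extravascular region is empty")
    if not vessel_mask.pixels.any():
        warnings.warn("vessel mask is empty; normalising by the whole-image mean",
                      stacklevel=2)
    denom = float(pixels[outside].mean())
    if denom <= 0:
        raise ValueError(f"extravascular mean must be positive, got {denom}")
    return CalibratedImage(pixels / denom, marker.pixel_size,
                           channel_name=marker.channel_name)


def profile(
    marker: CalibratedImage,
    vessel_mask: BinaryMask,
    front: BinaryMask,
    artery_mask: BinaryMask | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    *,
    replicate_id: str = "",
) -> GradientProfile:
    """Distance-binned mean normalised marker intensity inside the vessels.

    Pixels eligible for binning lie inside the vessel mask, outside the
    artery mask (if given), and closer than ``max_distance`` to the front.
    Bins are half-open ``[lo, hi)`` of width ``bin_width`` um.
    """
    for m, name in ((vessel_mask, "vessel"), (front, "front")):
        if not m.same_geometry(marker):
            raise ValueError(f"{name} mask geometry mismatch")
    if artery_mask is not None and not artery_mask.same_geometry(marker):
        raise ValueError("artery mask geometry mismatch")
    normalized = normalize_marker(marker, vessel_mask)
    dist = distance_to_front(marker.shape, front)
    eligible = vessel_mask.pixels.copy()
    if artery_mask is not None:
        eligible &= ~artery_mask.pixels
    eligible &= dist < max_distance
    if not eligible.any():
        raise ValueError("no eligible pixels for the profile")
    n_bins = int(np.ceil(max_distance / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    idx = np.floor(dist[eligible] / bin_width).astype(np.int64)
    vals = normalized.pixels[eligible]
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GradientProfile(edges, mean, counts, replicate_id=replicate_id)


def aggregate_profiles(profiles: list[GradientProfile]) -> AggregateProfile:
    """Unweighted mean and SEM across replicate curves, per bin.

    The mean and SEM are computed only in bins where every replicate has
    data; elsewhere they are NaN.  A single replicate has an undefined SEM
    (all-NaN), flagged rather than reported as 0.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if p.bin_edges.shape != edges.shape or not np.allclose(p.bin_edges, edges):
            raise ValueError("profiles have mismatched bin definitions")
    stack = np.vstack([p.mean_normalized_intensity for p in profiles])
    all_have = np.all(np.vstack([p.pixel_count > 0 for p in profiles]), axis=0)
    n = len(profiles)
    mean = np.full(stack.shape[1], np.nan)
    sem = np.full(stack.shape[1], np.nan)
    mean[all_have] = stack[:, all_have].mean(axis=0)
    if n >= 2:
        sem[all_have] = stack[:, all_have].std(axis=0, ddof=1) / np.sqrt(n)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AggregateProfile(centers, mean, sem, n_replicates=n)
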