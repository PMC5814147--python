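"""Synthetic microscopy data with known ground truth.

Every pipeline in this package is exercised on generated inputs that mimic
the relevant experiment while exposing the exact ground truth the analysers
should recover:

* nuclei fields — DAPI-like monolayers of non-overlapping elliptical nuclei
  whose long-axis orientations follow a spatially correlated nematic
  director field (correlation length xi) with per-nucleus angular jitter;
* vessel networks — perturbed hexagonal lattices rendered as binary vessel
  masks whose bounded lacunae form closed loops;
* front gradients — a marker channel decaying exponentially with distance
  from a "sprouting front" boundary, normalised to the extravascular level;
* photoconversion traces — ROI time courses with a pre-conversion baseline,
  post-conversion jump, exponential redistribution toward a plateau,
  global photobleaching and additive Gaussian noise, plus a paired
  fixed-cell control sharing the bleach rate;
* pulse-chase patches — two-channel junction patches whose retained-label
  ratio is drawn from three separated distributions (one per turnover
  class).

Every generator is a pure function of its spec, including the seed:
identical specs give bit-identical output.  Generators do not model optics
(no PSF, no camera noise beyond additive Gaussian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, spatial
from skimage import draw, morphology

from .coordination import NucleusRecord, fold_angle
from .flap import FlapTrace
from .front_gradient import distance_to_front
from .io_formats import BinaryMask, CalibratedImage
from .junction_patch import TURNOVER_CLASSES
from .plexus import LoopRecord, extract_loops

__all__ = [
    "NematicFieldSpec",
    "VesselNetworkSpec",
    "GradientSpec",
    "FlapTraceSpec",
    "gen_nematic_field",
    "gen_vessel_network",
    "gen_front_gradient",
    "gen_flap_trace",
    "gen_pulse_chase_patches",
]


# ---------------------------------------------------------------------------
# Nematic nuclei fields

@dataclass
class NematicFieldSpec:
    """A monolayer of elliptical nuclei with correlated orientations.

    ``correlation_length`` is the Gaussian smoothing width (um) of the
    director field; 0 means i.i.d. uniform orientations, ``inf`` a single
    global director.  ``orientation_noise`` is the SD (radians) of the
    per-nucleus angular jitter added to the local director; 0 means nuclei
    follow the director exactly.
    """

    n_nuclei: int = 200
    field_size: float = 1000.0  # um (square field)
    correlation_length: float = 100.0  # xi, um
    orientation_noise: float = 0.15  # kappa, radians
    major_axis: float = 18.0  # um, full length
    minor_axis: float = 10.0  # um, full length
    pixel_size: float = 1.0  # um per pixel
    background: float = 100.0
    foreground: float = 1000.0
    seed: int = 0


def _sample_director(spec: NematicFieldSpec, shape: tuple[int, int],
                     rng: np.random.Generator) -> np.ndarray:
    """Director angle per pixel, via smoothed doubled-angle complex noise.

    Smoothing the complex field exp(2i*theta) of white noise and halving the
    argument avoids the pi-wraparound artifacts of smoothing theta directly.
    """
    xi_px = spec.correlation_length / spec.pixel_size
    noise = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    smoothed = (ndimage.gaussian_filter(noise.real, xi_px)
                + 1j * ndimage.gaussian_filter(noise.imag, xi_px))
    return fold_angle(0.5 * np.angle(smoothed))


def _place_centers(spec: NematicFieldSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centres (um).

    Non-overlap is guaranteed conservatively by a minimum centre distance of
    one full major axis; a margin keeps nuclei off the field border.
    """
    margin = spec.major_axis / 2.0 + 2.0 * spec.pixel_size
    lo, hi = margin, spec.field_size - margin
    if hi <= lo:
        raise ValueError("field too small to hold a nucleus")
    min_dist = spec.major_axis
    centers = np.empty((spec.n_nuclei, 2))
    n_placed = 0
    max_tries = 500 * max(spec.n_nuclei, 1)
    tries = 0
    while n_placed < spec.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in a "
                f"{spec.field_size} um field after {max_tries} tries")
        cand = rng.uniform(lo, hi, size=2)
        if n_placed:
            d2 = np.sum((centers[:n_placed] - cand) ** 2, axis=1)
            if d2.min() < min_dist**2:
                continue
        centers[n_placed] = cand
        n_placed += 1
    return centers


def _fill_ellipse(canvas: np.ndarray, cx: float, cy: float, a: float,
                  b: float, theta: float, value: float) -> None:
    """Paint a filled, binary (no anti-aliasing) rotated ellipse in place.

    ``theta`` is the major-axis angle from the +x (column) axis toward +y
    (rows); a, b are semi-axes in pixels; cx, cy in pixels.
    """
    h, w = canvas.shape
    r0 = max(0, int(math.floor(cy - a - 1)))
    r1 = min(h, int(math.ceil(cy + a + 2)))
    c0 = max(0, int(math.floor(cx - a - 1)))
    c1 = min(w, int(math.ceil(cx + a + 2)))
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dx = cols - cx
    dy = rows - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[r0:r1, c0:c1][inside] = value


def gen_nematic_field(
    spec: NematicFieldSpec,
) -> tuple[list[NucleusRecord], CalibratedImage]:
    """Generate a nuclei monolayer and its exact per-nucleus ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_px = int(round(spec.field_size / spec.pixel_size))
    shape = (n_px, n_px)
    canvas = np.full(shape, spec.background, dtype=float)
    if spec.n_nuclei == 0:
        return [], CalibratedImage(canvas, spec.pixel_size, "nuclei")

    centers = _place_centers(spec, rng)

    if spec.correlation_length == 0:
        base = rng.uniform(0.0, np.pi, size=len(centers))
    elif np.isinf(spec.correlation_length):
        base = np.full(len(centers), rng.uniform(0.0, np.pi))
    else:
        director = _sample_director(spec, shape, rng)
        px = np.clip((centers / spec.pixel_size).astype(int), 0, n_px - 1)
        base = director[px[:, 1], px[:, 0]]  # centers are (x, y)
    if spec.orientation_noise > 0:
        base = base + rng.normal(0.0, spec.orientation_noise,
                                 size=len(centers))
    theta = fold_angle(base)

    a_px = spec.major_axis / 2.0 / spec.pixel_size
    b_px = spec.minor_axis / 2.0 / spec.pixel_size
    records = []
    for i, ((cx_um, cy_um), th) in enumerate(zip(centers, theta)):
        _fill_ellipse(canvas, cx_um / spec.pixel_size, cy_um / spec.pixel_size,
                      a_px, b_px, th, spec.foreground)
        records.append(NucleusRecord(
            id=i,
            centroid_x=float(cx_um),
            centroid_y=float(cy_um),
            orientation=float(th),
            major_axis=spec.major_axis,
            minor_axis=spec.minor_axis,
            area=np.pi * spec.major_axis * spec.minor_axis / 4.0,
            image_id=f"nematic_seed{spec.seed}",
        ))
    return records, CalibratedImage(canvas, spec.pixel_size, "nuclei")


# ---------------------------------------------------------------------------
# Vessel networks

@dataclass
class VesselNetworkSpec:
    """A plexus-like vessel mask built from a perturbed hexagonal lattice.

    Lattice sites are displaced by Gaussian noise of SD ``perturbation``
    times the lattice spacing; the Voronoi tessellation of the sites gives
    the loop geometry and its edges, dilated to ``vessel_width``, give the
    vessel mask.  ``mean_loop_area`` sets the lattice spacing (hexagonal
    cell area = sqrt(3)/2 * spacing^2).
    """

    n_loops: int = 50  # target count of interior loops
    mean_loop_area: float = 900.0  # um^2
    perturbation: float = 0.0  # fraction of lattice spacing
    vessel_width: float = 5.0  # um
    pixel_size: float = 1.0  # um per pixel
    seed: int = 0


def gen_vessel_network(
    spec: VesselNetworkSpec,
) -> tuple[BinaryMask, list[LoopRecord]]:
    """Render a vessel mask and its loop ground truth.

    The ground truth is computed from the rendered mask itself (via
    :func:`angioquant.plexus.extract_loops` with no area filter), so the
    generator and the analyser share one geometric definition of a loop.
    If the vessel width closes some loops entirely, fewer loops than the
    target survive — callers should check ``len(truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = math.sqrt(spec.mean_loop_area / (math.sqrt(3.0) / 2.0))
    # Lay out enough lattice columns/rows for the target interior loop
    # count, plus a ring of sacrificial boundary cells.
    n_cols = int(math.ceil(math.sqrt(spec.n_loops))) + 2
    n_rows = int(math.ceil(spec.n_loops / max(n_cols - 2, 1))) + 2
    row_step = spacing * math.sqrt(3.0) / 2.0
    pts = []
    for r in range(n_rows + 2):
        for c in range(n_cols + 2):
            x = c * spacing + (spacing / 2.0 if r % 2 else 0.0)
            y = r * row_step
            pts.append((x, y))
    pts = np.array(pts)
    if spec.perturbation > 0:
        pts = pts + rng.normal(0.0, spec.perturbation * spacing,
                               size=pts.shape)
    extent = pts.max(axis=0) + spacing
    vor = spatial.Voronoi(pts)

    n_px = (int(math.ceil(extent[1] / spec.pixel_size)) + 1,
            int(math.ceil(extent[0] / spec.pixel_size)) + 1)
    mask = np.zeros(n_px, dtype=bool)
    for v0, v1 in vor.ridge_vertices:
        if v0 < 0 or v1 < 0:
            continue  # unbounded ridge; its cells touch the border anyway
        p0 = vor.vertices[v0] / spec.pixel_size
        p1 = vor.vertices[v1] / spec.pixel_size
        r0, c0 = int(round(p0[1])), int(round(p0[0]))
        r1, c1 = int(round(p1[1])), int(round(p1[0]))
        rr, cc = draw.line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < n_px[0]) & (cc >= 0) & (cc < n_px[1])
        mask[rr[keep], cc[keep]] = True
    radius = max(1, int(round(spec.vessel_width / 2.0 / spec.pixel_size)))
    mask = morphology.dilation(mask, morphology.disk(radius))
    # Crop away the outermost lattice band: its Voronoi cells are distorted
    # by the lattice boundary, so only bulk loops remain as ground truth.
    band = int(round(1.5 * spacing / spec.pixel_size))
    if mask.shape[0] > 2 * band + 10 and mask.shape[1] > 2 * band + 10:
        mask = mask[band:-band, band:-band]
    binary = BinaryMask(mask, spec.pixel_size)
    truth = extract_loops(binary, min_loop_area=0.0)
    return binary, truth


# ---------------------------------------------------------------------------
# Front gradients

@dataclass
class GradientSpec:
    """Marker decaying exponentially with distance from the front.

    The expected normalised intensity at distance d is
    ``B + (A - B) * exp(-d / decay_length)`` with amplitude ``A`` and
    plateau ``B`` in fold-over-background units; extravascular pixels sit at
    ``extravascular_mean``.  ``noise_sd`` is additive Gaussian, in raw
    intensity units.
    """

    decay_length: float = 50.0  # lambda, um
    amplitude: float = 3.0  # A, fold over background
    plateau: float = 1.0  # B, fold over background
    extravascular_mean: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0


def gen_front_gradient(
    spec: GradientSpec, mask: BinaryMask, front: BinaryMask
) -> CalibratedImage:
    """Render the marker channel over a vessel mask and front mask."""
    if mask.shape != front.shape or not np.isclose(mask.pixel_size,
                                                   front.pixel_size):
        raise ValueError("vessel mask and front mask geometry mismatch")
    rng = np.random.default_rng(spec.seed)
    d = distance_to_front(mask.shape, front)  # raises if front is empty
    if np.isinf(spec.decay_length):
        decay = np.ones_like(d)
    else:
        decay = np.exp(-d / spec.decay_length)
    fold = spec.plateau + (spec.amplitude - spec.plateau) * decay
    pixels = np.where(mask.pixels, spec.extravascular_mean * fold,
                      spec.extravascular_mean)
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    return CalibratedImage(pixels.astype(float), mask.pixel_size, "marker")


# ---------------------------------------------------------------------------
# Photoconversion traces

@dataclass
class FlapTraceSpec:
    """A photoconversion ROI trace and its fixed-cell bleach control.

    The noiseless, bleach-free, background-free post-conversion signal obeys
    ``I(t) = f + (1 - f) * 2**(-t / half_time)`` with t = 0 at the first
    post-conversion frame; pre-conversion frames sit at the background
    level.  Bleaching multiplies everything (signal and background) by
    ``exp(-bleach_rate * t_global)`` with t_global counted from acquisition
    start, the way a microscope bleaches.  Defaults follow a 15 min
    acquisition at 10 s frames.
    """

    immobile_fraction: float = 0.3  # f in [0, 1]
    half_time: float = 90.0  # s
    n_pre: int = 5  # pre-conversion frames
    frame_interval: float = 10.0  # s
    duration: float = 900.0  # s of post-conversion monitoring
    bleach_rate: float = 0.0  # k_b, 1/s
    background: float = 50.0
    signal: float = 1000.0  # post-conversion amplitude S
    noise_sd: float = 0.0  # absolute intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile fraction must lie in [0, 1]")


def gen_flap_trace(spec: FlapTraceSpec) -> tuple[FlapTrace, FlapTrace]:
    """Generate ``(trace, fixed_cell_control)`` from one spec.

    The control shares the bleach rate, background and noise level but has
    no redistribution (signal identically at the converted level, immobile
    fraction 1), mimicking a fixed cell.
    """
    rng = np.random.default_rng(spec.seed)
    n_post = int(round(spec.duration / spec.frame_interval)) + 1
    n_total = spec.n_pre + n_post
    times = np.arange(n_total) * spec.frame_interval
    t_post = np.arange(n_post) * spec.frame_interval

    signal = np.zeros(n_total)
    if np.isinf(spec.half_time):
        redist = np.ones(n_post)
    else:
        redist = (spec.immobile_fraction
                  + (1.0 - spec.immobile_fraction)
                  * 2.0 ** (-t_post / spec.half_time))
    signal[spec.n_pre:] = redist

    bleach = np.exp(-spec.bleach_rate * times)

    def _trace(sig: np.ndarray, trace_id: str) -> FlapTrace:
        roi = (spec.background + spec.signal * sig) * bleach
        bg = spec.background * bleach
        if spec.noise_sd > 0:
            roi = roi + rng.normal(0.0, spec.noise_sd, size=n_total)
            bg = bg + rng.normal(0.0, spec.noise_sd, size=n_total)
        return FlapTrace(times.copy(), roi, bg,
                         conversion_index=spec.n_pre, trace_id=trace_id)

    trace = _trace(signal, f"flap_seed{spec.seed}")
    control = _trace(np.ones(n_total), f"control_seed{spec.seed}")
    return trace, control


# ---------------------------------------------------------------------------
# Pulse-chase junction patches

# Retained-ratio distributions per turnover class: low retained ratio means
# fast turnover.  The class means are separated by 7 SD, comfortably more
# than the 4 SD needed for near-perfect classification.
RATIO_DISTRIBUTIONS = {"high": (0.15, 0.05),
                       "intermediate": (0.50, 0.05),
                       "low": (0.85, 0.05)}


def gen_pulse_chase_patches(
    category_mix: tuple[float, float, float],
    n_patches: int,
    seed: int = 0,
    *,
    patch_size: float = 16.0,  # um
    pixel_size: float = 0.25,  # um per pixel
) -> tuple[list[tuple[CalibratedImage, CalibratedImage]], list[str],
           list[float]]:
    """Generate two-channel pulse-chase patches with turnover ground truth.

    ``category_mix`` gives the (high, intermediate, low) turnover fractions
    and must sum to 1.  Each patch holds a junction-like curvilinear
    structure; the surface channel marks total junctional protein and the
    pulse channel the retained label, at a ratio drawn from the patch's
    class distribution.  Returns ``(patches, labels, true_ratios)`` where
    each patch is a ``(pulse, surface)`` image pair.
    """
    mix = np.asarray(category_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("category_mix must be three non-negative fractions "
                         "summing to 1")
    rng = np.random.default_rng(seed)
    size_px = int(round(patch_size / pixel_size))
    labels = [TURNOVER_CLASSES[i]
              for i in rng.choice(3, size=n_patches, p=mix)]
    patches = []
    ratios = []
    surface_level, background = 200.0, 20.0
    noise_sd = 5.0
    for lab in labels:
        mu, sd = RATIO_DISTRIBUTIONS[lab]
        ratio = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        ratios.append(ratio)
        # Junction: a quadratic Bezier curve spanning the patch, dilated to
        # a few pixels' width.
        jmask = np.zeros((size_px, size_px), dtype=bool)
        if rng.random() < 0.5:  # left-right crossing
            p0 = np.array([rng.uniform(0, size_px - 1), 0.0])
            p2 = np.array([rng.uniform(0, size_px - 1), size_px - 1.0])
        else:  # top-bottom crossing
            p0 = np.array([0.0, rng.uniform(0, size_px - 1)])
            p2 = np.array([size_px - 1.0, rng.uniform(0, size_px - 1)])
        p1 = rng.uniform(0.2 * size_px, 0.8 * size_px, size=2)
        t = np.linspace(0.0, 1.0, 4 * size_px)[:, None]
        curve = ((1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2)
        rr = np.clip(np.round(curve[:, 0]).astype(int), 0, size_px - 1)
        cc = np.clip(np.round(curve[:, 1]).astype(int), 0, size_px - 1)
        jmask[rr, cc] = True
        jmask = morphology.dilation(jmask, morphology.disk(2))

        surface = np.full((size_px, size_px), background)
        surface[jmask] = surface_level
        surface = surface + rng.normal(0.0, noise_sd, size=surface.shape)
        pulse = np.zeros((size_px, size_px))
        pulse[jmask] = ratio * surface_level
        pulse = pulse + rng.normal(0.0, noise_sd, size=pulse.shape)
        patches.append((
            CalibratedImage(pulse, pixel_size, "pulse"),
            CalibratedImage(surface, pixel_size, "surface"),
        ))
    return patches, labels, ratios
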