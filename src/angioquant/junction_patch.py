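"""Blinded patch-based scoring of endothelial junction images.

Manual classification of adherens-junction morphology and turnover is done
on small square patches ((16 um)^2 by default) cut from (160 um)^2 fields,
presented to the scorer in random order under anonymous names so the
condition cannot be guessed.  This module owns the bookkeeping: tiling
fields into patches, the shuffled manifest (the blinding key), re-joining
scored labels to their source coordinates, and the marginal / crosstab
summaries of morphology and turnover classes.

Morphology categories: straight, thick, thick_to_reticular, reticular,
fingers (plus unscorable).  Turnover categories: high, intermediate, low
(plus unscored).  Categories with fewer than 5 scored patches are flagged
as unreliable in the report.

An optional quantitative turnover score is provided as an extension for
two-channel pulse-chase images: the ratio of retained pulse label to total
surface label over junction pixels (high retained ratio = low turnover).
Its class thresholds are calibrated on synthetic data only and do not
replace manual classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BinaryMask, CalibratedImage, write_image

__all__ = [
    "MORPHOLOGIES",
    "TURNOVER_CLASSES",
    "PatchSet",
    "PatchLabel",
    "CrosstabReport",
    "make_patches",
    "ingest_labels",
    "crosstab",
    "turnover_score",
    "classify_turnover",
]

MORPHOLOGIES = ("straight", "thick", "thick_to_reticular", "reticular",
                "fingers")
TURNOVER_CLASSES = ("high", "intermediate", "low")
DEFAULT_PATCH_SIZE = 16.0  # um
MIN_RELIABLE_PATCHES = 5

# Retained-ratio cut points separating the turnover classes; calibrated on
# the synthetic pulse-chase generator (see classify_turnover).
DEFAULT_RATIO_THRESHOLDS = (0.35, 0.65)


@dataclass
class PatchSet:
    """A blinded tiling of one or more fields into square patches.

    ``manifest`` is the blinding key: a bijection between anonymous patch
    names (their order is the shuffled presentation order) and source
    coordinates (image_id, grid row, grid col).  Patch pixel data is kept in
    ``patches`` under the anonymous name.
    """

    patch_size: float  # um
    pixel_size: float  # um per pixel
    shuffle_seed: int
    manifest: pd.DataFrame  # columns: patch_name, image_id, row, col
    patches: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_patches(self) -> int:
        return len(self.manifest)

    def lookup(self, patch_name: str) -> tuple[str, int, int]:
        rows = self.manifest[self.manifest.patch_name == patch_name]
        if rows.empty:
            raise KeyError(f"unknown patch name {patch_name!r}")
        r = rows.iloc[0]
        return str(r.image_id), int(r.row), int(r.col)

    def write(self, out_dir: str | Path) -> Path:
        """Write anonymous patch TIFFs and the manifest CSV (blinding key)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, pixels in self.patches.items():
            write_image(CalibratedImage(pixels, self.pixel_size), out_dir / f"{name}.tif")
        manifest_path = out_dir / "manifest.csv"
        self.manifest.to_csv(manifest_path, index=False)
        return manifest_path


@dataclass
class PatchLabel:
    """A scored patch, de-blinded back to its source coordinates."""

    patch_name: str
    image_id: str
    row: int
    col: int
    morphology: str = "unscorable"
    turnover: str = "unscored"

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES + ("unscorable",):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.turnover not in TURNOVER_CLASSES + ("unscored",):
            raise ValueError(f"unknown turnover class {self.turnover!r}")


@dataclass
class CrosstabReport:
    """Marginal percentages and the morphology x turnover table.

    Percentages are over scored patches only; unscorable/unscored patches
    are excluded from the denominators and counted in ``n_excluded``.
    ``unreliable_categories`` lists categories with < 5 scored patches.
    """

    n_scored_morphology: int
    n_scored_turnover: int
    n_excluded: int
    morphology_counts: dict[str, int]
    morphology_percent: dict[str, float]
    turnover_counts: dict[str, int]
    turnover_percent: dict[str, float]
    table: pd.DataFrame  # morphology x turnover counts
    high_turnover_percent_by_morphology: dict[str, float]
    unreliable_categories: list[str]


def make_patches(
    images: dict[str, CalibratedImage],
    patch_size: float = DEFAULT_PATCH_SIZE,
    seed: int = 0,
) -> PatchSet:
    """Tile fields into (patch_size)^2 patches under shuffled anonymous names.

    The tiling is deterministic; only the presentation order (and hence the
    anonymous names ``patch_00000`` ...) is shuffled, reproducibly from
    ``seed``.  Fields whose extent is not an integer multiple of the patch
    size lose the trailing remainder (with a warning).
    """
    if not images:
        raise ValueError("no images supplied")
    entries: list[tuple[str, int, int, np.ndarray]] = []
    pixel_size = None
    for image_id, img in images.items():
        if pixel_size is None:
            pixel_size = img.pixel_size
        elif not np.isclose(pixel_size, img.pixel_size):
            raise ValueError("all images in a patch set must share pixel size")
        size_px = patch_size / img.pixel_size
        if abs(size_px - round(size_px)) > 1e-9:
            raise ValueError(
                f"patch size {patch_size} um is not an integer number of "
                f"pixels at {img.pixel_size} um/px")
        size_px = int(round(size_px))
        h, w = img.shape
        if size_px > min(h, w):
            raise ValueError("patch size exceeds the field")
        n_rows, n_cols = h // size_px, w // size_px
        if h % size_px or w % size_px:
            warnings.warn(
                f"field {image_id!r} is not a multiple of the patch size; "
                f"dropping the trailing remainder", stacklevel=2)
        for r in range(n_rows):
            for c in range(n_cols):
                tile = img.pixels[r * size_px:(r + 1) * size_px,
                                  c * size_px:(c + 1) * size_px]
                entries.append((image_id, r, c, tile))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    width = max(5, len(str(len(entries))))
    manifest_rows = []
    patches = {}
    for k, idx in enumerate(order):
        image_id, r, c, tile = entries[idx]
        name = f"patch_{k:0{width}d}"
        manifest_rows.append({"patch_name": name, "image_id": image_id,
                              "row": r, "col": c})
        patches[name] = tile
    manifest = pd.DataFrame(manifest_rows,
                            columns=["patch_name", "image_id", "row", "col"])
    return PatchSet(patch_size=patch_size, pixel_size=float(pixel_size),
                    shuffle_seed=seed, manifest=manifest, patches=patches)


def ingest_labels(
    patchset: PatchSet, labels: pd.DataFrame | str | Path
) -> list[PatchLabel]:
    """Join blind scores back to source coordinates via the manifest.

    ``labels`` is a DataFrame or CSV with columns ``patch_name``,
    ``morphology``, ``turnover`` (either label column may be omitted).
    Unknown patch names and duplicate labels are errors.
    """
    if not isinstance(labels, pd.DataFrame):
        labels = pd.read_csv(labels)
    if labels.empty:
        return []
    if "patch_name" not in labels.columns:
        raise ValueError("label table must have a patch_name column")
    dupes = labels.patch_name[labels.patch_name.duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate labels for patches: {sorted(set(dupes))}")
    out = []
    for rec in labels.to_dict("records"):
        name = str(rec["patch_name"])
        image_id, row, col = patchset.lookup(name)  # raises on unknown name
        out.append(PatchLabel(
            patch_name=name, image_id=image_id, row=row, col=col,
            morphology=str(rec.get("morphology", "unscorable")),
            turnover=str(rec.get("turnover", "unscored")),
        ))
    return out


def crosstab(labels: list[PatchLabel]) -> CrosstabReport:
    """Marginal percentages and the morphology x turnover table.

    Denominators exclude unscorable (morphology) / unscored (turnover)
    patches.  The per-morphology high-turnover percentage uses patches
    scored on both axes.
    """
    if not labels:
        raise ValueError("need at least one scored patch")
    df = pd.DataFrame([{
        "morphology": l.morphology, "turnover": l.turnover} for l in labels])
    morph_scored = df[df.morphology != "unscorable"]
    turn_scored = df[df.turnover != "unscored"]
    n_excluded = int(((df.morphology == "unscorable")
                      & (df.turnover == "unscored")).sum())

    morph_counts = {m: int((morph_scored.morphology == m).sum())
                    for m in MORPHOLOGIES}
    turn_counts = {t: int((turn_scored.turnover == t).sum())
                   for t in TURNOVER_CLASSES}
    n_morph = len(morph_scored)
    n_turn = len(turn_scored)
    morph_pct = {m: 100.0 * c / n_morph if n_morph else float("nan")
                 for m, c in morph_counts.items()}
    turn_pct = {t: 100.0 * c / n_turn if n_turn else float("nan")
                for t, c in turn_counts.items()}

    both = df[(df.morphology != "unscorable") & (df.turnover != "unscored")]
    table = pd.crosstab(both.morphology, both.turnover).reindex(
        index=list(MORPHOLOGIES), columns=list(TURNOVER_CLASSES), fill_value=0
    ).fillna(0).astype(int)
    high_by_morph = {}
    for m in MORPHOLOGIES:
        total = int(table.loc[m].sum())
        high_by_morph[m] = (100.0 * table.loc[m, "high"] / total
                            if total else float("nan"))
    unreliable = [m for m, c in morph_counts.items()
                  if 0 < c < MIN_RELIABLE_PATCHES]
    unreliable += [f"turnover:{t}" for t, c in turn_counts.items()
                   if 0 < c < MIN_RELIABLE_PATCHES]
    return CrosstabReport(
        n_scored_morphology=n_morph,
        n_scored_turnover=n_turn,
        n_excluded=n_excluded,
        morphology_counts=morph_counts,
        morphology_percent=morph_pct,
        turnover_counts=turn_counts,
        turnover_percent=turn_pct,
        table=table,
        high_turnover_percent_by_morphology=high_by_morph,
        unreliable_categories=unreliable,
    )


def turnover_score(
    pulse: CalibratedImage,
    surface: CalibratedImage,
    junction_mask: BinaryMask,
) -> float | None:
    """Retained-label ratio of a pulse-chase patch (extension, not a
    replacement for manual scoring).

    Ratio = mean pulse intensity over junction pixels / mean surface
    intensity over the same pixels.  A high retained ratio means slow
    turnover.  Returns ``None`` (unscorable) for an empty junction mask.
    """
    if pulse.shape != surface.shape or pulse.shape != junction_mask.shape:
        raise ValueError("pulse, surface and junction mask must share shape")
    sel = junction_mask.pixels
    if not sel.any():
        return None
    surf = float(np.asarray(surface.pixels, dtype=float)[sel].mean())
    if surf <= 0:
        return None
    return float(np.asarray(pulse.pixels, dtype=float)[sel].mean()) / surf


def classify_turnover(
    ratio: float | None,
    thresholds: tuple[float, float] = DEFAULT_RATIO_THRESHOLDS,
) -> str:
    """Map a retained ratio to a turnover class (synthetic-calibrated).

    Low retained ratio = fast turnover: ratio < thresholds[0] -> "high",
    ratio > thresholds[1] -> "low", in between -> "intermediate";
    ``None`` -> "unscored".
    """
    if ratio is None:
        return "unscored"
    lo, hi = thresholds
    if ratio < lo:
        return "high"
    if ratio > hi:
        return "low"
    return "intermediate"
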