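"""Calibrated images, binary masks, typed CSV tables and run configuration.

Every physical quantity downstream (areas, distances, bin edges) is expressed
in micrometres via the ``pixel_size`` carried by :class:`CalibratedImage` and
:class:`BinaryMask`.  Pixel size always comes from configuration, never from
image metadata: TIFF resolution dialects are too unreliable.  If the file does
carry a resolution tag that disagrees with the configured value by more than
1 %, a warning is emitted and the configured value wins.

Coordinate convention: row-major arrays, origin at the top-left corner,
``x`` = column index, ``y`` = row index, 0-based.  Positions are reported in
micrometres as ``(x * pixel_size, y * pixel_size)``.  Only isotropic pixels
are supported.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "RunConfig",
    "read_image",
    "write_image",
    "write_table",
    "read_table",
    "write_run_log",
]


def _check_geometry(pixels: np.ndarray, pixel_size: float) -> None:
    if not np.isfinite(pixel_size) or pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size!r}")
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2D plane, got shape {pixels.shape}")
    if pixels.shape[0] < 2 or pixels.shape[1] < 2:
        raise ValueError(f"image too small: shape {pixels.shape}")


@dataclass
class CalibratedImage:
    """A single-channel 2D intensity image with isotropic pixel calibration.

    Parameters
    ----------
    pixels : numpy.ndarray
        2D scalar intensity array (at least 2x2).
    pixel_size : float
        Micrometres per pixel, identical in x and y; must be positive.
    channel_name : str
        Free-text channel identifier (e.g. ``"DAPI"``, ``"IB4"``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        _check_geometry(self.pixels, self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_area(self) -> float:
        """Field-of-view area in square micrometres."""
        return self.pixels.size * self.pixel_size**2


@dataclass
class BinaryMask:
    """A 2D boolean mask sharing the calibration rules of CalibratedImage."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        _check_geometry(self.pixels, self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def same_geometry(self, other: "BinaryMask | CalibratedImage") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_size, other.pixel_size
        )


def _tiff_metadata_pixel_size(path: Path) -> float | None:
    """Best-effort pixel size (um) from TIFF resolution tags; None if absent."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            if num == 0 or den == 0:
                return None
            per_unit = num / den  # pixels per unit
            unit_val = getattr(unit, "value", None)
            unit_um = {2: 25_400.0, 3: 10_000.0}.get(
                int(unit_val) if unit_val is not None else -1
            )
            if unit_um is None:
                return None
            return unit_um / per_unit
    except Exception:
        return None


def read_image(path: str | Path, pixel_size: float) -> list[CalibratedImage]:
    """Read a single-plane or multi-channel TIFF/PNG as calibrated channels.

    Returns one :class:`CalibratedImage` per channel, in file order.
    Intensities are preserved without rescaling.  ``pixel_size`` is required
    and authoritative; a conflicting TIFF resolution tag only triggers a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pixel_size is None:
        raise ValueError("pixel_size is required")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        meta_ps = _tiff_metadata_pixel_size(path)
        if meta_ps is not None and abs(meta_ps - pixel_size) > 0.01 * pixel_size:
            warnings.warn(
                f"TIFF metadata pixel size {meta_ps:.4g} um disagrees with "
                f"configured {pixel_size:.4g} um by >1%; using configured value",
                stacklevel=2,
            )
        channel_axis = 0
    else:
        arr = np.asarray(iio.imread(path))
        channel_axis = -1  # PNG interleaves channels last
    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3:
        planes = [np.take(arr, i, axis=channel_axis) for i in range(arr.shape[channel_axis])]
    else:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as 2D channels")
    for p in planes:
        if p.ndim != 2:
            raise ValueError("non-2D plane after channel split")
    return [
        CalibratedImage(p, pixel_size, channel_name=f"ch{i}")
        for i, p in enumerate(planes)
    ]


def write_image(image: CalibratedImage | BinaryMask, path: str | Path) -> Path:
    """Write an image or mask to TIFF (masks as uint8 0/255)."""
    path = Path(path)
    pixels = image.pixels
    if pixels.dtype == bool:
        pixels = pixels.astype(np.uint8) * 255
    tifffile.imwrite(path, pixels)
    return path


# ---------------------------------------------------------------------------
# Typed tables

def write_table(records: Sequence[Any], path: str | Path,
                record_type: type | None = None) -> Path:
    """Write a homogeneous list of dataclass records as a CSV table.

    An empty list is allowed when ``record_type`` is given (header-only file).
    Floats are written at full precision with '.' as decimal separator.
    """
    path = Path(path)
    if len(records) == 0:
        if record_type is None:
            raise ValueError("empty record list requires record_type for the header")
        cols = [f.name for f in dataclasses.fields(record_type)]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return path
    first_type = type(records[0])
    if not dataclasses.is_dataclass(first_type):
        raise TypeError(f"records must be dataclasses, got {first_type}")
    for r in records:
        if type(r) is not first_type:
            raise TypeError(
                f"heterogeneous records: {type(r).__name__} vs {first_type.__name__}"
            )
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    # pandas' default float repr is shortest-roundtrip: full precision.
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, record_type: type) -> list[Any]:
    """Read a CSV written by :func:`write_table` back into typed records."""
    df = pd.read_csv(path)
    fields = {f.name: f for f in dataclasses.fields(record_type)}
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for name in fields:
            val = getattr(row, name)
            if isinstance(val, float) and np.isnan(val):
                val = None
            kwargs[name] = val
        records.append(record_type(**kwargs))
    return records


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Run-level parameters shared by all pipelines.

    ``modules`` holds one free-form parameter block per pipeline (thresholds,
    bin widths, windows, ...) so that every tunable introduced anywhere in the
    package is representable here and logged with the run.
    """

    pixel_size: float = 1.0
    random_seed: int = 0
    out_dir: str = "."
    modules: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        top = {k: v for k, v in data.items() if k in known}
        return cls(**top)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path

    def module_params(self, name: str) -> dict[str, Any]:
        return dict(self.modules.get(name, {}))


def write_run_log(path: str | Path, config: RunConfig, *,
                  subcommand: str = "", inputs: Sequence[str] = (),
                  outputs: Sequence[str] = (), version: str = "") -> Path:
    """Write a plain-text run record: timestamp, seed, parameter dump."""
    path = Path(path)
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    lines = [
        f"timestamp: {stamp}",
        f"subcommand: {subcommand}",
        f"package_version: {version}",
        f"random_seed: {config.random_seed}",
        f"pixel_size_um: {config.pixel_size}",
        f"inputs: {list(inputs)}",
        f"outputs: {list(outputs)}",
        "parameters:",
        yaml.safe_dump(config.modules, sort_keys=False, default_flow_style=False),
    ]
    path.write_text("\n".join(lines))
    return path
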