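"""Scan I/O and physical calibration.

Anterior-segment OCT frames arrive as DICOM, headerless RAW or plain
grayscale images (PNG/TIFF for phantoms and fixtures).  Every frame is
carried through the pipeline as an :class:`OctScan`: a 2-D intensity array
normalized to [0, 1] plus a single isotropic μm/pixel scale.  The Visante
frames this pipeline was designed around are 256 × 1024 pixels covering
8 mm × 16 mm, i.e. 31.3 μm/pixel.

Coordinates everywhere in the package are 0-based ``(row, col)`` with row 0
at the top (anterior) and rows increasing posteriorly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CalibrationError, FormatError

__all__ = [
    "OctScan",
    "read_scan",
    "px_to_um",
    "um_to_px",
    "derive_scale",
]

_SOURCES = ("dicom", "raw", "png", "phantom")


@dataclass(frozen=True)
class OctScan:
    """A calibrated grayscale B-scan.

    Parameters
    ----------
    pixels
        2-D float array, intensities in [0, 1], finite and non-negative.
    scale_um_per_px
        Isotropic physical pixel pitch in micrometres, > 0.
    source
        Provenance tag: one of ``dicom``, ``raw``, ``png``, ``phantom``.
    frame_id
        Free-form identifier (typically the file stem).
    """

    pixels: np.ndarray
    scale_um_per_px: float
    source: str = "phantom"
    frame_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise FormatError(f"expected a 2-D grayscale array, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise FormatError("intensities must be finite and non-negative")
        if not (math.isfinite(self.scale_um_per_px) and self.scale_um_per_px > 0):
            raise CalibrationError(
                f"scale_um_per_px must be positive, got {self.scale_um_per_px}"
            )
        if self.source not in _SOURCES:
            raise FormatError(f"unknown source {self.source!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def _normalize_int(arr: np.ndarray) -> np.ndarray:
    """Map an integer image onto [0, 1] by its dtype range."""
    info = np.iinfo(arr.dtype)
    return arr.astype(float) / float(info.max)


def px_to_um(d_px: float, scale_um_per_px: float) -> float:
    """Convert a pixel distance to micrometres (d_px × scale)."""
    if not (math.isfinite(scale_um_per_px) and scale_um_per_px > 0):
        raise CalibrationError(f"non-positive scale: {scale_um_per_px}")
    return float(d_px) * float(scale_um_per_px)


def um_to_px(d_um: float, scale_um_per_px: float, mode: str = "nearest") -> int:
    """Convert a physical distance to a whole pixel count.

    ``mode`` selects the rounding: ``nearest`` (half away from zero, the
    default: 500 μm at 31.3 μm/px gives 16 px), ``ceil`` or ``floor``.
    """
    if not (math.isfinite(scale_um_per_px) and scale_um_per_px > 0):
        raise CalibrationError(f"non-positive scale: {scale_um_per_px}")
    x = float(d_um) / float(scale_um_per_px)
    if mode == "nearest":
        return int(math.floor(x + 0.5))
    if mode == "ceil":
        return int(math.ceil(x))
    if mode == "floor":
        return int(math.floor(x))
    raise ValueError(f"unknown rounding mode {mode!r}")


def derive_scale(field_mm: float, extent_px: int) -> float:
    """μm/pixel implied by a field of view: field_mm × 1000 / extent_px."""
    if not (field_mm > 0 and extent_px > 0):
        raise CalibrationError(
            f"field and extent must be positive, got {field_mm}, {extent_px}"
        )
    return float(field_mm) * 1000.0 / float(extent_px)


def _read_dicom(path: Path, scale_um_per_px):
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise FormatError(f"{path}: multi-frame or color DICOM not supported")
    header_scale = None
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None and len(spacing) >= 1:
        row_mm, col_mm = float(spacing[0]), float(spacing[-1])
        if not math.isclose(row_mm, col_mm, rel_tol=1e-6):
            warnings.warn(
                f"{path.name}: anisotropic PixelSpacing {row_mm}×{col_mm} mm; "
                "treating calibration as isotropic using the row spacing",
                stacklevel=3,
            )
        header_scale = row_mm * 1000.0
    scale = scale_um_per_px if scale_um_per_px is not None else header_scale
    if arr.dtype.kind in "ui":
        px = _normalize_int(arr)
    else:
        px = arr.astype(float)
        if px.max() > 1:
            px = px / px.max()
    return px, scale


def _read_raw(path: Path, raw_dims, raw_depth):
    if raw_dims is None or raw_depth is None:
        raise FormatError("RAW input requires raw_dims=(rows, cols) and raw_depth")
    rows, cols = int(raw_dims[0]), int(raw_dims[1])
    if raw_depth not in (8, 16):
        raise FormatError(f"raw_depth must be 8 or 16, got {raw_depth}")
    nbytes = path.stat().st_size
    expected = rows * cols * (raw_depth // 8)
    if nbytes != expected:
        raise FormatError(
            f"{path}: {nbytes} bytes inconsistent with dims {rows}×{cols} "
            f"at {raw_depth}-bit ({expected} bytes expected)"
        )
    dtype = "<u1" if raw_depth == 8 else "<u2"
    arr = np.fromfile(str(path), dtype=dtype).reshape(rows, cols)
    return _normalize_int(arr)


def _read_image(path: Path):
    import imageio.v3 as iio

    arr = iio.imread(str(path))
    if arr.ndim == 3:  # collapse identical channels; otherwise luminance mean
        if np.all(arr[..., 0] == arr[..., 1]) and np.all(arr[..., 0] == arr[..., -1]):
            arr = arr[..., 0]
        else:
            arr = arr[..., :3].mean(axis=-1)
    if arr.dtype.kind in "ui":
        return _normalize_int(arr)
    arr = arr.astype(float)
    return arr / arr.max() if arr.max() > 1 else arr


def read_scan(
    path,
    format: str | None = None,
    raw_dims: tuple[int, int] | None = None,
    raw_depth: int | None = None,
    scale_um_per_px: float | None = None,
) -> OctScan:
    """Read an OCT frame and attach its physical calibration.

    ``format`` is inferred from the file suffix when omitted.  For DICOM,
    PixelSpacing populates the scale when present; an explicit
    ``scale_um_per_px`` always wins.  RAW is headerless row-major
    little-endian, top row first, and requires ``raw_dims`` and
    ``raw_depth``.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".dcm": "dicom",
            ".dicom": "dicom",
            ".raw": "raw",
            ".png": "png",
            ".tif": "png",
            ".tiff": "png",
        }.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")

    if format == "dicom":
        px, scale = _read_dicom(path, scale_um_per_px)
        source = "dicom"
    elif format == "raw":
        px = _read_raw(path, raw_dims, raw_depth)
        scale = scale_um_per_px
        source = "raw"
    elif format in ("png", "tiff", "image"):
        px = _read_image(path)
        scale = scale_um_per_px
        source = "png"
    else:
        raise FormatError(f"unknown format {format!r}")

    if scale is None:
        raise CalibrationError(
            f"{path.name}: no μm/pixel scale in header and none supplied"
        )
    return OctScan(px, float(scale), source=source, frame_id=path.stem)
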