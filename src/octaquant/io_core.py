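"""Image/metadata I/O, scan geometry, and metric record plumbing.

An en-face OCT-angiogram is a grayscale image with known physical extent
(typically 3 mm x 3 mm sampled by 320 x 320 A-scans).  All millimetre
quantities downstream derive from the :class:`ScanGeometry` attached to the
image at load time, so every mm <-> pixel conversion lives here.

Intensities are normalized to [0, 1] by the declared bit depth of the file
(255 for 8-bit, 65535 for 16-bit), never by per-image min/max, so adaptive
thresholding behaves identically across a batch.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import ChannelMismatchError, DimensionMismatchError, EmptyRecordsError

logger = logging.getLogger(__name__)

#: quality-score cutoff below which a scan is excluded from analysis
DEFAULT_MIN_QUALITY = 40


@dataclass(frozen=True)
class ScanGeometry:
    """Physical and pixel dimensions of an en-face scan.

    Parameters
    ----------
    width_mm, height_mm
        Physical extent of the scan in millimetres; must be positive.
    width_px, height_px
        Number of pixel columns / rows; at least 16 each.
    """

    width_mm: float
    height_mm: float
    width_px: int
    height_px: int

    def __post_init__(self):
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValueError("physical scan dimensions must be positive")
        if self.width_px < 16 or self.height_px < 16:
            raise ValueError("pixel dimensions must be at least 16")

    @property
    def pixel_size_mm_x(self) -> float:
        return self.width_mm / self.width_px

    @property
    def pixel_size_mm_y(self) -> float:
        return self.height_mm / self.height_px

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm_x * self.pixel_size_mm_y

    @property
    def is_isotropic(self) -> bool:
        return math.isclose(self.pixel_size_mm_x, self.pixel_size_mm_y, rel_tol=1e-9)

    @classmethod
    def macula_3mm(cls) -> "ScanGeometry":
        """The standard 3 mm x 3 mm / 320 x 320 macular scan pattern."""
        return cls(3.0, 3.0, 320, 320)


def pixel_scale(geometry: ScanGeometry) -> tuple[float, float, float]:
    """Return ``(pixel_size_mm_x, pixel_size_mm_y, pixel_area_mm2)``.

    Exact quotients of the declared geometry; no rounding is applied.
    """
    return (
        geometry.pixel_size_mm_x,
        geometry.pixel_size_mm_y,
        geometry.pixel_area_mm2,
    )


@dataclass
class GrayImage:
    """A grayscale angiogram with intensities in [0, 1] plus its geometry."""

    pixels: np.ndarray
    geometry: ScanGeometry
    quality_score: Optional[int] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DimensionMismatchError("GrayImage requires a 2-D array")
        expected = (self.geometry.height_px, self.geometry.width_px)
        if self.pixels.shape != expected:
            raise DimensionMismatchError(
                f"image shape {self.pixels.shape} != geometry {expected}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"intensities outside [0, 1]: range ({lo}, {hi})")


@dataclass
class BinaryImage:
    """A vessel mask: True = vessel (white), False = background (dark)."""

    pixels: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        expected = (self.geometry.height_px, self.geometry.width_px)
        if self.pixels.shape != expected:
            raise DimensionMismatchError(
                f"mask shape {self.pixels.shape} != geometry {expected}"
            )


#: fixed column order of metric tables
METRIC_COLUMNS = [
    "image_id",
    "faz_area_mm2",
    "faz_circularity",
    "total_vd_pct",
    "parafoveal_vd_pct",
    "fractal_dimension",
    "vdi_mm",
    "qc_pass",
]


@dataclass
class MetricRecord:
    """One row of pipeline output: the six headline metrics plus QC state.

    Metrics are ``None`` when a scan was gated out by quality control and
    not force-processed.
    """

    image_id: str
    faz_area_mm2: Optional[float] = None
    faz_circularity: Optional[float] = None
    total_vd_pct: Optional[float] = None
    parafoveal_vd_pct: Optional[float] = None
    fractal_dimension: Optional[float] = None
    vdi_mm: Optional[float] = None
    qc_pass: bool = True

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale a raw integer/float image to [0, 1] by its declared bit depth."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if arr.dtype == bool:
        return arr.astype(np.float64)
    arr = arr.astype(np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError(
            f"float image of dtype {arr.dtype} must already be in [0, 1]"
        )
    return arr


def load_angiogram(
    path: str | Path,
    geometry: ScanGeometry,
    quality_score: Optional[int] = None,
) -> GrayImage:
    """Load a PNG/TIFF angiogram, normalize it, and attach its geometry.

    RGB(A) files whose color channels are identical (grayscale stored as
    color) are collapsed to one channel; genuinely colored images raise
    :class:`ChannelMismatchError`.  A pixel-dimension disagreement with
    ``geometry`` raises :class:`DimensionMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise ChannelMismatchError(
                f"{path.name}: color channels differ; expected grayscale content"
            )
        arr = rgb[..., 0]
    elif arr.ndim != 2:
        raise ChannelMismatchError(f"{path.name}: unsupported array rank {arr.ndim}")
    pixels = _normalize(arr)
    expected = (geometry.height_px, geometry.width_px)
    if pixels.shape != expected:
        raise DimensionMismatchError(
            f"{path.name}: file is {pixels.shape}, geometry declares {expected}"
        )
    return GrayImage(pixels, geometry, quality_score)


def save_angiogram(image: GrayImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write a GrayImage back to disk as 8- or 16-bit grayscale."""
    if bit_depth == 8:
        raw = np.round(image.pixels * 255).astype(np.uint8)
    elif bit_depth == 16:
        raw = np.round(image.pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), raw)


def qc_gate(image: GrayImage, min_quality: int = DEFAULT_MIN_QUALITY) -> bool:
    """Quality gate: False iff a quality score is present and below cutoff.

    Scans without a score pass with a logged warning — automated gating
    cannot replace manual artifact grading, so absence never blocks.
    """
    if image.quality_score is None:
        logger.warning("no quality score attached; QC gate passes by default")
        return True
    return image.quality_score >= min_quality


def write_metrics(
    records: Sequence[MetricRecord], path: str | Path, format: str = "csv"
) -> None:
    """Write metric records as CSV (fixed column order) or a JSON array."""
    if len(records) == 0:
        raise EmptyRecordsError("no metric records to write")
    rows = [r.to_dict() for r in records]
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metrics(path: str | Path) -> list[MetricRecord]:
    """Read back a metric table written by :func:`write_metrics`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            rows = json.load(fh)
    else:
        df = pd.read_csv(path)
        rows = df.to_dict(orient="records")
    out = []
    for row in rows:
        clean = {}
        for key in METRIC_COLUMNS:
            val = row.get(key)
            if isinstance(val, float) and math.isnan(val):
                val = None
            clean[key] = val
        clean["qc_pass"] = bool(clean["qc_pass"])
        out.append(MetricRecord(**clean))
    return out


def read_sidecar(path: str | Path) -> dict:
    """Read a JSON sidecar with image_id, width_mm, height_mm, quality_score."""
    with open(path) as fh:
        return json.load(fh)
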