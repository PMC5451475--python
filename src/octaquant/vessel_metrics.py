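"""Vessel-network metrics on the ETDRS grid.

Given the binarized angiogram this module computes:

* vessel density (VD, %) in the central 1 mm disk, the 1-3 mm parafoveal
  annulus, and the full 3 mm disk of the ETDRS grid.  Non-perfused regions
  are 8-connected components of dark (background) pixels strictly larger
  than 0.02 mm^2; VD is the percentage of region area *not* covered by such
  components, so sub-threshold dark specks count as perfused;
* fractal dimension (FD) of the skeletonized network by box counting
  (least-squares slope of log N(s) against log 1/s over dyadic box sizes);
* vessel diameter index (VDI, mm): vessel mask area divided by total
  skeleton length — an average vessel caliber.

``compute_all`` chains preprocessing, FAZ segmentation and these metrics in
the fixed order denoise -> binarize -> FAZ -> grid -> metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize
from skimage.morphology import thin as _sk_thin

from . import faz_metrics, preprocess
from .exceptions import (
    EmptyRegionError,
    GridFitError,
    InsufficientScalesError,
    StageError,
    ZeroSkeletonError,
)
from .io_core import (
    BinaryImage,
    GrayImage,
    MetricRecord,
    ScanGeometry,
    qc_gate,
)
from .preprocess import NlmParams, PhansalkarParams

logger = logging.getLogger(__name__)

#: strict lower bound on the area of a qualifying non-perfused region
MIN_NONPERFUSION_AREA_MM2 = 0.02

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class EtdrsGrid:
    """Pixel masks of the 1 / 3 mm ETDRS zones centred on the fovea."""

    center: tuple[float, float]  # (row, col), pixel units
    inner_diameter_mm: float
    outer_diameter_mm: float
    central_mask: np.ndarray
    parafoveal_mask: np.ndarray
    total_mask: np.ndarray


@dataclass
class NonPerfusionInventory:
    """Qualifying dark components within a grid region.

    components: list of (label, pixel_count, area_mm2), each strictly larger
    than min_area_mm2.
    """

    components: list[tuple[int, int, float]]
    min_area_mm2: float = MIN_NONPERFUSION_AREA_MM2
    labels: Optional[np.ndarray] = None

    @property
    def total_area_mm2(self) -> float:
        return sum(a for _, _, a in self.components)

    @property
    def total_pixels(self) -> int:
        return sum(n for _, n, a in self.components)


@dataclass
class SkeletonImage:
    """One-pixel-wide vessel centerline mask."""

    pixels: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)


@dataclass
class VesselMetrics:
    total_vd_pct: float
    parafoveal_vd_pct: float
    fractal_dimension: float
    vdi_mm: float
    skeleton_length_mm: float
    vessel_area_mm2: float


def build_etdrs_grid(
    geometry: ScanGeometry,
    center: Optional[tuple[float, float]] = None,
    inner_diameter_mm: float = 1.0,
    outer_diameter_mm: float = 3.0,
) -> EtdrsGrid:
    """Construct the central-disk / parafoveal-annulus / total masks.

    A pixel belongs to a zone iff its centre lies within the circle.  The
    outer circle must fit inside the scan to within one pixel of overhang
    (a fovea-centred 3 mm grid on a 3 mm scan is exactly tangent), otherwise
    :class:`GridFitError` is raised.
    """
    if center is None:
        center = (geometry.height_px / 2.0, geometry.width_px / 2.0)
    px, py = geometry.pixel_size_mm_x, geometry.pixel_size_mm_y
    cy_mm = (center[0] + 0.5) * py
    cx_mm = (center[1] + 0.5) * px
    r_out = outer_diameter_mm / 2.0
    slack_x, slack_y = px, py  # one pixel of tolerated overhang
    if (
        cx_mm - r_out < -slack_x
        or cx_mm + r_out > geometry.width_mm + slack_x
        or cy_mm - r_out < -slack_y
        or cy_mm + r_out > geometry.height_mm + slack_y
    ):
        raise GridFitError(
            f"outer circle (d={outer_diameter_mm} mm) at centre "
            f"({cy_mm:.3f}, {cx_mm:.3f}) mm exceeds the "
            f"{geometry.width_mm} x {geometry.height_mm} mm scan"
        )
    rows = (np.arange(geometry.height_px) + 0.5) * py
    cols = (np.arange(geometry.width_px) + 0.5) * px
    d2 = (rows[:, None] - cy_mm) ** 2 + (cols[None, :] - cx_mm) ** 2
    inner = d2 <= (inner_diameter_mm / 2.0) ** 2
    outer = d2 <= r_out**2
    return EtdrsGrid(
        center=(float(center[0]), float(center[1])),
        inner_diameter_mm=inner_diameter_mm,
        outer_diameter_mm=outer_diameter_mm,
        central_mask=inner,
        parafoveal_mask=outer & ~inner,
        total_mask=outer,
    )


def find_nonperfusion(
    mask: BinaryImage,
    region_mask: np.ndarray,
    min_area_mm2: float = MIN_NONPERFUSION_AREA_MM2,
) -> NonPerfusionInventory:
    """Inventory dark components strictly larger than ``min_area_mm2``.

    Components are 8-connected sets of background pixels clipped to the
    region of interest *before* the area test (a component straddling the
    region boundary counts only its in-region pixels).
    """
    dark = (~mask.pixels) & np.asarray(region_mask, dtype=bool)
    labels, n = ndimage.label(dark, structure=_EIGHT)
    pa = mask.geometry.pixel_area_mm2
    components = []
    if n:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        for lab in range(1, n + 1):
            area = counts[lab] * pa
            if area > min_area_mm2:
                components.append((lab, int(counts[lab]), float(area)))
    return NonPerfusionInventory(components, min_area_mm2, labels)


def vessel_density(
    mask: BinaryImage,
    region_mask: np.ndarray,
    inventory: Optional[NonPerfusionInventory] = None,
) -> float:
    """Vessel density (%) of a grid region.

    VD = 100 * (region area - sum of qualifying non-perfusion areas within
    the region) / region area.  Dark areas below the 0.02 mm^2 cutoff count
    as perfused.
    """
    region = np.asarray(region_mask, dtype=bool)
    n_region = int(region.sum())
    if n_region == 0:
        raise EmptyRegionError("vessel density of an empty region")
    if inventory is None:
        inventory = find_nonperfusion(mask, region)
    return 100.0 * (n_region - inventory.total_pixels) / n_region


def skeletonize_mask(mask: BinaryImage, method: str = "thin") -> SkeletonImage:
    """Thin the vessel mask to 1-px-wide 8-connected centerlines.

    The default Guo-Hall iterative thinning preserves topology and never
    leaves 2x2 blocks; Zhang-Suen ('zhang') is available for comparison.
    """
    if method == "thin":
        sk = _sk_thin(mask.pixels)
    elif method == "zhang":
        sk = _sk_skeletonize(mask.pixels)
    else:
        raise ValueError(f"unknown skeletonization method {method!r}")
    return SkeletonImage(sk, mask.geometry)


def skeleton_length(skeleton: SkeletonImage) -> float:
    """Total centerline length in mm.

    Sums each undirected 8-neighbour link once: horizontal/vertical links at
    the pixel size, diagonal links at the Euclidean diagonal.
    """
    sk = skeleton.pixels
    px = skeleton.geometry.pixel_size_mm_x
    py = skeleton.geometry.pixel_size_mm_y
    diag = math.hypot(px, py)
    n_h = int((sk[:, :-1] & sk[:, 1:]).sum())
    n_v = int((sk[:-1, :] & sk[1:, :]).sum())
    n_d1 = int((sk[:-1, :-1] & sk[1:, 1:]).sum())
    n_d2 = int((sk[:-1, 1:] & sk[1:, :-1]).sum())
    return n_h * px + n_v * py + (n_d1 + n_d2) * diag


def box_counts(pixels: np.ndarray, sizes: list[int]) -> list[int]:
    """N(s): number of grid-aligned s x s boxes containing >= 1 true pixel.

    The grid is anchored at the (0, 0) corner; the image is zero-padded up
    to a multiple of s.
    """
    arr = np.asarray(pixels, dtype=bool)
    H, W = arr.shape
    out = []
    for s in sizes:
        Hp = -(-H // s) * s
        Wp = -(-W // s) * s
        padded = np.zeros((Hp, Wp), dtype=bool)
        padded[:H, :W] = arr
        blocks = padded.reshape(Hp // s, s, Wp // s, s).any(axis=(1, 3))
        out.append(int(blocks.sum()))
    return out


def _box_sizes(shape: tuple[int, int]) -> list[int]:
    limit = min(shape) // 4
    sizes = []
    s = 2
    while s <= limit:
        sizes.append(s)
        s *= 2
    return sizes


def fractal_dimension_fit(
    pixels: np.ndarray,
) -> tuple[float, float, list[int], list[int]]:
    """Box-counting fit: returns (fd, r_squared, sizes, counts)."""
    arr = np.asarray(pixels, dtype=bool)
    if arr.sum() < 2:
        raise InsufficientScalesError("need at least 2 foreground pixels")
    sizes = _box_sizes(arr.shape)
    if len(sizes) < 3:
        raise InsufficientScalesError(
            f"only {len(sizes)} box scales available for image {arr.shape}"
        )
    counts = box_counts(arr, sizes)
    x = -np.log(np.asarray(sizes, dtype=float))  # log(1/s)
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2, sizes, counts


def fractal_dimension(skeleton: SkeletonImage | BinaryImage) -> float:
    """Box-counting fractal dimension of a skeleton (or binary) image."""
    fd, _, _, _ = fractal_dimension_fit(skeleton.pixels)
    return fd


def vessel_diameter_index(
    mask: BinaryImage, skeleton: SkeletonImage
) -> float:
    """Mean vessel caliber (mm): vessel mask area over skeleton length."""
    length = skeleton_length(skeleton)
    if length <= 0:
        raise ZeroSkeletonError("VDI undefined for zero skeleton length")
    area = int(mask.pixels.sum()) * mask.geometry.pixel_area_mm2
    return area / length


@dataclass
class PipelineConfig:
    """One parameter set for the full quantification chain."""

    nlm: NlmParams = field(default_factory=NlmParams)
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    min_quality: int = 40
    faz_seed: Optional[tuple[int, int]] = None
    perimeter_method: str = "corner_corrected"
    fd_source: str = "skeleton"  # or "binary"
    skeleton_method: str = "thin"
    inner_diameter_mm: float = 1.0
    outer_diameter_mm: float = 3.0
    min_nonperfusion_area_mm2: float = MIN_NONPERFUSION_AREA_MM2
    etdrs_center: str = "faz"  # or "image"
    force: bool = False


@dataclass
class PipelineResult:
    """Record plus the intermediate images, for provenance/inspection."""

    record: MetricRecord
    denoised: Optional[GrayImage] = None
    mask: Optional[BinaryImage] = None
    skeleton: Optional[SkeletonImage] = None
    faz: Optional["faz_metrics.FazResult"] = None
    grid: Optional[EtdrsGrid] = None


def compute_all(
    image: GrayImage,
    config: Optional[PipelineConfig] = None,
    image_id: str = "image",
    return_intermediates: bool = False,
) -> MetricRecord | PipelineResult:
    """Run the full chain denoise -> binarize -> FAZ -> grid -> metrics.

    A scan failing the quality gate (and not forced) yields a record with
    ``qc_pass=False`` and missing metrics.  Stage failures re-raise as
    :class:`StageError` carrying the stage name.
    """
    if config is None:
        config = PipelineConfig()
    passed = qc_gate(image, config.min_quality)
    if not passed and not config.force:
        record = MetricRecord(image_id=image_id, qc_pass=False)
        return PipelineResult(record) if return_intermediates else record

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise StageError(stage, exc) from exc

    denoised = run("denoise", preprocess.denoise_nlm, image, config.nlm)
    mask = run("binarize", preprocess.binarize_phansalkar, denoised, config.phansalkar)
    faz = run(
        "faz",
        faz_metrics.segment_faz,
        mask,
        seed=config.faz_seed,
        perimeter_method=config.perimeter_method,
    )
    if config.etdrs_center == "faz":
        center = faz.centroid
        try:
            grid = build_etdrs_grid(
                image.geometry, center, config.inner_diameter_mm, config.outer_diameter_mm
            )
        except GridFitError:
            logger.warning("FAZ centroid too eccentric for the grid; using image centre")
            grid = run("etdrs_grid", build_etdrs_grid, image.geometry)
    else:
        grid = run("etdrs_grid", build_etdrs_grid, image.geometry)
    inv_total = run(
        "nonperfusion",
        find_nonperfusion,
        mask,
        grid.total_mask,
        config.min_nonperfusion_area_mm2,
    )
    inv_para = run(
        "nonperfusion",
        find_nonperfusion,
        mask,
        grid.parafoveal_mask,
        config.min_nonperfusion_area_mm2,
    )
    total_vd = run("vessel_density", vessel_density, mask, grid.total_mask, inv_total)
    para_vd = run(
        "vessel_density", vessel_density, mask, grid.parafoveal_mask, inv_para
    )
    skeleton = run("skeletonize", skeletonize_mask, mask, config.skeleton_method)
    fd_input = skeleton if config.fd_source == "skeleton" else mask
    fd = run("fractal_dimension", fractal_dimension, fd_input)
    vdi = run("vdi", vessel_diameter_index, mask, skeleton)
    record = MetricRecord(
        image_id=image_id,
        faz_area_mm2=faz.area_mm2,
        faz_circularity=faz.circularity,
        total_vd_pct=total_vd,
        parafoveal_vd_pct=para_vd,
        fractal_dimension=fd,
        vdi_mm=vdi,
        qc_pass=passed,
    )
    if return_intermediates:
        return PipelineResult(record, denoised, mask, skeleton, faz, grid)
    return record
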