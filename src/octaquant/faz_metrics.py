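"""Foveal avascular zone segmentation and morphometry.

The FAZ is segmented from the binarized angiogram by region growing: the
4-connected component of *background* (non-vessel) pixels containing a seed
point, which defaults to the scan centre because scans are fovea-centred.
4-connectivity prevents the region leaking diagonally through single-pixel
capillary junctions.

From the region we compute:

* area — pixel count x pixel area (mm^2);
* perimeter — length of the traced closed boundary (Moore 8-connected
  contour following).  Two chain-length estimators are provided: the plain
  chain rule (axial step = 1 px, diagonal = sqrt(2) px), and the
  Vossepoel-Smeulders corner-corrected estimator
  ``0.980 * n_axial + 1.406 * n_diag - 0.091 * n_corner`` which removes the
  ~5 % digitization overshoot of the plain rule on smooth curves and is the
  default;
* circularity — the isoperimetric quotient 4 * pi * A / P^2, i.e. the ratio
  of the region's area to the area of the circle with the same perimeter.
  1.0 is a perfect circle; values toward 0 indicate an irregular FAZ.
  Rasterization can push the quotient marginally above 1; such values are
  clipped to 1.0 and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import EmptyRegionError, SeedSearchError, ZeroPerimeterError
from .io_core import BinaryImage, ScanGeometry

logger = logging.getLogger(__name__)

#: clip tolerance for rasterization overshoot of the isoperimetric quotient
CIRCULARITY_EPS = 0.02

# clockwise Moore neighbourhood, starting East
_DIRS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity


@dataclass
class FazResult:
    """FAZ segmentation output: region, seed, and the three shape metrics."""

    region_mask: np.ndarray
    seed: tuple[int, int]
    area_mm2: float
    perimeter_mm: float
    circularity: float
    contour: list[tuple[int, int]]

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.region_mask)
        return float(rows.mean()), float(cols.mean())


def grow_faz(
    mask: BinaryImage,
    seed: Optional[tuple[int, int]] = None,
    max_seed_search_px: Optional[int] = None,
) -> np.ndarray:
    """Region-grow the FAZ from a seed point on the binarized image.

    Returns the 4-connected background component containing the seed.  If
    the seed lands on a vessel pixel, the nearest background pixel (by
    Euclidean distance) within ``max_seed_search_px`` is used instead and a
    warning is logged.  An all-vessel neighbourhood raises
    :class:`SeedSearchError`.
    """
    background = ~mask.pixels
    H, W = background.shape
    if seed is None:
        seed = (H // 2, W // 2)
    seed = (int(seed[0]), int(seed[1]))
    if not (0 <= seed[0] < H and 0 <= seed[1] < W):
        raise SeedSearchError(f"seed {seed} outside image {background.shape}")
    if max_seed_search_px is None:
        max_seed_search_px = max(H, W) // 4
    if not background[seed]:
        if not background.any():
            raise SeedSearchError("mask is all vessel; no background to grow")
        # distance from every pixel to the nearest background pixel
        dist, (ir, ic) = ndimage.distance_transform_edt(
            mask.pixels, return_indices=True
        )
        d = dist[seed]
        if d > max_seed_search_px:
            raise SeedSearchError(
                f"no background pixel within {max_seed_search_px} px of seed {seed}"
            )
        moved = (int(ir[seed]), int(ic[seed]))
        logger.warning("seed %s on vessel; moved to nearest background %s", seed, moved)
        seed = moved
    labels, _ = ndimage.label(background, structure=_CROSS)
    region = labels == labels[seed]
    if region.all():
        logger.warning("FAZ region is the entire image (unbounded; all-background mask)")
    return region


def faz_area(region_mask: np.ndarray, geometry: ScanGeometry) -> float:
    """Region area in mm^2: pixel count times pixel area, exact."""
    count = int(np.count_nonzero(region_mask))
    if count == 0:
        raise EmptyRegionError("empty region has no area")
    return count * geometry.pixel_area_mm2


def trace_contour(region_mask: np.ndarray) -> list[tuple[int, int]]:
    """Trace the outer boundary of a region (Moore neighbourhood, clockwise).

    Returns the ordered closed chain of boundary pixels (first pixel not
    repeated at the end).  A single-pixel region yields a one-element chain.
    """
    region = np.asarray(region_mask, dtype=bool)
    rows, cols = np.nonzero(region)
    if len(rows) == 0:
        raise EmptyRegionError("cannot trace an empty region")
    H, W = region.shape

    def inside(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and region[r, c]

    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    contour = [start]
    current = start
    backtrack = (start[0], start[1] - 1)  # West of start is background
    first_move = None
    for _ in range(8 * len(rows) + 16):
        i = _DIRS.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        cand = None
        for j in range(1, 9):
            d = _DIRS[(i + j) % 8]
            nb = (current[0] + d[0], current[1] + d[1])
            if inside(*nb):
                cand = nb
                break
        if cand is None:
            return contour  # isolated single pixel
        move = (current, cand)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        contour.append(cand)
        prev = _DIRS[(i + j - 1) % 8]
        backtrack = (current[0] + prev[0], current[1] + prev[1])
        current = cand
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def _chain_steps(contour: list[tuple[int, int]]) -> tuple[int, int, int]:
    """Count (axial, diagonal, corner) steps of a closed contour chain."""
    n = len(contour)
    n_axial = n_diag = n_corner = 0
    steps = []
    for t in range(n):
        a, b = contour[t], contour[(t + 1) % n]
        d = (b[0] - a[0], b[1] - a[1])
        steps.append(d)
        if abs(d[0]) + abs(d[1]) == 1:
            n_axial += 1
        else:
            n_diag += 1
    for t in range(n):
        if steps[t] != steps[t - 1]:
            n_corner += 1
    return n_axial, n_diag, n_corner


def faz_perimeter(
    region_mask: np.ndarray,
    geometry: ScanGeometry,
    method: str = "corner_corrected",
) -> float:
    """Perimeter of the region's traced boundary chain, in mm.

    method='chain' sums axial steps at pixel_size and diagonal steps at
    sqrt(2) x pixel_size.  method='corner_corrected' (default) applies the
    Vossepoel-Smeulders weights, which are unbiased to <1 % on digitized
    smooth contours.  A single-pixel region has zero perimeter.  Regions
    touching the image border are measured along the clipped contour with a
    warning.
    """
    region = np.asarray(region_mask, dtype=bool)
    contour = trace_contour(region)
    if len(contour) < 2:
        return 0.0
    H, W = region.shape
    if (
        region[0, :].any()
        or region[-1, :].any()
        or region[:, 0].any()
        or region[:, -1].any()
    ):
        logger.warning("region touches image border; perimeter uses clipped contour")
    n_axial, n_diag, n_corner = _chain_steps(contour)
    px, py = geometry.pixel_size_mm_x, geometry.pixel_size_mm_y
    if method == "chain":
        if geometry.is_isotropic:
            return (n_axial + n_diag * math.sqrt(2.0)) * px
        # anisotropic: sum true step lengths
        total = 0.0
        n = len(contour)
        for t in range(n):
            a, b = contour[t], contour[(t + 1) % n]
            total += math.hypot((b[0] - a[0]) * py, (b[1] - a[1]) * px)
        return total
    if method == "corner_corrected":
        if not geometry.is_isotropic:
            logger.warning(
                "corner correction assumes isotropic pixels; using mean pixel size"
            )
        size = (px + py) / 2.0
        return (0.980 * n_axial + 1.406 * n_diag - 0.091 * n_corner) * size
    raise ValueError(f"unknown perimeter method {method!r}")


def faz_circularity(area_mm2: float, perimeter_mm: float) -> float:
    """Isoperimetric quotient 4*pi*A/P^2, clipped to 1.0."""
    if perimeter_mm <= 0:
        raise ZeroPerimeterError("circularity undefined for zero perimeter")
    q = 4.0 * math.pi * area_mm2 / perimeter_mm**2
    if q > 1.0:
        if q > 1.0 + CIRCULARITY_EPS:
            logger.warning("circularity %.4f clipped to 1.0", q)
        q = 1.0
    return q


def segment_faz(
    mask: BinaryImage,
    seed: Optional[tuple[int, int]] = None,
    perimeter_method: str = "corner_corrected",
) -> FazResult:
    """Full FAZ analysis: grow, measure area/perimeter/circularity."""
    region = grow_faz(mask, seed)
    rows, cols = np.nonzero(region)
    used_seed = seed if seed is not None else (
        mask.geometry.height_px // 2,
        mask.geometry.width_px // 2,
    )
    area = faz_area(region, mask.geometry)
    contour = trace_contour(region)
    perimeter = faz_perimeter(region, mask.geometry, method=perimeter_method)
    circ = faz_circularity(area, perimeter) if perimeter > 0 else 0.0
    return FazResult(
        region_mask=region,
        seed=(int(used_seed[0]), int(used_seed[1])),
        area_mm2=area,
        perimeter_mm=perimeter,
        circularity=circ,
        contour=contour,
    )
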