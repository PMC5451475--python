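"""Synthetic en-face angiograms with analytic ground truth.

Emulates the image class the pipeline targets: bright superficial-plexus
vessels on a dark background, a central avascular zone bounded by a
terminal capillary ring, optional capillary-dropout patches, and
speckle-like noise.  Every scene carries a :class:`SceneTruth` whose FAZ
area/perimeter/circularity come from the *continuous* boundary curve
(quadrature on the Fourier radial perturbation, independent of any pixel
processing), making it a legitimate oracle for the raster pipeline.

The FAZ boundary is  r(theta) = R * (1 + sum_{m=2..6} a_m cos(m theta +
phi_m))  with amplitudes scaled by the ``faz_irregularity`` parameter;
irregularity 0 is a perfect circle.  Vessels are branching random
trees rooted just outside the terminal capillary ring and growing
outward, over an anastomotic background capillary mesh; all strokes are
drawn anti-aliased so adaptive binarization is exercised on soft edges.  The noise model is
``clean * (1 + speckle * u) + N(0, sigma)`` clipped to [0, 1].

All randomness flows from one integer seed through one generator instance;
identical parameters give byte-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import InfeasibleSceneError
from .io_core import BinaryImage, GrayImage, ScanGeometry
from .vessel_metrics import build_etdrs_grid, find_nonperfusion, vessel_density

_N_THETA = 4096  # quadrature samples for the continuous boundary

#: intensity levels of the clean scene
BACKGROUND_LEVEL = 0.10
VESSEL_LEVEL = 0.85


@dataclass(frozen=True)
class SceneParams:
    """Structural and noise parameters of one synthetic angiogram."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry.macula_3mm)
    faz_radius_mm: float = 0.35
    faz_irregularity: float = 0.0
    n_vessel_roots: int = 48
    branch_density: float = 0.10
    vessel_width_px: float = 3.0
    capillary_spacing_px: float = 8.0
    """Mean spacing of the background capillary mesh; 0 disables the mesh."""
    dropout_patches: tuple[tuple[float, float, float], ...] = ()
    """Dropout patches as (center_y_mm, center_x_mm, radius_mm)."""
    noise_sigma: float = 0.05
    speckle_strength: float = 0.15
    quality_score: Optional[int] = 70
    rng_seed: int = 0

    def __post_init__(self):
        half = min(self.geometry.width_mm, self.geometry.height_mm) / 2.0
        if not (0 < self.faz_radius_mm < half):
            raise InfeasibleSceneError(
                f"FAZ radius {self.faz_radius_mm} mm must be inside the "
                f"{half} mm scan half-width"
            )
        if self.faz_irregularity < 0:
            raise InfeasibleSceneError("irregularity must be >= 0")
        if not (0 <= self.branch_density <= 1):
            raise InfeasibleSceneError("branch_density is a probability")


@dataclass
class SceneTruth:
    """Analytic/continuous-model ground truth for one scene."""

    faz_mask: np.ndarray
    faz_area_mm2: float
    faz_perimeter_mm: float
    faz_circularity: float
    vessel_mask: np.ndarray
    true_total_vd_pct: float
    true_parafoveal_vd_pct: float
    dropout_inventory: list[tuple[int, int, float]]
    faz_center_px: tuple[float, float]


def _boundary_coefficients(params: SceneParams, rng: np.random.Generator):
    """Draw the Fourier amplitudes/phases of the FAZ boundary."""
    modes = np.arange(2, 7)
    amps = params.faz_irregularity * rng.uniform(0.4, 1.0, size=modes.size) / (modes - 1)
    total = np.abs(amps).sum()
    if total > 0.7:  # keep r(theta) strictly positive
        amps *= 0.7 / total
    phases = rng.uniform(0, 2 * math.pi, size=modes.size)
    return modes, amps, phases


def _boundary_radius(theta: np.ndarray, R: float, modes, amps, phases) -> np.ndarray:
    pert = np.zeros_like(theta)
    for m, a, ph in zip(modes, amps, phases):
        pert += a * np.cos(m * theta + ph)
    return R * (1.0 + pert)


def _continuous_shape_metrics(R, modes, amps, phases) -> tuple[float, float, float]:
    """Area, perimeter, circularity of the continuous boundary by quadrature."""
    theta = np.linspace(0, 2 * math.pi, _N_THETA, endpoint=False)
    r = _boundary_radius(theta, R, modes, amps, phases)
    dr = np.zeros_like(theta)
    for m, a, ph in zip(modes, amps, phases):
        dr += -R * a * m * np.sin(m * theta + ph)
    dtheta = 2 * math.pi / _N_THETA
    area = 0.5 * float((r**2).sum()) * dtheta
    perim = float(np.sqrt(r**2 + dr**2).sum()) * dtheta
    circ = min(4 * math.pi * area / perim**2, 1.0)
    return area, perim, circ


def _render_strokes(
    shape: tuple[int, int],
    points: np.ndarray,
    widths: np.ndarray,
) -> np.ndarray:
    """Render anti-aliased strokes from centerline sample points.

    Coverage at distance d from the nearest centerline sample is
    clip(w/2 + 0.5 - d, 0, 1): a one-pixel soft edge around a stroke of
    total width w, with w taken from that nearest sample.  Implemented as
    one Euclidean distance transform over the rasterized sample points, so
    cost is independent of stroke count.
    """
    H, W = shape
    canvas = np.zeros(shape)
    if len(points) == 0:
        return canvas
    rr = np.clip(np.rint(points[:, 0]).astype(int), 0, H - 1)
    cc = np.clip(np.rint(points[:, 1]).astype(int), 0, W - 1)
    keep = (
        (points[:, 0] > -1)
        & (points[:, 0] < H)
        & (points[:, 1] > -1)
        & (points[:, 1] < W)
    )
    rr, cc, ww = rr[keep], cc[keep], widths[keep]
    on = np.zeros(shape, dtype=bool)
    width_map = np.zeros(shape)
    on[rr, cc] = True
    # keep the widest stroke where samples collide
    np.maximum.at(width_map, (rr, cc), ww)
    dist, (ir, ic) = ndimage.distance_transform_edt(~on, return_indices=True)
    w_near = width_map[ir, ic]
    return np.clip(w_near / 2.0 + 0.5 - dist, 0.0, 1.0)


def _grow_trees(
    params: SceneParams,
    rng: np.random.Generator,
    center: np.ndarray,
    R_px: float,
    modes,
    amps,
    phases,
    shape: tuple[int, int],
) -> tuple[list[tuple[float, float]], list[float]]:
    """Branching random trees rooted outside the terminal ring, growing outward.

    Returns centerline sample points and per-sample widths.  Growth stops
    when a branch leaves the image, narrows below capillary caliber, or the
    global step budget (which scales overall network density together with
    ``branch_density``) is spent.
    """
    H, W = shape
    step = 2.5  # px per growth step
    subsample = 0.5  # px spacing of rendered samples along a step
    max_depth = 6
    min_width = 1.35  # a branch below capillary caliber stops growing
    pts: list[tuple[float, float]] = []
    wds: list[float] = []
    n_sub = max(int(step / subsample), 1)
    fracs = [(i + 1) / n_sub for i in range(n_sub)]
    root_angles = (
        np.arange(params.n_vessel_roots) / max(params.n_vessel_roots, 1) * 2 * math.pi
        + rng.uniform(0, 2 * math.pi)
    )
    stack = []
    for ang in root_angles:
        r_b = _boundary_radius(np.array([ang]), R_px, modes, amps, phases)[0]
        width = params.vessel_width_px * rng.uniform(0.8, 1.2)
        # root sits outside the terminal ring so it cannot intrude on the FAZ
        r0 = r_b + params.vessel_width_px + width / 2
        py = center[0] + r0 * math.sin(ang)
        px = center[1] + r0 * math.cos(ang)
        stack.append((py, px, ang, width, 0))
    # safety cap only; ordinary parameter ranges terminate by width taper
    budget = 2500 * max(params.n_vessel_roots, 1)
    while stack and budget > 0:
        py, px, ang, width, depth = stack.pop()
        while width >= min_width and budget > 0:
            budget -= 1
            ang += rng.normal(0.0, 0.35)
            ny = py + step * math.sin(ang)
            nx = px + step * math.cos(ang)
            dy, dx = ny - center[0], nx - center[1]
            d_faz = math.hypot(dy, dx)
            r_b = _boundary_radius(
                np.array([math.atan2(dy, dx)]), R_px, modes, amps, phases
            )[0]
            # 1 px clearance beyond the soft edge: never invade the FAZ
            if d_faz < r_b + width / 2 + 1.0:
                ang += rng.uniform(0.8, 1.6) * (1.0 if rng.random() < 0.5 else -1.0)
                continue
            for f in fracs:
                pts.append((py + f * (ny - py), px + f * (nx - px)))
                wds.append(width)
            py, px = ny, nx
            if not (-4 <= py <= H + 4 and -4 <= px <= W + 4):
                break
            if depth < max_depth and rng.random() < params.branch_density:
                child_ang = ang + rng.uniform(0.5, 1.1) * (
                    1.0 if rng.random() < 0.5 else -1.0
                )
                stack.append((py, px, child_ang, width * 0.8, depth + 1))
            width *= rng.uniform(0.985, 0.998)
    return pts, wds


def _capillary_mesh(
    params: SceneParams,
    rng: np.random.Generator,
    center: np.ndarray,
    R_px: float,
    modes,
    amps,
    phases,
    shape: tuple[int, int],
) -> tuple[list[tuple[float, float]], list[float]]:
    """Anastomotic capillary net with closed loops outside the FAZ.

    The superficial plexus is a closed-loop capillary bed, so the avascular
    pockets it encloses are small compared with the 0.02 mm^2 non-perfusion
    rule.  Capillaries (apparent caliber ~2 px, matching the point-spread-function
    broadening of capillary flow signal) are drawn as gently curved edges
    of a jittered square lattice of mean spacing ``capillary_spacing_px``:
    enclosed pockets are ~spacing^2 pixels, so qualifying dark areas arise
    only from the FAZ and from explicit dropout patches, as in real
    angiograms.
    """
    H, W = shape
    spacing = params.capillary_spacing_px
    if spacing <= 0:
        return [], []
    pts: list[tuple[float, float]] = []
    wds: list[float] = []

    def inside_faz(y: float, x: float, margin: float) -> bool:
        dy, dx = y - center[0], x - center[1]
        r_b = _boundary_radius(
            np.array([math.atan2(dy, dx)]), R_px, modes, amps, phases
        )[0]
        return math.hypot(dy, dx) < r_b + margin

    ny_nodes = int(H / spacing) + 2
    nx_nodes = int(W / spacing) + 2
    jit = spacing * 0.30
    nodes = np.empty((ny_nodes, nx_nodes, 2))
    for i in range(ny_nodes):
        for j in range(nx_nodes):
            nodes[i, j] = (
                (i - 0.5) * spacing + rng.uniform(-jit, jit),
                (j - 0.5) * spacing + rng.uniform(-jit, jit),
            )

    def draw_edge(a: np.ndarray, b: np.ndarray) -> None:
        if inside_faz(*a, 2.5) or inside_faz(*b, 2.5):
            return
        width = rng.uniform(2.0, 2.6)
        # quadratic bend: offset the midpoint perpendicular to the chord
        mid = (a + b) / 2.0
        chord = b - a
        norm = np.array([-chord[1], chord[0]])
        n_len = np.linalg.norm(norm)
        if n_len > 0:
            mid = mid + norm / n_len * rng.uniform(-0.25, 0.25) * spacing
        for t in np.linspace(0.0, 1.0, max(int(spacing), 4)):
            p = (1 - t) ** 2 * a + 2 * (1 - t) * t * mid + t**2 * b
            if inside_faz(*p, width / 2.0 + 1.0):
                continue
            pts.append((p[0], p[1]))
            wds.append(width)

    for i in range(ny_nodes):
        for j in range(nx_nodes):
            if j + 1 < nx_nodes:
                draw_edge(nodes[i, j], nodes[i, j + 1])
            if i + 1 < ny_nodes:
                draw_edge(nodes[i, j], nodes[i + 1, j])
    return pts, wds


def generate_scene(params: SceneParams) -> tuple[GrayImage, SceneTruth]:
    """Generate one synthetic angiogram and its ground truth."""
    geo = params.geometry
    H, W = geo.height_px, geo.width_px
    px, py = geo.pixel_size_mm_x, geo.pixel_size_mm_y
    rng = np.random.default_rng(params.rng_seed)
    center = np.array([H / 2.0, W / 2.0])
    R_px = params.faz_radius_mm / px
    modes, amps, phases = _boundary_coefficients(params, rng)

    # --- continuous-model truth -------------------------------------------
    area_px2, perim_px, circ = _continuous_shape_metrics(R_px, modes, amps, phases)
    faz_area_mm2 = area_px2 * geo.pixel_area_mm2
    faz_perimeter_mm = perim_px * px

    yy = np.arange(H)[:, None] - center[0]
    xx = np.arange(W)[None, :] - center[1]
    theta_px = np.arctan2(yy, xx * np.ones_like(yy))
    r_px = np.sqrt(yy**2 + xx**2)
    r_bound = _boundary_radius(theta_px, R_px, modes, amps, phases)
    faz_mask = r_px < r_bound

    # --- clean scene -------------------------------------------------------
    # terminal capillary ring: stroke whose inner edge sits on the boundary
    theta = np.linspace(0, 2 * math.pi, _N_THETA // 4, endpoint=False)
    rb = _boundary_radius(theta, R_px, modes, amps, phases) + params.vessel_width_px / 2
    pts = list(
        zip(center[0] + rb * np.sin(theta), center[1] + rb * np.cos(theta))
    )
    wds = [params.vessel_width_px] * len(pts)
    if params.n_vessel_roots > 0:
        tree_pts, tree_wds = _grow_trees(
            params, rng, center, R_px, modes, amps, phases, (H, W)
        )
        pts.extend(tree_pts)
        wds.extend(tree_wds)
    cap_pts, cap_wds = _capillary_mesh(
        params, rng, center, R_px, modes, amps, phases, (H, W)
    )
    pts.extend(cap_pts)
    wds.extend(cap_wds)
    vesselness = _render_strokes(
        (H, W), np.asarray(pts, dtype=float), np.asarray(wds, dtype=float)
    )
    for cy_mm, cx_mm, rad_mm in params.dropout_patches:
        dy = np.arange(H)[:, None] - (cy_mm / py - 0.5)
        dx = np.arange(W)[None, :] - (cx_mm / px - 0.5)
        vesselness[dy**2 + dx**2 <= (rad_mm / px) ** 2] = 0.0
    clean = BACKGROUND_LEVEL + (VESSEL_LEVEL - BACKGROUND_LEVEL) * vesselness

    # --- truth masks and VD ------------------------------------------------
    vessel_mask = vesselness >= 0.5
    bin_truth = BinaryImage(vessel_mask, geo)
    # ETDRS 1/3 mm zones, scaled down proportionally on scans under 3 mm
    outer_d = min(3.0, geo.width_mm, geo.height_mm)
    grid = build_etdrs_grid(
        geo,
        (float(center[0] - 0.5), float(center[1] - 0.5)),
        inner_diameter_mm=outer_d / 3.0,
        outer_diameter_mm=outer_d,
    )
    inv_total = find_nonperfusion(bin_truth, grid.total_mask)
    inv_para = find_nonperfusion(bin_truth, grid.parafoveal_mask)
    true_total_vd = vessel_density(bin_truth, grid.total_mask, inv_total)
    true_para_vd = vessel_density(bin_truth, grid.parafoveal_mask, inv_para)

    # --- noise -------------------------------------------------------------
    noisy = clean * (1.0 + params.speckle_strength * rng.standard_normal((H, W)))
    noisy = noisy + params.noise_sigma * rng.standard_normal((H, W))
    image = GrayImage(np.clip(noisy, 0.0, 1.0), geo, params.quality_score)

    truth = SceneTruth(
        faz_mask=faz_mask,
        faz_area_mm2=faz_area_mm2,
        faz_perimeter_mm=faz_perimeter_mm,
        faz_circularity=circ,
        vessel_mask=vessel_mask,
        true_total_vd_pct=true_total_vd,
        true_parafoveal_vd_pct=true_para_vd,
        dropout_inventory=list(inv_total.components),
        faz_center_px=(float(center[0]), float(center[1])),
    )
    return image, truth


def generate_repeatability_set(
    params: SceneParams,
    n_subjects: int,
    noise_realizations: int = 2,
    faz_radius_sd_mm: float = 0.06,
    irregularity_range: tuple[float, float] = (0.0, 0.2),
    branch_density_sd: float = 0.02,
) -> tuple[list[list[GrayImage]], list[SceneTruth], pd.DataFrame]:
    """Per-subject scenes with repeated noise realizations.

    Each subject gets its own structural parameters (FAZ radius and shape,
    branching density) drawn around ``params``; its ``noise_realizations``
    images share the structure and differ only in the noise draw, emulating
    consecutive scans of the same eye.  Setting the structural spreads to
    zero makes all subjects share one anatomy (pure-noise design).

    Returns (images_per_subject, truths, truth_table).
    """
    if n_subjects < 3:
        raise InfeasibleSceneError("need at least 3 subjects")
    master = np.random.default_rng(params.rng_seed)
    # collapsed structural spreads mean every subject shares one anatomy
    structure_varies = (
        faz_radius_sd_mm > 0
        or irregularity_range[1] > irregularity_range[0]
        or branch_density_sd > 0
    )
    images: list[list[GrayImage]] = []
    truths: list[SceneTruth] = []
    rows = []
    half = min(params.geometry.width_mm, params.geometry.height_mm) / 2.0
    for subject in range(n_subjects):
        radius = float(
            np.clip(
                params.faz_radius_mm + faz_radius_sd_mm * master.standard_normal(),
                0.08,
                0.8 * half,
            )
        )
        irr = float(master.uniform(*irregularity_range))
        bd = float(
            np.clip(params.branch_density + branch_density_sd * master.standard_normal(), 0.0, 1.0)
        )
        structural_seed = (
            int(master.integers(0, 2**31 - 1))
            if structure_varies
            else params.rng_seed
        )
        p = replace(
            params,
            faz_radius_mm=radius,
            faz_irregularity=irr,
            branch_density=bd,
            rng_seed=structural_seed,
        )
        clean_img, truth = generate_scene(
            replace(p, noise_sigma=0.0, speckle_strength=0.0)
        )
        subject_imgs = []
        for _session in range(noise_realizations):
            noise_seed = int(master.integers(0, 2**31 - 1))
            subject_imgs.append(_add_noise(clean_img, p, noise_seed))
        images.append(subject_imgs)
        truths.append(truth)
        rows.append(
            {
                "subject_id": f"S{subject:03d}",
                "faz_radius_mm": radius,
                "faz_irregularity": irr,
                "branch_density": bd,
                "true_faz_area_mm2": truth.faz_area_mm2,
                "true_faz_circularity": truth.faz_circularity,
                "true_total_vd_pct": truth.true_total_vd_pct,
                "true_parafoveal_vd_pct": truth.true_parafoveal_vd_pct,
            }
        )
    return images, truths, pd.DataFrame(rows)


def _add_noise(clean_image: GrayImage, params: SceneParams, noise_seed: int) -> GrayImage:
    """Apply the scene noise model to a clean image with its own seed."""
    rng = np.random.default_rng(noise_seed % (2**31 - 1))
    clean = clean_image.pixels
    noisy = clean * (1.0 + params.speckle_strength * rng.standard_normal(clean.shape))
    noisy = noisy + params.noise_sigma * rng.standard_normal(clean.shape)
    return GrayImage(np.clip(noisy, 0.0, 1.0), params.geometry, params.quality_score)
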