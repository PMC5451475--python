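import math

import numpy as np
import pytest
from scipy import ndimage

import oracles
from octaquant import (
    BinaryImage,
    PipelineConfig,
    ScanGeometry,
    box_counts,
    build_etdrs_grid,
    compute_all,
    find_nonperfusion,
    fractal_dimension,
    fractal_dimension_fit,
    skeleton_length,
    skeletonize_mask,
    vessel_density,
    vessel_diameter_index,
)
from octaquant.exceptions import (
    EmptyRegionError,
    GridFitError,
    InsufficientScalesError,
    ZeroSkeletonError,
)
from octaquant.vessel_metrics import SkeletonImage

MACULA = ScanGeometry.macula_3mm()
PX = 3.0 / 320


class TestEtdrsGrid:
    def test_annulus_area_matches_analytic(self):
        grid = build_etdrs_grid(MACULA, (160, 160))
        analytic = 2 * math.pi / 9 * 320**2  # pi(1.5^2-0.5^2)/9 of the scan
        assert grid.parafoveal_mask.sum() == pytest.approx(analytic, rel=0.01)

    def test_zones_disjoint_and_nested(self):
        grid = build_etdrs_grid(MACULA)
        assert not (grid.central_mask & grid.parafoveal_mask).any()
        assert ((grid.central_mask | grid.parafoveal_mask) == grid.total_mask).all()

    def test_eccentric_center_rejected(self):
        with pytest.raises(GridFitError):
            build_etdrs_grid(MACULA, (0, 0))


class TestNonPerfusion:
    def _mask_with_dark_square(self, side):
        pixels = np.ones((320, 320), dtype=bool)
        pixels[100 : 100 + side, 100 : 100 + side] = False
        return BinaryImage(pixels, MACULA)

    def test_16px_square_qualifies(self):
        mask = self._mask_with_dark_square(16)  # 256 px = 0.0225 mm^2
        inv = find_nonperfusion(mask, np.ones((320, 320), bool))
        assert len(inv.components) == 1
        assert inv.components[0][1] == 256

    def test_15px_square_below_rule(self):
        mask = self._mask_with_dark_square(15)  # 225 px = 0.0198 mm^2
        inv = find_nonperfusion(mask, np.ones((320, 320), bool))
        assert inv.components == []

    def test_all_white_mask_empty_inventory(self):
        mask = BinaryImage(np.ones((320, 320), bool), MACULA)
        inv = find_nonperfusion(mask, np.ones((320, 320), bool))
        assert inv.components == []

    def test_threshold_boundary_227_vs_228(self):
        # 227 px = 0.019951 mm^2 (below, strict rule); 228 px = 0.020039 (above)
        region = np.ones((320, 320), dtype=bool)
        for n_px, expected in [(227, 0), (228, 1)]:
            pixels = np.ones((320, 320), dtype=bool)
            dark = np.unravel_index(np.arange(n_px), (20, 20))
            pixels[dark[0] + 50, dark[1] + 50] = False
            mask = BinaryImage(pixels, MACULA)
            inv = find_nonperfusion(mask, region)
            assert len(inv.components) == expected

    def test_component_clipped_to_region_before_area_test(self):
        pixels = np.ones((320, 320), dtype=bool)
        pixels[100:120, 100:130] = False  # 600 px dark
        region = np.zeros((320, 320), dtype=bool)
        region[:, :110] = True  # only 200 px of the component inside
        mask = BinaryImage(pixels, MACULA)
        inv = find_nonperfusion(mask, region)
        assert inv.components == []  # 200 px < 228 px


class TestVesselDensity:
    def test_all_white_region_is_100(self):
        mask = BinaryImage(np.ones((320, 320), bool), MACULA)
        assert vessel_density(mask, np.ones((320, 320), bool)) == 100.0

    def test_single_qualifying_component_fraction(self):
        pixels = np.ones((320, 320), dtype=bool)
        pixels[:25, :20] = False  # 500 px dark, qualifies
        region = np.zeros((320, 320), dtype=bool)
        region.ravel()[:10000] = True
        mask = BinaryImage(pixels, MACULA)
        assert vessel_density(mask, region) == pytest.approx(95.0)

    def test_all_black_region_is_0(self):
        mask = BinaryImage(np.zeros((320, 320), bool), MACULA)
        assert vessel_density(mask, np.ones((320, 320), bool)) == 0.0

    def test_empty_region_raises(self):
        mask = BinaryImage(np.ones((320, 320), bool), MACULA)
        with pytest.raises(EmptyRegionError):
            vessel_density(mask, np.zeros((320, 320), bool))

    def test_adding_dark_patch_never_increases_vd(self, rng):
        pixels = np.ones((320, 320), dtype=bool)
        region = np.ones((320, 320), bool)
        vd_prev = vessel_density(BinaryImage(pixels, MACULA), region)
        for k in range(4):
            r0, c0 = 40 + 70 * k, 40 + 60 * k
            pixels[r0 : r0 + 17, c0 : c0 + 17] = False
            vd = vessel_density(BinaryImage(pixels, MACULA), region)
            assert vd <= vd_prev
            vd_prev = vd


class TestSkeleton:
    def test_wide_bar_thins_to_single_row(self):
        pixels = np.zeros((320, 320), dtype=bool)
        pixels[100:105, :] = True
        sk = skeletonize_mask(BinaryImage(pixels, MACULA))
        cols = sk.pixels[:, 10:-10]
        assert (cols.sum(axis=0) == 1).all()

    def test_empty_mask_empty_skeleton(self):
        sk = skeletonize_mask(BinaryImage(np.zeros((320, 320), bool), MACULA))
        assert not sk.pixels.any()

    def test_topology_and_thinness_on_random_blobs(self, rng):
        geo = ScanGeometry(1.0, 1.0, 128, 128)
        eight = np.ones((3, 3))
        for _ in range(20):
            blob = ndimage.gaussian_filter(rng.random((128, 128)), 4) > 0.55
            sk = skeletonize_mask(BinaryImage(blob, geo))
            assert sk.pixels[blob | ~blob].shape  # same frame
            assert not (sk.pixels & ~blob).any()  # skeleton subset of mask
            n_before = ndimage.label(blob, structure=eight)[1]
            n_after = ndimage.label(sk.pixels, structure=eight)[1]
            assert n_before == n_after
            # one pixel wide: no 2x2 block survives thinning
            s = sk.pixels
            assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()


class TestSkeletonLength:
    def test_horizontal_line_link_count(self):
        pixels = np.zeros((320, 320), dtype=bool)
        pixels[160, :] = True
        sk = SkeletonImage(pixels, MACULA)
        assert skeleton_length(sk) == pytest.approx(319 * PX, abs=1e-12)

    def test_isolated_pixel_zero_length(self):
        pixels = np.zeros((320, 320), dtype=bool)
        pixels[10, 10] = True
        assert skeleton_length(SkeletonImage(pixels, MACULA)) == 0.0

    def test_diagonal_line(self):
        pixels = np.zeros((320, 320), dtype=bool)
        idx = np.arange(100)
        pixels[idx, idx] = True
        sk = SkeletonImage(pixels, MACULA)
        assert skeleton_length(sk) == pytest.approx(99 * math.sqrt(2) * PX, abs=1e-12)


class TestFractalDimension:
    def test_line_has_dimension_one(self):
        geo = ScanGeometry(1.0, 1.0, 256, 256)
        pixels = np.zeros((256, 256), dtype=bool)
        pixels[128, :] = True
        assert fractal_dimension(SkeletonImage(pixels, geo)) == pytest.approx(1.0, abs=0.05)

    def test_plane_has_dimension_two(self):
        geo = ScanGeometry(1.0, 1.0, 256, 256)
        pixels = np.ones((256, 256), dtype=bool)
        assert fractal_dimension(SkeletonImage(pixels, geo)) == pytest.approx(2.0, abs=0.05)

    def test_box_counts_match_bruteforce(self, rng):
        pixels = rng.random((16, 16)) < 0.2
        pixels[3, 7] = True
        sizes = [2, 4, 8]
        ours = box_counts(pixels, sizes)
        assert ours == [oracles.box_count_bruteforce(pixels, s) for s in sizes]

    def test_counts_non_increasing_and_fit_quality(self, rng):
        geo = ScanGeometry(1.0, 1.0, 256, 256)
        for maker in (
            lambda: np.eye(256, dtype=bool),
            lambda: np.ones((256, 256), dtype=bool),
        ):
            fd, r2, sizes, counts = fractal_dimension_fit(maker())
            assert all(a >= b for a, b in zip(counts, counts[1:]))
            assert r2 > 0.95

    def test_too_small_image_rejected(self):
        with pytest.raises(InsufficientScalesError):
            fractal_dimension_fit(np.ones((16, 16), dtype=bool))


class TestVdi:
    def _bar_mask(self, width):
        pixels = np.zeros((320, 320), dtype=bool)
        pixels[160 - width // 2 : 160 - width // 2 + width, :] = True
        return BinaryImage(pixels, MACULA)

    def test_bar_recovers_width(self):
        mask = self._bar_mask(5)
        sk = skeletonize_mask(mask)
        vdi = vessel_diameter_index(mask, sk)
        assert vdi == pytest.approx(5 * PX, abs=PX)

    def test_vdi_linear_in_width(self):
        vdis = []
        for w in (5, 10):
            mask = self._bar_mask(w)
            vdis.append(vessel_diameter_index(mask, skeletonize_mask(mask)))
        assert vdis[1] == pytest.approx(2 * vdis[0], rel=0.1)

    def test_dilation_increases_vdi_by_two_pixels(self):
        mask = self._bar_mask(5)
        vdi0 = vessel_diameter_index(mask, skeletonize_mask(mask))
        dilated = BinaryImage(
            ndimage.binary_dilation(mask.pixels, np.ones((3, 3))), MACULA
        )
        vdi1 = vessel_diameter_index(dilated, skeletonize_mask(dilated))
        assert vdi1 - vdi0 == pytest.approx(2 * PX, abs=0.5 * PX)

    def test_empty_mask_raises(self):
        mask = BinaryImage(np.zeros((320, 320), bool), MACULA)
        sk = skeletonize_mask(mask)
        with pytest.raises(ZeroSkeletonError):
            vessel_diameter_index(mask, sk)


class TestComputeAll:
    def test_full_record_on_synthetic_scene(self, noisy_result):
        rec = noisy_result.record
        assert rec.qc_pass
        for field in (
            "faz_area_mm2",
            "faz_circularity",
            "total_vd_pct",
            "parafoveal_vd_pct",
            "fractal_dimension",
            "vdi_mm",
        ):
            assert getattr(rec, field) is not None
        assert 0 <= rec.total_vd_pct <= 100
        assert 0.9 <= rec.fractal_dimension <= 2.1
        assert rec.vdi_mm >= PX

    def test_deterministic_rerun(self, noisy_scene, noisy_result):
        _, image, _ = noisy_scene
        rec2 = compute_all(image, image_id="noisy")
        assert rec2 == noisy_result.record

    def test_qc_gated_scan_yields_missing_metrics(self, noisy_scene):
        from octaquant import GrayImage

        params, image, _ = noisy_scene
        low_q = GrayImage(image.pixels, image.geometry, quality_score=10)
        rec = compute_all(low_q, image_id="lowq")
        assert rec.qc_pass is False
        assert rec.faz_area_mm2 is None
        forced = compute_all(low_q, PipelineConfig(force=True), image_id="lowq")
        assert forced.qc_pass is False
        assert forced.faz_area_mm2 is not None
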