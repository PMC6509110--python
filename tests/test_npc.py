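import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import sheetloc as sl
from sheetloc.npc import BinnedImage, NpcParams, suggested_area_bounds


def ring_events(r0=50.0, sigma=15.0, n=400, center=(0.0, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    th = rng.uniform(0, 2 * np.pi, n)
    x = center[0] + r0 * np.cos(th) + rng.normal(0, sigma, n)
    y = center[1] + r0 * np.sin(th) + rng.normal(0, sigma, n)
    return np.column_stack([x, y])


def render_donut(shape, cx, cy, r0, sr, amp, pixel=10.0, offset=0.0):
    y, x = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot((x + 0.5) * pixel - cx, (y + 0.5) * pixel - cy)
    return amp * np.exp(-((r - r0) ** 2) / (2 * sr**2)) + offset


def npc_table(diameter=100.0, precision=15.0, n_pores=100, seed=0, n_frames=3000):
    pores = sl.make_ground_truth(
        "npc_ring",
        {"n_pores": n_pores, "ring_diameter_nm": diameter, "sites_per_ring": 8,
         "labeling_efficiency": 0.8, "extent_nm": (20000, 20000)},
        seed,
    )
    blink = sl.BlinkingModel(k_on=0.5, k_off=50.0)
    return sl.simulate_localizations(pores, blink, n_frames, 0.02, precision, seed=seed + 100)


class TestBinning:
    def test_single_point(self):
        binned = sl.bin_pointcloud(np.array([[123.0, 456.0]]), 10.0)
        assert binned.counts.sum() == 1
        assert binned.counts.shape == (1, 1)
        assert binned.origin_px == (12, 45)

    def test_matches_floor_division_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-500, 2000, (1000, 2))
        binned = sl.bin_pointcloud(pts, 10.0)
        assert binned.counts.sum() == 1000
        for x, y in pts[::37]:
            ix = int(np.floor(x / 10.0)) - binned.origin_px[0]
            iy = int(np.floor(y / 10.0)) - binned.origin_px[1]
            explicit = sum(
                1
                for (px, py) in pts
                if int(np.floor(px / 10.0)) - binned.origin_px[0] == ix
                and int(np.floor(py / 10.0)) - binned.origin_px[1] == iy
            )
            assert binned.counts[iy, ix] == explicit

    def test_empty_input(self):
        binned = sl.bin_pointcloud(np.empty((0, 2)), 10.0)
        assert binned.counts.size == 0


class TestCandidateSelection:
    def test_empty_image_no_candidates(self):
        binned = sl.bin_pointcloud(np.empty((0, 2)), 10.0)
        assert sl.select_candidates(binned) == []

    def test_constructed_cluster_selected(self):
        # dense ring whose filled+dilated footprint lands inside [250, 300];
        # distant sentinels give the image a field so the 32x32 crop fits
        pts = np.vstack([
            ring_events(r0=50.0, sigma=15.0, n=2000, center=(1000.0, 1000.0), seed=2),
            [[0.0, 0.0], [2000.0, 2000.0]],
        ])
        binned = sl.bin_pointcloud(pts, 10.0)
        # verify the oracle area (largest component) by direct pixel count
        mask = ndimage.binary_fill_holes(binned.counts > 0)
        mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        area = int(max((labels == lab).sum() for lab in range(1, n + 1)))
        cands = sl.select_candidates(binned, NpcParams(area_bounds_px=(area - 1, area + 1)))
        assert len(cands) == 1
        assert cands[0].area_px == area
        assert np.hypot(cands[0].centroid_nm[0] - 1000.0, cands[0].centroid_nm[1] - 1000.0) < 15.0

    def test_area_window_rejects_small_and_large(self):
        small = ring_events(r0=30.0, sigma=5.0, n=300, center=(800.0, 800.0), seed=3)
        large = ring_events(r0=120.0, sigma=30.0, n=3000, center=(3000.0, 3000.0), seed=4)
        binned = sl.bin_pointcloud(np.vstack([small, large]), 10.0)
        mask = ndimage.binary_fill_holes(binned.counts > 0)
        mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        assert (areas < 250).any() and (areas > 300).any()  # construction holds
        assert sl.select_candidates(binned, NpcParams(area_bounds_px=(250, 300))) == []

    def test_matches_brute_force_component_oracle(self):
        # random blob masks: survivor count equals a naive component counter
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = []
            for _ in range(6):
                c = rng.uniform(500, 4500, 2)
                pts.append(ring_events(r0=rng.uniform(30, 80), sigma=rng.uniform(8, 25),
                                       n=rng.integers(100, 1500), center=c, seed=rng.integers(1e6)))
            binned = sl.bin_pointcloud(np.vstack(pts), 10.0)
            params = NpcParams(area_bounds_px=(250, 300), roi_size_px=32)
            mask = ndimage.binary_fill_holes(binned.counts > 0)
            mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
            labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
            ny, nx = binned.counts.shape
            expected = 0
            for lab in range(1, n + 1):
                area = int((labels == lab).sum())
                if 250 <= area <= 300:
                    cy, cx = ndimage.center_of_mass(labels == lab)
                    icx, icy = int(round(cx)), int(round(cy))
                    if 16 <= icx <= nx - 16 and 16 <= icy <= ny - 16:
                        expected += 1
            assert len(sl.select_candidates(binned, params)) == expected

    def test_permutation_invariance(self):
        pts = np.vstack([
            ring_events(n=1500, center=(1000, 1000), seed=5),
            [[0.0, 0.0], [2000.0, 2000.0]],
        ])
        rng = np.random.default_rng(6)
        shuffled = pts[rng.permutation(len(pts))]
        p = NpcParams(area_bounds_px=(50, 10**6))
        a = sl.select_candidates(sl.bin_pointcloud(pts, 10.0), p)
        b = sl.select_candidates(sl.bin_pointcloud(shuffled, 10.0), p)
        assert len(a) == len(b) == 1
        assert a[0].centroid_nm == b[0].centroid_nm
        assert np.array_equal(a[0].crop, b[0].crop)


class TestDonutFit:
    def test_noise_free_recovery(self):
        img = render_donut((32, 32), 160.0, 160.0, 50.0, 15.0, 100.0)
        fit = sl.fit_donut(img, 10.0)
        assert fit.success
        assert fit.ring_radius_nm == pytest.approx(50.0, abs=0.1)
        assert fit.ring_width_nm == pytest.approx(15.0, abs=0.1)
        assert fit.rss < 1e-6 * (img**2).sum()

    def test_poisson_noise_small_bias(self):
        rng = np.random.default_rng(7)
        r0s = []
        for _ in range(100):
            img = rng.poisson(render_donut((32, 32), 160.0, 160.0, 50.0, 15.0, 20.0))
            fit = sl.fit_donut(img, 10.0)
            if fit.success:
                r0s.append(fit.ring_radius_nm)
        assert abs(np.mean(r0s) - 50.0) / 50.0 < 0.02

    def test_flat_crop_fails(self):
        assert not sl.fit_donut(np.ones((32, 32)), 10.0).success
        assert not sl.fit_donut(np.zeros((32, 32)), 10.0).success


class TestKdeCenter:
    def test_single_event_fallback(self):
        x, y, fallback = sl.kde_center(np.array([[12.0, 34.0]]))
        assert (x, y) == (12.0, 34.0)
        assert fallback

    def test_symmetric_set_centered(self):
        base = ring_events(n=100, seed=8)
        sym = np.vstack([base + [200.0, 300.0], -base + [200.0, 300.0]])
        x, y, fallback = sl.kde_center(sym, kde_grid_nm=2.0)
        assert not fallback
        assert x == pytest.approx(200.0, abs=2.0)
        assert y == pytest.approx(300.0, abs=2.0)

    def test_gaussian_cloud_matches_mean(self):
        rng = np.random.default_rng(9)
        pts = rng.normal([100.0, 150.0], 20.0, (200, 2))
        x, y, _ = sl.kde_center(pts)
        se = 20.0 / np.sqrt(200)
        assert abs(x - pts[:, 0].mean()) < 2 * se
        assert abs(y - pts[:, 1].mean()) < 2 * se


class TestOverlayAndDiameter:
    def test_single_candidate_overlay_is_centered_crop(self):
        img = render_donut((32, 32), 160.0, 160.0, 50.0, 15.0, 100.0)
        cand = sl.npc.Candidate((160.0, 160.0), 270, img, (0, 0))
        fit = sl.fit_donut(img, 10.0)
        overlay = sl.overlay_average([cand], [fit], centers_nm=[(160.0, 160.0)], n_top=50)
        assert np.allclose(overlay, img, atol=1e-9)

    def test_identical_crops_with_known_shifts(self):
        base = render_donut((32, 32), 160.0, 160.0, 50.0, 15.0, 100.0)
        shifts = [(0, 0), (2, -1), (-3, 2)]
        cands, fits, centers = [], [], []
        for sx, sy in shifts:
            crop = np.roll(np.roll(base, sy, axis=0), sx, axis=1)
            cands.append(sl.npc.Candidate((0.0, 0.0), 270, crop, (0, 0)))
            fits.append(sl.fit_donut(crop, 10.0))
            centers.append((160.0 + sx * 10.0, 160.0 + sy * 10.0))
        overlay = sl.overlay_average(cands, fits, centers_nm=centers, n_top=3)
        inner = (slice(4, 28), slice(4, 28))
        assert np.allclose(overlay[inner], 3 * base[inner], atol=1e-6 * base.max())

    def test_diameter_of_perfect_donut(self):
        img = render_donut((32, 32), 160.0, 160.0, 50.0, 12.0, 80.0)
        assert sl.estimate_diameter(img, 10.0) == pytest.approx(100.0, abs=0.2)

    @pytest.mark.parametrize("diameter", [100.0, 120.0])
    def test_full_pipeline_recovers_generator_diameter(self, diameter):
        precision = 15.0
        diams = []
        for seed in range(3):
            tab = npc_table(diameter=diameter, precision=precision, seed=seed)
            params = NpcParams(area_bounds_px=suggested_area_bounds(diameter, precision))
            result = sl.average_pipeline(tab, params)
            assert len(result["candidates"]) >= 5
            diams.append(result["diameter_nm"])
        assert abs(np.median(diams) - diameter) <= 10.0

    def test_diameter_scale_equivariance(self):
        tab = npc_table(diameter=100.0, precision=15.0, seed=11, n_frames=2000)
        params = NpcParams(area_bounds_px=suggested_area_bounds(100.0, 15.0))
        d1 = sl.average_pipeline(tab, params)["diameter_nm"]
        scaled = tab.assign(x_nm=tab["x_nm"] * 1.2, y_nm=tab["y_nm"] * 1.2)
        params_scaled = NpcParams(area_bounds_px=suggested_area_bounds(120.0, 18.0))
        d2 = sl.average_pipeline(scaled, params_scaled)["diameter_nm"]
        assert d2 / d1 == pytest.approx(1.2, rel=0.05)
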