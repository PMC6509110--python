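import numpy as np
import pandas as pd
import pytest

import sheetloc as sl


def fiducial_table(n_fid=3, n_frames=1000, precision=10.0, drift=(0.0, 0.0, 0.0), seed=0):
    fid = sl.make_ground_truth("fiducial", {"n": n_fid, "extent_nm": (8000, 8000)}, seed)
    return sl.simulate_localizations(
        fid, sl.BlinkingModel(), n_frames, 0.02, precision, seed=seed + 50,
        drift_per_frame_nm=drift,
    )


def filament_table(n_frames=2000, precision=20.0, drift=(0.0, 0.0, 0.0), seed=0,
                   density=150.0, k_on=1.0):
    fil = sl.make_ground_truth(
        "filament",
        {"polylines": [
            [[1000, 1000, 0], [7000, 2000, 0]],
            [[1500, 6000, 0], [6500, 3500, 0]],
            [[2000, 1500, 0], [3000, 7000, 0]],
        ], "density_per_um": density},
        seed,
    )
    blink = sl.BlinkingModel(k_on=k_on, k_off=50.0)
    return sl.simulate_localizations(fil, blink, n_frames, 0.02, precision, seed=seed + 60,
                                     drift_per_frame_nm=drift)


class TestFiducialTracking:
    def test_static_noise_free_gives_zero_trace(self):
        tab = fiducial_table(precision=1e-6)
        trace = sl.track_fiducials(tab)
        assert np.allclose(trace.dx, 0.0, atol=1e-3)
        assert np.allclose(trace.dy, 0.0, atol=1e-3)

    def test_linear_drift_slope_recovered(self):
        tab = fiducial_table(n_frames=2000, drift=(0.5, 0.0, 0.0), seed=1)
        trace = sl.track_fiducials(tab)
        slope = np.polyfit(trace.frames, trace.dx, 1)[0]
        assert slope == pytest.approx(0.5, rel=0.05)

    def test_residual_scatter_reports_precision(self):
        # corrected-track scatter is the achieved localization precision
        tab = fiducial_table(n_fid=4, n_frames=3000, precision=40.0, seed=2)
        trace = sl.track_fiducials(tab)
        assert trace.residual_std_nm["x"] == pytest.approx(40.0, abs=2.0)
        assert trace.residual_std_nm["y"] == pytest.approx(40.0, abs=2.0)

    def test_no_fiducials_raises(self):
        tab = filament_table(n_frames=200, k_on=0.2)
        with pytest.raises(ValueError, match="no fiducials"):
            sl.track_fiducials(tab, seed_positions=np.empty((0, 2)))


class TestXcorrDrift:
    def test_identical_blocks_zero_shift(self):
        tab = filament_table(n_frames=500)
        doubled = pd.concat(
            [tab, tab.assign(frame=tab["frame"] + 500)], ignore_index=True
        )
        trace = sl.estimate_drift_xcorr(doubled, block_frames=500, render_pixel_nm=10.0)
        assert abs(trace.dx[1]) < 1e-9
        assert abs(trace.dy[1]) < 1e-9

    def test_known_shift_recovered(self):
        tab = filament_table(n_frames=500, seed=3)
        shifted = tab.assign(frame=tab["frame"] + 500, x_nm=tab["x_nm"] + 30.0)
        both = pd.concat([tab, shifted], ignore_index=True)
        trace = sl.estimate_drift_xcorr(both, block_frames=500, render_pixel_nm=10.0)
        assert trace.dx[1] == pytest.approx(30.0, abs=5.0)  # render_pixel/2

    def test_agrees_with_fiducial_tracking(self):
        # same drifted acquisition carries both filaments and fiducials
        drift = (0.4, 0.25, 0.0)
        fil = filament_table(n_frames=2000, drift=drift, seed=4)
        fid = fiducial_table(n_fid=3, n_frames=2000, drift=drift, seed=5)
        both = pd.concat([fil, fid], ignore_index=True).sort_values("frame")
        t_fid = sl.track_fiducials(fid)
        t_x = sl.estimate_drift_xcorr(both, block_frames=250, render_pixel_nm=10.0)
        fx = np.interp(t_x.frames, t_fid.frames, t_fid.dx)
        fy = np.interp(t_x.frames, t_fid.frames, t_fid.dy)
        rms = np.sqrt(np.mean((t_x.dx - (fx - fx[0])) ** 2 + (t_x.dy - (fy - fy[0])) ** 2))
        assert rms < 10.0

    def test_drift_correction_improves_fiducial_scatter(self):
        improved = 0
        for seed in range(20):
            tab = fiducial_table(n_fid=2, n_frames=600, precision=10.0,
                                 drift=(0.5, 0.3, 0.0), seed=seed)
            trace = sl.track_fiducials(tab)
            corr = sl.apply_drift(tab, trace)
            for fid_id in tab["emitter_id"].unique():
                raw_std = tab.loc[tab["emitter_id"] == fid_id, "x_nm"].std()
                cor_std = corr.loc[corr["emitter_id"] == fid_id, "x_nm"].std()
                improved += cor_std < raw_std
        assert improved == 2 * 20  # strict improvement for every fiducial/seed


class TestApplyDrift:
    def test_zero_trace_is_identity(self):
        tab = fiducial_table()
        trace = sl.DriftTrace(np.arange(0, 1000), np.zeros(1000), np.zeros(1000),
                              np.zeros(1000), "fiducial")
        assert np.allclose(sl.apply_drift(tab, trace)["x_nm"], tab["x_nm"])

    def test_apply_then_invert_round_trips(self):
        tab = fiducial_table()
        rng = np.random.default_rng(0)
        trace = sl.DriftTrace(np.arange(0, 1000), rng.normal(0, 5, 1000),
                              rng.normal(0, 5, 1000), rng.normal(0, 5, 1000), "fiducial")
        back = sl.apply_drift(sl.apply_drift(tab, trace), trace.negated())
        assert np.allclose(back["x_nm"], tab["x_nm"], atol=1e-9)
        assert np.allclose(back["z_nm"], tab["z_nm"], atol=1e-9)


class TestDeskew:
    def make_table(self):
        return pd.DataFrame(
            {
                "plane": [0, 0, 3, 7],
                "frame": [0, 0, 3, 7],
                "x_nm": [1000.0, 2500.0, 400.0, -300.0],
                "y_nm": [0.0, 500.0, 800.0, 1200.0],
                "z_nm": [0.0, 150.0, -200.0, 90.0],
            }
        )

    def test_hand_computed_point(self):
        tab = pd.DataFrame({"plane": [0], "frame": [0], "x_nm": [1000.0],
                            "y_nm": [0.0], "z_nm": [0.0]})
        out = sl.deskew(tab, 32.5, 316.0)
        assert out["Z_nm"][0] == pytest.approx(537.3, abs=0.05)
        assert out["X_nm"][0] == pytest.approx(843.4, abs=0.05)

    def test_near_orthogonal_sheet_limit(self):
        tab = self.make_table()
        out = sl.deskew(tab, 89.9999, 316.0)
        assert np.allclose(out["Z_nm"], tab["x_nm"], atol=0.01)
        assert np.allclose(out["X_nm"], tab["plane"] * 316.0 - tab["z_nm"], atol=0.01)

    def test_inverse_round_trip(self):
        tab = self.make_table()
        out = sl.deskew(tab, 32.5, 316.0)
        back = sl.deskew_inverse(out, 32.5, 316.0)
        for col in ("x_nm", "y_nm", "z_nm"):
            assert np.allclose(back[col], tab[col], atol=1e-9)

    def test_is_isometry_within_plane(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "plane": np.zeros(20, dtype=int), "frame": np.zeros(20, dtype=int),
            "x_nm": rng.uniform(0, 5000, 20), "y_nm": rng.uniform(0, 5000, 20),
            "z_nm": rng.uniform(-400, 400, 20),
        })
        out = sl.deskew(tab, 32.5, 316.0)
        p_in = tab[["x_nm", "y_nm", "z_nm"]].to_numpy()
        p_out = out[["X_nm", "Y_nm", "Z_nm"]].to_numpy()
        d_in = np.linalg.norm(p_in[:, None] - p_in[None, :], axis=-1)
        d_out = np.linalg.norm(p_out[:, None] - p_out[None, :], axis=-1)
        assert np.allclose(d_out, d_in, rtol=1e-9)

    def test_bad_angle_rejected(self):
        with pytest.raises(ValueError):
            sl.deskew(self.make_table(), 90.0, 316.0)


class TestTranspose:
    def test_exhaustive_index_bookkeeping(self):
        arr = np.arange(3 * 4 * 5 * 6).reshape(3, 4, 5, 6)
        out = sl.transpose_to_time_series(arr)
        assert out.shape == (4, 3, 5, 6)
        for v in range(3):
            for p in range(4):
                assert np.array_equal(out[p, v], arr[v, p])

    def test_involution(self):
        arr = np.arange(2 * 3 * 4 * 5).reshape(2, 3, 4, 5)
        assert np.array_equal(sl.transpose_to_time_series(sl.transpose_to_time_series(arr)), arr)

    def test_single_plane(self):
        arr = np.arange(7 * 1 * 4 * 4).reshape(7, 1, 4, 4)
        out = sl.transpose_to_time_series(arr)
        assert out.shape == (1, 7, 4, 4)
        assert np.array_equal(out[0], arr[:, 0])


class TestRendering:
    def one_event(self, unc=20.0):
        return pd.DataFrame({"frame": [0], "x_nm": [500.0], "y_nm": [500.0],
                             "uncertainty_xy_nm": [unc]})

    def test_single_event_sums_to_one(self):
        img = sl.render_density(self.one_event(), pixel_nm=10.0)
        assert img.sum() == pytest.approx(1.0, abs=1e-6)

    def test_weight_conserved_at_any_pixel_size(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({
            "frame": np.zeros(50, dtype=int),
            "x_nm": rng.uniform(500, 1500, 50), "y_nm": rng.uniform(500, 1500, 50),
            "uncertainty_xy_nm": rng.uniform(5, 40, 50),
        })
        for pixel in (5.0, 17.0, 50.0):
            img = sl.render_density(tab, pixel_nm=pixel)
            assert img.sum() == pytest.approx(50.0, rel=1e-6)

    def test_two_events_resolved(self):
        tab = pd.DataFrame({"frame": [0, 0], "x_nm": [500.0, 700.0],
                            "y_nm": [500.0, 500.0], "uncertainty_xy_nm": [40.0, 40.0]})
        img = sl.render_density(tab, pixel_nm=10.0)
        row = img[img.sum(axis=1).argmax()]
        peaks = np.nonzero((row[1:-1] > row[:-2]) & (row[1:-1] > row[2:]) & (row[1:-1] > 1e-5))[0]
        assert len(peaks) == 2

    def test_per_event_sigma_matches_uncertainty(self):
        # event rendered with sigma = its uncertainty: compare against an
        # explicit Gaussian of that width
        pixel = 5.0
        img = sl.render_density(self.one_event(unc=20.0), pixel_nm=pixel)
        xs = np.arange(img.shape[1]) * pixel
        wx = img.sum(axis=0)
        mean = (wx * xs).sum() / wx.sum()
        var = (wx * (xs - mean) ** 2).sum() / wx.sum()
        sigma = np.sqrt(var - pixel**2 / 12.0)  # remove pixel-integration variance
        assert sigma == pytest.approx(20.0, rel=0.01)

    def test_3d_histogram_mode(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({
            "frame": np.zeros(200, dtype=int),
            "x_nm": rng.uniform(0, 1000, 200), "y_nm": rng.uniform(0, 1000, 200),
            "z_nm": rng.uniform(-200, 200, 200),
        })
        vol = sl.render_density(tab, pixel_nm=50.0, mode="3d")
        assert vol.sum() == pytest.approx(200.0)
        smoothed = sl.render_density(tab, pixel_nm=50.0, mode="3d", smooth_sigma_nm=50.0)
        assert smoothed.sum() == pytest.approx(200.0, rel=0.05)


class TestTemporalRendering:
    def test_bin_count_and_partition(self):
        tab = filament_table(n_frames=1000, seed=6)
        tab["frame"] = tab["frame"] * 10  # spread over 10000 frames
        rgb, subs = sl.render_temporal(tab, frames_per_bin=2000, pixel_nm=50.0,
                                       sigma_source="fixed", fixed_sigma_nm=30.0)
        assert len(subs) == 5
        assert sum(len(s) for s in subs) == len(tab)
        assert rgb.dtype == np.uint8 and rgb.shape[2] == 3

    def test_single_bin_is_identity_partition(self):
        tab = filament_table(n_frames=200, seed=7)
        _, subs = sl.render_temporal(tab, frames_per_bin=10**6, pixel_nm=50.0,
                                     sigma_source="fixed", fixed_sigma_nm=30.0)
        assert len(subs) == 1
        assert subs[0].equals(tab)

    def test_per_bin_density_maps_sum_to_total(self):
        tab = filament_table(n_frames=600, seed=8)
        pad = 3 * 50.0
        extent = ((tab["x_nm"].min() - pad, tab["x_nm"].max() + pad),
                  (tab["y_nm"].min() - pad, tab["y_nm"].max() + pad))
        full = sl.render_density(tab, 50.0, sigma_source="fixed", fixed_sigma_nm=30.0,
                                 extent_nm=extent)
        _, subs = sl.render_temporal(tab, frames_per_bin=200, pixel_nm=50.0,
                                     sigma_source="fixed", fixed_sigma_nm=30.0)
        parts = [
            sl.render_density(s, 50.0, sigma_source="fixed", fixed_sigma_nm=30.0,
                              extent_nm=extent)
            for s in subs
        ]
        assert np.allclose(np.sum(parts, axis=0), full, atol=1e-9)
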