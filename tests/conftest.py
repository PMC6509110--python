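import numpy as np
import pytest

import sheetloc as sl


@pytest.fixture(scope="session")
def paper_beam():
    """The reference annular-pupil excitation beam (637 nm, NA 0.42/0.50)."""
    return sl.BesselBeamSpec(637.0, 0.42, 0.50)


@pytest.fixture(scope="session")
def calib():
    """Representative astigmatic calibration (foci at +/-250 nm, depth 400 nm)."""
    return sl.default_calibration()


@pytest.fixture(scope="session")
def camera():
    """Unit-QE camera so photon bookkeeping is exact in tests."""
    return sl.CameraModel(qe=1.0)


def sheet_frame_positions(uvwp, sheet_angle_deg=32.5, scan_step_nm=316.0):
    """Sample-frame positions of emitters given their sheet-frame (u, v, w, p)."""
    th = np.deg2rad(sheet_angle_deg)
    ct, st = np.cos(th), np.sin(th)
    return np.array(
        [[p * scan_step_nm + u * ct - w * st, v, u * st + w * ct] for u, v, w, p in uvwp]
    )


@pytest.fixture(scope="session")
def on_sheet_grid(calib, camera):
    """3x3 grid of always-on emitters lying exactly on the sheet plane (w=0)."""
    geom = sl.AcquisitionGeometry(n_planes=1, img_shape=(64, 64))
    rng = np.random.default_rng(42)
    us = np.linspace(1000, 5500, 3)
    uvwp = [(u + rng.uniform(-50, 50), v + rng.uniform(-50, 50), 0.0, 0) for u in us for v in us]
    pos = sheet_frame_positions(uvwp, geom.sheet_angle_deg, geom.scan_step_nm)
    truth = sl.EmitterSet(pos, np.arange(len(pos)), "fiducial", always_on=True)
    return truth, geom
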