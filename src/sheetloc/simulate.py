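"""Synthetic acquisition generator for the Bessel-lightsheet localization scope.

Produces seeded camera stacks plus ground-truth event tables with the
statistical structure the analysis pipeline assumes:

* emitters attached to filaments, nuclear-pore rings, or fiducial beads;
* two-state spontaneous blinking (off <-> on, plus absorbing bleached), the
  thermal-equilibrium switching of spontaneously blinking dyes such as HMSiR;
* sheet-weighted excitation at the 32.5 deg sample-scan geometry, by default a
  Gaussian sheet with the Bessel central-lobe FWHM and optional side-lobe
  replicas;
* an astigmatic detection PSF whose widths come from an
  :class:`~sheetloc.calibration.AstigCalibration`;
* sCMOS shot + read noise at 102 nm pixels.

Coordinates: emitters live in the coverslip ("sample") frame (X, Y, Z) in nm.
For scan plane ``p`` (scan step ``s``, sheet angle ``theta``) the sheet-frame
coordinates are

    u = (X - p*s) cos(theta) + Z sin(theta)      (camera x, tilt direction)
    v = Y                                        (camera y)
    w = -(X - p*s) sin(theta) + Z cos(theta)     (sheet-normal; astigmatic z)

which is the exact inverse of the deskew transform in
:mod:`sheetloc.postprocess`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .calibration import AstigCalibration, defocus_sigma

__all__ = [
    "EmitterSet",
    "BlinkingModel",
    "CameraModel",
    "AcquisitionGeometry",
    "make_ground_truth",
    "simulate_blinking_trace",
    "simulate_stack",
    "simulate_series",
    "simulate_localizations",
    "sheet_weight",
]

STATE_OFF, STATE_ON, STATE_BLEACHED = 0, 1, 2

# events excited below this relative sheet weight are not recorded as truth
MIN_TRUTH_WEIGHT = 1e-3


@dataclass(frozen=True)
class EmitterSet:
    """Ground-truth emitters in the sample frame.

    positions: (n, 3) array of (X, Y, Z) nm; structure_id maps each emitter to
    exactly one structure; always_on marks fiducial-like emitters that never
    blink or bleach.
    """

    positions: np.ndarray
    structure_id: np.ndarray
    structure_kind: str
    always_on: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size and (pos.ndim != 2 or pos.shape[1] != 3):
            raise ValueError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if len(self.structure_id) != len(pos):
            raise ValueError("structure_id must label every emitter")
        object.__setattr__(self, "positions", pos.reshape(-1, 3))
        object.__setattr__(self, "structure_id", np.asarray(self.structure_id, dtype=int))

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def concatenate(sets: list["EmitterSet"]) -> "EmitterSet":
        """Merge emitter sets, renumbering structures to stay disjoint."""
        pos, sid, offset = [], [], 0
        for s in sets:
            pos.append(s.positions)
            sid.append(s.structure_id + offset)
            if len(s.structure_id):
                offset += s.structure_id.max() + 1
        kind = "+".join(dict.fromkeys(s.structure_kind for s in sets))
        return EmitterSet(
            np.concatenate(pos) if pos else np.empty((0, 3)),
            np.concatenate(sid) if sid else np.empty(0, int),
            kind,
            always_on=all(s.always_on for s in sets) and bool(sets),
        )


@dataclass(frozen=True)
class BlinkingModel:
    """Two-state blinking kinetics with an absorbing bleached state.

    Rates are continuous-time (1/s); the duty cycle (stationary on-fraction
    with no bleaching) is ``k_on / (k_on + k_off)``.  Photon output per
    on-frame is Gamma-distributed with mean ``photons_per_frame_mean`` and
    coefficient of variation ``photon_dispersion`` (0 = deterministic).
    """

    k_on: float = 0.25  # off -> on (1/s)
    k_off: float = 50.0  # on -> off (1/s); duty cycle 5e-3
    k_bleach: float = 0.0  # on -> bleached (1/s)
    photons_per_frame_mean: float = 1000.0
    photon_dispersion: float = 0.3

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.k_bleach) < 0:
            raise ValueError("rates must be non-negative")
        if self.photons_per_frame_mean <= 0:
            raise ValueError("photons_per_frame_mean must be positive")

    @property
    def duty_cycle(self) -> float:
        if self.k_on + self.k_off == 0:
            return 0.0
        return self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class CameraModel:
    """sCMOS camera in the image plane (102 nm effective pixel by default)."""

    pixel_size_nm: float = 102.0
    gain: float = 2.0  # counts / photoelectron
    offset: float = 100.0  # counts
    read_noise: float = 1.6  # counts RMS
    qe: float = 0.82

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 < self.qe <= 1:
            raise ValueError("qe must be in (0, 1]")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Sample-scan sweep geometry and sheet shape."""

    sheet_angle_deg: float = 32.5
    scan_step_nm: float = 316.0  # per-plane sample translation along X
    n_planes: int = 151
    exposure_s: float = 0.020
    sheet_fwhm_nm: float = 500.0
    sidelobe_fraction: float = 0.0
    sidelobe_offset_nm: float = 720.0  # first Bessel side-lobe position
    img_shape: tuple[int, int] = (64, 64)  # (ny, nx) camera pixels

    def __post_init__(self) -> None:
        if not 0 < self.sheet_angle_deg < 90:
            raise ValueError("sheet angle must be in (0, 90) degrees")
        if self.scan_step_nm <= 0:
            raise ValueError("scan step must be positive")


# ---------------------------------------------------------------------------
# ground truth structures
# ---------------------------------------------------------------------------


def _filament_truth(params: dict, rng: np.random.Generator) -> EmitterSet:
    polylines = params.get("polylines")
    if polylines is None:
        polylines = [params["control_points"]]
    density = float(params.get("density_per_um", 20.0))
    pos, sid = [], []
    for s_idx, pts in enumerate(polylines):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        total_um = seg_len.sum() / 1000.0
        n = rng.poisson(density * total_um)
        if n == 0:
            continue
        t = rng.uniform(0, seg_len.sum(), n)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        k = np.searchsorted(cum, t, side="right") - 1
        k = np.clip(k, 0, len(seg) - 1)
        frac = (t - cum[k]) / seg_len[k]
        pos.append(pts[k] + frac[:, None] * seg[k])
        sid.append(np.full(n, s_idx))
    return EmitterSet(
        np.concatenate(pos) if pos else np.empty((0, 3)),
        np.concatenate(sid) if sid else np.empty(0, int),
        "filament",
    )


def _npc_ring_truth(params: dict, rng: np.random.Generator) -> EmitterSet:
    n_pores = int(params.get("n_pores", 100))
    diameter = float(params.get("ring_diameter_nm", 100.0))
    sites = int(params.get("sites_per_ring", 8))
    eff = float(params.get("labeling_efficiency", 1.0))
    extent = params.get("extent_nm", (6000.0, 6000.0))
    z0 = float(params.get("z_nm", 0.0))
    min_sep = float(params.get("min_separation_nm", 3.0 * diameter))
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_pores and attempts < 200 * max(n_pores, 1):
        c = rng.uniform([0, 0], extent)
        attempts += 1
        if all(np.linalg.norm(c - prev) >= min_sep for prev in centers):
            centers.append(c)
    pos, sid = [], []
    r = diameter / 2.0
    for s_idx, c in enumerate(centers):
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + 2 * np.pi * np.arange(sites) / sites
        labeled = rng.random(sites) < eff
        if not labeled.any():
            continue
        xy = c + r * np.column_stack([np.cos(ang[labeled]), np.sin(ang[labeled])])
        pos.append(np.column_stack([xy, np.full(labeled.sum(), z0)]))
        sid.append(np.full(labeled.sum(), s_idx))
    return EmitterSet(
        np.concatenate(pos) if pos else np.empty((0, 3)),
        np.concatenate(sid) if sid else np.empty(0, int),
        "npc_ring",
    )


def _fiducial_truth(params: dict, rng: np.random.Generator) -> EmitterSet:
    n = int(params.get("n", 3))
    extent = params.get("extent_nm", (6000.0, 6000.0))
    z0 = float(params.get("z_nm", 0.0))
    xy = rng.uniform([0, 0], extent, size=(n, 2))
    pos = np.column_stack([xy, np.full(n, z0)])
    return EmitterSet(pos, np.arange(n), "fiducial", always_on=True)


def make_ground_truth(kind: str, params: dict, seed: int) -> EmitterSet:
    """Generate a ground-truth emitter set.

    kind is one of ``filament`` (polyline control points + linear labeling
    density), ``npc_ring`` (rings of ``ring_diameter_nm`` with
    ``sites_per_ring`` label sites and Bernoulli ``labeling_efficiency``),
    or ``fiducial`` (always-on beads).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    builders = {
        "filament": _filament_truth,
        "npc_ring": _npc_ring_truth,
        "fiducial": _fiducial_truth,
    }
    if kind not in builders:
        raise ValueError(f"unknown structure kind {kind!r}; expected one of {sorted(builders)}")
    return builders[kind](params, rng)


# ---------------------------------------------------------------------------
# blinking kinetics
# ---------------------------------------------------------------------------


def simulate_blinking_trace(
    model: BlinkingModel,
    n_frames: int,
    exposure_s: float,
    seed: int,
    n_emitters: int = 1,
    initial: str = "stationary",
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-resolution blinking states and photon counts.

    The continuous-time chain (off <-> on, on -> bleached) is sampled exactly
    at the frame clock: the per-frame transition matrix is the matrix
    exponential of the generator over one exposure, so the stationary
    on-fraction equals the duty cycle k_on/(k_on + k_off) at any frame rate
    (a naive 1 - exp(-k dt) per-frame probability would inflate it by
    O(k_off dt), over 50% at 20 ms frames for typical spontaneous blinkers).
    Sub-frame partial on-times are still ignored: a frame is wholly on or off.

    Returns ``(states, photons)`` of shape (n_emitters, n_frames); photons are
    nonzero only in on-frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    from scipy.linalg import expm

    rng = np.random.default_rng(seed)
    dt = exposure_s
    generator = np.array(
        [
            [-model.k_on, model.k_on, 0.0],
            [model.k_off, -(model.k_off + model.k_bleach), model.k_bleach],
            [0.0, 0.0, 0.0],
        ]
    )
    trans = expm(generator * dt)  # rows: from off/on/bleached
    cum = np.cumsum(trans, axis=1)

    states = np.empty((n_emitters, n_frames), dtype=np.uint8)
    if initial == "stationary":
        state = np.where(rng.random(n_emitters) < model.duty_cycle, STATE_ON, STATE_OFF)
    elif initial == "off":
        state = np.full(n_emitters, STATE_OFF)
    else:
        raise ValueError("initial must be 'stationary' or 'off'")
    state = state.astype(np.uint8)
    for t in range(n_frames):
        states[:, t] = state
        u = rng.random(n_emitters)
        state = (u[:, None] > cum[state]).sum(axis=1).astype(np.uint8)

    photons = np.zeros((n_emitters, n_frames))
    on = states == STATE_ON
    n_on = int(on.sum())
    if n_on:
        if model.photon_dispersion > 0:
            shape = 1.0 / model.photon_dispersion**2
            scale = model.photons_per_frame_mean * model.photon_dispersion**2
            photons[on] = rng.gamma(shape, scale, n_on)
        else:
            photons[on] = model.photons_per_frame_mean
    return states, photons


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------


def sheet_weight(w_nm: np.ndarray, geom: AcquisitionGeometry) -> np.ndarray:
    """Relative excitation at sheet-normal offset ``w``.

    Gaussian central lobe of FWHM ``sheet_fwhm_nm``; if ``sidelobe_fraction``
    is nonzero, two replicas at +/- ``sidelobe_offset_nm`` are added with that
    relative amplitude (a cheap stand-in for the Bessel side-lobe pedestal).
    """
    w = np.asarray(w_nm, dtype=float)
    ln2_4 = 4.0 * np.log(2.0)
    central = np.exp(-ln2_4 * (w / geom.sheet_fwhm_nm) ** 2)
    if geom.sidelobe_fraction > 0:
        off = geom.sidelobe_offset_nm
        central = central + geom.sidelobe_fraction * (
            np.exp(-ln2_4 * ((w - off) / geom.sheet_fwhm_nm) ** 2)
            + np.exp(-ln2_4 * ((w + off) / geom.sheet_fwhm_nm) ** 2)
        )
    return central


def _sheet_component_weights(w: np.ndarray, geom: AcquisitionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """(central, side-lobe) excitation components, for truth bookkeeping."""
    ln2_4 = 4.0 * np.log(2.0)
    central = np.exp(-ln2_4 * (w / geom.sheet_fwhm_nm) ** 2)
    side = np.zeros_like(central)
    if geom.sidelobe_fraction > 0:
        off = geom.sidelobe_offset_nm
        side = geom.sidelobe_fraction * (
            np.exp(-ln2_4 * ((w - off) / geom.sheet_fwhm_nm) ** 2)
            + np.exp(-ln2_4 * ((w + off) / geom.sheet_fwhm_nm) ** 2)
        )
    return central, side


def _render_emitters(
    img: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    sx_px: np.ndarray,
    sy_px: np.ndarray,
    photons: np.ndarray,
) -> None:
    """Accumulate integrated elliptical Gaussians (expected photons) in place."""
    ny, nx = img.shape
    for xc, yc, sx, sy, n in zip(x_px, y_px, sx_px, sy_px, photons):
        half = int(np.ceil(5.5 * max(sx, sy))) + 1
        i0, i1 = int(np.floor(yc)) - half, int(np.floor(yc)) + half + 1
        j0_, j1 = int(np.floor(xc)) - half, int(np.floor(xc)) + half + 1
        i0, i1 = max(i0, 0), min(i1, ny)
        j0_, j1 = max(j0_, 0), min(j1, nx)
        if i0 >= i1 or j0_ >= j1:
            continue
        ex = _pixel_integral(np.arange(j0_, j1), xc, sx)
        ey = _pixel_integral(np.arange(i0, i1), yc, sy)
        img[i0:i1, j0_:j1] += n * np.outer(ey, ex)


def _pixel_integral(idx: np.ndarray, center: float, sigma: float) -> np.ndarray:
    a = (idx - center) / (np.sqrt(2.0) * sigma)
    b = (idx + 1 - center) / (np.sqrt(2.0) * sigma)
    return 0.5 * (erf(b) - erf(a))


def simulate_series(
    truth: EmitterSet,
    blink: BlinkingModel,
    camera: CameraModel,
    geom: AcquisitionGeometry,
    calib: AstigCalibration,
    seed: int,
    n_volumes: int = 1,
    background_photons: float = 2.0,
    drift_per_frame_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate ``n_volumes`` consecutive sample-scan sweeps.

    Returns ``(stacks, events)`` where ``stacks`` has shape
    ``(n_volumes, n_planes, ny, nx)`` (uint16 camera counts) and ``events`` is
    the ground-truth table with one row per rendered on-event:
    columns volume, plane, frame, structure_id, emitter_id, x_nm, y_nm, z_nm
    (sheet-frame u, v, w), photons (expected collected photons after sheet
    weighting), weight, sidelobe (True when side-lobe excitation dominates).

    Blinking runs on one continuous frame clock across volumes.  Rigid drift
    ``drift_per_frame_nm`` is added to all emitter positions in the sample
    frame, accumulating per camera frame.
    """
    rng = np.random.default_rng(seed)
    n_frames = n_volumes * geom.n_planes
    ny, nx = geom.img_shape
    theta = np.deg2rad(geom.sheet_angle_deg)
    ct, st = np.cos(theta), np.sin(theta)
    a = camera.pixel_size_nm

    if len(truth):
        states, photon_draw = simulate_blinking_trace(
            blink, n_frames, geom.exposure_s, int(rng.integers(2**31)), len(truth)
        )
        if truth.always_on:
            states[:] = STATE_ON
            photon_draw[:] = blink.photons_per_frame_mean
    else:
        states = np.zeros((0, n_frames), dtype=np.uint8)
        photon_draw = np.zeros((0, n_frames))

    stacks = np.zeros((n_volumes, geom.n_planes, ny, nx),
                      dtype=np.uint16 if noise else np.float64)
    rows: list[dict] = []
    drift = np.asarray(drift_per_frame_nm, dtype=float)
    any_excited = False

    for vol in range(n_volumes):
        for p in range(geom.n_planes):
            frame = vol * geom.n_planes + p
            expected = np.zeros((ny, nx))
            if len(truth):
                pos = truth.positions + frame * drift
                X, Y, Z = pos[:, 0], pos[:, 1], pos[:, 2]
                dxp = X - p * geom.scan_step_nm
                u = dxp * ct + Z * st
                v = Y
                w = -dxp * st + Z * ct
                central, side = _sheet_component_weights(w, geom)
                weight = central + side
                on = states[:, frame] == STATE_ON
                sel = on & (weight > MIN_TRUTH_WEIGHT)
                x_px, y_px = u[sel] / a, v[sel] / a
                inside = (x_px > -2) & (x_px < nx + 2) & (y_px > -2) & (y_px < ny + 2)
                idx = np.nonzero(sel)[0][inside]
                if idx.size:
                    any_excited = True
                    u_s, v_s, w_s = u[idx], v[idx], w[idx]
                    n_phot = photon_draw[idx, frame] * weight[idx] * camera.qe
                    sx = np.array([defocus_sigma(wi, calib.x) for wi in w_s]) / a
                    sy = np.array([defocus_sigma(wi, calib.y) for wi in w_s]) / a
                    _render_emitters(expected, u_s / a, v_s / a, sx, sy, n_phot)
                    for e, uu, vv, ww, nn in zip(idx, u_s, v_s, w_s, photon_draw[idx, frame] * weight[idx]):
                        rows.append(
                            dict(
                                volume=vol,
                                plane=p,
                                frame=frame,
                                structure_id=int(truth.structure_id[e]),
                                emitter_id=int(e),
                                x_nm=float(uu),
                                y_nm=float(vv),
                                z_nm=float(ww),
                                photons=float(nn),
                                weight=float(weight[e]),
                                sidelobe=bool(side[e] > central[e]),
                            )
                        )
            expected += background_photons * camera.qe
            if noise:
                img = (
                    camera.gain * rng.poisson(expected)
                    + rng.normal(0.0, camera.read_noise, expected.shape)
                    + camera.offset
                )
                stacks[vol, p] = np.clip(np.rint(img), 0, 65535)
            else:
                # exact expectation, unquantized, so photon bookkeeping is lossless
                stacks[vol, p] = camera.gain * expected + camera.offset

    if len(truth) and not any_excited:
        warnings.warn("no emitter was ever excited inside the scanned slab", stacklevel=2)

    columns = [
        "volume", "plane", "frame", "structure_id", "emitter_id",
        "x_nm", "y_nm", "z_nm", "photons", "weight", "sidelobe",
    ]
    events = pd.DataFrame(rows, columns=columns)
    return stacks, events


#: Labeling density (fluorophores per um^2) that, at the default blinking
#: kinetics (duty cycle k_on/(k_on+k_off) = 0.25/50.25 ~= 5e-3), registers
#: about 1.7 events per um^2 per frame — the high-density regime the thin
#: sheet makes usable.
REGISTERED_DENSITY_LABELS_PER_UM2 = 342.0


def registered_event_density(
    label_density_per_um2: float,
    model: BlinkingModel,
    n_frames: int,
    exposure_s: float,
    seed: int,
    area_um2: float = 100.0,
) -> float:
    """Measured registered-event density (events per um^2 per frame).

    Simulates the blinking of ``label_density * area`` emitters and counts
    on-states; the expectation is label density times the duty cycle.
    """
    n_emitters = int(round(label_density_per_um2 * area_um2))
    states, _ = simulate_blinking_trace(model, n_frames, exposure_s, seed, n_emitters)
    events_per_frame = np.mean(np.sum(states == STATE_ON, axis=0))
    return float(events_per_frame / area_um2)


def simulate_localizations(
    truth: EmitterSet,
    blink: BlinkingModel,
    n_frames: int,
    exposure_s: float,
    precision_nm: float,
    seed: int,
    precision_z_nm: float | None = None,
    drift_per_frame_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Localization table generated directly from blinking ground truth.

    Skips image formation and refitting: every on-frame of every emitter
    becomes one localization at the true position plus isotropic Gaussian
    noise of the stated lateral ``precision_nm`` (axial ``precision_z_nm``,
    defaulting to 2.5x lateral).  Rigid drift accumulates per frame.  Useful
    for exercising drift correction, FRC and particle averaging at realistic
    event counts without the cost of rendering and fitting camera frames.

    Returns a table with frame, structure_id, emitter_id, x_nm, y_nm, z_nm,
    photons, uncertainty_xy_nm plus the true coordinates (x_true_nm, ...).
    """
    rng = np.random.default_rng(seed)
    if precision_z_nm is None:
        precision_z_nm = 2.5 * precision_nm
    states, photons = simulate_blinking_trace(
        blink, n_frames, exposure_s, int(rng.integers(2**31)), len(truth)
    )
    if truth.always_on:
        states[:] = STATE_ON
        photons[:] = blink.photons_per_frame_mean
    em, fr = np.nonzero(states == STATE_ON)
    drift = np.asarray(drift_per_frame_nm, dtype=float)
    pos = truth.positions[em] + fr[:, None] * drift
    noise_xy = rng.normal(0.0, precision_nm, (len(em), 2))
    noise_z = rng.normal(0.0, precision_z_nm, len(em))
    order = np.argsort(fr, kind="stable")
    table = pd.DataFrame(
        {
            "frame": fr,
            "structure_id": truth.structure_id[em],
            "emitter_id": em,
            "x_nm": pos[:, 0] + noise_xy[:, 0],
            "y_nm": pos[:, 1] + noise_xy[:, 1],
            "z_nm": pos[:, 2] + noise_z,
            "photons": photons[em, fr],
            "uncertainty_xy_nm": precision_nm,
            "x_true_nm": pos[:, 0],
            "y_true_nm": pos[:, 1],
            "z_true_nm": pos[:, 2],
        }
    )
    return table.iloc[order].reset_index(drop=True)


def simulate_stack(
    truth: EmitterSet,
    blink: BlinkingModel,
    camera: CameraModel,
    geom: AcquisitionGeometry,
    calib: AstigCalibration,
    seed: int,
    **kwargs,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Single-volume convenience wrapper around :func:`simulate_series`."""
    stacks, events = simulate_series(truth, blink, camera, geom, calib, seed, n_volumes=1, **kwargs)
    return stacks[0], events
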