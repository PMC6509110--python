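"""Astigmatic defocus calibration: PSF width vs axial position, and its inverse.

A cylindrical lens in the detection path makes the PSF elliptical, with the
x and y Gaussian widths focusing at different axial positions.  Each axis is
modeled by the quartic-corrected defocus hyperbola standard in astigmatic
3D localization,

    sigma_i(z) = sigma0_i * sqrt(1 + u^2 + A_i u^3 + B_i u^4),
    u = (z - c_i) / d_i,

fitted per axis to bead z-stacks.  Axial positions are recovered by
minimizing the root-width distance

    D(z) = (sqrt(sx) - sqrt(sx_cal(z)))^2 + (sqrt(sy) - sqrt(sy_cal(z)))^2

over the calibrated range.  Events whose widths match no in-range model value
(out-of-focus or side-lobe excitation) are flagged invalid, which is what lets
the astigmatism act as an optical-sectioning filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.optimize import least_squares

__all__ = [
    "AstigCalibration",
    "AxisDefocus",
    "defocus_sigma",
    "fit_defocus_model",
    "sigma_at_z",
    "z_from_sigma",
    "save_calibration",
    "load_calibration",
    "FitError",
]

# Axial scan and inversion defaults
Z_GRID_NM = 1.0  # inversion grid pitch
DEFAULT_MAX_RESIDUAL = 1.0  # sqrt-width distance above which z is rejected


class FitError(RuntimeError):
    """Raised when the defocus model cannot be fitted to bead data."""


@dataclass(frozen=True)
class AxisDefocus:
    """Defocus parameters of one lateral axis."""

    sigma0_nm: float  # in-focus width
    focus_offset_nm: float  # c: axial position of this axis' focus
    depth_nm: float  # d: defocus depth scale
    a3: float = 0.0  # cubic correction A
    a4: float = 0.0  # quartic correction B

    def __post_init__(self) -> None:
        if self.sigma0_nm <= 0:
            raise ValueError("sigma0 must be positive")
        if self.depth_nm <= 0:
            raise ValueError("depth must be positive")


@dataclass(frozen=True)
class AstigCalibration:
    """Per-axis defocus curves plus the z range over which they are valid."""

    x: AxisDefocus
    y: AxisDefocus
    z_range_nm: tuple[float, float]
    residual_rms_nm: float = 0.0
    max_residual: float = DEFAULT_MAX_RESIDUAL

    def __post_init__(self) -> None:
        lo, hi = self.z_range_nm
        if not lo < hi:
            raise ValueError("z_range must satisfy z_min < z_max")


def defocus_sigma(z: np.ndarray | float, axis: AxisDefocus) -> np.ndarray | float:
    """Evaluate sigma_i(z) of the defocus model for one axis."""
    u = (np.asarray(z, dtype=float) - axis.focus_offset_nm) / axis.depth_nm
    val = axis.sigma0_nm * np.sqrt(np.maximum(1.0 + u**2 + axis.a3 * u**3 + axis.a4 * u**4, 0.0))
    return val if np.ndim(z) else float(val)


def _fit_axis(z: np.ndarray, sigma: np.ndarray) -> AxisDefocus:
    i_min = int(np.argmin(sigma))
    span = z.max() - z.min()
    p0 = np.array([sigma[i_min], z[i_min], span / 4.0, 0.0, 0.0])

    def resid(p: np.ndarray) -> np.ndarray:
        ax = AxisDefocus(p[0], p[1], p[2], p[3], p[4])
        return defocus_sigma(z, ax) - sigma

    lb = [1.0, z.min() - span, 10.0, -2.0, -2.0]
    ub = [np.inf, z.max() + span, 10.0 * span, 2.0, 2.0]
    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf")
    if not sol.success:
        raise FitError(f"defocus fit did not converge: {sol.message}")
    return AxisDefocus(*(float(v) for v in sol.x))  # plain floats: YAML-safe


def fit_defocus_model(
    bead_observations: np.ndarray | list[tuple[float, float, float]],
    z_range_nm: tuple[float, float] | None = None,
) -> AstigCalibration:
    """Fit the per-axis defocus model to bead width measurements.

    Parameters
    ----------
    bead_observations
        Sequence of ``(z_nm, sigma_x_nm, sigma_y_nm)`` rows, e.g. widths
        measured from a bead stack acquired at a fixed z step (40 nm in the
        reference acquisition protocol).
    z_range_nm
        Valid calibration range; defaults to the span of the observations.

    Raises
    ------
    FitError
        If fewer than 15 distinct z samples are given or a fit fails.
    """
    obs = np.asarray(bead_observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise FitError("bead observations must be (z, sigma_x, sigma_y) rows")
    z, sx, sy = obs[:, 0], obs[:, 1], obs[:, 2]
    if np.unique(z).size < 15:
        raise FitError(
            f"need >= 15 distinct z samples, got {np.unique(z).size}"
        )
    ax = _fit_axis(z, sx)
    ay = _fit_axis(z, sy)
    resid = np.concatenate(
        [defocus_sigma(z, ax) - sx, defocus_sigma(z, ay) - sy]
    )
    rms = float(np.sqrt(np.mean(resid**2)))
    if z_range_nm is None:
        z_range_nm = (float(z.min()), float(z.max()))
    return AstigCalibration(x=ax, y=ay, z_range_nm=tuple(z_range_nm), residual_rms_nm=rms)


def sigma_at_z(calib: AstigCalibration, z: float) -> tuple[float, float]:
    """Model widths ``(sigma_x, sigma_y)`` in nm at axial position ``z``.

    Evaluation outside ``z_range_nm`` is permitted (extrapolation) but the
    caller should treat it as unreliable.
    """
    return (
        float(defocus_sigma(z, calib.x)),
        float(defocus_sigma(z, calib.y)),
    )


def _sqrt_distance(calib: AstigCalibration, z: np.ndarray, sx: float, sy: float) -> np.ndarray:
    mx = defocus_sigma(z, calib.x)
    my = defocus_sigma(z, calib.y)
    return (np.sqrt(sx) - np.sqrt(mx)) ** 2 + (np.sqrt(sy) - np.sqrt(my)) ** 2


def z_from_sigma(
    calib: AstigCalibration,
    sigma_x_nm: float,
    sigma_y_nm: float,
    max_residual: float | None = None,
    edge_margin_nm: float = 20.0,
) -> tuple[float, bool]:
    """Invert the defocus model: widths -> axial position.

    Scans D(z) on a 1 nm grid over the calibrated range, refines the minimum
    with a 3-point parabolic fit (ties broken toward smaller ``|z|``), and
    returns ``(z_nm, valid)``.  ``valid`` is False when the best distance
    exceeds ``max_residual`` — the width pair is inconsistent with any
    in-focus axial position, as happens for out-of-focus background or
    side-lobe-excited events — or when the minimum falls within
    ``edge_margin_nm`` of the calibration boundary, where out-of-range
    events fold onto the range edge.
    """
    if sigma_x_nm <= 0 or sigma_y_nm <= 0:
        raise ValueError("widths must be positive")
    if max_residual is None:
        max_residual = calib.max_residual
    lo, hi = calib.z_range_nm
    grid = np.arange(lo, hi + Z_GRID_NM, Z_GRID_NM)
    d = _sqrt_distance(calib, grid, sigma_x_nm, sigma_y_nm)
    best = np.nonzero(d == d.min())[0]
    i = int(best[np.argmin(np.abs(grid[best]))])  # tie-break toward small |z|
    z_hat = grid[i]
    if 0 < i < grid.size - 1:
        denom = d[i - 1] - 2 * d[i] + d[i + 1]
        if denom > 0:
            z_hat = grid[i] + 0.5 * (d[i - 1] - d[i + 1]) / denom * Z_GRID_NM
    valid = d[i] <= max_residual and lo + edge_margin_nm <= z_hat <= hi - edge_margin_nm
    return float(z_hat), bool(valid)


def save_calibration(calib: AstigCalibration, path: str) -> None:
    """Write a calibration to YAML."""
    payload = {
        "x": asdict(calib.x),
        "y": asdict(calib.y),
        "z_range_nm": list(calib.z_range_nm),
        "residual_rms_nm": calib.residual_rms_nm,
        "max_residual": calib.max_residual,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_calibration(path: str) -> AstigCalibration:
    """Read a calibration written by :func:`save_calibration`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return AstigCalibration(
        x=AxisDefocus(**payload["x"]),
        y=AxisDefocus(**payload["y"]),
        z_range_nm=tuple(payload["z_range_nm"]),
        residual_rms_nm=payload.get("residual_rms_nm", 0.0),
        max_residual=payload.get("max_residual", DEFAULT_MAX_RESIDUAL),
    )
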