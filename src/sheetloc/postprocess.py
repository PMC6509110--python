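"""Drift correction, deskew to sample coordinates, transposition and rendering.

Drift is estimated either from always-on fiducial beads (per-frame
nearest-neighbor tracks, averaged and smoothed) or by phase cross-correlation
between temporally blocked reconstructions.  Because the raw acquisition is a
sample scan, the per-plane time series are first transposed so drift acts on a
simple frame clock; estimated traces are interpolated and subtracted.

Deskew maps the tilted sheet-frame coordinates (u = camera tilt direction,
v = camera horizontal, w = astigmatic sheet-normal z) of plane p (scan step s,
sheet angle theta) into coverslip coordinates:

    X = p*s + u cos(theta) - w sin(theta)
    Y = v
    Z = u sin(theta) + w cos(theta)

Density rendering represents each event as a symmetric Gaussian whose standard
deviation is the event's theoretical localization uncertainty (or a fixed
value); 3D volumes are histogrammed and optionally smoothed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

__all__ = [
    "DriftTrace",
    "track_fiducials",
    "estimate_drift_xcorr",
    "apply_drift",
    "deskew",
    "deskew_inverse",
    "transpose_to_time_series",
    "render_density",
    "render_temporal",
    "max_intensity_projection",
]

DEFAULT_SMOOTHING_WINDOW = 50  # frames, moving average applied to drift traces
FIDUCIAL_MIN_COVERAGE = 0.8  # fraction of frames a proposed fiducial must span


@dataclass
class DriftTrace:
    """Per-frame (or per-block) rigid displacement estimates in nm."""

    frames: np.ndarray  # strictly increasing frame (or block-center) indices
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    method: str  # "fiducial" or "xcorr"
    smoothing_window: int = 0
    residual_std_nm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("trace indices must be strictly increasing")
        for name in ("dx", "dy", "dz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)

    def negated(self) -> "DriftTrace":
        return DriftTrace(self.frames.copy(), -self.dx, -self.dy, -self.dz,
                          self.method, self.smoothing_window, dict(self.residual_std_nm))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    return (
        pd.Series(x).rolling(window, min_periods=1, center=True).mean().to_numpy()
    )


def _propose_fiducials(table: pd.DataFrame, link_radius_nm: float) -> np.ndarray:
    """Seed positions of persistent tracks (>=80% coverage of an early window).

    Coverage is judged over the first 200 frames so slow drift does not smear
    a genuine fiducial across grid cells; the tracker follows it from there.
    """
    frames = np.sort(table["frame"].unique())
    window = frames[: min(200, frames.size)]
    early = table[table["frame"].isin(window)]
    gx = np.round(early["x_nm"].to_numpy() / link_radius_nm).astype(int)
    gy = np.round(early["y_nm"].to_numpy() / link_radius_nm).astype(int)
    cells = pd.DataFrame({"gx": gx, "gy": gy, "frame": early["frame"].to_numpy(),
                          "x": early["x_nm"].to_numpy(), "y": early["y_nm"].to_numpy()})
    seeds = []
    for _, grp in cells.groupby(["gx", "gy"]):
        if grp["frame"].nunique() >= FIDUCIAL_MIN_COVERAGE * window.size:
            seeds.append([grp["x"].mean(), grp["y"].mean()])
    return np.asarray(seeds, dtype=float).reshape(-1, 2)


def track_fiducials(
    table: pd.DataFrame,
    seed_positions: np.ndarray | None = None,
    link_radius_nm: float = 500.0,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
) -> DriftTrace:
    """Estimate drift from fiducial-bead tracks.

    Each fiducial is linked per frame to its nearest localization within
    ``link_radius_nm``; its displacement is taken relative to its own track
    mean, displacements are averaged across fiducials, gaps interpolated and
    the trace moving-average smoothed.  The residual per-axis standard
    deviation of the corrected tracks — the bead scatter left after drift
    removal — is stored in ``residual_std_nm``; it is the actual localization
    precision the instrument achieved.
    """
    if seed_positions is None:
        seed_positions = _propose_fiducials(table, link_radius_nm)
    seed_positions = np.asarray(seed_positions, dtype=float).reshape(-1, 2)
    if len(seed_positions) == 0:
        raise ValueError("no fiducials found (and none seeded)")
    frames = np.sort(table["frame"].unique())
    has_z = "z_nm" in table.columns and table["z_nm"].notna().any()
    n_fid = len(seed_positions)
    tracks = np.full((n_fid, frames.size, 3), np.nan)
    by_frame = dict(tuple(table.groupby("frame")))
    current = seed_positions.copy()  # follows each fiducial through drift
    for t, fr in enumerate(frames):
        sub = by_frame[fr]
        xy = sub[["x_nm", "y_nm"]].to_numpy()
        z = sub["z_nm"].to_numpy() if has_z else np.zeros(len(sub))
        for k in range(n_fid):
            d2 = np.sum((xy - current[k]) ** 2, axis=1)
            j = int(np.argmin(d2))
            if d2[j] <= link_radius_nm**2:
                tracks[k, t] = [xy[j, 0], xy[j, 1], z[j]]
                current[k] = xy[j]
    coverage = np.mean(np.isfinite(tracks[:, :, 0]), axis=1)
    if np.any(coverage < 0.8):
        warnings.warn(
            f"{int(np.sum(coverage < 0.8))} fiducial(s) lost in >20% of frames",
            stacklevel=2,
        )
    # displacement of each fiducial relative to its own mean, averaged
    rel = tracks - np.nanmean(tracks, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        disp = np.nanmean(rel, axis=0)
    for axis in range(3):
        col = disp[:, axis]
        bad = ~np.isfinite(col)
        if bad.any():
            col[bad] = np.interp(frames[bad], frames[~bad], col[~bad])
    smooth = np.column_stack([_moving_average(disp[:, i], smoothing_window) for i in range(3)])
    # residual scatter against the smoothed trace: the unsmoothed per-frame
    # mean contains 1/n of each bead's own localization noise and would
    # understate the achieved precision
    resid = rel - smooth[None, :, :]
    residual_std = {
        ax: float(np.nanstd(resid[:, :, i]))
        for i, ax in enumerate(("x", "y", "z"))
    }
    return DriftTrace(
        frames=frames,
        dx=smooth[:, 0],
        dy=smooth[:, 1],
        dz=smooth[:, 2],
        method="fiducial",
        smoothing_window=smoothing_window,
        residual_std_nm=residual_std,
    )


def _histogram2d(sub: pd.DataFrame, edges_x: np.ndarray, edges_y: np.ndarray) -> np.ndarray:
    h, _, _ = np.histogram2d(sub["x_nm"], sub["y_nm"], bins=[edges_x, edges_y])
    return h


def _parabolic_peak(corr: np.ndarray) -> tuple[float, float]:
    """Sub-pixel peak of a circular correlation surface (3-point parabola)."""
    ny, nx = corr.shape
    i, j = np.unravel_index(np.argmax(corr), corr.shape)

    def refine(cm: float, c0: float, cp: float) -> float:
        denom = cm - 2 * c0 + cp
        return 0.5 * (cm - cp) / denom if denom < 0 else 0.0

    di = refine(corr[(i - 1) % ny, j], corr[i, j], corr[(i + 1) % ny, j])
    dj = refine(corr[i, (j - 1) % nx], corr[i, j], corr[i, (j + 1) % nx])
    # map circular indices to signed shifts
    si = i + di
    sj = j + dj
    if si > ny / 2:
        si -= ny
    if sj > nx / 2:
        sj -= nx
    return si, sj


def estimate_drift_xcorr(
    table: pd.DataFrame,
    block_frames: int,
    render_pixel_nm: float = 10.0,
) -> DriftTrace:
    """Drift by cross-correlating blocked 2D reconstructions.

    Events are grouped into blocks of ``block_frames``; each block's 2D
    histogram is correlated (via FFT) against the first block's and the peak
    located to sub-pixel precision with a 3-point parabolic fit per axis.
    The trace is indexed at block-center frames; featureless blocks produce a
    warning and a zero shift.
    """
    frames = table["frame"].to_numpy()
    block = (frames // block_frames).astype(int)
    blocks = np.unique(block)
    if blocks.size < 2:
        raise ValueError("need at least 2 blocks for cross-correlation drift")
    pad = 5 * render_pixel_nm
    edges_x = np.arange(table["x_nm"].min() - pad, table["x_nm"].max() + pad, render_pixel_nm)
    edges_y = np.arange(table["y_nm"].min() - pad, table["y_nm"].max() + pad, render_pixel_nm)
    ref = _histogram2d(table[block == blocks[0]], edges_x, edges_y)
    f_ref = np.fft.rfft2(ref)
    centers, dxs, dys = [], [], []
    for b in blocks:
        sub = table[block == b]
        centers.append((b + 0.5) * block_frames)
        if b == blocks[0]:
            dxs.append(0.0)
            dys.append(0.0)
            continue
        h = _histogram2d(sub, edges_x, edges_y)
        if h.sum() == 0:
            warnings.warn(f"featureless block {b}; zero shift assumed", stacklevel=2)
            dxs.append(0.0)
            dys.append(0.0)
            continue
        corr = np.fft.irfft2(np.fft.rfft2(h) * np.conj(f_ref), s=ref.shape)
        sx, sy = _parabolic_peak(corr)
        dxs.append(sx * render_pixel_nm)
        dys.append(sy * render_pixel_nm)
    centers = np.asarray(centers, dtype=float)
    return DriftTrace(
        frames=centers,
        dx=np.asarray(dxs),
        dy=np.asarray(dys),
        dz=np.zeros(len(centers)),
        method="xcorr",
    )


def apply_drift(table: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the (interpolated) drift trace from every record."""
    out = table.copy()
    f = out["frame"].to_numpy(dtype=float)
    out["x_nm"] = out["x_nm"] - np.interp(f, trace.frames, trace.dx)
    out["y_nm"] = out["y_nm"] - np.interp(f, trace.frames, trace.dy)
    if "z_nm" in out.columns:
        out["z_nm"] = out["z_nm"] - np.interp(f, trace.frames, trace.dz)
    return out


def deskew(table: pd.DataFrame, sheet_angle_deg: float, scan_step_nm: float) -> pd.DataFrame:
    """Sheet-frame (u, v, w, plane) -> coverslip (X, Y, Z) coordinates.

    Adds columns X_nm, Y_nm, Z_nm; the sheet-frame columns are kept.  The
    transform is a rotation plus a per-plane translation, hence an isometry
    within each plane.
    """
    if not 0 < sheet_angle_deg < 90:
        raise ValueError("sheet angle must be in (0, 90) degrees")
    if scan_step_nm <= 0:
        raise ValueError("scan step must be positive")
    th = np.deg2rad(sheet_angle_deg)
    ct, st = np.cos(th), np.sin(th)
    out = table.copy()
    u = out["x_nm"].to_numpy(dtype=float)
    v = out["y_nm"].to_numpy(dtype=float)
    w = out["z_nm"].to_numpy(dtype=float) if "z_nm" in out.columns else np.zeros(len(out))
    p = out["plane"].to_numpy(dtype=float) if "plane" in out.columns else np.zeros(len(out))
    out["X_nm"] = p * scan_step_nm + u * ct - w * st
    out["Y_nm"] = v
    out["Z_nm"] = u * st + w * ct
    return out


def deskew_inverse(table: pd.DataFrame, sheet_angle_deg: float, scan_step_nm: float) -> pd.DataFrame:
    """Recover sheet-frame (u, v, w) from (X_nm, Y_nm, Z_nm) and plane."""
    th = np.deg2rad(sheet_angle_deg)
    ct, st = np.cos(th), np.sin(th)
    out = table.copy()
    p = out["plane"].to_numpy(dtype=float) if "plane" in out.columns else np.zeros(len(out))
    dx = out["X_nm"].to_numpy(dtype=float) - p * scan_step_nm
    z = out["Z_nm"].to_numpy(dtype=float)
    out["x_nm"] = dx * ct + z * st
    out["y_nm"] = out["Y_nm"]
    out["z_nm"] = -dx * st + z * ct
    return out


def transpose_to_time_series(volume_series: np.ndarray) -> np.ndarray:
    """Reindex (volume, plane, y, x) stacks into per-plane time series.

    Output axis order is (plane, volume, y, x): element (v, p, i, j) of the
    input is element (v, i, j) of output plane p.  Pure reindexing, lossless
    and an involution.
    """
    arr = np.asarray(volume_series)
    if arr.ndim != 4:
        raise ValueError("expected a (volume, plane, y, x) array with consistent plane counts")
    return np.swapaxes(arr, 0, 1)


def _gauss_kernel_1d(offsets: np.ndarray, center: float, sigma: float) -> np.ndarray:
    a = (offsets - center) / (np.sqrt(2.0) * sigma)
    b = (offsets + 1 - center) / (np.sqrt(2.0) * sigma)
    return 0.5 * (erf(b) - erf(a))


def render_density(
    table: pd.DataFrame,
    pixel_nm: float,
    mode: str = "2d",
    sigma_source: str = "per_event_uncertainty",
    fixed_sigma_nm: float | None = None,
    extent_nm: tuple | None = None,
    smooth_sigma_nm: float = 0.0,
    coords: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Uncertainty-weighted density rendering.

    2D: each event contributes a unit-integral symmetric Gaussian of standard
    deviation equal to its theoretical localization uncertainty (or
    ``fixed_sigma_nm``); kernels are truncated at 6 sigma so interior events
    conserve total weight to better than 1e-6 (no border renormalization).
    3D: an event-count histogram, optionally smoothed by a Gaussian kernel of
    ``smooth_sigma_nm``.

    ``extent_nm`` is ((x0, x1), (y0, y1)[, (z0, z1)]); defaults to the table's
    bounding box padded by 6 sigma.  ``coords`` selects the coordinate
    columns (defaults to sheet-frame x_nm/y_nm/z_nm).
    """
    if pixel_nm <= 0:
        raise ValueError("pixel size must be positive")
    if coords is None:
        coords = ("x_nm", "y_nm") if mode == "2d" else ("x_nm", "y_nm", "z_nm")
    if mode == "3d":
        pts = table[list(coords)].to_numpy(dtype=float)
        if extent_nm is None:
            lo = pts.min(axis=0) - 3 * pixel_nm
            hi = pts.max(axis=0) + 3 * pixel_nm
            extent_nm = tuple(zip(lo, hi))
        edges = [np.arange(lo, hi + pixel_nm, pixel_nm) for lo, hi in extent_nm]
        hist, _ = np.histogramdd(pts, bins=edges)
        if smooth_sigma_nm > 0:
            hist = ndimage.gaussian_filter(hist, smooth_sigma_nm / pixel_nm)
        return hist
    if mode != "2d":
        raise ValueError("mode must be '2d' or '3d'")

    x = table[coords[0]].to_numpy(dtype=float)
    y = table[coords[1]].to_numpy(dtype=float)
    if sigma_source == "fixed":
        if fixed_sigma_nm is None:
            raise ValueError("fixed_sigma_nm required for sigma_source='fixed'")
        sig = np.full(len(x), float(fixed_sigma_nm))
    elif sigma_source == "per_event_uncertainty":
        sig = table["uncertainty_xy_nm"].to_numpy(dtype=float)
    else:
        raise ValueError("sigma_source must be 'per_event_uncertainty' or 'fixed'")
    sig = np.maximum(sig, 1e-3)
    if extent_nm is None:
        pad = 6 * (sig.max() if len(sig) else pixel_nm)
        extent_nm = (
            (x.min() - pad, x.max() + pad),
            (y.min() - pad, y.max() + pad),
        ) if len(x) else ((0, pixel_nm), (0, pixel_nm))
    (x0, x1), (y0, y1) = extent_nm[:2]
    nx = int(np.ceil((x1 - x0) / pixel_nm))
    ny = int(np.ceil((y1 - y0) / pixel_nm))
    img = np.zeros((ny, nx))
    for xi, yi, si in zip(x, y, sig):
        s_px = si / pixel_nm
        cx = (xi - x0) / pixel_nm
        cy = (yi - y0) / pixel_nm
        half = int(np.ceil(6.0 * s_px)) + 1
        j0, j1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        i0, i1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        j0c, j1c = max(j0, 0), min(j1, nx)
        i0c, i1c = max(i0, 0), min(i1, ny)
        if j0c >= j1c or i0c >= i1c:
            continue
        kx = _gauss_kernel_1d(np.arange(j0c, j1c), cx, s_px)
        ky = _gauss_kernel_1d(np.arange(i0c, i1c), cy, s_px)
        img[i0c:i1c, j0c:j1c] += np.outer(ky, kx)
    return img


def render_temporal(
    table: pd.DataFrame,
    frames_per_bin: int,
    pixel_nm: float = 20.0,
    cmap: str = "jet",
    **render_kwargs,
) -> tuple[np.ndarray, list[pd.DataFrame]]:
    """Temporal color-coded rendering.

    Events are partitioned by ``floor(frame / frames_per_bin)``; each bin is
    density-rendered on a common grid and assigned a colormap color by bin
    index.  Returns the 8-bit RGB composite and the per-bin sub-tables (which
    partition the input).
    """
    if frames_per_bin < 1:
        raise ValueError("frames_per_bin must be >= 1")
    import matplotlib

    bins = (table["frame"].to_numpy() // frames_per_bin).astype(int)
    uniq = np.unique(bins)
    pad = 3 * pixel_nm
    extent = (
        (table["x_nm"].min() - pad, table["x_nm"].max() + pad),
        (table["y_nm"].min() - pad, table["y_nm"].max() + pad),
    )
    colormap = matplotlib.colormaps[cmap]
    sub_tables = []
    rgb = None
    for k, b in enumerate(uniq):
        sub = table[bins == b]
        sub_tables.append(sub)
        dens = render_density(sub, pixel_nm, mode="2d", extent_nm=extent, **render_kwargs)
        color = np.asarray(colormap(k / max(len(uniq) - 1, 1))[:3])
        if rgb is None:
            rgb = np.zeros(dens.shape + (3,))
        rgb += dens[:, :, None] * color[None, None, :]
    peak = rgb.max()
    if peak > 0:
        rgb = rgb / peak
    return (255 * rgb).astype(np.uint8), sub_tables


def max_intensity_projection(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Simple MIP helper for rendered volumes."""
    return np.asarray(volume).max(axis=axis)
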