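"""Nuclear-pore-complex candidate selection, KDE centering and donut averaging.

The 2D localization point cloud is binned at a 10 nm effective pixel, a
candidate mask is built (pixels with events -> morphological hole fill ->
dilation by a 3x3 square), and 8-connected clusters whose dilated area lies
in [250, 300] px^2 are kept — the size window that singles out isolated pores
at this binning.  A 32x32 crop around each centroid is fitted with a radial
ring ("donut") model

    I(x, y) = A exp(-(r - r0)^2 / (2 sigma_r^2)) + c,   r = |(x, y) - center|

by least squares with multi-start ring radii.  Each candidate's true center
is re-estimated by bivariate Gaussian kernel density estimation (centroid of
the probability map), the best-fitting n_top crops are shifted onto a common
center and accumulated, and the pore diameter is read off a final donut fit
of the overlay as 2 r0.

Note the donut center estimate inherits the inward bias of a smeared ring:
the radial image density of a ring of radius r0 observed with localization
precision sigma peaks below r0 (by roughly sigma^2/r0 for sigma << r0) and
loses the ring maximum entirely once r0 < sigma*sqrt(2).  The procedure is
therefore meaningful only when the localization precision is comfortably
below r0/sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

__all__ = [
    "NpcParams",
    "BinnedImage",
    "Candidate",
    "DonutFit",
    "suggested_area_bounds",
    "bin_pointcloud",
    "select_candidates",
    "fit_donut",
    "kde_center",
    "overlay_average",
    "estimate_diameter",
    "average_pipeline",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class NpcParams:
    """Knobs of the candidate-selection / averaging procedure."""

    bin_pixel_nm: float = 10.0
    area_bounds_px: tuple[int, int] = (250, 300)  # inclusive, on the dilated mask
    dilation_size_px: int = 3
    roi_size_px: int = 32
    n_top: int = 50
    kde_grid_nm: float = 2.0
    kde_bandwidth_rule: str = "silverman"  # or "fixed"
    kde_bandwidth_nm: float = 10.0  # used when rule == "fixed"
    multistart_r0_nm: tuple[float, ...] = (30.0, 50.0, 70.0)

    def __post_init__(self) -> None:
        lo, hi = self.area_bounds_px
        if lo > hi:
            raise ValueError("area_bounds must be a non-empty interval")
        if self.roi_size_px % 2:
            raise ValueError("roi_size must be even")


@dataclass(frozen=True)
class BinnedImage:
    """Event-count image plus the mapping back to nm coordinates."""

    counts: np.ndarray
    origin_px: tuple[int, int]  # (ix0, iy0): pixel indices of counts[0, 0]
    pixel_nm: float

    def pixel_to_nm(self, ix: float, iy: float) -> tuple[float, float]:
        """Center of pixel (ix, iy) — image-local indices — in nm."""
        return (
            (self.origin_px[0] + ix + 0.5) * self.pixel_nm,
            (self.origin_px[1] + iy + 0.5) * self.pixel_nm,
        )


@dataclass(frozen=True)
class Candidate:
    """One selected pore cluster."""

    centroid_nm: tuple[float, float]
    area_px: int
    crop: np.ndarray  # roi_size x roi_size counts, indexed [iy, ix]
    crop_origin_px: tuple[int, int]  # global (ix, iy) of crop[0, 0]


@dataclass(frozen=True)
class DonutFit:
    """Ring-model parameters of one candidate (or of the overlay)."""

    center_nm: tuple[float, float]  # in the crop's local nm frame
    ring_radius_nm: float
    ring_width_nm: float
    amplitude: float
    offset: float
    rss: float
    norm_rss: float  # rss / total crop energy, the ranking score
    success: bool
    rank: int = -1


def suggested_area_bounds(
    diameter_nm: float,
    precision_nm: float,
    bin_pixel_nm: float = 10.0,
    dilation_size_px: int = 3,
    rel_halfwidth: float = 0.09,
) -> tuple[int, int]:
    """Area window matched to the expected single-pore footprint.

    The dilated mask of an isolated pore is roughly a disk of radius
    ``r0 + 2 sigma`` (ring radius plus the localization smear) plus the
    dilation margin.  The returned inclusive window brackets that disk area by
    ``rel_halfwidth``; at the defaults (100 nm pore, 15 nm precision, 10 nm
    bin) it reproduces the canonical [250, 300] px^2 window.  Selecting with a
    window sized for a different pore diameter picks an atypically small or
    large subpopulation and biases the averaged diameter.
    """
    r_px = (diameter_nm / 2.0 + 2.0 * precision_nm) / bin_pixel_nm + (dilation_size_px - 1) / 2.0 + 0.5
    area = np.pi * r_px**2
    return int(round(area * (1 - rel_halfwidth))), int(round(area * (1 + rel_halfwidth)))


def bin_pointcloud(points: np.ndarray | pd.DataFrame, bin_pixel_nm: float = 10.0) -> BinnedImage:
    """Bin (x, y) nm coordinates into a count image by floor division.

    Total counts equal the number of points; the image covers exactly the
    occupied pixel range (``origin_px`` records the offset).
    """
    if bin_pixel_nm <= 0:
        raise ValueError("bin pixel must be positive")
    if isinstance(points, pd.DataFrame):
        pts = points[["x_nm", "y_nm"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return BinnedImage(np.zeros((0, 0), dtype=int), (0, 0), bin_pixel_nm)
    ix = np.floor(pts[:, 0] / bin_pixel_nm).astype(int)
    iy = np.floor(pts[:, 1] / bin_pixel_nm).astype(int)
    x0, y0 = ix.min(), iy.min()
    counts = np.zeros((iy.max() - y0 + 1, ix.max() - x0 + 1), dtype=int)
    np.add.at(counts, (iy - y0, ix - x0), 1)
    return BinnedImage(counts, (int(x0), int(y0)), bin_pixel_nm)


def select_candidates(binned: BinnedImage, params: NpcParams | None = None) -> list[Candidate]:
    """Mask -> fill -> dilate -> 8-connected components -> area window -> crops.

    The area filter runs on the dilated mask (operation order as stated:
    dilation first, then size selection), bounds inclusive.  Crops span
    ``[c - roi/2, c + roi/2)`` around the rounded centroid and candidates
    whose crop would leave the image are dropped.
    """
    if params is None:
        params = NpcParams()
    counts = binned.counts
    if counts.size == 0:
        return []
    mask = counts > 0
    mask = ndimage.binary_fill_holes(mask)
    d = params.dilation_size_px
    mask = ndimage.binary_dilation(mask, structure=np.ones((d, d), dtype=bool))
    labels, n_lab = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n_lab == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    lo, hi = params.area_bounds_px
    keep = np.nonzero((areas >= lo) & (areas <= hi))[0] + 1
    half = params.roi_size_px // 2
    ny, nx = counts.shape
    out: list[Candidate] = []
    for lab in keep:
        cy, cx = ndimage.center_of_mass(mask, labels, lab)
        icx, icy = int(round(cx)), int(round(cy))
        if icx - half < 0 or icx + half > nx or icy - half < 0 or icy + half > ny:
            continue  # edge-clipped
        crop = counts[icy - half : icy + half, icx - half : icx + half].copy()
        cen_nm = binned.pixel_to_nm(cx, cy)
        out.append(
            Candidate(
                centroid_nm=(float(cen_nm[0]), float(cen_nm[1])),
                area_px=int(areas[lab - 1]),
                crop=crop,
                crop_origin_px=(binned.origin_px[0] + icx - half,
                                binned.origin_px[1] + icy - half),
            )
        )
    return out


def fit_donut(
    crop: np.ndarray,
    pixel_nm: float = 10.0,
    multistart_r0_nm: tuple[float, ...] = (30.0, 50.0, 70.0),
) -> DonutFit:
    """Least-squares ring fit of a crop; lowest-RSS multi-start solution.

    Needs >= 20 nonzero pixels; otherwise (or if every start fails) returns a
    fit with ``success=False``.
    """
    img = np.asarray(crop, dtype=float)
    if np.count_nonzero(img) < 20:
        return _failed_donut()
    ny, nx = img.shape
    x = (np.arange(nx) + 0.5) * pixel_nm
    y = (np.arange(ny) + 0.5) * pixel_nm
    X, Y = np.meshgrid(x, y)
    total = img.sum()
    cx0 = float((X * img).sum() / total)
    cy0 = float((Y * img).sum() / total)
    energy = float((img**2).sum())

    def resid(p: np.ndarray) -> np.ndarray:
        cx, cy, r0, sr, amp, off = p
        r = np.hypot(X - cx, Y - cy)
        return (amp * np.exp(-((r - r0) ** 2) / (2 * sr**2)) + off - img).ravel()

    best = None
    span = max(nx, ny) * pixel_nm
    for r0_init in multistart_r0_nm:
        p0 = np.array([cx0, cy0, r0_init, 15.0, max(img.max(), 1.0), 0.0])
        lb = [0.0, 0.0, 1.0, 1.0, 0.0, -np.inf]
        ub = [span, span, span, span, np.inf, np.inf]
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return _failed_donut()
    cx, cy, r0, sr, amp, off = best.x
    rss = float(np.sum(best.fun**2))
    # a ring fit that explains nothing beyond a flat offset is no detection
    flat_rss = float(np.sum((img - img.mean()) ** 2))
    success = amp > 0 and rss < 0.98 * flat_rss
    return DonutFit(
        center_nm=(float(cx), float(cy)),
        ring_radius_nm=float(r0),
        ring_width_nm=float(sr),
        amplitude=float(amp),
        offset=float(off),
        rss=rss,
        norm_rss=rss / energy if energy > 0 else np.inf,
        success=bool(success),
    )


def _failed_donut() -> DonutFit:
    return DonutFit((np.nan, np.nan), np.nan, np.nan, np.nan, np.nan,
                    np.inf, np.inf, False)


def kde_center(
    points: np.ndarray,
    kde_grid_nm: float = 2.0,
    bandwidth_rule: str = "silverman",
    bandwidth_nm: float = 10.0,
) -> tuple[float, float, bool]:
    """Most-probable-position center of an event subset.

    Evaluates a bivariate Gaussian kernel density (per-axis Silverman
    bandwidth ``sigma_i n^(-1/6)`` by default) on a ``kde_grid_nm`` lattice
    over the padded bounding box and returns the probability-weighted
    centroid as ``(x_nm, y_nm, fallback)``.  With fewer than 5 events the
    arithmetic mean is returned with ``fallback=True``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("kde_center needs at least one event")
    if len(pts) < 5:
        m = pts.mean(axis=0)
        return float(m[0]), float(m[1]), True
    if bandwidth_rule == "silverman":
        h = pts.std(axis=0, ddof=1) * len(pts) ** (-1.0 / 6.0)
        h = np.maximum(h, kde_grid_nm)
    elif bandwidth_rule == "fixed":
        h = np.array([bandwidth_nm, bandwidth_nm])
    else:
        raise ValueError("bandwidth_rule must be 'silverman' or 'fixed'")
    pad = 3.0 * h.max()
    gx = np.arange(pts[:, 0].min() - pad, pts[:, 0].max() + pad, kde_grid_nm)
    gy = np.arange(pts[:, 1].min() - pad, pts[:, 1].max() + pad, kde_grid_nm)
    dens_x = np.exp(-0.5 * ((gx[None, :] - pts[:, 0][:, None]) / h[0]) ** 2)
    dens_y = np.exp(-0.5 * ((gy[None, :] - pts[:, 1][:, None]) / h[1]) ** 2)
    dens = dens_y.T @ dens_x  # (ny, nx) summed over events
    total = dens.sum()
    cx = float((dens.sum(axis=0) * gx).sum() / total)
    cy = float((dens.sum(axis=1) * gy).sum() / total)
    return cx, cy, False


def overlay_average(
    candidates: list[Candidate],
    fits: list[DonutFit],
    centers_nm: list[tuple[float, float]] | None = None,
    n_top: int = 50,
    pixel_nm: float = 10.0,
) -> np.ndarray:
    """Center and accumulate the best-fitting crops.

    Fits are ranked ascending by energy-normalized RSS; the ``n_top``
    survivors are each shifted (bilinear interpolation) so that their center
    — the KDE center when given, else the donut-fit center — lands on the
    crop midpoint, then summed.
    """
    ok = [i for i, f in enumerate(fits) if f.success]
    if not ok:
        raise ValueError("no successful donut fit to overlay")
    ok.sort(key=lambda i: fits[i].norm_rss)
    chosen = ok[:n_top]
    shape = candidates[chosen[0]].crop.shape
    mid = ((shape[1] / 2.0) * pixel_nm, (shape[0] / 2.0) * pixel_nm)
    acc = np.zeros(shape, dtype=float)
    for i in chosen:
        cen = centers_nm[i] if centers_nm is not None else fits[i].center_nm
        # positive shift moves content by +delta; we want center -> midpoint
        dx_px = (mid[0] - cen[0]) / pixel_nm
        dy_px = (mid[1] - cen[1]) / pixel_nm
        acc += ndimage.shift(candidates[i].crop.astype(float), (dy_px, dx_px),
                             order=1, mode="constant", cval=0.0)
    return acc


def estimate_diameter(overlay: np.ndarray, pixel_nm: float = 10.0,
                      multistart_r0_nm: tuple[float, ...] = (30.0, 50.0, 70.0)) -> float:
    """Pore diameter (nm) from a donut fit of the overlay: 2 r0."""
    fit = fit_donut(overlay, pixel_nm, multistart_r0_nm)
    if not fit.success:
        raise RuntimeError("donut fit of the overlay failed")
    return 2.0 * fit.ring_radius_nm


def average_pipeline(
    table: pd.DataFrame,
    params: NpcParams | None = None,
) -> dict:
    """Full selection -> per-candidate donut fit + KDE centering -> overlay -> diameter.

    Returns a dict with keys ``candidates``, ``fits``, ``centers_nm`` (crop-local),
    ``overlay``, ``diameter_nm`` and ``summary`` (a per-candidate DataFrame).
    """
    if params is None:
        params = NpcParams()
    binned = bin_pointcloud(table, params.bin_pixel_nm)
    candidates = select_candidates(binned, params)
    fits: list[DonutFit] = []
    centers: list[tuple[float, float]] = []
    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    for cand in candidates:
        fits.append(fit_donut(cand.crop, params.bin_pixel_nm, params.multistart_r0_nm))
        ox, oy = cand.crop_origin_px
        x_lo, x_hi = ox * params.bin_pixel_nm, (ox + params.roi_size_px) * params.bin_pixel_nm
        y_lo, y_hi = oy * params.bin_pixel_nm, (oy + params.roi_size_px) * params.bin_pixel_nm
        sel = (x >= x_lo) & (x < x_hi) & (y >= y_lo) & (y < y_hi)
        pts = np.column_stack([x[sel] - x_lo, y[sel] - y_lo])
        cx, cy, _ = kde_center(pts, params.kde_grid_nm, params.kde_bandwidth_rule,
                               params.kde_bandwidth_nm)
        centers.append((cx, cy))
    result: dict = {
        "candidates": candidates,
        "fits": fits,
        "centers_nm": centers,
        "overlay": None,
        "diameter_nm": np.nan,
    }
    ok = [i for i, f in enumerate(fits) if f.success]
    if ok:
        overlay = overlay_average(candidates, fits, centers, params.n_top, params.bin_pixel_nm)
        result["overlay"] = overlay
        result["diameter_nm"] = estimate_diameter(overlay, params.bin_pixel_nm,
                                                  params.multistart_r0_nm)
    order = sorted(range(len(fits)), key=lambda i: fits[i].norm_rss if fits[i].success else np.inf)
    ranks = {i: r for r, i in enumerate(order)}
    result["summary"] = pd.DataFrame(
        [
            dict(
                centroid_x_nm=c.centroid_nm[0],
                centroid_y_nm=c.centroid_nm[1],
                area_px=c.area_px,
                r0_nm=f.ring_radius_nm,
                sigma_r_nm=f.ring_width_nm,
                rss=f.rss,
                rank=ranks[i] if f.success else -1,
            )
            for i, (c, f) in enumerate(zip(candidates, fits))
        ]
    )
    return result
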