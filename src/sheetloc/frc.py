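"""Fourier ring correlation resolution estimation.

The event table is randomly split in half (seeded; a random event split
rather than odd/even frames, to avoid blinking-correlation bias — though
re-blinks of the same molecule landing in both halves can still bias FRC
optimistically).  Both halves are rendered as plain 2D histograms (no
Gaussian smoothing, which would inflate the correlation), Fourier
transformed, and correlated ring by ring:

    FRC(q) = Re sum_ring F1 conj(F2) / sqrt(sum_ring |F1|^2 sum_ring |F2|^2)

The resolution is 1/q* at the first downward crossing of the threshold
(fixed 1/7 by default, the standard criterion), linearly interpolated between
rings.  When the curve never crosses, the resolution is reported as twice the
render pixel with a "bound" flag: better than measurable at that sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FRCCurve", "frc_curve", "frc_two_halves", "frc_resolution", "frc_vs_accumulation"]

DEFAULT_THRESHOLD = 1.0 / 7.0
MIN_EVENTS = 100


@dataclass(frozen=True)
class FRCCurve:
    """Ring-wise correlation spectrum of two half-reconstructions."""

    spatial_frequency_nm_inv: np.ndarray  # ring centers, strictly increasing
    correlation: np.ndarray
    render_pixel_nm: float
    n_splits: int
    threshold: float = DEFAULT_THRESHOLD


def _render_histogram(x: np.ndarray, y: np.ndarray, x0: float, y0: float,
                      n: int, pixel: float) -> np.ndarray:
    edges = np.arange(n + 1) * pixel
    h, _, _ = np.histogram2d(y - y0, x - x0, bins=[edges, edges])
    return h


def _ring_sums(field: np.ndarray, rings: np.ndarray, n_rings: int) -> np.ndarray:
    return np.bincount(rings.ravel(), weights=field.ravel(), minlength=n_rings)[:n_rings]


def frc_curve(
    table: pd.DataFrame,
    render_pixel_nm: float = 10.0,
    n_splits: int = 5,
    seed: int = 0,
    split: bool = True,
    coords: tuple[str, str] = ("x_nm", "y_nm"),
) -> FRCCurve:
    """Average Fourier ring correlation over ``n_splits`` random half-splits.

    ``split=False`` correlates the full set against itself (FRC == 1), which
    is useful as an estimator self-check.
    """
    if len(table) < MIN_EVENTS:
        raise ValueError(f"FRC needs >= {MIN_EVENTS} events, got {len(table)}")
    x = table[coords[0]].to_numpy(dtype=float)
    y = table[coords[1]].to_numpy(dtype=float)
    x0, y0 = x.min(), y.min()
    span = max(x.max() - x0, y.max() - y0)
    n = int(np.ceil(span / render_pixel_nm)) + 1
    n += n % 2  # even grid

    qy = np.fft.fftfreq(n, d=render_pixel_nm)
    qx = np.fft.rfftfreq(n, d=render_pixel_nm)
    qr = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2)
    dq = 1.0 / (n * render_pixel_nm)
    rings = np.rint(qr / dq).astype(int)
    n_rings = n // 2  # up to Nyquist
    # rfft2 stores each |qx|>0 column once; double-count those to keep ring
    # sums equal to the full-plane FFT
    mult = np.full(qx.shape, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    mult2d = np.broadcast_to(mult, qr.shape)

    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_splits if split else 1):
        if split:
            half = rng.permutation(len(x)) < len(x) // 2
            x1, y1, x2, y2 = x[half], y[half], x[~half], y[~half]
        else:
            x1, y1, x2, y2 = x, y, x, y
        f1 = np.fft.rfft2(_render_histogram(x1, y1, x0, y0, n, render_pixel_nm))
        f2 = np.fft.rfft2(_render_histogram(x2, y2, x0, y0, n, render_pixel_nm))
        num = _ring_sums((f1 * np.conj(f2)).real * mult2d, rings, n_rings)
        d1 = _ring_sums(np.abs(f1) ** 2 * mult2d, rings, n_rings)
        d2 = _ring_sums(np.abs(f2) ** 2 * mult2d, rings, n_rings)
        denom = np.sqrt(d1 * d2)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves.append(np.where(denom > 0, num / denom, 0.0))
    corr = np.mean(curves, axis=0)
    q = np.arange(n_rings) * dq
    return FRCCurve(
        spatial_frequency_nm_inv=q[1:],  # drop the DC ring
        correlation=corr[1:],
        render_pixel_nm=render_pixel_nm,
        n_splits=n_splits if split else 1,
    )


def frc_two_halves(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    render_pixel_nm: float = 10.0,
    coords: tuple[str, str] = ("x_nm", "y_nm"),
) -> FRCCurve:
    """FRC between two explicitly given half-datasets (no internal splitting)."""
    x1 = table1[coords[0]].to_numpy(dtype=float)
    y1 = table1[coords[1]].to_numpy(dtype=float)
    x2 = table2[coords[0]].to_numpy(dtype=float)
    y2 = table2[coords[1]].to_numpy(dtype=float)
    x0 = min(x1.min(), x2.min())
    y0 = min(y1.min(), y2.min())
    span = max(max(x1.max(), x2.max()) - x0, max(y1.max(), y2.max()) - y0)
    n = int(np.ceil(span / render_pixel_nm)) + 1
    n += n % 2
    qy = np.fft.fftfreq(n, d=render_pixel_nm)
    qx = np.fft.rfftfreq(n, d=render_pixel_nm)
    qr = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2)
    dq = 1.0 / (n * render_pixel_nm)
    rings = np.rint(qr / dq).astype(int)
    n_rings = n // 2
    mult = np.full(qx.shape, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    mult2d = np.broadcast_to(mult, qr.shape)
    f1 = np.fft.rfft2(_render_histogram(x1, y1, x0, y0, n, render_pixel_nm))
    f2 = np.fft.rfft2(_render_histogram(x2, y2, x0, y0, n, render_pixel_nm))
    num = _ring_sums((f1 * np.conj(f2)).real * mult2d, rings, n_rings)
    d1 = _ring_sums(np.abs(f1) ** 2 * mult2d, rings, n_rings)
    d2 = _ring_sums(np.abs(f2) ** 2 * mult2d, rings, n_rings)
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    q = np.arange(n_rings) * dq
    return FRCCurve(q[1:], corr[1:], render_pixel_nm, 1)


def frc_resolution(curve: FRCCurve, smooth_rings: int = 0) -> tuple[float, bool]:
    """Resolution (nm) from the first downward threshold crossing.

    Returns ``(resolution_nm, bound)``; ``bound`` is True when the curve never
    crosses the threshold, in which case the value is the 2-pixel sampling
    limit (the data resolve everything measurable at this rendering).
    ``smooth_rings`` applies a moving average over that many rings first.
    """
    corr = curve.correlation
    if smooth_rings > 1:
        kernel = np.ones(smooth_rings) / smooth_rings
        corr = np.convolve(corr, kernel, mode="same")
    q = curve.spatial_frequency_nm_inv
    thr = curve.threshold
    below = np.nonzero((corr[1:] < thr) & (corr[:-1] >= thr))[0]
    if below.size == 0:
        return 2.0 * curve.render_pixel_nm, True
    i = int(below[0])
    frac = (corr[i] - thr) / (corr[i] - corr[i + 1])
    q_star = q[i] + frac * (q[i + 1] - q[i])
    return float(1.0 / q_star), False


def frc_vs_accumulation(
    table: pd.DataFrame,
    volume_boundaries: list[tuple[int, int]],
    render_pixel_nm: float = 10.0,
    n_splits: int = 5,
    seed: int = 0,
    checkpoints: list[int] | None = None,
) -> list[tuple[int, float]]:
    """Resolution versus number of accumulated volumes.

    ``volume_boundaries`` lists per-volume frame ranges ``[start, end)`` that
    partition the acquisition.  For each checkpoint k the events of the first
    k volumes are pooled and their FRC resolution computed; pooling more
    volumes adds events, so the curve should fall and then saturate.
    """
    frames = table["frame"].to_numpy()
    ks = checkpoints if checkpoints is not None else range(1, len(volume_boundaries) + 1)
    out = []
    for k in ks:
        end = volume_boundaries[k - 1][1]
        start = volume_boundaries[0][0]
        sub = table[(frames >= start) & (frames < end)]
        res, _ = frc_resolution(
            frc_curve(sub, render_pixel_nm, n_splits, seed=seed + k)
        )
        out.append((int(k), float(res)))
    return out
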