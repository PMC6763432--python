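"""Post-processing of single-molecule localization (PAINT) data.

The module starts from localization tables (frame, x_nm, y_nm) — spot
detection and fitting are upstream — and provides the reconstruction
chain: fiducial identification, LOESS drift estimation and correction,
2D-histogram rendering, radial cross-correlation colocalization sizing,
and trans-synaptic 1D profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DriftTrajectory",
    "RadialCorrCurve",
    "identify_fiducials",
    "estimate_drift_loess",
    "correct_drift",
    "render_histogram",
    "radial_cross_correlation",
    "transsynaptic_profile",
    "fit_gaussian_fwhm",
    "cross_section_fwhm",
    "FWHM_FACTOR",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.3548 sigma for a Gaussian


@dataclass(frozen=True)
class DriftTrajectory:
    """Per-frame rigid (dx, dy) drift in nm, zero at the reference frame."""

    frames: np.ndarray
    dx_nm: np.ndarray
    dy_nm: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.dx_nm) == len(self.dy_nm)):
            raise ValueError("trajectory arrays must have equal length")

    def at(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames)
        if frames.min(initial=0) < self.frames.min() or frames.max(initial=0) > self.frames.max():
            raise ValueError("frame outside drift trajectory domain")
        dx = np.interp(frames, self.frames, self.dx_nm)
        dy = np.interp(frames, self.frames, self.dy_nm)
        return np.column_stack([dx, dy])

    def negated(self) -> "DriftTrajectory":
        return DriftTrajectory(self.frames, -self.dx_nm, -self.dy_nm)


@dataclass(frozen=True)
class RadialCorrCurve:
    """Angle-averaged normalized cross-correlation vs radial shift.

    The no-correlation baseline is 1 (pair-correlation normalization by
    the product of channel means); ``decay_length_nm`` is the smallest
    radius where C(r) - 1 falls below (C(0) - 1) / e.
    """

    r_nm: np.ndarray
    values: np.ndarray
    decay_length_nm: float


def identify_fiducials(
    locs: pd.DataFrame, persistence_frac: float = 0.5, link_radius_nm: float = 100.0
) -> list[pd.DataFrame]:
    """Find persistently emitting particles (gold fiducials) in a localization table.

    Localizations are greedily linked frame to frame within
    ``link_radius_nm`` of a track's running position; tracks detected in at
    least ``persistence_frac`` of all frames are fiducials.  Transient
    PAINT binding events (lifetimes of a few frames) never qualify.
    """
    n_frames = int(locs["frame"].max()) + 1 if len(locs) else 0
    max_gap = 20  # frames a track may go dark before it stops being linkable
    active: list[dict] = []  # {"pos", "last", "frames", "xs", "ys"}
    finished: list[dict] = []
    for f, grp in locs.groupby("frame", sort=True):
        f = int(f)
        still = []
        for tr in active:
            if f - tr["last"] > max_gap:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        pts = grp[["x_nm", "y_nm"]].to_numpy()
        used = np.zeros(len(pts), dtype=bool)
        for tr in active:
            d = np.hypot(pts[:, 0] - tr["pos"][0], pts[:, 1] - tr["pos"][1])
            d[used] = np.inf
            j = int(np.argmin(d)) if len(d) else -1
            if j >= 0 and d[j] < link_radius_nm:
                used[j] = True
                tr["frames"].append(f)
                tr["xs"].append(pts[j, 0])
                tr["ys"].append(pts[j, 1])
                tr["pos"] = (pts[j, 0], pts[j, 1])
                tr["last"] = f
        for j in np.flatnonzero(~used):
            active.append(
                {
                    "pos": (pts[j, 0], pts[j, 1]),
                    "last": f,
                    "frames": [f],
                    "xs": [pts[j, 0]],
                    "ys": [pts[j, 1]],
                }
            )
    fiducials = [
        pd.DataFrame({"frame": tr["frames"], "x_nm": tr["xs"], "y_nm": tr["ys"]})
        for tr in finished + active
        if len(tr["frames"]) >= persistence_frac * n_frames
    ]
    if not fiducials:
        raise ValueError("no fiducials: no track persists long enough")
    return fiducials


def estimate_drift_loess(
    tracks: list[pd.DataFrame],
    n_frames: int | None = None,
    span: float = 0.1,
    min_track_frames: int = 10,
) -> DriftTrajectory:
    """Estimate per-frame drift by LOESS-smoothing fiducial trajectories.

    For each track, x(t) and y(t) are separately smoothed by locally
    weighted linear regression (tricube weights, span as a fraction of the
    frames); each smoothed curve is anchored to zero at the reference
    frame 0, the centered curves are averaged over tracks, and the average
    is interpolated to every frame.
    """
    kept = [t for t in tracks if len(t) >= min_track_frames]
    for t in tracks:
        if len(t) < min_track_frames:
            warnings.warn(f"excluding fiducial track covering only {len(t)} frames")
    if not kept:
        raise ValueError("no fiducial track covers enough frames")
    if n_frames is None:
        n_frames = int(max(t["frame"].max() for t in kept)) + 1
    frames = np.arange(n_frames)
    curves = []
    for t in kept:
        f = t["frame"].to_numpy(float)
        sx = lowess(t["x_nm"].to_numpy(), f, frac=span, return_sorted=True)
        sy = lowess(t["y_nm"].to_numpy(), f, frac=span, return_sorted=True)
        cx = np.interp(frames, sx[:, 0], sx[:, 1])
        cy = np.interp(frames, sy[:, 0], sy[:, 1])
        curves.append(np.column_stack([cx - cx[0], cy - cy[0]]))
    avg = np.mean(curves, axis=0)
    return DriftTrajectory(frames, avg[:, 0], avg[:, 1])


def correct_drift(locs: pd.DataFrame, trajectory: DriftTrajectory) -> pd.DataFrame:
    """Subtract the per-frame drift from every localization."""
    d = trajectory.at(locs["frame"].to_numpy())
    out = locs.copy()
    out["x_nm"] = locs["x_nm"].to_numpy() - d[:, 0]
    out["y_nm"] = locs["y_nm"].to_numpy() - d[:, 1]
    return out


def render_histogram(
    locs: pd.DataFrame,
    bin_nm: float = 5.4,
    smooth_sigma_bins: float = 1.0,
    extent_nm: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render a super-resolution image as a smoothed 2D localization histogram.

    Counts per ``bin_nm`` square bin, then Gaussian smoothing with
    ``smooth_sigma_bins``; the unsmoothed histogram mass equals the number
    of localizations.  Returns (image, (x0_nm, y0_nm)) where the origin is
    the lower edge of bin (0, 0); image axes are [y, x].
    """
    if len(locs) == 0:
        raise ValueError("empty localization table")
    x = locs["x_nm"].to_numpy()
    y = locs["y_nm"].to_numpy()
    if extent_nm is None:
        x0, x1 = x.min(), x.max() + bin_nm
        y0, y1 = y.min(), y.max() + bin_nm
    else:
        x0, x1, y0, y1 = extent_nm
    nx = max(int(np.ceil((x1 - x0) / bin_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_nm)), 1)
    hist, _, _ = np.histogram2d(
        y, x, bins=[ny, nx], range=[[y0, y0 + ny * bin_nm], [x0, x0 + nx * bin_nm]]
    )
    if smooth_sigma_bins > 0:
        img = gaussian_filter(hist, smooth_sigma_bins)
        lost = 1.0 - img.sum() / hist.sum()
        if lost > 1e-3:
            warnings.warn(f"{lost:.1%} of localization mass smoothed off the image edge")
    else:
        img = hist
    return img, (float(x0), float(y0))


def radial_cross_correlation(
    image_a: np.ndarray,
    image_b: np.ndarray,
    bin_nm: float,
    max_r_nm: float | None = None,
    bin_r_nm: float | None = None,
    decay_definition: str = "1/e",
) -> RadialCorrCurve:
    """Angle-averaged normalized cross-correlation of two rendered channels.

    C(r) = <A(x) B(x+r)> / (<A><B>), averaged over the displacement angle;
    statistically independent images give C = 1 at all r, and the decay
    length of C(r) - 1 measures the common structure size (for two
    perfectly overlapping channels, the object size; for apposed pre/post
    synaptic channels, the synapse scale).
    """
    A = np.asarray(image_a, float)
    B = np.asarray(image_b, float)
    if A.shape != B.shape:
        raise ValueError("images must share geometry")
    if A.sum() == 0 or B.sum() == 0:
        raise ValueError("empty image")
    if max_r_nm is None:
        max_r_nm = min(A.shape) * bin_nm / 4.0
    if bin_r_nm is None:
        bin_r_nm = bin_nm
    # full cross-correlation with per-shift overlap normalization
    corr = fftconvolve(A, B[::-1, ::-1], mode="full")
    ones = np.ones_like(A)
    overlap = fftconvolve(ones, ones, mode="full")
    mean_prod = corr / overlap
    C = mean_prod / (A.mean() * B.mean())

    h, w = A.shape
    cy, cx = h - 1, w - 1  # zero-shift position in the full correlation
    max_r_px = int(np.ceil(max_r_nm / bin_nm))
    yy, xx = np.mgrid[-max_r_px : max_r_px + 1, -max_r_px : max_r_px + 1]
    win = C[cy - max_r_px : cy + max_r_px + 1, cx - max_r_px : cx + max_r_px + 1]
    r = np.hypot(yy, xx) * bin_nm
    nbins = int(np.ceil(max_r_nm / bin_r_nm))
    idx = np.clip((r / bin_r_nm).astype(int), 0, nbins)
    sums = np.bincount(idx.ravel(), weights=win.ravel(), minlength=nbins + 1)
    counts = np.bincount(idx.ravel(), minlength=nbins + 1)
    values = (sums / np.maximum(counts, 1))[:nbins]
    r_centers = (np.arange(nbins) + 0.5) * bin_r_nm
    r_centers[0] = 0.0  # first bin contains the zero shift

    c0 = values[0] - 1.0
    if c0 <= 0:
        decay = float("nan")
    else:
        target = c0 / np.e if decay_definition == "1/e" else c0 / 2.0
        below = np.flatnonzero(values - 1.0 < target)
        decay = float(r_centers[below[0]]) if len(below) else float(r_centers[-1])
    return RadialCorrCurve(r_nm=r_centers, values=values, decay_length_nm=decay)


def _gauss(x, a, mu, sig, c):
    return a * np.exp(-((x - mu) ** 2) / (2 * sig**2)) + c


def fit_gaussian_fwhm(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Fit a Gaussian to a 1D histogram; return (mu, FWHM)."""
    centers = np.asarray(centers, float)
    counts = np.asarray(counts, float)
    mu0 = float(np.average(centers, weights=np.maximum(counts, 0) + 1e-12))
    sig0 = float(
        np.sqrt(np.average((centers - mu0) ** 2, weights=np.maximum(counts, 0) + 1e-12))
    )
    try:
        popt, _ = curve_fit(
            _gauss,
            centers,
            counts,
            p0=[counts.max(), mu0, max(sig0, 1e-6), 0.0],
            maxfev=10000,
        )
        mu, sig = popt[1], abs(popt[2])
    except RuntimeError:
        mu, sig = mu0, sig0
    return float(mu), float(FWHM_FACTOR * sig)


def cross_section_fwhm(
    image: np.ndarray,
    origin_nm: float,
    bin_nm: float,
    smooth_sigma_bins: float = 1.0,
    axis: int = 0,
) -> float:
    """Gaussian-fit FWHM of a rendered structure's cross-section, in nm.

    Collapses the image along ``axis`` (the structure's long axis), fits a
    Gaussian to the resulting profile, and removes the known rendering
    kernel — the Gaussian smoothing and the bin-integration variance
    (``bin_nm^2 / 12``) — in quadrature, so the returned FWHM estimates
    the underlying structure, not the rendering.
    """
    profile = np.asarray(image, float).sum(axis=axis)
    centers = origin_nm + (np.arange(len(profile)) + 0.5) * bin_nm
    _, fwhm_raw = fit_gaussian_fwhm(centers, profile)
    sig2 = (fwhm_raw / FWHM_FACTOR) ** 2
    kernel2 = (smooth_sigma_bins * bin_nm) ** 2 + bin_nm**2 / 12.0
    sig2_true = max(sig2 - kernel2, 0.0)
    return float(FWHM_FACTOR * np.sqrt(sig2_true))


def transsynaptic_profile(
    locs_by_channel: dict[str, pd.DataFrame],
    center_nm: tuple[float, float],
    axis_angle_rad: float,
    length_nm: float,
    width_nm: float,
    bin_nm: float = 10.0,
    min_locs_for_fwhm: int = 20,
) -> pd.DataFrame:
    """Project localizations in an oriented box onto the trans-synaptic axis.

    The box is centered at ``center_nm`` with its long axis (``length_nm``)
    at ``axis_angle_rad``; localizations inside are projected onto the
    axis (coordinate 0 at the box center).  Per channel the function
    returns the median axial position and, when enough localizations are
    present, the Gaussian-fit FWHM of the axial histogram.
    """
    ax = np.array([np.cos(axis_angle_rad), np.sin(axis_angle_rad)])
    perp = np.array([-ax[1], ax[0]])
    c = np.asarray(center_nm, float)
    rows = []
    for ch, locs in locs_by_channel.items():
        xy = locs[["x_nm", "y_nm"]].to_numpy() - c[None, :]
        u = xy @ ax
        v = xy @ perp
        inside = (np.abs(u) <= length_nm / 2) & (np.abs(v) <= width_nm / 2)
        ui = u[inside]
        if len(ui) == 0:
            rows.append({"channel": ch, "n": 0, "median_nm": np.nan, "fwhm_nm": np.nan})
            continue
        median = float(np.median(ui))
        if len(ui) >= min_locs_for_fwhm:
            edges = np.arange(-length_nm / 2, length_nm / 2 + bin_nm, bin_nm)
            counts, edges = np.histogram(ui, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            _, fwhm = fit_gaussian_fwhm(centers, counts)
        else:
            fwhm = np.nan
        rows.append({"channel": ch, "n": int(len(ui)), "median_nm": median, "fwhm_nm": fwhm})
    return pd.DataFrame(rows, columns=["channel", "n", "median_nm", "fwhm_nm"])
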