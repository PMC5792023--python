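"""Focus detection, 2-D Gaussian fitting and ROI intensity trajectories.

A focus is a diffraction-limited spot fitted with an elliptical Gaussian
plus a constant background over a small window; its integrated intensity is
the volume under the fitted Gaussian, ``2*pi*A*sigma_x*sigma_y`` (sigmas in
pixels, amplitude in a.u. per pixel).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .geometry import CellOutline
from .stack import MovieStack

__all__ = [
    "Focus", "IntensityTrajectory", "detect_peaks", "fit_gaussian_2d",
    "local_background_correct", "extract_trajectory", "foci_density",
    "foci_per_cell", "detect_and_fit", "write_focus_csv",
]


@dataclass
class Focus:
    """One fitted fluorescent spot."""

    x_nm: float
    y_nm: float
    sigma_x_nm: float
    sigma_y_nm: float
    amplitude: float               # a.u. per pixel
    background: float              # a.u. per pixel
    integrated_au: float           # 2*pi*A*sx*sy with sigmas in px
    residual: float
    pixel_size_nm: float
    channel: str = ""
    cell_id: Optional[int] = None
    frame: int = 0
    time_s: float = 0.0
    status: str = "ok"

    @property
    def accepted(self) -> bool:
        return self.status == "ok"


@dataclass
class IntensityTrajectory:
    """Background-corrected ROI intensity versus time at a fixed position."""

    times_s: np.ndarray
    intensities_au: np.ndarray
    center_nm: tuple
    roi_px: int = 5
    channel: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)
        if self.times_s.shape != self.intensities_au.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_peaks(
    image: np.ndarray,
    pixel_size_nm: float,
    min_separation_nm: float = 300.0,
    threshold_sd: float = 5.0,
    mask: Optional[np.ndarray] = None,
    psf_sigma_px: float = 1.3,
) -> np.ndarray:
    """Candidate focus positions (row, col pixel indices), brightest first.

    The image is band-pass filtered (difference of Gaussians around the PSF
    scale); local maxima above ``median + threshold_sd * robust SD`` of the
    filtered image (statistics restricted to ``mask`` when given) are kept,
    and maxima closer than ``min_separation_nm`` are merged keeping the
    brighter one.
    """
    img = np.asarray(image, dtype=float)
    filt = difference_of_gaussians(img, low_sigma=psf_sigma_px * 0.7,
                                   high_sigma=psf_sigma_px * 2.5)
    stat = filt[mask] if mask is not None else filt.ravel()
    thr = float(np.median(stat)) + threshold_sd * _robust_sd(stat)
    min_sep_px = max(1, int(round(min_separation_nm / pixel_size_nm)))
    peaks = peak_local_max(filt, min_distance=1, threshold_abs=thr,
                           exclude_border=False)
    if mask is not None and peaks.size:
        peaks = peaks[mask[peaks[:, 0], peaks[:, 1]]]
    if peaks.size == 0:
        return np.zeros((0, 2), dtype=int)
    order = np.argsort(-filt[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= min_sep_px for q in kept):
            kept.append(p)
    return np.array(kept, dtype=int)


def _gauss_model(params, jj, ii):
    a, px, py, sx, sy, bg = params
    return bg + a * np.exp(-((jj + 0.5 - px) ** 2 / (2 * sx * sx)
                             + (ii + 0.5 - py) ** 2 / (2 * sy * sy)))


def fit_gaussian_2d(
    image: np.ndarray,
    candidate: tuple,
    pixel_size_nm: float,
    window_px: int = 9,
    channel: str = "",
    frame: int = 0,
    time_s: float = 0.0,
    sigma_bounds_px: tuple = (0.5, 4.0),
) -> Focus:
    """Least-squares elliptical Gaussian + constant background over a window.

    ``candidate`` is a (row, col) pixel position.  The focus is marked
    rejected (with a reason in ``status``) when the window is clipped by the
    image edge, the fit does not converge, a fitted sigma falls outside
    ``sigma_bounds_px``, or the amplitude is consistent with zero.
    """
    if window_px < 7:
        raise ValueError("window_px must be >= 7")
    img = np.asarray(image, dtype=float)
    r, c = int(candidate[0]), int(candidate[1])
    half = window_px // 2

    def rejected(reason: str) -> Focus:
        return Focus(x_nm=(c + 0.5) * pixel_size_nm,
                     y_nm=(r + 0.5) * pixel_size_nm,
                     sigma_x_nm=np.nan, sigma_y_nm=np.nan, amplitude=np.nan,
                     background=np.nan, integrated_au=np.nan, residual=np.nan,
                     pixel_size_nm=pixel_size_nm, channel=channel,
                     frame=frame, time_s=time_s, status=f"rejected:{reason}")

    if (r - half < 0 or c - half < 0 or r + half + 1 > img.shape[0]
            or c + half + 1 > img.shape[1]):
        return rejected("window clipped by image edge")
    win = img[r - half:r + half + 1, c - half:c + half + 1]
    ii, jj = np.meshgrid(np.arange(r - half, r + half + 1),
                         np.arange(c - half, c + half + 1), indexing="ij")
    bg0 = float(win.min())
    a0 = max(float(win.max()) - bg0, 1e-6)
    p0 = [a0, c + 0.5, r + 0.5, 1.3, 1.3, bg0]
    lo = [0.0, c - half, r - half, 0.3, 0.3, -np.inf]
    hi = [np.inf, c + half + 1, r + half + 1, 6.0, 6.0, np.inf]
    try:
        res = least_squares(
            lambda p: (_gauss_model(p, jj, ii) - win).ravel(), p0,
            bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    except Exception:
        return rejected("fit failed")
    if not res.success:
        return rejected("no convergence")
    a, px, py, sx, sy, bg = res.x
    rss = float(res.cost * 2.0)
    m = win.size
    dof = max(m - 6, 1)
    s2 = rss / dof
    # amplitude uncertainty from the Jacobian at the solution
    try:
        jtj = res.jac.T @ res.jac
        cov = s2 * np.linalg.pinv(jtj)
        a_se = float(np.sqrt(max(cov[0, 0], 0.0)))
    except Exception:
        a_se = np.inf
    if a <= 1e-6 * max(1.0, abs(bg)) or (a_se > 0 and a < 3.0 * a_se):
        return rejected("amplitude consistent with zero")
    if not (sigma_bounds_px[0] <= sx <= sigma_bounds_px[1]
            and sigma_bounds_px[0] <= sy <= sigma_bounds_px[1]):
        return rejected("sigma outside bounds")
    return Focus(
        x_nm=px * pixel_size_nm, y_nm=py * pixel_size_nm,
        sigma_x_nm=sx * pixel_size_nm, sigma_y_nm=sy * pixel_size_nm,
        amplitude=float(a), background=float(bg),
        integrated_au=float(2.0 * np.pi * a * sx * sy),
        residual=np.sqrt(s2), pixel_size_nm=pixel_size_nm,
        channel=channel, frame=frame, time_s=time_s,
    )


def local_background_correct(
    image: np.ndarray,
    center: tuple,
    roi_px: int = 5,
    ring_px: int = 2,
) -> tuple[float, float]:
    """Background level and background-corrected ROI intensity.

    The background is the mean within a ``ring_px``-wide square ring
    immediately outside the ``roi_px`` x ``roi_px`` box centred on
    ``center`` (row, col); the corrected intensity is the ROI sum minus
    background times the ROI pixel count.
    """
    if roi_px % 2 == 0:
        raise ValueError("roi_px must be odd")
    img = np.asarray(image, dtype=float)
    r, c = int(round(center[0])), int(round(center[1]))
    hr = roi_px // 2
    ho = hr + ring_px
    if (r - ho < 0 or c - ho < 0 or r + ho + 1 > img.shape[0]
            or c + ho + 1 > img.shape[1]):
        raise ValueError("background ring clipped by image edge")
    outer = img[r - ho:r + ho + 1, c - ho:c + ho + 1]
    inner = img[r - hr:r + hr + 1, c - hr:c + hr + 1]
    ring_sum = outer.sum() - inner.sum()
    ring_n = outer.size - inner.size
    bg = float(ring_sum / ring_n)
    corrected = float(inner.sum() - bg * inner.size)
    return bg, corrected


def extract_trajectory(
    stack: MovieStack,
    position_nm: tuple,
    roi_px: int = 5,
    ring_px: int = 2,
    channel: Optional[str] = None,
) -> IntensityTrajectory:
    """Background-corrected ROI intensity at a fixed position, per frame."""
    c = int(position_nm[0] / stack.pixel_size_nm)
    r = int(position_nm[1] / stack.pixel_size_nm)
    vals = np.empty(stack.n_frames)
    for f in range(stack.n_frames):
        _, vals[f] = local_background_correct(stack.data[f], (r, c),
                                              roi_px=roi_px, ring_px=ring_px)
    return IntensityTrajectory(
        times_s=stack.timestamps_s, intensities_au=vals,
        center_nm=(float(position_nm[0]), float(position_nm[1])),
        roi_px=roi_px, channel=channel or stack.channel)


def foci_density(foci: list, outline: CellOutline) -> float:
    """Number of foci per um^2 of cell area."""
    if outline.area_um2 <= 0:
        raise ValueError("cell area must be positive")
    return len(foci) / outline.area_um2


def foci_per_cell(foci: list, outlines: list) -> dict:
    """Assign foci to cells by centroid and summarise counts per cell.

    Masks must partition (no overlaps); foci outside every mask are dropped
    and counted in ``n_unassigned``.  Returns counts, mean and SEM.
    """
    if outlines:
        total = np.zeros(outlines[0].mask.shape, dtype=np.int32)
        for o in outlines:
            total += o.mask
        if (total > 1).any():
            raise ValueError("cell masks overlap; they must partition")
    counts = {o.cell_id: 0 for o in outlines}
    unassigned = 0
    for f in foci:
        hit = None
        for o in outlines:
            if o.contains_nm(f.x_nm, f.y_nm):
                hit = o.cell_id
                break
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
            if isinstance(f, Focus):
                f.cell_id = hit
    vals = np.array(list(counts.values()), dtype=float)
    n = vals.size
    mean = float(vals.mean()) if n else 0.0
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return {"counts": counts, "mean": mean, "sem": sem, "n_cells": n,
            "n_unassigned": unassigned}


def detect_and_fit(
    image: np.ndarray,
    pixel_size_nm: float,
    mask: Optional[np.ndarray] = None,
    min_separation_nm: float = 300.0,
    threshold_sd: float = 5.0,
    window_px: int = 9,
    psf_sigma_px: float = 1.3,
    channel: str = "",
    frame: int = 0,
    time_s: float = 0.0,
) -> list[Focus]:
    """Detection followed by per-candidate Gaussian fitting."""
    cands = detect_peaks(image, pixel_size_nm,
                         min_separation_nm=min_separation_nm,
                         threshold_sd=threshold_sd, mask=mask,
                         psf_sigma_px=psf_sigma_px)
    return [fit_gaussian_2d(image, tuple(p), pixel_size_nm,
                            window_px=window_px, channel=channel,
                            frame=frame, time_s=time_s) for p in cands]


def write_focus_csv(foci: list, path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame([{
        "frame": f.frame, "time_s": f.time_s, "channel": f.channel,
        "cell_id": -1 if f.cell_id is None else f.cell_id,
        "x_nm": f.x_nm, "y_nm": f.y_nm,
        "sigma_x_nm": f.sigma_x_nm, "sigma_y_nm": f.sigma_y_nm,
        "amplitude": f.amplitude, "background": f.background,
        "integrated_au": f.integrated_au, "status": f.status,
    } for f in foci])
    df.to_csv(path, index=False)
    return df
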